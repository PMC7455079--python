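"""Reading and writing of the pipeline's tabular carriers.

Expression matrices travel as TSV with genes in rows (first column = gene
identifier, header row = sample identifiers, values = log2 expression).
Sample metadata travels as CSV with one row per sample and a ``sample_id``
column. Both readers validate identifier uniqueness and numeric content so
that downstream stages can assume clean input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: metadata columns that must be 0/1 flags when present
FLAG_COLUMNS = (
    "is_control",
    "dsdna", "rnp", "sm", "ssa", "ssb",
    "c3_low", "c4_low",
    "corticosteroids", "antimalarials", "nsaids", "aza", "mtx", "mmf",
    "cyclophosphamide",
    "rash", "arthritis", "mucosal_ulcers", "vasculitis", "alopecia",
    "age_gt50",
)

DURATION_CATEGORIES = ("le1y", "1_5y", "5_10y", "gt10y")


def _check_unique(values, what: str) -> None:
    dup = pd.Index(values)[pd.Index(values).duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate {what}: {', '.join(map(str, dup[:5]))}")


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples log2 expression TSV.

    Raises ``ValueError`` on duplicate gene/sample identifiers and reports
    the (gene, sample) coordinate of any non-numeric cell.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample identifiers")  # pandas would mangle them
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "gene identifiers")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}: {df.iloc[g, s]!r}"
        )
    return coerced.astype(float)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata CSV indexed by ``sample_id``."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: metadata requires a 'sample_id' column")
    _check_unique(df["sample_id"], "sample identifiers")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    for col in FLAG_COLUMNS:
        if col in df.columns:
            vals = set(pd.unique(df[col].dropna()))
            if not vals <= {0, 1, True, False}:
                raise ValueError(f"metadata column {col!r} is not binary: {vals}")
            df[col] = df[col].astype(int)
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index_label="sample_id")


def check_sample_concordance(expr: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Require expression columns and metadata rows to name the same samples."""
    e, m = set(expr.columns), set(metadata.index)
    if e != m:
        missing = sorted(e ^ m)
        raise ValueError(
            "expression and metadata sample identifiers differ; "
            f"symmetric difference: {', '.join(missing[:10])}"
        )
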