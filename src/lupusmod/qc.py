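"""Transcriptome-based sex inference for sample QC.

The sex-module score is a fixed linear contrast of five sex-chromosome
genes on the log2 scale:

    score = XIST + TSIX - (UTY + RPS4Y1 + USP9Y)

Samples scoring above zero are inferred female, below zero male, and exactly
zero indeterminate. A discordance report flags samples whose inferred sex
disagrees with the recorded metadata sex.
"""

from __future__ import annotations

import pandas as pd

X_GENES = ("XIST", "TSIX")
Y_GENES = ("UTY", "RPS4Y1", "USP9Y")
SEX_GENES = X_GENES + Y_GENES


def _resolve_genes(expr: pd.DataFrame, alias: dict[str, str] | None) -> dict[str, str]:
    """Case-insensitive lookup of the 5 sex genes, via an optional alias map
    (canonical symbol -> row identifier, e.g. a probe id)."""
    lower = {str(g).lower(): g for g in expr.index}
    alias = {k.upper(): v for k, v in (alias or {}).items()}
    resolved, missing = {}, []
    for gene in SEX_GENES:
        target = alias.get(gene, gene)
        row = lower.get(str(target).lower())
        if row is None:
            missing.append(gene)
        else:
            resolved[gene] = row
    if missing:
        raise ValueError(f"sex gene(s) absent from expression matrix: "
                         f"{', '.join(missing)}")
    return resolved


def sex_module_score(
    expr: pd.DataFrame, alias: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-sample sex score and inferred sex (F > 0, M < 0, indeterminate = 0)."""
    rows = _resolve_genes(expr, alias)
    score = (expr.loc[rows["XIST"]] + expr.loc[rows["TSIX"]]
             - (expr.loc[rows["UTY"]] + expr.loc[rows["RPS4Y1"]]
                + expr.loc[rows["USP9Y"]]))
    inferred = score.apply(lambda s: "F" if s > 0 else ("M" if s < 0
                                                        else "indeterminate"))
    return pd.DataFrame({"score": score.astype(float), "inferred_sex": inferred})


def sex_discordance_report(
    scores: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Join inferred sex against metadata ``sex`` and flag mismatches."""
    if "sex" not in metadata.columns:
        raise ValueError("metadata lacks a 'sex' column")
    out = scores.copy()
    out["reported_sex"] = metadata["sex"].reindex(scores.index)
    out["concordant"] = out["inferred_sex"] == out["reported_sex"]
    return out
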