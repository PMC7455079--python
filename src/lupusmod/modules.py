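"""Gene-module registry: GMT I/O, overlap bookkeeping, SNOR derivation.

A *module* is a named, ordered set of gene identifiers representing a
hematopoietic cell type (plasma cell, LDG, ...) or process (cell cycle,
inflammasome, ...). Collections of modules are carried in the standard GMT
format (one tab-separated line per set: name, description, genes).

``derive_snor_modules`` implements the rule used to construct the two SNOR
sets: among SLE samples whose first principal component falls inside the
healthy-control PC1 range (i.e. patients that PCA does not separate from
controls), run a moderated-t comparison against the controls and keep the
``n_top`` most increased and most decreased transcripts at a stringent FDR.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GeneModule:
    """A named gene set. Genes keep their given order and must be unique."""

    name: str
    description: str = ""
    genes: tuple[str, ...] = ()

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"module {self.name!r} contains duplicate genes")
        if not self.genes:
            warnings.warn(f"module {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


class ModuleCollection:
    """An ordered collection of uniquely named gene modules."""

    def __init__(self, modules: Iterable[GeneModule], universe: set[str] | None = None):
        self.modules: list[GeneModule] = list(modules)
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate module names: {', '.join(dup)}")
        if universe is not None:
            universe = set(universe)
            for m in self.modules:
                extra = set(m.genes) - universe
                if extra:
                    raise ValueError(
                        f"module {m.name!r} has genes outside the universe: "
                        f"{', '.join(sorted(extra)[:5])}"
                    )
        self.universe = universe

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.modules]

    def gene_union(self) -> set[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= set(m.genes)
        return out

    def __iter__(self) -> Iterator[GeneModule]:
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def __getitem__(self, name: str) -> GeneModule:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __eq__(self, other) -> bool:
        return isinstance(other, ModuleCollection) and self.modules == other.modules


def read_gmt(path) -> ModuleCollection:
    """Parse a GMT file (name, description, >=1 gene per tab-separated line).

    Duplicate genes within a line are dropped (keeping first occurrence) with
    a warning; malformed lines and duplicate module names raise ``ValueError``
    naming the offending line.
    """
    modules = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    warnings.warn(
                        f"{path}: line {lineno}: duplicate gene {g!r} in module "
                        f"{name!r} dropped"
                    )
                seen.setdefault(g)
            modules.append(GeneModule(name, desc, tuple(seen)))
    return ModuleCollection(modules)


def write_gmt(collection: ModuleCollection, path) -> None:
    with open(path, "w") as fh:
        for m in collection:
            fh.write("\t".join([m.name, m.description, *m.genes]) + "\n")


def module_overlap_matrix(collection: ModuleCollection) -> pd.DataFrame:
    """Square table of shared-gene counts (diagonal = module sizes)."""
    if len(collection) == 0:
        raise ValueError("empty module collection")
    names = collection.names
    sets = [set(m.genes) for m in collection]
    out = np.zeros((len(sets), len(sets)), dtype=int)
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            out[i, j] = len(a & b)
    return pd.DataFrame(out, index=names, columns=names)


def _pc_coordinates(x: np.ndarray, n_components: int) -> np.ndarray:
    """Sample coordinates on the top principal components of a genes x samples
    matrix (covariance scaling: genes centered, no variance rescaling)."""
    centered = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    return (vt[:n_components] * s[:n_components, None]).T  # samples x k


def derive_snor_modules(
    expr: pd.DataFrame,
    hc_ids: Sequence[str],
    sle_ids: Sequence[str],
    n_top: int = 7,
    fdr_cut: float = 0.005,
    n_components: int = 1,
    up_name: str = "snor_up_low",
    down_name: str = "snor_down_low",
) -> tuple[GeneModule, GeneModule, dict]:
    """Derive the two SNOR gene sets from an expression matrix.

    Returns ``(up_module, down_module, provenance)`` where provenance records
    the selected (PCA-non-separating) SLE sample IDs and parameters. If fewer
    than ``n_top`` transcripts pass the FDR cut in a direction, the shorter
    list is returned with a warning — never padded.
    """
    from .de import moderated_t_test

    hc_ids, sle_ids = list(hc_ids), list(sle_ids)
    if not hc_ids or not sle_ids:
        raise ValueError("both HC and SLE sample sets must be non-empty")
    if set(hc_ids) & set(sle_ids):
        raise ValueError("HC and SLE sample sets must be disjoint")

    # order-invariance: fix column order by sorted sample id before PCA
    cols = sorted(hc_ids) + sorted(sle_ids)
    pcs = _pc_coordinates(expr[cols].to_numpy(float), n_components)
    n_hc = len(hc_ids)
    lo = pcs[:n_hc].min(axis=0)
    hi = pcs[:n_hc].max(axis=0)
    inside = np.all((pcs[n_hc:] >= lo) & (pcs[n_hc:] <= hi), axis=1)
    selected = [s for s, keep in zip(sorted(sle_ids), inside) if keep]

    provenance = {
        "n_top": n_top,
        "fdr_cut": fdr_cut,
        "n_components": n_components,
        "selected_sle_ids": selected,
        "n_hc": n_hc,
    }
    if len(selected) < 2:
        warnings.warn("fewer than 2 SLE samples within the HC PC range; "
                      "returning empty SNOR modules")
        return (GeneModule(up_name, "derived", ()),
                GeneModule(down_name, "derived", ()), provenance)

    de = moderated_t_test(expr, selected, hc_ids)
    sig = de[de["q"] < fdr_cut]
    up = sig[sig["log2fc"] > 0].sort_values("log2fc", ascending=False).head(n_top)
    down = sig[sig["log2fc"] < 0].sort_values("log2fc").head(n_top)
    if len(up) < n_top or len(down) < n_top:
        warnings.warn(
            f"only {len(up)} increased / {len(down)} decreased transcripts pass "
            f"FDR < {fdr_cut}; returning unpadded modules"
        )
    desc = f"derived: top {n_top} by fold change at FDR<{fdr_cut}"
    return (GeneModule(up_name, desc, tuple(up.index)),
            GeneModule(down_name, desc, tuple(down.index)), provenance)


def write_snor_provenance(provenance: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(provenance, fh, indent=2)
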