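"""Single-sample module enrichment via kernel-CDF gene statistics and a
Kolmogorov–Smirnov-like random walk, scores normalized to [-1, +1].

The two-stage procedure, applied to a genes x samples log2 expression matrix:

1. **Gene-level statistic.** For gene *i* in sample *j*,
   ``z(i, j) = sum_k Phi((x_ij - x_ik) / h_i)`` where Phi is the standard
   Gaussian CDF and the per-gene bandwidth is ``h_i = s_i / 4`` (``s_i`` the
   sample SD of gene *i*). This is a smoothed within-gene rank of sample *j*
   against the cohort: monotone in the expression value and invariant to
   per-gene location/scale shifts.

2. **KS-like walk.** Per sample, genes are ranked by ``z`` descending; the
   symmetric rank statistic ``r_i = |N/2 - rank_i|`` up-weights genes in the
   tails. Walking down the ranked list, module genes add
   ``r_i^tau / sum_{g in G} r_g^tau`` and non-module genes subtract
   ``1/(N - m)``. The score is the sum of the largest positive and largest
   negative deviations of this walk from zero (each taken as zero when the
   walk never crosses that side), which keeps the statistic bounded in
   [-1, +1]; the single-extreme deviation is available as
   ``mode="extreme"``.

Ties in ``z`` are broken by gene-identifier lexicographic order, so scores
are invariant to row permutation of the input.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .modules import ModuleCollection

#: bandwidth floor for zero-variance genes (keeps the gene universe intact)
BANDWIDTH_FLOOR = 1e-8


def gene_level_cdf_stats(expr: pd.DataFrame, chunk: int = 512) -> pd.DataFrame:
    """Gaussian-kernel CDF statistic ``z(i, j)`` per gene and sample.

    Requires >=2 samples. Genes with zero sample variance get the bandwidth
    floor (a warning lists them) rather than being excluded, so the gene
    universe is identical across samples.
    """
    if expr.shape[1] < 2:
        raise ValueError("gene-level CDF statistics require >=2 samples")
    x = expr.to_numpy(float)
    sd = x.std(axis=1, ddof=1)
    flat = sd <= 0
    if flat.any():
        names = list(expr.index[flat][:10])
        warnings.warn(
            f"{int(flat.sum())} gene(s) with zero variance assigned bandwidth "
            f"floor {BANDWIDTH_FLOOR:g}: {', '.join(names)}"
        )
    h = np.where(flat, BANDWIDTH_FLOOR, sd / 4.0)
    z = np.empty_like(x)
    for start in range(0, x.shape[0], chunk):  # chunk genes to bound memory
        sl = slice(start, min(start + chunk, x.shape[0]))
        diff = (x[sl, :, None] - x[sl, None, :]) / h[sl, None, None]
        z[sl] = ndtr(diff).sum(axis=2)
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def module_enrichment_scores(
    stats: pd.DataFrame,
    modules: ModuleCollection,
    tau: float = 1.0,
    mode: str = "diff",
) -> pd.DataFrame:
    """KS-like walk scores (modules x samples) from a gene-statistic matrix.

    Parameters
    ----------
    stats : genes x samples statistic matrix from :func:`gene_level_cdf_stats`.
    tau : exponent on the symmetric rank statistic (1 = standard weighting).
    mode : ``"diff"`` (max positive + max negative walk deviation, default) or
        ``"extreme"`` (the single deviation of largest magnitude).

    Module genes absent from the matrix are dropped with a warning; a module
    with zero measured genes is omitted from the result (with a warning), and
    a module spanning the whole gene universe is an error (the walk's
    complement term is undefined).
    """
    if mode not in ("diff", "extreme"):
        raise ValueError(f"unknown mode {mode!r}")
    z = stats.sort_index()  # lexicographic gene order for deterministic ties
    arr = z.to_numpy(float)
    n_genes, n_samples = arr.shape
    # per-sample descending-z order; 'stable' keeps the lexicographic tie-break
    order = np.argsort(-arr, axis=0, kind="stable")
    # |N/2 - rank| at walk position l is rank-determined: same for all samples
    rsym = np.abs(n_genes / 2.0 - np.arange(1, n_genes + 1)) ** tau

    gene_pos = {g: i for i, g in enumerate(z.index)}
    out = np.full((len(modules), n_samples), np.nan)
    kept_rows = []
    for mi, module in enumerate(modules):
        idx = [gene_pos[g] for g in module.genes if g in gene_pos]
        missing = len(module.genes) - len(idx)
        if missing:
            warnings.warn(
                f"module {module.name!r}: {missing} gene(s) absent from the "
                "expression matrix were dropped"
            )
        m = len(idx)
        if m == 0:
            warnings.warn(f"module {module.name!r} has no measured genes; omitted")
            continue
        if m == n_genes:
            raise ValueError(
                f"module {module.name!r} spans the entire gene universe; "
                "the random walk is undefined"
            )
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        mask_sorted = mask[order]  # positions x samples
        num = np.cumsum(rsym[:, None] * mask_sorted, axis=0)
        denom = num[-1]  # sum of r^tau over module genes, per sample
        with np.errstate(invalid="ignore", divide="ignore"):
            inside = np.where(denom > 0, num / denom, 0.0)
        walk = inside - np.cumsum(~mask_sorted, axis=0) / (n_genes - m)
        if mode == "diff":
            # largest positive plus largest negative deviation, each clipped
            # at zero so an all-one-sided walk contributes a single extreme
            out[mi] = (np.maximum(walk.max(axis=0), 0.0)
                       + np.minimum(walk.min(axis=0), 0.0))
        else:
            ext = np.take_along_axis(
                walk, np.abs(walk).argmax(axis=0)[None, :], axis=0
            )
            out[mi] = ext[0]
        kept_rows.append(mi)
    return pd.DataFrame(
        out[kept_rows],
        index=[modules.names[i] for i in kept_rows],
        columns=z.columns,
    )


def score_modules(
    expr: pd.DataFrame,
    modules: ModuleCollection,
    tau: float = 1.0,
    mode: str = "diff",
) -> pd.DataFrame:
    """Convenience composition: expression -> gene stats -> enrichment scores."""
    return module_enrichment_scores(gene_level_cdf_stats(expr), modules, tau, mode)
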