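"""Two-group differential expression with empirical-Bayes variance
moderation, BH FDR control, a randomized-split null check, and Fisher's-exact
gene-list overlap statistics.

The moderated t follows the standard empirical-Bayes recipe for microarray
data: per-gene pooled variances ``s_g^2`` on ``d`` residual df are shrunk
toward a global prior ``s0^2`` with prior df ``d0`` estimated by moment
matching the scaled log-variance distribution against a log-F (digamma /
trigamma closed forms), giving the posterior
``s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d)`` and a t statistic on ``d0 + d``
degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-10:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled-F prior from observed variances.

    Returns ``(d0, s0_squared)``; ``d0 = inf`` when the between-gene spread of
    log-variances is no larger than the trigamma(df/2) sampling noise.
    """
    s2 = np.asarray(s2, float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need >=2 positive gene variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0, s02 = np.inf, float(np.exp(emean))
    return float(d0), float(s02)


def moderated_t_test(
    expr: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t test of group1 vs group2, per gene.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (group1 -
    group2), ``t``, ``p``, ``q`` (BH), ``s2_post``, ``df_total``. ``prior_df``
    / ``prior_var`` override the estimated hyperparameters (``prior_df=0``
    turns shrinkage off, recovering the ordinary pooled-variance t).
    """
    g1, g2 = list(group1), list(group2)
    if set(g1) & set(g2):
        raise ValueError("groups must be disjoint")
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group requires >=2 samples")
    x1 = expr[g1].to_numpy(float)
    x2 = expr[g2].to_numpy(float)
    n1, n2 = x1.shape[1], x2.shape[1]
    if (x1.var(axis=1) == 0).all() or (x2.var(axis=1) == 0).all():
        raise ValueError("a group has constant expression for every gene")
    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    d = n1 + n2 - 2
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)) / d

    if prior_df is None:
        d0, s02 = fit_f_dist(s2, d)
        if np.isinf(d0):
            warnings.warn(
                "no between-gene variance spread beyond sampling noise; "
                "falling back to the pooled common variance"
            )
    else:
        d0 = float(prior_df)
        s02 = float(prior_var) if prior_var is not None else float(np.median(s2))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(d)
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = float(d0 + d)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    return pd.DataFrame(
        {"log2fc": lfc, "t": t, "p": p, "q": q,
         "s2_post": s2_post, "df_total": df_total},
        index=expr.index,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(p, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def randomization_control(
    expr: pd.DataFrame, samples: Sequence[str], seed: int, fdr: float = 0.05
) -> int:
    """DEG count at the FDR cut for a random balanced half-split of one group.

    A homogeneous group should yield 0 in the large majority of seeds — the
    negative control confirming that detected ancestry differences are not
    splitting artifacts.
    """
    samples = list(samples)
    if len(samples) < 4:
        raise ValueError("need >=4 samples for a half-split control")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    half = len(samples) // 2
    g1 = [samples[i] for i in perm[:half]]
    g2 = [samples[i] for i in perm[half: 2 * half]]
    res = moderated_t_test(expr, g1, g2)
    return int((res["q"] < fdr).sum())


@dataclass(frozen=True)
class OverlapResult:
    """Fisher's-exact overlap of two gene lists against a universe.

    ``odds_ratio`` is the sample (cross-product) OR of the 2x2 membership
    table; ``p`` is the two-sided Fisher probability (sum of all tables with
    probability <= the observed one).
    """

    universe_size: int
    n_a: int
    n_b: int
    overlap: int
    odds_ratio: float
    p: float
    fdr_note: str | None = None


def overlap_test(
    list_a, list_b, universe, fdr_note: str | None = None
) -> OverlapResult:
    """Significance of the overlap between two gene lists."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    a, b = set(list_a), set(list_b)
    if not a <= universe or not b <= universe:
        raise ValueError("both gene lists must be subsets of the universe")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe) - n11 - n12 - n21
    odds, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
    return OverlapResult(len(universe), len(a), len(b), n11, float(odds), float(p),
                         fdr_note)
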