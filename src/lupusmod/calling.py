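"""Healthy-control-referenced signature calling and group comparisons.

Enrichment scores become per-patient calls in {-1, 0, +1} against the
"normal range" defined by the healthy-control mean +/- 1 SD per module:
+1 above the range, -1 below, 0 inside (boundary scores call 0, the literal
reading of "greater or less than"). Call frequencies are tabulated per group
(typically ancestry) and compared by two-sided Fisher's exact tests; score
distributions themselves are compared by Welch's unequal-variance t with an
optional Sidak family adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class NormalRange:
    """Per-module HC mean and SD (sample SD, n-1 denominator)."""

    mean: pd.Series
    sd: pd.Series
    n_hc: int
    hc_sex: str | None = None

    def __post_init__(self):
        if self.n_hc < 2:
            raise ValueError("normal range requires >=2 healthy controls")
        if (self.sd < 0).any():
            raise ValueError("negative SD in normal range")


def fit_normal_range(
    scores: pd.DataFrame, hc_ids, hc_sex: str | None = None
) -> NormalRange:
    """Fit the HC normal range from a modules x samples score matrix."""
    hc_ids = list(hc_ids)
    missing = [s for s in hc_ids if s not in scores.columns]
    if missing:
        raise ValueError(f"HC sample(s) absent from scores: {', '.join(missing)}")
    if len(hc_ids) < 2:
        raise ValueError("need >=2 HC samples to fit a normal range")
    block = scores[hc_ids]
    return NormalRange(block.mean(axis=1), block.std(axis=1, ddof=1),
                       len(hc_ids), hc_sex)


def trichotomize(scores: pd.DataFrame, normal_range: NormalRange) -> pd.DataFrame:
    """Call each score +1 / -1 / 0 against mean +/- 1 SD (boundaries -> 0).

    Missing scores propagate as missing calls (a warning reports the count).
    """
    if set(scores.index) != set(normal_range.mean.index):
        raise ValueError("modules of scores and normal range differ")
    mean = normal_range.mean.reindex(scores.index)
    sd = normal_range.sd.reindex(scores.index)
    upper = scores.gt(mean + sd, axis=0)
    lower = scores.lt(mean - sd, axis=0)
    calls = upper.astype(float) - lower.astype(float)
    na = scores.isna()
    if na.to_numpy().any():
        warnings.warn(f"{int(na.to_numpy().sum())} missing score(s) propagated "
                      "as missing calls")
        calls = calls.mask(na)
    return calls


def group_frequencies(calls: pd.DataFrame, grouping: pd.Series) -> pd.DataFrame:
    """Counts and percentages of +1 and -1 calls per module x group.

    ``grouping`` maps every patient (column of ``calls``) to a group label;
    empty groups are excluded with a warning.
    """
    grouping = pd.Series(grouping)
    missing = [s for s in calls.columns if s not in grouping.index]
    if missing:
        raise ValueError(f"no group for sample(s): {', '.join(missing[:5])}")
    rows = []
    for group, members in grouping.reindex(calls.columns).groupby(
        grouping.reindex(calls.columns)
    ):
        ids = list(members.index)
        if not ids:
            warnings.warn(f"group {group!r} is empty; excluded")
            continue
        block = calls[ids]
        for module in calls.index:
            row = block.loc[module]
            n = int(row.notna().sum())
            n_up = int((row == 1).sum())
            n_down = int((row == -1).sum())
            rows.append({
                "module": module, "group": group, "n": n,
                "n_up": n_up, "pct_up": 100.0 * n_up / n if n else np.nan,
                "n_down": n_down, "pct_down": 100.0 * n_down / n if n else np.nan,
            })
    return pd.DataFrame(rows)


def frequency_tests(table: pd.DataFrame, direction: str = "up") -> pd.DataFrame:
    """Two-sided Fisher's exact test of call frequency per module x group pair.

    ``table`` is the output of :func:`group_frequencies`; ``direction``
    selects the +1 ("up") or -1 ("down") calls.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    count_col = f"n_{direction}"
    rows = []
    for module, sub in table.groupby("module", sort=False):
        sub = sub.set_index("group")
        for g1, g2 in itertools.combinations(sub.index, 2):
            n1, n2 = int(sub.loc[g1, "n"]), int(sub.loc[g2, "n"])
            if n1 == 0 or n2 == 0:
                continue
            k1, k2 = int(sub.loc[g1, count_col]), int(sub.loc[g2, count_col])
            _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]],
                                      alternative="two-sided")
            rows.append({"module": module, "group1": g1, "group2": g2,
                         "direction": direction, "p": float(p)})
    return pd.DataFrame(rows)


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's t statistic, Welch–Satterthwaite df, and two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        warnings.warn("both groups have zero variance; p undefined, reported as 1")
        return 0.0, float(n1 + n2 - 2), 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    denom = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    df = se2 ** 2 / denom if denom > 0 else 1.0
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def pairwise_group_tests(
    scores: pd.DataFrame, grouping: pd.Series, adjust: str = "sidak"
) -> pd.DataFrame:
    """Welch's t per module x group pair, optionally Sidak-adjusted.

    The Sidak adjustment ``1 - (1 - p)^m`` is applied over the family of
    group pairs within each module.
    """
    if adjust not in ("none", "sidak"):
        raise ValueError("adjust must be 'none' or 'sidak'")
    grouping = pd.Series(grouping).reindex(scores.columns)
    groups = {g: list(m.index) for g, m in grouping.groupby(grouping)}
    for g, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    pairs = list(itertools.combinations(sorted(groups), 2))
    rows = []
    for module in scores.index:
        for g1, g2 in pairs:
            t, df, p = welch_t(scores.loc[module, groups[g1]],
                               scores.loc[module, groups[g2]])
            rows.append({"module": module, "group1": g1, "group2": g2,
                         "t": t, "df": df, "p": p})
    out = pd.DataFrame(rows)
    if adjust == "sidak" and len(out):
        m = len(pairs)
        out["p_adj"] = 1.0 - (1.0 - out["p"]) ** m
    else:
        out["p_adj"] = out["p"]
    return out
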