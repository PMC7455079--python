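"""Stepwise logistic odds-ratio framework over binary signature outcomes.

Each of the 34 signature calls (as a binary outcome: +1 call for "high"
signatures, -1 call for "low" ones) is modeled against 26 binary predictors:
3 ancestry indicators, 7 drugs, 5 clinical manifestations, 6 serology
indicators (4 mutually exclusive autoantibody-combination groups plus low C3
and low C4), age > 50, and 4 disease-duration categories. Collinear
predictors are screened out by tie-corrected Spearman correlation
(|rho| > 0.5 drops the later-listed column). Selection is forward-by-score-
test / backward-by-Wald (entry and stay p at 0.05, the SAS stepwise
convention); final models failing the Hosmer–Lemeshow decile-of-risk
calibration test at p < 0.05 are flagged as discarded.

Odds ratios feed the interval-graph edge encoding used for Circos-style
displays: ORs below 1 are shown as 1/OR with negative direction, and line
width follows display-OR intervals [1,2)->1pt, [2,3)->5pt, [3,10)->10pt,
[10,inf)->20pt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

SEROLOGY_GROUPS = (
    "rnp_pos_dsdna_pos",
    "rnp_pos_dsdna_neg",
    "rnp_neg_dsdna_pos",
    "sm_ssa_ssb_only",
    "seronegative",
)

#: canonical order of the 26 binary predictors
PREDICTOR_COLUMNS = (
    "ancestry_AA", "ancestry_EA", "ancestry_NAA",
    "corticosteroids", "antimalarials", "nsaids", "aza", "mtx", "mmf",
    "cyclophosphamide",
    "rash", "arthritis", "mucosal_ulcers", "vasculitis", "alopecia",
    "sero_rnp_pos_dsdna_pos", "sero_rnp_pos_dsdna_neg",
    "sero_rnp_neg_dsdna_pos", "sero_sm_ssa_ssb_only",
    "c3_low", "c4_low",
    "age_gt50",
    "duration_le1y", "duration_1_5y", "duration_5_10y", "duration_gt10y",
)


def autoantibody_group(rnp, dsdna, sm, ssa, ssb) -> str:
    """Map the five autoantibody flags to the serology combination group.

    RNP+ and/or dsDNA+ groups may carry Sm/SSA/SSB in any combination; the
    Sm/SSA/SSB group requires neither RNP nor dsDNA; all five negative is
    ``"seronegative"``.
    """
    rnp, dsdna = bool(rnp), bool(dsdna)
    other = bool(sm) or bool(ssa) or bool(ssb)
    if rnp and dsdna:
        return "rnp_pos_dsdna_pos"
    if rnp:
        return "rnp_pos_dsdna_neg"
    if dsdna:
        return "rnp_neg_dsdna_pos"
    if other:
        return "sm_ssa_ssb_only"
    return "seronegative"


def build_predictor_matrix(metadata: pd.DataFrame) -> pd.DataFrame:
    """Patients x 26 binary predictor matrix from a metadata table.

    Controls (``is_control == 1``) are excluded. The four serology-group
    indicators are mutually exclusive by construction.
    """
    md = metadata
    if "is_control" in md.columns:
        md = md[md["is_control"] == 0]
    X = pd.DataFrame(index=md.index)
    for anc in ("AA", "EA", "NAA"):
        X[f"ancestry_{anc}"] = (md["ancestry"] == anc).astype(int)
    for col in ("corticosteroids", "antimalarials", "nsaids", "aza", "mtx",
                "mmf", "cyclophosphamide", "rash", "arthritis",
                "mucosal_ulcers", "vasculitis", "alopecia"):
        X[col] = md[col].astype(int)
    groups = md.apply(
        lambda r: autoantibody_group(r["rnp"], r["dsdna"], r["sm"], r["ssa"],
                                     r["ssb"]),
        axis=1,
    )
    for g in SEROLOGY_GROUPS[:4]:
        X[f"sero_{g}"] = (groups == g).astype(int)
    X["c3_low"] = md["c3_low"].astype(int)
    X["c4_low"] = md["c4_low"].astype(int)
    X["age_gt50"] = md["age_gt50"].astype(int)
    for cat in ("le1y", "1_5y", "5_10y", "gt10y"):
        X[f"duration_{cat}"] = (md["duration_cat"] == cat).astype(int)
    assert list(X.columns) == list(PREDICTOR_COLUMNS)
    return X


def spearman_screen(
    X: pd.DataFrame, threshold: float = 0.5
) -> tuple[pd.DataFrame, list[str]]:
    """Tie-corrected Spearman rho for all column pairs + collinearity drops.

    For each pair with |rho| > threshold the later-listed column is flagged
    for removal; constant columns yield missing rho with a warning.
    """
    if X.shape[1] < 2:
        raise ValueError("need >=2 columns to screen")
    cols = list(X.columns)
    constant = [c for c in cols if X[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant column(s) with undefined rho: {', '.join(constant)}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on constant input
        rho, _ = stats.spearmanr(X.to_numpy(float))
    if X.shape[1] == 2:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    drops: list[str] = []
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            r = rho_df.iloc[i, j]
            if np.isfinite(r) and abs(r) > threshold and b not in drops:
                drops.append(b)
    return rho_df, drops


@dataclass
class LogisticFit:
    """A fitted logistic model: per-term OR table plus fit diagnostics."""

    table: pd.DataFrame  # index: term; columns: coef, se, or, ci_low, ci_high, p
    llf: float
    fitted: pd.Series    # in-sample probabilities
    converged: bool
    cov: pd.DataFrame


def logistic_fit(y, X: pd.DataFrame | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald ORs and 95% CIs.

    ``X`` may be ``None`` / empty for an intercept-only model. Raises
    ``ValueError`` on constant outcome, singular design, or (quasi-)perfect
    separation.
    """
    y = pd.Series(y).astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome is constant")
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        design = pd.DataFrame({"const": np.ones(len(y))}, index=y.index)
    else:
        X = pd.DataFrame(X).astype(float)
        if len(y) <= X.shape[1] + 1:
            raise ValueError("more parameters than observations")
        design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y.to_numpy(), design.to_numpy()).fit(
                disp=0, maxiter=100, tol=1e-8
            )
    except Exception as exc:  # LinAlgError, PerfectSeparationError, ...
        raise ValueError(f"logistic fit failed ({exc}); check for perfect "
                         "separation or a singular design") from exc
    coefs = pd.Series(res.params, index=design.columns)
    slopes = coefs.drop("const", errors="ignore")
    if len(slopes) and slopes.abs().max() > 15:
        big = slopes.abs().idxmax()
        raise ValueError(f"diverging coefficient for predictor {big!r}; "
                         "likely perfect separation")
    se = pd.Series(res.bse, index=design.columns)
    table = pd.DataFrame({
        "coef": coefs,
        "se": se,
        "or": np.exp(coefs),
        "ci_low": np.exp(coefs - 1.96 * se),
        "ci_high": np.exp(coefs + 1.96 * se),
        "p": pd.Series(res.pvalues, index=design.columns),
    })
    fitted = pd.Series(res.predict(design.to_numpy()), index=y.index)
    cov = pd.DataFrame(res.cov_params(), index=design.columns,
                       columns=design.columns)
    return LogisticFit(table, float(res.llf), fitted, bool(res.mle_retvals["converged"]),
                       cov)


def score_test(y, fitted: pd.Series, design: pd.DataFrame, candidate: pd.Series
               ) -> float:
    """Rao score-test p-value for adding one column to a fitted logistic model.

    Only the null fit is needed: with null probabilities p, the score is
    U = x'(y - p) and its variance the efficient information of x after
    projecting out the current design under weights w = p(1 - p).
    """
    y = np.asarray(y, float)
    p = np.asarray(fitted, float)
    x = np.asarray(candidate, float)
    X0 = np.asarray(design, float)
    w = p * (1.0 - p)
    u = x @ (y - p)
    xwx = (w * x) @ x
    xwX0 = (w * x) @ X0
    X0wX0 = X0.T @ (w[:, None] * X0)
    try:
        v = xwx - xwX0 @ np.linalg.solve(X0wX0, xwX0)
    except np.linalg.LinAlgError:
        return 1.0
    if v <= 1e-12:
        return 1.0  # no information gain (e.g. duplicate column)
    return float(stats.chi2.sf(u * u / v, 1))


def hosmer_lemeshow(y, fitted, g: int = 10) -> tuple[float, int, float]:
    """Hosmer–Lemeshow decile-of-risk calibration test.

    Groups by quantiles of fitted probability (ties kept together, so fewer
    than ``g`` effective groups can result); returns (statistic, df, p) with
    df = groups - 2. Groups with zero expected events/non-events are merged
    with their neighbor (warning).
    """
    y = np.asarray(y, float)
    p = np.asarray(fitted, float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("fitted probabilities must lie strictly in (0, 1)")
    if g < 3:
        raise ValueError("need g >= 3 risk groups (df = g - 2 must be positive)")
    if len(y) < g:
        raise ValueError("fewer observations than risk groups")
    try:
        bins = pd.qcut(p, g, labels=False, duplicates="drop")
    except ValueError as exc:
        raise ValueError(f"cannot form risk groups: {exc}") from exc
    obs1, exp1, obs0, exp0 = [], [], [], []
    for b in np.unique(bins):
        m = bins == b
        obs1.append(y[m].sum()); exp1.append(p[m].sum())
        obs0.append((1 - y[m]).sum()); exp0.append((1 - p[m]).sum())
    obs1, exp1 = np.array(obs1), np.array(exp1)
    obs0, exp0 = np.array(obs0), np.array(exp0)
    # merge groups whose expected counts vanish numerically
    while len(exp1) > 3 and (exp1.min() < 1e-9 or exp0.min() < 1e-9):
        warnings.warn("risk group with zero expected count merged with neighbor")
        i = int(np.argmin(np.minimum(exp1, exp0)))
        j = i - 1 if i > 0 else i + 1
        for arr in (obs1, exp1, obs0, exp0):
            arr[j] += arr[i]
        obs1, exp1 = np.delete(obs1, i), np.delete(exp1, i)
        obs0, exp0 = np.delete(obs0, i), np.delete(exp0, i)
    if len(exp1) < 3:
        raise ValueError("too few distinct risk groups for the test")
    stat = float(((obs1 - exp1) ** 2 / exp1 + (obs0 - exp0) ** 2 / exp0).sum())
    df = len(exp1) - 2
    return stat, df, float(stats.chi2.sf(stat, df))


@dataclass
class StepwiseResult:
    """Outcome of stepwise selection for one signature outcome."""

    outcome: str
    selected: list[str]
    table: pd.DataFrame            # per selected predictor: coef, or, ci, p
    hl_stat: float
    hl_df: int
    hl_p: float
    converged: bool
    discarded: bool                # True when the HL gate rejects calibration
    intercept_only: bool

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "selected": self.selected,
            "terms": self.table.reset_index()
                          .rename(columns={"index": "predictor"})
                          .to_dict(orient="records"),
            "hosmer_lemeshow": {"stat": self.hl_stat, "df": self.hl_df,
                                "p": self.hl_p},
            "converged": self.converged,
            "discarded": self.discarded,
            "intercept_only": self.intercept_only,
        }


def stepwise_select(
    y,
    X: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.05,
    hl_groups: int = 10,
    hl_alpha: float = 0.05,
    outcome: str = "",
    max_cycles: int = 50,
) -> StepwiseResult:
    """Forward(score test) / backward(Wald) stepwise logistic selection.

    Iterates entry of the smallest-score-p candidate while p < ``p_enter``
    with removal of any included term whose Wald p > ``p_remove``, to
    stability (oscillation guard at ``max_cycles``). The final model is refit
    and gated by Hosmer–Lemeshow calibration: ``discarded`` is set when
    HL p < ``hl_alpha``.
    """
    y = pd.Series(y).astype(float)
    X = pd.DataFrame(X).astype(float)
    included: list[str] = []
    converged = True
    for _ in range(max_cycles):
        changed = False
        fit = logistic_fit(y, X[included] if included else None)
        design = sm.add_constant(X[included], has_constant="add") if included \
            else pd.DataFrame({"const": np.ones(len(y))}, index=y.index)
        candidates = [c for c in X.columns if c not in included]
        if candidates:
            pvals = {c: score_test(y, fit.fitted, design, X[c]) for c in candidates}
            best = min(pvals, key=pvals.get)
            if pvals[best] < p_enter:
                trial = included + [best]
                try:
                    logistic_fit(y, X[trial])
                except ValueError:
                    converged = False
                    break
                included.append(best)
                changed = True
        # backward pass
        while included:
            fit = logistic_fit(y, X[included])
            wald = fit.table.drop("const")["p"]
            worst = wald.idxmax()
            if wald[worst] > p_remove:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    else:
        warnings.warn(f"stepwise selection for {outcome!r} hit the "
                      f"{max_cycles}-cycle oscillation guard")
        converged = False

    final = logistic_fit(y, X[included] if included else None)
    intercept_only = not included
    table = final.table.drop("const") if included else final.table.iloc[0:0]
    hl_stat = hl_df = hl_p = np.nan
    discarded = False
    if not intercept_only:
        try:
            hl_stat, hl_df, hl_p = hosmer_lemeshow(y, final.fitted, hl_groups)
            discarded = hl_p < hl_alpha
        except ValueError as exc:
            warnings.warn(f"Hosmer–Lemeshow not computable for {outcome!r}: {exc}")
    return StepwiseResult(outcome, included, table, float(hl_stat),
                          int(hl_df) if np.isfinite(hl_df) else 0,
                          float(hl_p), converged and final.converged, discarded,
                          intercept_only)


@dataclass(frozen=True)
class CircosEdge:
    """Interval-graph encoding of one predictor->outcome odds ratio."""

    predictor: str
    outcome: str
    odds_ratio: float
    display_or: float
    direction: str  # "positive" (OR > 1) or "negative" (OR < 1)
    width_pt: int


def or_to_edge(predictor: str, outcome: str, or_value: float) -> CircosEdge:
    """Map an odds ratio to its display edge (reciprocal for OR < 1;
    widths 1/5/10/20pt on display-OR intervals [1,2)/[2,3)/[3,10)/[10,inf))."""
    if not np.isfinite(or_value) or or_value <= 0:
        raise ValueError(f"odds ratio must be positive and finite, got {or_value}")
    display = or_value if or_value >= 1 else 1.0 / or_value
    direction = "negative" if or_value < 1 else "positive"
    if display < 2:
        width = 1
    elif display < 3:
        width = 5
    elif display < 10:
        width = 10
    else:
        width = 20
    return CircosEdge(predictor, outcome, float(or_value), float(display),
                      direction, width)


class LinearFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def simple_linear_fit(x, y) -> LinearFit:
    """Ordinary least squares of a score on a clinical value; returns slope,
    intercept, and R^2 = 1 - SSE/SST."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need >=3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope undefined")
    res = stats.linregress(x, y)
    return LinearFit(float(res.slope), float(res.intercept),
                     float(res.rvalue ** 2))
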