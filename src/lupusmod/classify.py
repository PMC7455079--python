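"""Cross-validated transcriptomic ancestry classification.

The native engine is elastic-net penalized logistic regression on the module
genes (inputs standardized on training data only); a maximum-margin (linear
SVM) engine plugs in behind the same contract. Performance follows the
study's protocol: stratified 10-fold cross-validation, out-of-fold class
probabilities pooled for the ROC/AUC, per-fold sensitivity / specificity /
accuracy at the 0.5 threshold averaged across folds, and gene importance
taken as |coefficient on standardized inputs| to rank the top predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Per-sample fold indices 1..k, stratified by class, deterministic per seed.

    Raises if any class has fewer than ``k`` members.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < k]
    if len(small):
        raise ValueError(
            f"class(es) smaller than k={k}: {', '.join(map(str, small))}; "
            "use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.zeros(len(y), dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y), start=1):
        folds[test_idx] = i
    return folds


@dataclass
class ClassifierModel:
    """A fitted binary classifier on standardized gene inputs."""

    coef: pd.Series          # per-gene coefficient on standardized scale
    intercept: float
    feature_mean: pd.Series
    feature_sd: pd.Series
    l1_weight: float
    l2_weight: float
    engine: str = "logistic"
    classes: tuple = (0, 1)
    _sk: object = field(default=None, repr=False)

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.coef.index] - self.feature_mean) / self.feature_sd
        return Z.to_numpy(float) @ self.coef.to_numpy() + self.intercept

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        s = self.decision_scores(X)
        if self.engine == "svm":
            # margin scores squashed only for thresholding convenience
            return 1.0 / (1.0 + np.exp(-s))
        return 1.0 / (1.0 + np.exp(-s))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def _standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    mean = X.mean()
    sd = X.std(ddof=0).replace(0.0, 1.0)
    return (X - mean) / sd, mean, sd


def fit_penalized_logistic(
    X: pd.DataFrame, y, l1_weight: float = 0.01, l2_weight: float = 0.01
) -> ClassifierModel:
    """Elastic-net logistic regression minimizing
    mean log-loss + l1*||b||_1 + (l2/2)*||b||_2^2 on standardized inputs."""
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y).astype(int)
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("non-finite values in the feature matrix")
    if l1_weight < 0 or l2_weight < 0:
        raise ValueError("penalty weights must be >= 0")
    Z, mean, sd = _standardize(X)
    n = len(y)
    total = l1_weight + l2_weight
    if total == 0:
        clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000,
                                 tol=1e-6)
    elif l1_weight == 0:
        clf = LogisticRegression(penalty="l2", C=1.0 / (n * l2_weight),
                                 solver="lbfgs", max_iter=2000, tol=1e-6)
    else:
        clf = LogisticRegression(
            penalty="elasticnet", solver="saga",
            l1_ratio=l1_weight / total, C=1.0 / (n * total),
            max_iter=5000, tol=1e-6, random_state=0,
        )
    clf.fit(Z.to_numpy(), y)
    return ClassifierModel(
        coef=pd.Series(clf.coef_[0], index=X.columns),
        intercept=float(clf.intercept_[0]),
        feature_mean=mean, feature_sd=sd,
        l1_weight=l1_weight, l2_weight=l2_weight,
        engine="logistic", _sk=clf,
    )


def fit_svm(X: pd.DataFrame, y, c: float = 1.0) -> ClassifierModel:
    """Linear maximum-margin engine behind the same model contract."""
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y).astype(int)
    Z, mean, sd = _standardize(X)
    clf = SVC(kernel="linear", C=c)
    clf.fit(Z.to_numpy(), y)
    return ClassifierModel(
        coef=pd.Series(clf.coef_[0], index=X.columns),
        intercept=float(clf.intercept_[0]),
        feature_mean=mean, feature_sd=sd,
        l1_weight=0.0, l2_weight=1.0 / c,
        engine="svm", _sk=clf,
    )


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal AUC by threshold sweep over unique scores.

    Tied scores step simultaneously. Equals the normalized Mann–Whitney U
    statistic; requires both classes present.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted == 1).astype(float)
    fps = np.cumsum(y_sorted == 0).astype(float)
    # keep only the last index of each tied block (simultaneous step)
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class ClassifierReport:
    """Cross-validation report: fold metrics, pooled ROC, final-model ranking."""

    fold_metrics: pd.DataFrame       # per fold: sensitivity, specificity, accuracy
    mean_metrics: dict
    pooled_probs: pd.Series          # out-of-fold probability per sample
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    final_model: ClassifierModel
    engine: str

    def to_dict(self) -> dict:
        return {
            "engine": self.engine,
            "auc": self.auc,
            "mean_metrics": self.mean_metrics,
            "fold_metrics": self.fold_metrics.to_dict(orient="records"),
        }


def _fold_metrics(y_true: np.ndarray, prob: np.ndarray) -> dict:
    pred = (prob >= 0.5).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "accuracy": (tp + tn) / len(y_true),
    }


def cross_validate(
    X: pd.DataFrame,
    y,
    folds: np.ndarray,
    engine: str = "logistic",
    l1_weight: float = 0.01,
    l2_weight: float = 0.01,
    svm_c: float = 1.0,
) -> ClassifierReport:
    """Out-of-fold probabilities per sample, pooled ROC/AUC, averaged fold
    metrics, and a final all-data model for predictor ranking.

    Standardization happens inside each training fold; folds containing a
    single class are skipped with a warning.
    """
    X = pd.DataFrame(X).astype(float)
    y = pd.Series(np.asarray(y).astype(int), index=X.index)
    folds = np.asarray(folds)
    probs = pd.Series(np.nan, index=X.index)
    rows = []
    for f in np.unique(folds):
        train, test = folds != f, folds == f
        if y[train].nunique() < 2:
            warnings.warn(f"fold {f}: training data has a single class; skipped")
            continue
        if engine == "svm":
            model = fit_svm(X[train], y[train], c=svm_c)
        else:
            model = fit_penalized_logistic(X[train], y[train], l1_weight,
                                           l2_weight)
        p = model.predict_proba(X[test])
        probs[test] = p
        rows.append({"fold": int(f), **_fold_metrics(y[test].to_numpy(), p)})
    fold_metrics = pd.DataFrame(rows)
    mean_metrics = {
        k: float(fold_metrics[k].mean())
        for k in ("sensitivity", "specificity", "accuracy")
    } if len(fold_metrics) else {}
    scored = probs.notna()
    fpr, tpr, auc = roc_auc(probs[scored], y[scored])
    if engine == "svm":
        final = fit_svm(X, y, c=svm_c)
    else:
        final = fit_penalized_logistic(X, y, l1_weight, l2_weight)
    return ClassifierReport(fold_metrics, mean_metrics, probs, fpr, tpr, auc,
                            final, engine)


def top_predictors(model: ClassifierModel, n: int = 25) -> pd.DataFrame:
    """Genes ranked by importance = |standardized coefficient|; ties broken
    lexicographically; ``n`` larger than the gene count returns the full list."""
    if n < 0:
        raise ValueError("n must be >= 0")
    imp = model.coef.abs()
    order = sorted(imp.index, key=lambda g: (-imp[g], g))
    top = order[: min(n, len(order))]
    return pd.DataFrame({
        "gene": top,
        "importance": [float(imp[g]) for g in top],
        "coefficient": [float(model.coef[g]) for g in top],
    })
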