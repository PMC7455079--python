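"""scikit-learn-style estimator facades over the functional core.

These classes follow sklearn conventions (``fit`` / ``transform`` /
``predict``, ``get_params`` / ``set_params``, fitted attributes with a
trailing underscore) so the pipeline stages compose with sklearn model
selection. They operate on samples x features DataFrames (sklearn
orientation); the functional core uses the field's genes x samples
orientation and the facades transpose at the boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import calling, classify, gsva
from .association import stepwise_select
from .modules import ModuleCollection


class ModuleScorer(BaseEstimator, TransformerMixin):
    """Transform samples x genes log2 expression into samples x modules
    enrichment scores via the kernel-CDF / KS-walk engine.

    The gene-level statistic is population-referenced: each sample is scored
    against the cohort passed to ``transform``, so ``fit`` only validates the
    module collection.
    """

    def __init__(self, modules: ModuleCollection | None = None,
                 tau: float = 1.0, mode: str = "diff"):
        self.modules = modules
        self.tau = tau
        self.mode = mode

    def fit(self, X, y=None):
        if self.modules is None or len(self.modules) == 0:
            raise ValueError("ModuleScorer requires a non-empty ModuleCollection")
        self.module_names_ = list(self.modules.names)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "module_names_")
        scores = gsva.score_modules(pd.DataFrame(X).T, self.modules,
                                    tau=self.tau, mode=self.mode)
        return scores.T


class ReferenceRangeCaller(BaseEstimator, TransformerMixin):
    """Fit the healthy-control normal range (mean +/- 1 SD per module) and
    trichotomize scores into {-1, 0, +1} calls."""

    def __init__(self, n_sd: float = 1.0):
        self.n_sd = n_sd

    def fit(self, X: pd.DataFrame, y=None):
        """``X``: samples x modules scores of the healthy controls."""
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValueError("need >=2 healthy controls")
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1)
        self.n_hc_ = X.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "mean_")
        X = pd.DataFrame(X)
        nr = calling.NormalRange(self.mean_, self.sd_ * self.n_sd / 1.0,
                                 self.n_hc_)
        return calling.trichotomize(X.T, nr).T


class ElasticNetAncestryClassifier(BaseEstimator, ClassifierMixin):
    """Elastic-net logistic (or linear-SVM) classifier on standardized gene
    expression, with importance ranking of the top predictors."""

    def __init__(self, l1_weight: float = 0.01, l2_weight: float = 0.01,
                 engine: str = "logistic", svm_c: float = 1.0):
        self.l1_weight = l1_weight
        self.l2_weight = l2_weight
        self.engine = engine
        self.svm_c = svm_c

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if self.engine == "svm":
            self.model_ = classify.fit_svm(X, y, c=self.svm_c)
        else:
            self.model_ = classify.fit_penalized_logistic(
                X, y, self.l1_weight, self.l2_weight
            )
        self.coef_ = self.model_.coef.to_numpy()[None, :]
        self.intercept_ = np.array([self.model_.intercept])
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        p1 = self.model_.predict_proba(pd.DataFrame(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def top_predictors(self, n: int = 25) -> pd.DataFrame:
        check_is_fitted(self, "model_")
        return classify.top_predictors(self.model_, n)


class StepwiseLogistic(BaseEstimator):
    """Stepwise (score-test entry / Wald removal) logistic selection with the
    Hosmer–Lemeshow calibration gate, as an estimator."""

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.05,
                 hl_groups: int = 10, hl_alpha: float = 0.05):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.hl_groups = hl_groups
        self.hl_alpha = hl_alpha

    def fit(self, X: pd.DataFrame, y):
        res = stepwise_select(
            pd.Series(y), pd.DataFrame(X),
            p_enter=self.p_enter, p_remove=self.p_remove,
            hl_groups=self.hl_groups, hl_alpha=self.hl_alpha,
        )
        self.result_ = res
        self.selected_ = list(res.selected)
        self.discarded_ = res.discarded
        return self
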