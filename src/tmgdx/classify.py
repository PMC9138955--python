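"""Youden-cut-off threshold classifier in sklearn estimator form.

The screening rule at the heart of the asymmetry analysis is a univariate
threshold classifier: a subject whose asymmetry score exceeds a cut-off is
called injured.  :class:`YoudenCutoffClassifier` estimates that cut-off by
maximising Youden's J on the training scores and exposes the full ROC and
precision–recall evaluation as fitted attributes, so it plugs directly
into sklearn model selection and pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import metrics

__all__ = ["YoudenCutoffClassifier"]


class YoudenCutoffClassifier(ClassifierMixin, BaseEstimator):
    """Univariate threshold classifier with a Youden-optimal cut-off.

    Parameters
    ----------
    se_method : {"delong", "hanley_mcneil"}
        Standard-error estimator for the training AUC.
    bootstrap_resamples : int
        Stratified-bootstrap resamples for 95 % CIs on AUC, J and the
        cut-off; 0 disables the bootstrap.
    random_state : int, optional
        Seed for the bootstrap.

    Attributes
    ----------
    cutoff_ : float
        Youden-optimal threshold; predict positive when score > cutoff_.
    auc_, se_auc_, youden_j_, sens_, spec_ : float
        Training-set ROC summary.
    roc_result_ : metrics.ROCResult
    prc_result_ : metrics.PRCResult
    classes_ : ndarray of shape (2,)
        ``classes_[1]`` is the positive class (the class of the larger
        scores by convention of the label encoding).
    """

    def __init__(
        self,
        se_method: str = "delong",
        bootstrap_resamples: int = 0,
        random_state: int | None = None,
    ) -> None:
        self.se_method = se_method
        self.bootstrap_resamples = bootstrap_resamples
        self.random_state = random_state

    @staticmethod
    def _as_scores(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single score column, got shape %s" % (X.shape,))
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("X must be 1-D scores or an (n, 1) column")
        if not np.isfinite(X).all():
            raise ValueError("scores must be finite")
        return X

    def fit(self, X, y) -> "YoudenCutoffClassifier":
        scores = self._as_scores(X)
        y = np.asarray(y)
        if y.shape[0] != scores.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("need exactly two classes")
        labels = y == self.classes_[1]
        self.roc_result_ = metrics.evaluate_roc(
            scores, labels,
            se_method=self.se_method,
            bootstrap_B=self.bootstrap_resamples,
            seed=self.random_state,
        )
        self.prc_result_ = metrics.pr_curve(scores, labels)
        self.auc_ = self.roc_result_.auc
        self.se_auc_ = self.roc_result_.se_auc
        self.youden_j_ = self.roc_result_.youden_j
        self.cutoff_ = self.roc_result_.cutoff
        self.sens_ = self.roc_result_.sens_at_cutoff
        self.spec_ = self.roc_result_.spec_at_cutoff
        self.n_features_in_ = 1
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "cutoff_")
        return self._as_scores(X)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cutoff_")
        scores = self._as_scores(X)
        return self.classes_[(scores > self.cutoff_).astype(int)]
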