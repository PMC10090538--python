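"""One-vs-all decomposition of a K-class problem into K binary stage-2 fits.

Each class in turn is coded 1 against the rest; K independent
forward-selection fits share one predictor layout and configuration.  The
predicted class is the argmax of the K raw positive-class probabilities
(maximum-probability aggregation) — no softmax renormalization and no
threshold stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from .solver import ForwardSelectionLogistic


def binarize(y, positive_class):
    """1 where y equals the positive class, else 0."""
    y = np.asarray(y)
    if positive_class not in y:
        raise ValueError(f"class {positive_class!r} absent from the response")
    return (y == positive_class).astype(int)


def count_binary_problems(K: int, scheme: str) -> int:
    """Binary sub-problems needed: OVA -> K, OVO -> K(K-1)/2.

    K = 2 is already a binary problem: one classifier under either scheme.
    """
    if K < 2:
        raise ValueError("need at least 2 classes")
    if K == 2:
        return 1
    if scheme == "ova":
        return K
    if scheme == "ovo":
        return K * (K - 1) // 2
    raise ValueError("scheme must be 'ova' or 'ovo'")


@dataclass
class OVAEnsemble:
    fits: list
    class_labels: np.ndarray
    ensemble_model_size: int


class OneVsAllForwardSelection(ClassifierMixin, BaseEstimator):
    """OVA ensemble of binary forward-selection logistic fits.

    Parameters are those of :class:`ForwardSelectionLogistic` (shared by all
    K sub-fits) or a pre-built ``base_estimator``.

    Attributes
    ----------
    estimators_ : list of fitted ForwardSelectionLogistic, one per class.
    classes_ : sorted class labels.
    ensemble_model_size_ : distinct variables nonzero in any sub-fit.
    """

    def __init__(self, base_estimator=None, **solver_params):
        self.base_estimator = base_estimator
        self.solver_params = solver_params

    def get_params(self, deep=True):
        return {"base_estimator": self.base_estimator, **self.solver_params}

    def set_params(self, **params):
        if "base_estimator" in params:
            self.base_estimator = params.pop("base_estimator")
        self.solver_params.update(params)
        return self

    def _base(self):
        if self.base_estimator is not None:
            return clone(self.base_estimator)
        return ForwardSelectionLogistic(**self.solver_params)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.estimators_ = []
        for c in self.classes_:
            yb = binarize(y, c)
            if yb.sum() < 2:
                raise ValueError(f"class {c!r} has fewer than 2 training observations")
            est = self._base().fit(X, yb)
            self.estimators_.append(est)
        nz = set()
        for est in self.estimators_:
            nz.update(np.where(est.coef_ != 0)[0].tolist())
        self.ensemble_model_size_ = len(nz)
        self.selected_variables_ = sorted(nz)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        """K raw positive-class probabilities per row (not renormalized)."""
        check_is_fitted(self, "estimators_")
        return np.column_stack([est.predict_proba(X)[:, 1] for est in self.estimators_])

    def predict(self, X):
        """Maximum-probability class; exact ties go to the lower class label."""
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]

    def ensemble(self) -> OVAEnsemble:
        check_is_fitted(self, "estimators_")
        return OVAEnsemble([e.fit_result() for e in self.estimators_],
                           self.classes_, self.ensemble_model_size_)


def fit_ova(X, y, base_estimator=None, **solver_params) -> OneVsAllForwardSelection:
    """Fit a one-vs-all forward-selection ensemble on (X, y)."""
    return OneVsAllForwardSelection(base_estimator=base_estimator, **solver_params).fit(X, y)


def predict_multiclass(ensemble: OneVsAllForwardSelection, Z_new):
    """(predicted classes, K-column probability matrix)."""
    return ensemble.predict(Z_new), ensemble.predict_proba(Z_new)
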