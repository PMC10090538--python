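"""Confusion-matrix metrics: accuracy, per-class TPR/TNR, weighted macros, model size.

For class k, TPR_k = TP/(TP+FN) and TNR_k = TN/(TN+FP) from the one-vs-rest
collapse of the K x K confusion matrix.  The weighted macro rates combine
the per-class rates with the class proportions of the *training* split:

    mTPR = sum_k w_k TPR_k,    sum_k w_k = 1.

A variant dividing by K is available via ``divide_by_k=True``; the default
reports the plain weighted mean (the /K form caps the macro rate at 1/K and
cannot match observed macro rates above it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion


def confusion_matrix(y_true, y_pred, K: int) -> np.ndarray:
    """K x K count matrix, entry (a, b) = # true class a predicted class b (labels 1..K)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred length mismatch")
    return _sk_confusion(y_true, y_pred, labels=np.arange(1, K + 1))


def class_rates(confusion: np.ndarray, k: int) -> tuple[float, float]:
    """(TPR_k, TNR_k) for class label k (1-indexed); NaN when a denominator is empty."""
    cm = np.asarray(confusion, dtype=float)
    i = k - 1
    tp = cm[i, i]
    fn = cm[i].sum() - tp
    fp = cm[:, i].sum() - tp
    tn = cm.sum() - tp - fn - fp
    tpr = tp / (tp + fn) if tp + fn > 0 else np.nan
    tnr = tn / (tn + fp) if tn + fp > 0 else np.nan
    return float(tpr), float(tnr)


def weighted_macro(rates, weights, divide_by_k: bool = False) -> float:
    """Weighted mean of per-class rates; NaN rates are dropped with weight renormalization."""
    rates = np.asarray(rates, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    ok = ~np.isnan(rates)
    if not np.all(ok):
        w = w[ok] / w[ok].sum()
        rates = rates[ok]
    val = float(np.sum(w * rates))
    return val / len(np.asarray(weights)) if divide_by_k else val


def model_size(fit_or_ensemble):
    """Distinct predictors used by a fitted model; None where undefined (SVM).

    Forward-selection fits count nonzero coefficients (union across OVA
    sub-fits); random forests count distinct split features across all trees.
    """
    obj = fit_or_ensemble
    if obj is None:
        return None
    if hasattr(obj, "ensemble_model_size_"):
        return int(obj.ensemble_model_size_)
    if hasattr(obj, "model_size_"):
        return int(obj.model_size_)
    if hasattr(obj, "model_size"):
        return int(obj.model_size)
    if hasattr(obj, "fits"):  # OVAEnsemble dataclass
        nz = set()
        for f in obj.fits:
            nz.update(np.where(f.theta != 0)[0].tolist())
        return len(nz)
    if hasattr(obj, "estimators_") and hasattr(obj, "n_features_in_"):  # random forest
        feats = set()
        for tree in obj.estimators_:
            t = tree.tree_
            feats.update(t.feature[t.feature >= 0].tolist())
        return len(feats)
    if obj.__class__.__name__ in ("SVC", "NuSVC", "LinearSVC"):
        return None
    if hasattr(obj, "coef_"):
        return int(np.sum(np.asarray(obj.coef_) != 0))
    raise ValueError(f"cannot determine model size for {type(obj)!r}; is it fitted?")


@dataclass
class ClassificationReport:
    """Test-set evaluation of one fitted model."""

    confusion: np.ndarray
    accuracy: float
    per_class_tpr: np.ndarray
    per_class_tnr: np.ndarray
    weighted_macro_tpr: float
    weighted_macro_tnr: float
    weights: np.ndarray
    model_size: int | None = None

    def to_row(self) -> dict:
        return {
            "Acc": self.accuracy,
            "mTPR": self.weighted_macro_tpr,
            "mTNR": self.weighted_macro_tnr,
            "MDS": self.model_size,
        }

    def to_json_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class_tpr": self.per_class_tpr.tolist(),
            "per_class_tnr": self.per_class_tnr.tolist(),
            "weighted_macro_tpr": self.weighted_macro_tpr,
            "weighted_macro_tnr": self.weighted_macro_tnr,
            "weights": self.weights.tolist(),
            "model_size": self.model_size,
        }


def evaluate(y_true, y_pred, train_labels, K: int | None = None,
             model=None, divide_by_k: bool = False) -> ClassificationReport:
    """Build a full report; macro weights come from the training labels."""
    train_labels = np.asarray(train_labels)
    if K is None:
        K = int(np.max(train_labels))
    cm = confusion_matrix(y_true, y_pred, K)
    weights = np.array([(train_labels == k).sum() for k in range(1, K + 1)], dtype=float)
    weights = weights / weights.sum()
    tprs, tnrs = zip(*(class_rates(cm, k) for k in range(1, K + 1)))
    return ClassificationReport(
        confusion=cm,
        accuracy=float(np.trace(cm) / cm.sum()),
        per_class_tpr=np.array(tprs),
        per_class_tnr=np.array(tnrs),
        weighted_macro_tpr=weighted_macro(tprs, weights, divide_by_k),
        weighted_macro_tnr=weighted_macro(tnrs, weights, divide_by_k),
        weights=weights,
        model_size=model_size(model) if model is not None else None,
    )
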