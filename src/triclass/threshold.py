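"""Stage 3: optimal probability-threshold search for binary classification.

With imbalanced classes the conventional 0.5 cutoff can be a poor
classifier; the threshold is instead chosen on a held-out optimization set
by maximizing a criterion over a grid.  Multi-class prediction uses
maximum-probability aggregation instead and skips this stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CRITERIA = ("balanced_accuracy", "youden_j", "accuracy", "f1")


@dataclass
class ThresholdResult:
    threshold: float
    criterion: str
    criterion_value: float
    grid: list  # (threshold, criterion value) pairs


def classify_binary(probs, threshold: float):
    """Class 1 iff probability strictly exceeds the threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return (np.asarray(probs, dtype=float) > threshold).astype(int)


def _criterion_value(y, pred, criterion):
    tp = np.sum((y == 1) & (pred == 1))
    tn = np.sum((y == 0) & (pred == 0))
    fp = np.sum((y == 0) & (pred == 1))
    fn = np.sum((y == 1) & (pred == 0))
    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp)
    if criterion == "balanced_accuracy":
        return 0.5 * (tpr + tnr)
    if criterion == "youden_j":
        return tpr + tnr - 1.0
    if criterion == "accuracy":
        return (tp + tn) / len(y)
    if criterion == "f1":
        denom = 2 * tp + fp + fn
        return 2 * tp / denom if denom else 0.0
    raise ValueError(f"criterion must be one of {CRITERIA}")


def optimize_threshold(probs, y_true, criterion: str = "balanced_accuracy",
                       grid_step: float = 0.01) -> ThresholdResult:
    """Scan thresholds {step, 2*step, ..., 1-step}; return the argmax.

    Ties are broken toward 0.5.  Requires both classes present (the per-class
    rates are undefined otherwise).
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y_true, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("y_true must contain both classes")
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    ts = np.arange(grid_step, 1.0 - grid_step / 2, grid_step)
    vals = np.array([_criterion_value(y, probs > t, criterion) for t in ts])
    best_val = vals.max()
    tied = ts[np.isclose(vals, best_val)]
    best_t = float(tied[np.argmin(np.abs(tied - 0.5))])
    return ThresholdResult(best_t, criterion, float(best_val), list(zip(ts, vals)))
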