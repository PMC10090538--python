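"""Stage 1: intrinsic secondary-trait effects by penalized residualization.

Each secondary trait is regressed on the weather block and, separately, on
the genomic block; the two residual sets replace the raw traits as the first
2P predictors of the stage-2 classifier.  Coefficients minimize

    sum_i (u_ip - x_i' b_p)^2 + lambda * pen(b_p)

with pen any of {none, ridge, lasso, adaptive_lasso, elastic_net}.  Removing
the weather and genomic signal from the secondary traits breaks their
confounding with the higher-dimensional blocks, so the classifier attributes
shared signal to the block that actually carries it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import ElasticNet, Lasso, LassoCV, Ridge, RidgeCV

from .data import IntegratedDataset, PredictorBlock, Standardizer

PENALTY_KINDS = ("none", "ridge", "lasso", "adaptive_lasso", "elastic_net")


@dataclass
class PenaltySpec:
    """Penalty for the stage-1 linear fits.

    ``lam`` is on the residual-sum-of-squares scale (RSS + lam * pen); it is
    converted internally to each sklearn solver's parameterization.  ``lam=None``
    requests internal 5-fold cross-validation over a log grid.
    """

    kind: str = "ridge"
    lam: float | None = None
    alpha: float = 0.5  # elastic-net mixing; 1 -> lasso, 0 -> ridge
    adaptive_weights: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in PENALTY_KINDS:
            raise ValueError(f"penalty kind must be one of {PENALTY_KINDS}")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class ResidualizedTraits:
    """The two stage-1 residual sets and the coefficients that produced them."""

    u_hat_W: np.ndarray  # n x P, weather-removed
    u_hat_V: np.ndarray  # n x P, genomic-removed
    b_hat: np.ndarray    # Q x P
    d_hat: np.ndarray    # R x P
    penalty_used: PenaltySpec


_CV_GRID = np.logspace(-3, 4, 15)


def _fit_one(X, y, penalty: PenaltySpec, seed: int) -> np.ndarray:
    n, m = X.shape
    kind, lam = penalty.kind, penalty.lam
    if kind == "none":
        if m >= n:
            raise ValueError("penalty 'none' requires fewer predictors than observations")
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef
    if kind == "adaptive_lasso":
        w = penalty.adaptive_weights
        if w is None:
            # pilot ridge fit defines the weights 1/|b_pilot|, floored at 1e-6
            pilot = Ridge(alpha=1.0, fit_intercept=False).fit(X, y).coef_
            w = 1.0 / np.maximum(np.abs(pilot), 1e-6)
        w = np.asarray(w, dtype=float)
        if np.any(w <= 0):
            raise ValueError("adaptive weights must be positive")
        Xs = X / w  # lasso on rescaled columns == weighted-L1 on original
        coef = _fit_one(Xs, y, PenaltySpec("lasso", lam), seed)
        return coef / w
    if kind == "ridge":
        if lam is None:
            model = RidgeCV(alphas=_CV_GRID, fit_intercept=False, cv=5).fit(X, y)
        else:
            model = Ridge(alpha=lam, fit_intercept=False).fit(X, y)
        return model.coef_
    if kind == "lasso":
        # sklearn Lasso: (1/2n)||y-Xb||^2 + alpha||b||_1  ->  alpha = lam/(2n)
        if lam is None:
            model = LassoCV(fit_intercept=False, cv=5, random_state=seed).fit(X, y)
        elif lam == 0:
            return _fit_one(X, y, PenaltySpec("none"), seed)
        else:
            model = Lasso(alpha=lam / (2 * n), fit_intercept=False, max_iter=50_000).fit(X, y)
        return model.coef_
    # elastic net: RSS + lam*(alpha*||b||_1 + (1-alpha)*||b||_2^2)
    a = penalty.alpha
    if a == 1.0:
        return _fit_one(X, y, PenaltySpec("lasso", lam), seed)
    if a == 0.0:
        return _fit_one(X, y, PenaltySpec("ridge", lam), seed)
    if lam is None:
        lam = 1.0
    sk_alpha = lam * (a / (2 * n) + (1 - a) / n)
    l1_ratio = (a / (2 * n)) / (a / (2 * n) + (1 - a) / n)
    model = ElasticNet(alpha=sk_alpha, l1_ratio=l1_ratio, fit_intercept=False,
                       max_iter=50_000).fit(X, y)
    return model.coef_


def residualize_block(targets: np.ndarray, predictors: np.ndarray,
                      penalty: PenaltySpec, seed: int = 0):
    """Residualize each target column on the predictor matrix.

    Returns ``(residuals, coefficients)`` with residuals n × P and
    coefficients M × P; residuals are returned raw (not re-standardized).
    """
    U = np.atleast_2d(np.asarray(targets, dtype=float).T).T
    X = np.asarray(predictors, dtype=float)
    coefs = np.column_stack([_fit_one(X, U[:, p], penalty, seed) for p in range(U.shape[1])])
    return U - X @ coefs, coefs


class SecondaryTraitResidualizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer computing the stage-1 residual pairs.

    ``fit`` learns the penalized coefficients of each secondary trait on the
    (standardized) weather and genomic blocks from training rows;
    ``transform`` produces the 2P-column matrix [u_hat_W | u_hat_V], each
    column re-standardized with training statistics so the stage-2 solver
    sees unit-variance predictors.

    Parameters
    ----------
    penalty : str, default "ridge"
        Penalty kind for both regressions.
    lam : float or None
        RSS-scale penalty weight; None triggers 5-fold CV on a log grid.
    alpha : float
        Elastic-net mixing weight (ignored otherwise).
    seed : int
        Passed to the CV routines.
    """

    def __init__(self, penalty: str = "ridge", lam: float | None = None,
                 alpha: float = 0.5, seed: int = 0):
        self.penalty = penalty
        self.lam = lam
        self.alpha = alpha
        self.seed = seed

    def _spec(self, M, n) -> PenaltySpec:
        kind, lam = self.penalty, self.lam
        if kind == "none" and M >= n:
            raise ValueError("penalty 'none' is undefined when predictors outnumber observations; "
                             "set a positive lambda")
        return PenaltySpec(kind, lam, self.alpha)

    def fit(self, secondary: np.ndarray, weather: np.ndarray, genomic: np.ndarray):
        U = np.asarray(secondary, dtype=float)
        W = np.asarray(weather, dtype=float)
        V = np.asarray(genomic, dtype=float)
        n = U.shape[0]
        rW, self.b_hat_ = residualize_block(U, W, self._spec(W.shape[1], n), self.seed)
        rV, self.d_hat_ = residualize_block(U, V, self._spec(V.shape[1], n), self.seed)
        self.penalty_used_ = PenaltySpec(self.penalty, self.lam, self.alpha)
        self.scaler_W_ = Standardizer().fit(rW)
        self.scaler_V_ = Standardizer().fit(rV)
        self.n_traits_ = U.shape[1]
        return self

    def transform(self, secondary: np.ndarray, weather: np.ndarray, genomic: np.ndarray):
        U = np.asarray(secondary, dtype=float)
        rW = U - np.asarray(weather, dtype=float) @ self.b_hat_
        rV = U - np.asarray(genomic, dtype=float) @ self.d_hat_
        return np.hstack([self.scaler_W_.transform(rW), self.scaler_V_.transform(rV)])

    def raw_residuals(self, secondary, weather, genomic) -> ResidualizedTraits:
        U = np.asarray(secondary, dtype=float)
        return ResidualizedTraits(
            u_hat_W=U - np.asarray(weather, dtype=float) @ self.b_hat_,
            u_hat_V=U - np.asarray(genomic, dtype=float) @ self.d_hat_,
            b_hat=self.b_hat_, d_hat=self.d_hat_, penalty_used=self.penalty_used_,
        )


def run_stage1(dataset: IntegratedDataset, penalty: PenaltySpec | None = None,
               seed: int = 0) -> ResidualizedTraits:
    """Residualize a dataset's secondary traits on its weather and genomic blocks.

    Blocks are standardized internally; residuals are returned raw.  The default
    penalty is ridge.
    """
    penalty = penalty or PenaltySpec("ridge")
    from .data import standardize

    sec, _ = standardize(dataset.secondary)
    wea, _ = standardize(dataset.weather)
    gen, _ = standardize(dataset.genomic)
    n = dataset.n
    if penalty.kind == "none" and gen.width >= n:
        raise ValueError("penalty 'none' undefined for the genomic block when R >= n")
    rW, b = residualize_block(sec.values, wea.values, penalty, seed)
    rV, d = residualize_block(sec.values, gen.values, penalty, seed)
    return ResidualizedTraits(rW, rV, b, d, penalty)
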