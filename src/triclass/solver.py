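"""Stage 2: penalized forward-selection logistic regression.

The classifier grows one coordinate at a time under an L1 penalty, in a
fixed block order — secondary-trait residuals first, then weather, then
genomic markers — so low-dimensional blocks are never crowded out by the
10,000-column marker block.  Each candidate coordinate is updated by a
one-dimensional Newton-Raphson step taken on the left or right side of the
penalty's kink at zero:

    theta_L = theta - s * (f' + lambda) / f''
    theta_R = theta - s * (f' - lambda) / f''

with f the binomial log-likelihood.  If theta_L < 0 the left branch is
valid; else if theta_R > 0 the right branch is valid; otherwise the
coordinate is set to zero (the one-sided soft-threshold resolution, which
at theta = 0 leaves the coordinate at zero exactly when |f'| <= lambda).
The step size s is halved (1, 1/2, ..., 1/2^10) when a candidate update
fails to improve the penalized log-likelihood (PLL).  At each pass the
single candidate giving the largest PLL increase is applied; a block's
phase ends when no candidate clears its block-specific relative-improvement
threshold epsilon.  Per-block penalties (lambda1, lambda2, lambda3) and
epsilons let the caller weight data types asymmetrically; the defaults
(1e-3 / 1e-5 / 1e-8) make entry progressively harder for wider blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

CLIP = 30.0  # linear predictor clip before exponentiation; sigmoid saturates ~1e-13 beyond

BLOCK_SECONDARY, BLOCK_WEATHER, BLOCK_GENOMIC = 0, 1, 2


@dataclass
class SolverConfig:
    """Hyperparameters of the forward-selection NR solver.

    lambdas: per-block L1 weights (secondary residuals, weather, genomic).
    eps: per-block relative convergence thresholds.
    initial_step / step_halvings: the learning-rate schedule s = 1, 1/2, ..., 1/2^10.
    max_steps: cap on accepted coordinate updates (safety bound, not a tuning knob).
    """

    lambda_secondary: float = 1.0
    lambda_weather: float = 1.0
    lambda_genomic: float = 1.0
    eps_secondary: float = 1e-3
    eps_weather: float = 1e-5
    eps_genomic: float = 1e-8
    initial_step: float = 1.0
    step_halvings: int = 10
    max_steps: int = 3000

    @property
    def lambdas(self):
        return np.array([self.lambda_secondary, self.lambda_weather, self.lambda_genomic])

    @property
    def eps(self):
        return np.array([self.eps_secondary, self.eps_weather, self.eps_genomic])


@dataclass
class TraceEntry:
    step: int
    variable: int
    block: int
    coefficient: float
    pll: float
    is_new: bool


@dataclass
class ForwardSelectionFit:
    """Fitted coefficients and the selection history of one binary sub-problem."""

    theta: np.ndarray
    intercept: float
    block_index: np.ndarray
    selection_trace: list
    model_size: int
    converged_blocks: dict
    config: SolverConfig


def _loglik(y, eta):
    eta = np.clip(eta, -CLIP, CLIP)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _sigmoid(eta):
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -CLIP, CLIP)))


def penalized_loglik(theta, y, Z, block_index=None, config: SolverConfig | None = None,
                     intercept: float = 0.0) -> float:
    """Binomial log-likelihood minus the per-block L1 penalties.

    ``block_index`` assigns each column of Z to a block (0 secondary residual,
    1 weather, 2 genomic); each block's lambda applies only to its own
    coefficients.
    """
    theta = np.asarray(theta, dtype=float)
    config = config or SolverConfig()
    if block_index is None:
        block_index = np.zeros(len(theta), dtype=int)
    eta = intercept + np.asarray(Z, dtype=float) @ theta
    pen = float(np.sum(config.lambdas[np.asarray(block_index)] * np.abs(theta)))
    return _loglik(np.asarray(y, dtype=float), eta) - pen


def nr_update(theta_ct: float, gradient: float, hessian: float,
              lambda_block: float, step: float = 1.0) -> float:
    """One left/right NR coordinate update for an L1-penalized concave objective.

    ``gradient`` and ``hessian`` are f' and f'' of the unpenalized
    log-likelihood in the coordinate; ``hessian`` must be negative.
    """
    if hessian >= 0:
        raise ValueError("log-likelihood hessian must be negative (concavity)")
    left = theta_ct - step * (gradient + lambda_block) / hessian
    right = theta_ct - step * (gradient - lambda_block) / hessian
    if left < 0:
        return left
    if right > 0:
        return right
    return 0.0


class ForwardSelectionLogistic(ClassifierMixin, BaseEstimator):
    """Binary penalized forward-selection logistic classifier.

    Parameters mirror :class:`SolverConfig`; ``block_index`` assigns each
    predictor column to a block (0 = secondary residual, 1 = weather,
    2 = genomic).  ``None`` treats every column as secondary.  An unpenalized
    intercept is refined by an exact (step-guarded) Newton step after every
    accepted coordinate update.

    Attributes
    ----------
    coef_ : ndarray (T,)
        Final coefficients, mostly zero.
    intercept_ : float
    selection_trace_ : list of TraceEntry
        Accepted updates in order, with the PLL after each.
    model_size_ : int
        Distinct variables with nonzero final coefficient.
    converged_blocks_ : dict
        Per-block flag: the phase ended with no acceptable candidate.
    """

    def __init__(self, lambda_secondary=1.0, lambda_weather=1.0, lambda_genomic=1.0,
                 eps_secondary=1e-3, eps_weather=1e-5, eps_genomic=1e-8,
                 initial_step=1.0, step_halvings=10, max_steps=3000,
                 block_index=None, refine=True):
        self.lambda_secondary = lambda_secondary
        self.lambda_weather = lambda_weather
        self.lambda_genomic = lambda_genomic
        self.eps_secondary = eps_secondary
        self.eps_weather = eps_weather
        self.eps_genomic = eps_genomic
        self.initial_step = initial_step
        self.step_halvings = step_halvings
        self.max_steps = max_steps
        self.block_index = block_index
        self.refine = refine

    def _config(self) -> SolverConfig:
        return SolverConfig(self.lambda_secondary, self.lambda_weather, self.lambda_genomic,
                            self.eps_secondary, self.eps_weather, self.eps_genomic,
                            self.initial_step, self.step_halvings, self.max_steps)

    # -- internals ---------------------------------------------------------

    def _intercept_step(self, y, eta, b0):
        """Exact Newton step on the unpenalized intercept, halved until the
        log-likelihood does not decrease."""
        ll = _loglik(y, eta)
        p = _sigmoid(eta)
        g = float(np.sum(y - p))
        h = float(-np.sum(p * (1 - p)))
        if h > -1e-12:
            return b0, eta, ll
        delta = -g / h
        s = 1.0
        for _ in range(self.step_halvings + 1):
            cand = eta + s * delta
            if _loglik(y, cand) >= ll:
                return b0 + s * delta, cand, _loglik(y, cand)
            s *= 0.5
        return b0, eta, ll

    def fit(self, X, y):
        Z = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("ForwardSelectionLogistic is binary; use "
                             "OneVsAllForwardSelection for multi-class responses")
        yb = (y == self.classes_[1]).astype(float)
        n, T = Z.shape
        cfg = self._config()
        block = (np.zeros(T, dtype=int) if self.block_index is None
                 else np.asarray(self.block_index, dtype=int))
        if len(block) != T:
            raise ValueError("block_index length must match number of columns")

        lam = cfg.lambdas[block]  # per-column lambda
        eps = cfg.eps[block]

        theta = np.zeros(T)
        pbar = float(np.clip(yb.mean(), 1e-12, 1 - 1e-12))
        b0 = float(np.log(pbar / (1 - pbar)))
        eta = np.full(n, b0)
        ll = _loglik(yb, eta)
        pll = ll  # penalty is zero at theta = 0
        trace: list[TraceEntry] = []
        selected: set[int] = set()
        converged = {}
        steps = cfg.initial_step * 0.5 ** np.arange(cfg.step_halvings + 1)
        n_accepted = 0

        for phase in (BLOCK_SECONDARY, BLOCK_WEATHER, BLOCK_GENOMIC):
            in_phase = np.where(block == phase)[0]
            if in_phase.size == 0:
                converged[phase] = True
                continue
            while n_accepted < cfg.max_steps:
                cand = in_phase
                if self.refine and selected:
                    cand = np.unique(np.concatenate([in_phase, np.fromiter(selected, int)]))
                p = _sigmoid(eta)
                w = p * (1 - p)
                ll = _loglik(yb, eta)
                Zc = Z[:, cand]
                g = Zc.T @ (yb - p)
                h = -(Zc * Zc).T @ w
                ok = h < -1e-12
                h_safe = np.where(ok, h, -1.0)  # masked out below
                accepted = False
                for s in steps:
                    left = theta[cand] - s * (g + lam[cand]) / h_safe
                    right = theta[cand] - s * (g - lam[cand]) / h_safe
                    new = np.where(left < 0, left, np.where(right > 0, right, 0.0))
                    new = np.where(ok, new, theta[cand])
                    delta = new - theta[cand]
                    live = delta != 0
                    if not np.any(live):
                        break  # smaller s only shrinks the same updates
                    idx = np.where(live)[0]
                    eta_new = eta[:, None] + Zc[:, idx] * delta[idx]
                    eta_c = np.clip(eta_new, -CLIP, CLIP)
                    ll_new = yb @ eta_c - np.logaddexp(0.0, eta_c).sum(axis=0)
                    pen_change = lam[cand[idx]] * (np.abs(new[idx]) - np.abs(theta[cand[idx]]))
                    gains = (ll_new - ll) - pen_change
                    best = int(np.argmax(gains))  # ties -> lowest column index
                    gain = float(gains[best])
                    j = int(cand[idx[best]])
                    pll_new = pll + gain
                    # Accept only if the PLL improves and the relative change
                    # still exceeds the candidate block's epsilon (otherwise
                    # the phase has converged for this candidate set).
                    if gain > 0 and gain > eps[j] * abs(pll_new):
                        was_new = j not in selected
                        theta[j] = new[idx[best]]
                        eta = eta + Zc[:, idx[best]] * delta[idx[best]]
                        if theta[j] == 0.0:
                            selected.discard(j)
                        else:
                            selected.add(j)
                        b0, eta, ll = self._intercept_step(yb, eta, b0)
                        pll = ll - float(np.sum(lam * np.abs(theta)))
                        n_accepted += 1
                        trace.append(TraceEntry(n_accepted, j, int(block[j]),
                                                float(theta[j]), pll, was_new))
                        accepted = True
                        break
                if not accepted:
                    converged[phase] = True
                    break
            else:
                converged[phase] = False

        self.coef_ = theta
        self.intercept_ = b0
        self.block_index_ = block
        self.selection_trace_ = trace
        self.model_size_ = int(np.sum(theta != 0))
        self.converged_blocks_ = converged
        self.pll_ = pll
        self.n_features_in_ = T
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        Z = np.asarray(X, dtype=float)
        if Z.shape[1] != self.n_features_in_:
            raise ValueError(f"X has {Z.shape[1]} columns, fit used {self.n_features_in_}")
        return self.intercept_ + Z @ self.coef_

    def predict_proba(self, X):
        p = _sigmoid(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X, threshold: float = 0.5):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p > threshold).astype(int)]

    def fit_result(self) -> ForwardSelectionFit:
        check_is_fitted(self, "coef_")
        return ForwardSelectionFit(self.coef_, self.intercept_, self.block_index_,
                                   self.selection_trace_, self.model_size_,
                                   self.converged_blocks_, self._config())


def forward_select_fit(y, residuals, weather, genomic, config: SolverConfig | None = None,
                       refine: bool = True) -> ForwardSelectionFit:
    """Functional wrapper: assemble [residuals | weather | genomic] and fit.

    ``residuals`` may be a ResidualizedTraits (its two sets are concatenated)
    or a plain matrix; all inputs must already be standardized.
    """
    config = config or SolverConfig()
    if hasattr(residuals, "u_hat_W"):
        Zu = np.hstack([residuals.u_hat_W, residuals.u_hat_V])
    else:
        Zu = np.asarray(residuals, dtype=float)
    parts, blocks = [], []
    for mat, code in ((Zu, BLOCK_SECONDARY), (weather, BLOCK_WEATHER), (genomic, BLOCK_GENOMIC)):
        if mat is None:
            continue
        mat = np.asarray(mat, dtype=float)
        if mat.size == 0:
            continue
        parts.append(mat)
        blocks.append(np.full(mat.shape[1], code))
    Z = np.hstack(parts)
    block_index = np.concatenate(blocks)
    est = ForwardSelectionLogistic(
        config.lambda_secondary, config.lambda_weather, config.lambda_genomic,
        config.eps_secondary, config.eps_weather, config.eps_genomic,
        config.initial_step, config.step_halvings, config.max_steps,
        block_index=block_index, refine=refine,
    ).fit(Z, np.asarray(y))
    return est.fit_result()


def predict_proba(fit: ForwardSelectionFit, Z_new) -> np.ndarray:
    """Positive-class probability for each row of Z_new (training layout)."""
    Z = np.asarray(Z_new, dtype=float)
    if Z.shape[1] != len(fit.theta):
        raise ValueError(f"Z_new has {Z.shape[1]} columns, fit used {len(fit.theta)}")
    return _sigmoid(fit.intercept + Z @ fit.theta)
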