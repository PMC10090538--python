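import numpy as np
import pytest

from triclass.solver import (BLOCK_GENOMIC, BLOCK_SECONDARY, BLOCK_WEATHER,
                             ForwardSelectionLogistic, SolverConfig, forward_select_fit,
                             nr_update, penalized_loglik, predict_proba)

from conftest import logistic_sample


def direct_binomial_loglik(theta, y, Z, intercept=0.0):
    """Pocket-calculator binomial log-likelihood (independent of the solver)."""
    eta = intercept + Z @ theta
    p = 1 / (1 + np.exp(-eta))
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


class TestPenalizedLoglik:
    def test_null_model_closed_form(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(25, 4))
        y = rng.integers(0, 2, 25)
        val = penalized_loglik(np.zeros(4), y, Z)
        assert np.isclose(val, 25 * np.log(0.5))

    def test_matches_direct_formula_when_unpenalized(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(40, 6))
        y = rng.integers(0, 2, 40)
        theta = rng.normal(size=6) * 0.5
        cfg = SolverConfig(0, 0, 0)
        got = penalized_loglik(theta, y, Z, config=cfg)
        assert np.isclose(got, direct_binomial_loglik(theta, y, Z), atol=1e-10)

    def test_per_block_penalty_arithmetic(self):
        Z = np.zeros((10, 5))
        y = np.zeros(10)
        theta = np.array([1.5, -0.5, 2.0, -1.0, 0.0])  # |alpha|=2, |beta|=3, |gamma|=0
        blocks = np.array([0, 0, 1, 1, 2])
        cfg = SolverConfig(1.0, 1.0, 1.0)
        base = penalized_loglik(np.zeros(5), y, Z, blocks, cfg)
        got = penalized_loglik(theta, y, Z, blocks, cfg)
        assert np.isclose(base - got, 5.0)


class TestNRUpdate:
    def test_zero_lambda_is_plain_newton(self):
        for theta, g, h, s in [(0.3, 1.2, -2.0, 1.0), (-1.0, -0.4, -0.5, 0.25)]:
            assert np.isclose(nr_update(theta, g, h, 0.0, s), theta - s * g / h)

    def test_soft_threshold_at_origin(self):
        # stays at zero exactly when |gradient| <= lambda (subgradient optimality)
        for g in np.linspace(-3, 3, 25):
            for lam in (0.0, 0.5, 1.0, 2.5):
                new = nr_update(0.0, g, -2.0, lam)
                if abs(g) <= lam:
                    assert new == 0.0
                else:
                    assert new != 0.0
                    assert np.sign(new) == np.sign(g)

    def test_quadratic_toy_matches_analytic_lasso(self):
        # f = -(theta-2)^2/2: f'(0) = 2, f'' = -1; lasso solution max(0, 2-1) = 1
        assert np.isclose(nr_update(0.0, 2.0, -1.0, 1.0, 1.0), 1.0)

    def test_positive_hessian_rejected(self):
        with pytest.raises(ValueError):
            nr_update(0.0, 1.0, 0.5, 1.0)


class TestForwardSelection:
    def test_pure_noise_large_lambda_selects_nothing(self):
        rng = np.random.default_rng(2)
        n = 40
        Z = rng.normal(size=(n, 30))
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        y = np.r_[np.ones(25), np.zeros(15)].astype(int)
        blocks = np.repeat([0, 1, 2], 10)
        est = ForwardSelectionLogistic(10, 10, 10, block_index=blocks).fit(Z, y)
        assert est.model_size_ == 0
        assert np.all(est.coef_ == 0)
        # null model predicts the majority class everywhere
        assert np.all(est.predict(Z) == 1)

    def test_true_secondary_variables_enter_first(self):
        rng = np.random.default_rng(3)
        n = 200
        Z = rng.normal(size=(n, 40))
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        eta = 2.0 * Z[:, 0] + 1.5 * Z[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        blocks = np.r_[np.zeros(4, int), np.ones(16, int), np.full(20, 2)]
        est = ForwardSelectionLogistic(2, 2, 2, block_index=blocks).fit(Z, y)
        new_order = [t.variable for t in est.selection_trace_ if t.is_new]
        assert set(new_order[:2]) == {0, 1}
        first_other = [v for v in new_order if blocks[v] != 0]
        assert all(new_order.index(v) >= 2 for v in first_other[:1])

    def test_unpenalized_low_dim_matches_mle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        Z, y = logistic_sample(rng, 200, [1.0, -0.7, 0.4])
        est = ForwardSelectionLogistic(0, 0, 0, eps_secondary=1e-12, eps_weather=1e-12,
                                       eps_genomic=1e-12, max_steps=20000).fit(Z, y)
        oracle = sm.Logit(y, sm.add_constant(Z)).fit(disp=0)
        assert np.allclose(est.coef_, oracle.params[1:], atol=1e-4)
        assert np.isclose(est.intercept_, oracle.params[0], atol=1e-4)

    def test_pll_monotone_along_trace(self):
        rng = np.random.default_rng(5)
        Z, y = logistic_sample(rng, 120, [1.2, -0.8], n_noise=20)
        est = ForwardSelectionLogistic(1, 1, 1,
                                       block_index=np.repeat([0, 1, 2], [8, 7, 7])).fit(Z, y)
        plls = [t.pll for t in est.selection_trace_]
        assert all(b >= a - 1e-9 for a, b in zip(plls, plls[1:]))

    def test_block_phases_never_interleave(self):
        rng = np.random.default_rng(6)
        Z, y = logistic_sample(rng, 150, [1.0, 0.8, -0.6], n_noise=27)
        blocks = np.repeat([0, 1, 2], 10)
        est = ForwardSelectionLogistic(1, 1, 1, block_index=blocks).fit(Z, y)
        first_sel = [t.block for t in est.selection_trace_ if t.is_new]
        assert first_sel == sorted(first_sel)

    def test_screened_variables_never_enter_at_null(self):
        # variable whose null-model score gradient is below lambda is not the
        # first selection
        rng = np.random.default_rng(7)
        Z, y = logistic_sample(rng, 100, [1.5], n_noise=14)
        lam = 4.0
        est = ForwardSelectionLogistic(lam, lam, lam).fit(Z, y)
        p0 = np.full(100, y.mean())
        g0 = np.abs(Z.T @ (y - p0))
        if est.selection_trace_:
            assert g0[est.selection_trace_[0].variable] > lam

    def test_multiclass_response_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="OneVsAll"):
            ForwardSelectionLogistic().fit(rng.normal(size=(30, 3)),
                                           np.repeat([1, 2, 3], 10))


class TestPrediction:
    def test_null_model_gives_half(self):
        rng = np.random.default_rng(9)
        Z, y = logistic_sample(rng, 40, [0.0])
        est = ForwardSelectionLogistic(50, 50, 50).fit(Z, y)
        est.intercept_ = 0.0
        assert np.allclose(est.predict_proba(Z)[:, 1], 0.5)

    def test_hand_logistic_evaluation(self):
        fit = forward_select_fit(
            np.array([0, 1, 0, 1] * 10),
            np.tile([[0.5, -0.5]], (40, 1)),
            np.tile([[0.1]], (40, 1)),
            None,
            SolverConfig(10, 10, 10),
        )
        fit.theta[:] = [1.0, -2.0, 0.5]
        fit.intercept = 0.3
        rows = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0], [-2.0, 0.5, 4.0]])
        got = predict_proba(fit, rows)
        eta = 0.3 + rows @ np.array([1.0, -2.0, 0.5])
        assert np.allclose(got, 1 / (1 + np.exp(-eta)), atol=1e-12)

    def test_single_coefficient_limits(self):
        fit = forward_select_fit(np.array([0, 1] * 10), np.zeros((20, 1)),
                                 None, None, SolverConfig(10, 10, 10))
        fit.theta[:] = [1.0]
        fit.intercept = 0.0
        assert np.isclose(predict_proba(fit, [[0.0]])[0], 0.5)
        assert predict_proba(fit, [[25.0]])[0] > 1 - 1e-6

    def test_column_mismatch_raises(self):
        rng = np.random.default_rng(10)
        Z, y = logistic_sample(rng, 30, [1.0, 0.5])
        est = ForwardSelectionLogistic(1, 1, 1).fit(Z, y)
        with pytest.raises(ValueError, match="columns"):
            est.predict_proba(Z[:, :1])


def test_sparsity_non_increasing_in_lambda():
    for seed in range(1, 6):
        rng = np.random.default_rng(seed)
        Z, y = logistic_sample(rng, 150, [1.5, -1.0, 0.8], n_noise=37)
        blocks = np.repeat([0, 1, 2], [10, 15, 15])
        small = ForwardSelectionLogistic(1, 1, 1, block_index=blocks).fit(Z, y)
        large = ForwardSelectionLogistic(5, 5, 5, block_index=blocks).fit(Z, y)
        assert large.model_size_ <= small.model_size_
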