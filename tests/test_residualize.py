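import numpy as np
import pytest

from triclass.residualize import (PenaltySpec, SecondaryTraitResidualizer,
                                  residualize_block, run_stage1)
from triclass.synthetic import GeneratorConfig, generate


def lasso_cd_oracle(X, y, lam, n_iter=5000, tol=1e-12):
    """Coordinate-descent minimizer of ||y - Xb||^2 + lam * sum|b| (test oracle)."""
    n, m = X.shape
    b = np.zeros(m)
    col_ss = np.sum(X ** 2, axis=0)
    r = y.copy()
    for _ in range(n_iter):
        max_move = 0.0
        for j in range(m):
            rho = X[:, j] @ r + col_ss[j] * b[j]
            new = np.sign(rho) * max(abs(rho) - lam / 2, 0.0) / col_ss[j]
            move = new - b[j]
            if move != 0:
                r -= X[:, j] * move
                b[j] = new
                max_move = max(max_move, abs(move))
        if max_move < tol:
            break
    return b


def test_ols_residuals_orthogonal_to_predictor():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(50, 1))
    y = 2 * x[:, 0] + rng.normal(size=50)
    res, coef = residualize_block(y[:, None], x, PenaltySpec("none"))
    slope = np.linalg.lstsq(x, y, rcond=None)[0][0]
    assert np.isclose(coef[0, 0], slope)
    assert abs(res[:, 0] @ x[:, 0]) < 1e-10


def test_ridge_infinite_lambda_keeps_targets():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 5))
    U = rng.normal(size=(40, 2))
    res, coef = residualize_block(U, X, PenaltySpec("ridge", 1e12))
    assert np.max(np.abs(coef)) < 1e-8
    assert np.allclose(res, U, atol=1e-6)


def test_lasso_matches_coordinate_descent_oracle():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 50))
    b_true = np.zeros(50)
    b_true[:3] = [2.0, -1.5, 1.0]
    y = X @ b_true + 0.1 * rng.normal(size=20)
    lam = 5.0
    _, coef = residualize_block(y[:, None], X, PenaltySpec("lasso", lam))
    oracle = lasso_cd_oracle(X, y, lam)
    assert np.allclose(coef[:, 0], oracle, atol=1e-6)


def test_lasso_support_shrinks_with_lambda():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(60, 30))
    y = X[:, :4] @ np.array([2.0, -2, 1.5, 1]) + 0.5 * rng.normal(size=60)
    sizes = []
    for lam in (0.5, 2, 8, 32, 128):
        _, coef = residualize_block(y[:, None], X, PenaltySpec("lasso", lam))
        sizes.append(int(np.sum(np.abs(coef) > 1e-10)))
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))


def test_lasso_support_recovery_precision():
    # u = Wb + e with sparse b: selected support should be mostly true
    rng = np.random.default_rng(4)
    n, m = 200, 50
    W = rng.normal(size=(n, m))
    b = np.zeros(m)
    true = [1, 7, 19, 30, 42]
    b[true] = rng.choice([-1, 1], 5) * rng.uniform(0.8, 1.5, 5)
    u = W @ b + rng.normal(size=n)
    lam = 2 * n * np.sqrt(2 * np.log(m) / n)  # universal-threshold scaling
    _, coef = residualize_block(u[:, None], W, PenaltySpec("lasso", lam))
    picked = set(np.where(np.abs(coef[:, 0]) > 1e-8)[0])
    assert picked, "nothing selected"
    precision = len(picked & set(true)) / len(picked)
    assert precision >= 0.9


def test_adaptive_lasso_runs_and_rejects_bad_weights():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 10))
    y = X[:, 0] * 2 + rng.normal(size=30)
    _, coef = residualize_block(y[:, None], X, PenaltySpec("adaptive_lasso", 1.0))
    assert abs(coef[0, 0]) > 0.5
    with pytest.raises(ValueError):
        residualize_block(y[:, None], X,
                          PenaltySpec("adaptive_lasso", 1.0, adaptive_weights=-np.ones(10)))


def test_penalty_none_requires_full_rank():
    rng = np.random.default_rng(6)
    with pytest.raises(ValueError):
        residualize_block(rng.normal(size=(10, 1)), rng.normal(size=(10, 20)),
                          PenaltySpec("none"))


def test_elastic_net_extremes_match_lasso_and_ridge():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 8))
    y = rng.normal(size=40)
    _, c_l = residualize_block(y[:, None], X, PenaltySpec("elastic_net", 3.0, alpha=1.0))
    _, c_lasso = residualize_block(y[:, None], X, PenaltySpec("lasso", 3.0))
    assert np.allclose(c_l, c_lasso)
    _, c_r = residualize_block(y[:, None], X, PenaltySpec("elastic_net", 3.0, alpha=0.0))
    _, c_ridge = residualize_block(y[:, None], X, PenaltySpec("ridge", 3.0))
    assert np.allclose(c_r, c_ridge)


class TestRunStage1:
    def test_default_penalty_is_ridge(self, tiny_dataset):
        ds, _ = tiny_dataset
        out = run_stage1(ds.subset(np.arange(100)))
        assert out.penalty_used.kind == "ridge"
        assert out.u_hat_W.shape == (100, ds.P)
        assert out.u_hat_V.shape == (100, ds.P)

    def test_residual_identity_holds(self, tiny_dataset):
        # u_hat = u - W b_hat exactly for the stored coefficients
        ds, _ = tiny_dataset
        sub = ds.subset(np.arange(150))
        from triclass.data import standardize

        sec, _ = standardize(sub.secondary)
        wea, _ = standardize(sub.weather)
        out = run_stage1(sub, PenaltySpec("ridge", 10.0))
        assert np.allclose(out.u_hat_W, sec.values - wea.values @ out.b_hat, atol=1e-10)

    def test_zero_confounding_leaves_traits_intact(self):
        # Q and R must be small relative to n or the unconfounded regression
        # itself erodes the traits by fitting noise (R^2 ~ Q/n)
        cfg = GeneratorConfig(n_lines=500, n_envs=8, n_days=10, n_snps=30,
                              window=(3, 9), snp_support=(2,), snp_effects=(0.4,),
                              confounding_weather=0.0, confounding_snp=0.0, seed=9)
        ds, _ = generate(cfg)
        out = run_stage1(ds, PenaltySpec("none"))
        sec = (ds.secondary.values - ds.secondary.values.mean(0)) / ds.secondary.values.std(0, ddof=1)
        for p in range(ds.P):
            r = np.corrcoef(out.u_hat_W[:, p], sec[:, p])[0, 1]
            assert r > 0.99


def test_residualizer_transform_uses_training_coefficients():
    rng = np.random.default_rng(8)
    n, P, Q, R = 80, 3, 10, 15
    U, W, V = rng.normal(size=(n, P)), rng.normal(size=(n, Q)), rng.normal(size=(n, R))
    res = SecondaryTraitResidualizer(penalty="ridge", lam=1.0).fit(U[:60], W[:60], V[:60])
    Zte = res.transform(U[60:], W[60:], V[60:])
    raw_W = U[60:] - W[60:] @ res.b_hat_
    expect = res.scaler_W_.transform(raw_W)
    assert np.allclose(Zte[:, :P], expect)
    assert Zte.shape == (20, 2 * P)
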