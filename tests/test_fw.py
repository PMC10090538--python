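import numpy as np
import pytest

from triclass.data import DailyWeatherPanel
from triclass.fw import (build_fwe_block, daily_first_pc, environmental_means,
                         find_optimal_window, scan_windows, window_mean)
from triclass.synthetic import GeneratorConfig, generate


def test_environmental_means_arithmetic():
    env = np.array(["a", "a", "b", "b"])
    labels, means = environmental_means(env, np.array([1.0, 3, 5, 7]))
    assert labels.tolist() == ["a", "b"]
    assert means.tolist() == [2.0, 6.0]
    _, const = environmental_means(env, np.full(4, 3.3))
    assert np.allclose(const, 3.3)


class TestDailyFirstPC:
    def test_rank_one_two_variables(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(6, 1, 10))
        vals = np.concatenate([base, 2 * base], axis=1)  # perfectly correlated pair
        panel = DailyWeatherPanel(vals, ["a", "b"], list(range(6)))
        scores = daily_first_pc(panel)
        norm = panel.normalized().values
        for d in range(10):
            r = np.corrcoef(scores[:, d], norm[:, 0, d])[0, 1]
            assert abs(r) > 1 - 1e-10

    def test_hand_computed_3x2_slice(self):
        vals = np.array([[[1.0], [2.0]], [[2.0], [0.0]], [[3.0], [4.0]]])  # k=3,V=2,D=1
        panel = DailyWeatherPanel(vals, ["a", "b"], [0, 1, 2])
        scores = daily_first_pc(panel)[:, 0]
        # oracle: eigen-decomposition of the 2x2 covariance of the centered slice
        norm = panel.normalized().values[:, :, 0]
        c = norm - norm.mean(0)
        cov = c.T @ c
        w, v = np.linalg.eigh(cov)
        lead = v[:, np.argmax(w)]
        if lead[np.argmax(np.abs(lead))] < 0:
            lead = -lead
        assert np.allclose(scores, c @ lead, atol=1e-10)

    def test_too_few_environments_rejected(self):
        panel = DailyWeatherPanel(np.zeros((1, 2, 5)), ["a", "b"], [0])
        with pytest.raises(ValueError):
            daily_first_pc(panel)


def test_window_mean_arithmetic_and_errors():
    series = np.arange(1.0, 11)[None, :]
    assert np.isclose(window_mean(series, 1, 10)[0], 5.5)
    assert np.isclose(window_mean(np.array([[4.0, 6.0]]), 1, 2)[0], 5.0)
    assert np.allclose(window_mean(np.full((3, 10), 2.5), 4, 7), 2.5)
    with pytest.raises(ValueError):
        window_mean(series, 7, 7)


class TestScanWindows:
    def test_constructed_perfect_fit_is_exact(self):
        rng = np.random.default_rng(1)
        index = rng.normal(size=(8, 60))
        ybar = index[:, 19:30].mean(axis=1)  # days 20..30
        res = scan_windows(ybar, index)
        assert res.best_window == (20, 30)
        assert res.best_r2 == 1.0

    def test_surface_bounded_and_nan_outside(self):
        rng = np.random.default_rng(2)
        res = scan_windows(rng.normal(size=8), rng.normal(size=(8, 20)), min_len=3)
        vals = res.r2_surface[~np.isnan(res.r2_surface)]
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.isnan(res.r2_surface[5, 5])  # b == e not a window
        assert np.isnan(res.r2_surface[3, 4])  # length 2 < min_len

    def test_affine_index_transform_leaves_surface_unchanged(self):
        rng = np.random.default_rng(3)
        index = rng.normal(size=(8, 30))
        ybar = rng.normal(size=8)
        a = scan_windows(ybar, index)
        b = scan_windows(ybar, 3.7 * index - 12.0)
        assert np.allclose(np.nan_to_num(a.r2_surface), np.nan_to_num(b.r2_surface))
        assert a.best_window == b.best_window

    def test_permutation_null_reference(self):
        rng = np.random.default_rng(4)
        ds, truth = generate(GeneratorConfig(n_lines=25, n_envs=8, n_days=40,
                                             n_snps=30, window=(10, 25), seed=5,
                                             snp_support=(2,), snp_effects=(0.4,)))
        _, ybar = environmental_means(ds.environment_id, ds.continuous_trait)
        index = daily_first_pc(ds.weather_panel)
        true_r2 = scan_windows(ybar, index).best_r2
        null = [scan_windows(rng.permutation(ybar), index).best_r2 for _ in range(50)]
        assert true_r2 > np.mean(null)

    def test_zero_variance_window_flagged(self):
        index = np.zeros((8, 10))
        index[:, 5:] = np.random.default_rng(6).normal(size=(8, 5))
        res = scan_windows(np.arange(8.0), index)
        assert (1, 2) in res.flagged_windows
        assert res.r2_surface[0, 1] == 0.0


class TestFweBlock:
    def test_window_18_25_width_32(self, tiny_dataset):
        ds, _ = tiny_dataset
        blk = build_fwe_block(ds, (18, 25))
        assert blk.width == 4 * 8
        assert blk.name == "weather"

    def test_identity_window_recovers_full_block(self, tiny_dataset):
        ds, _ = tiny_dataset
        blk = build_fwe_block(ds, (1, ds.weather_panel.n_days))
        assert blk.width == ds.Q
        assert np.allclose(blk.values, ds.weather.values)

    def test_values_match_panel_days(self, tiny_dataset):
        ds, _ = tiny_dataset
        blk = build_fwe_block(ds, (5, 9))
        env0 = ds.environment_id[0]
        k = list(ds.weather_panel.env_ids).index(env0)
        expect = ds.weather_panel.values[k, :, 4:9].ravel()
        assert np.allclose(blk.values[0], expect)


def test_mt_configs_force_zero_weather_penalty():
    from triclass.experiment import MODEL_GRID, _resolve_candidates

    for model in ("MT1", "MT2"):
        trips = _resolve_candidates(MODEL_GRID[model], [(1, 1, 1), (5, 5, 5)])
        assert all(t[1] == 0 for t in trips)
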