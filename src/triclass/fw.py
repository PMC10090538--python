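"""Finlay-Wilkinson-style optimal weather-window search.

The quantitative trait is decomposed as y_ij = mu + G_i + E_j + e_ij; the
environmental means ybar_.j summarize E_j.  Daily weather variables are
combined into a single environmental index by taking, for each day, the
first principal component of the normalized k x V slice.  The window (b, e)
whose window-mean index is most linearly associated with the environmental
means (highest R^2 = cor^2) is the optimal window; all daily weather
variables inside it form the FWE predictor block, which enters the stage-2
solver with lambda_weather = 0 (no further selection on that block).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DailyWeatherPanel, IntegratedDataset, PredictorBlock


@dataclass
class WindowScanResult:
    """R^2 surface over candidate windows and its argmax.

    ``r2_surface[b-1, e-1]`` holds cor(ybar, window mean)^2 for the window
    of days b..e; cells outside the candidate set are NaN.
    """

    r2_surface: np.ndarray
    best_window: tuple
    best_r2: float
    index_type: str = "pca_first_pc"
    flagged_windows: list = None


def environmental_means(environment_id, trait) -> tuple[np.ndarray, np.ndarray]:
    """Mean of the (continuous) trait over lines within each environment.

    Returns (env_labels, means), environments in sorted label order.
    """
    env = np.asarray(environment_id)
    y = np.asarray(trait, dtype=float)
    labels = np.unique(env)
    means = np.array([y[env == e].mean() for e in labels])
    if np.any([np.sum(env == e) == 0 for e in labels]):
        raise ValueError("environment with no observations")
    return labels, means


def daily_first_pc(panel: DailyWeatherPanel) -> np.ndarray:
    """First-PC score per environment per day from the normalized panel.

    Each day's k x V slice is column-centered and decomposed; the score is
    the projection on the leading right-singular vector, whose sign is fixed
    so its largest-magnitude loading is positive.  Returns a k x D matrix.
    """
    if panel.n_envs < 2:
        raise ValueError("PCA needs at least 2 environments")
    if panel.n_vars < 2:
        raise ValueError("PCA needs at least 2 variables")
    norm = panel.normalized().values  # (k, V, D)
    k, V, D = norm.shape
    scores = np.empty((k, D))
    for d in range(D):
        slc = norm[:, :, d]
        slc = slc - slc.mean(axis=0)
        _, _, vt = np.linalg.svd(slc, full_matrices=False)
        load = vt[0]
        if load[np.argmax(np.abs(load))] < 0:
            load = -load
        scores[:, d] = slc @ load
    return scores


def window_mean(series: np.ndarray, b: int, e: int) -> np.ndarray:
    """Arithmetic mean of days b..e inclusive (1-indexed) per environment."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if not 1 <= b < e <= series.shape[1]:
        raise ValueError(f"need 1 <= b < e <= D, got b={b}, e={e}")
    return series[:, b - 1:e].mean(axis=1)


def scan_windows(env_means: np.ndarray, index: np.ndarray, min_len: int = 2) -> WindowScanResult:
    """Exhaustive R^2 scan over all windows (b, e) with e-b+1 >= min_len.

    Ties are broken toward the earliest start, then the shortest window.
    Windows whose mean is constant across environments are set to R^2 = 0
    and flagged.
    """
    ybar = np.asarray(env_means, dtype=float)
    X = np.atleast_2d(np.asarray(index, dtype=float))
    k, D = X.shape
    if k < 3:
        raise ValueError("need at least 3 environments for a correlation")
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    yc = ybar - ybar.mean()
    ynorm = np.sqrt(np.sum(yc ** 2))
    cs = np.concatenate([np.zeros((k, 1)), np.cumsum(X, axis=1)], axis=1)
    surface = np.full((D, D), np.nan)
    flagged = []
    best = (None, -1.0)
    for b in range(1, D + 1):
        lens = np.arange(b + min_len - 1, D + 1) - b + 1  # e - b + 1
        es = np.arange(b + min_len - 1, D + 1)
        if es.size == 0:
            continue
        means = (cs[:, es] - cs[:, [b - 1]]) / lens  # k x n_windows
        mc = means - means.mean(axis=0)
        denom = np.sqrt(np.sum(mc ** 2, axis=0)) * ynorm
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = (yc @ mc / denom) ** 2
        # bound to [0, 1]; values within 1e-12 of 1 (floating residue of an
        # exact linear fit) are snapped to exactly 1
        r2 = np.clip(r2, 0.0, 1.0)
        r2 = np.where(r2 >= 1.0 - 1e-12, 1.0, r2)
        zerovar = denom == 0
        if np.any(zerovar):
            flagged.extend((b, int(e)) for e in es[zerovar])
            r2 = np.where(zerovar, 0.0, r2)
        surface[b - 1, es - 1] = r2
        j = int(np.argmax(r2))  # earliest (shortest) window wins ties within a row
        if r2[j] > best[1] + 1e-15:
            best = ((b, int(es[j])), float(r2[j]))
    return WindowScanResult(surface, best[0], best[1], flagged_windows=flagged)


def find_optimal_window(dataset: IntegratedDataset, trait=None, min_len: int = 2,
                        index_type: str = "pca_first_pc", variable: int = 0) -> WindowScanResult:
    """End-to-end window search on a dataset with a daily weather panel."""
    if dataset.weather_panel is None:
        raise ValueError("dataset has no daily weather panel")
    if trait is None:
        trait = dataset.continuous_trait
        if trait is None:
            raise ValueError("no continuous trait available; pass one explicitly")
    env_labels, ybar = environmental_means(dataset.environment_id, trait)
    panel = dataset.weather_panel
    order = [list(panel.env_ids).index(e) for e in env_labels]
    if index_type == "pca_first_pc":
        index = daily_first_pc(panel)[order]
    else:
        index = panel.normalized().values[order, variable, :]
    res = scan_windows(ybar, index, min_len=min_len)
    res.index_type = index_type
    return res


def build_fwe_block(dataset: IntegratedDataset, window: tuple) -> PredictorBlock:
    """All V daily weather variables restricted to days b..e (width V*(e-b+1)).

    Stage-2 configurations using this block set lambda_weather = 0: the
    window itself was the selection step, so its variables enter unpenalized.
    """
    b, e = window
    panel = dataset.weather_panel
    if panel is None:
        raise ValueError("dataset has no daily weather panel")
    if not 1 <= b < e <= panel.n_days:
        raise ValueError(f"invalid window {window}")
    env_pos = {env: i for i, env in enumerate(panel.env_ids)}
    rows = np.array([env_pos[env] for env in dataset.environment_id])
    sub = panel.values[:, :, b - 1:e]  # (k, V, len)
    flat = sub.reshape(panel.n_envs, -1)
    labels = [f"{v}_d{d}" for v in panel.variable_names for d in range(b, e + 1)]
    return PredictorBlock("weather", flat[rows], labels)
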