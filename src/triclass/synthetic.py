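"""Synthetic multi-environment trial generator.

Emulates the structure the three-stage classifier assumes: lines genotyped
at genome-wide markers, evaluated in a handful of environments with daily
weather records, secondary traits confounded with both weather and markers,
and a continuous main trait y_ij = mu + G_i + E_j + intrinsic + error whose
environmental component is driven by the weather inside one true time
window.  The continuous trait is discretized into three percentile classes
(bottom 25% / a 25%-wide band centered on the mean / top 25%) with the
remaining observations left unlabeled.

Every random draw flows from ``GeneratorConfig.seed``; the stored
``GeneratedTruth`` lets recovery tests score window and variable selection
against the planted signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DailyWeatherPanel, IntegratedDataset, PredictorBlock, SplitPlan, make_split, _largest_remainder

BALANCES = {"33-34-33": (33, 34, 33), "40-40-20": (40, 40, 20), "10-80-10": (10, 80, 10)}

WEATHER_VARIABLE_NAMES = ("Tmax", "Tmin", "WS", "Precip")


@dataclass
class GeneratorConfig:
    """Study-shaped simulation settings.

    Defaults mirror the full chickpea-shaped design (749 lines x 8
    environments, 6 secondary traits, 4 daily weather variables over a
    100-day season, 10,000 markers); ``test_scale`` shrinks only the line
    and marker counts for desk-scale runs, never the structure.
    """

    n_lines: int = 749
    n_envs: int = 8
    n_secondary: int = 6
    n_weather_vars: int = 4
    n_days: int = 100
    n_snps: int = 10_000
    # planted signal
    snp_support: tuple = (10, 25, 40, 55, 70)
    snp_effects: tuple = (0.4, 0.4, 0.4, 0.4, 0.4)
    window: tuple = (35, 55)
    window_effect: float = 1.0
    secondary_intrinsic_effects: tuple = (1.0, 0.8, 0.0, 0.0, 0.0, 0.0)
    confounding_weather: float = 0.5
    confounding_snp: float = 0.5
    noise_sd: float = 1.0
    mu: float = 100.0
    seed: int = 0

    def __post_init__(self):
        b, e = self.window
        if not 1 <= b < e <= self.n_days:
            raise ValueError(f"window {self.window} outside 1..{self.n_days}")
        if len(self.snp_support) != len(self.snp_effects):
            raise ValueError("snp_support and snp_effects length mismatch")
        if max(self.snp_support, default=-1) >= self.n_snps:
            raise ValueError("snp_support index outside marker range")
        if len(self.secondary_intrinsic_effects) != self.n_secondary:
            raise ValueError("secondary_intrinsic_effects must have one entry per trait")

    @classmethod
    def test_scale(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """Desk-scale defaults: 150 lines, 500 markers; structure unchanged."""
        return cls(n_lines=150, n_snps=500, seed=seed, **overrides)


@dataclass
class GeneratedTruth:
    true_snp_effects: np.ndarray
    true_window: tuple
    true_secondary_effects: np.ndarray
    continuous_trait: np.ndarray
    class_labels: np.ndarray
    intrinsic_latent: np.ndarray  # n x P, the component stage 1 should preserve


def _zscore(x, axis=0):
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=axis, keepdims=True)) / sd


def _smooth_curve(rng, d, sd):
    """Random smooth low-frequency curve: 3 damped cosine harmonics."""
    curve = np.zeros(len(d))
    for h in (1, 2, 3):
        curve += rng.normal(0, sd / h) * np.cos(2 * np.pi * h * d + rng.uniform(0, 2 * np.pi))
    return curve


def _weather_panel(cfg: GeneratorConfig, rng):
    """Daily weather per environment plus the latent common environmental mode.

    Each variable = seasonal trajectory + loading_v * common mode of the
    environment + a smaller variable-specific environment curve + AR(1)
    day-to-day noise.  The shared mode is what makes the daily first PC a
    coherent environmental index (co-varying weather variables), mirroring
    real multi-site weather.
    """
    k, V, D = cfg.n_envs, cfg.n_weather_vars, cfg.n_days
    d = np.arange(1, D + 1) / D
    base_level = np.array([28.0, 14.0, 8.0, 5.0][:V] if V <= 4 else
                          [10.0 + 6 * v for v in range(V)])
    base_amp = np.array([4.0, 4.0, 2.0, 3.0][:V] if V <= 4 else [2.0 + v for v in range(V)])
    phase = np.array([0.3, 0.5, 1.8, 1.2][:V] if V <= 4 else rng.uniform(0, 2, V))
    loadings = rng.uniform(0.8, 1.2, V)  # every variable tracks the common mode
    common = np.stack([_smooth_curve(rng, d, 4.0) for _ in range(k)])  # (k, D)
    vals = np.empty((k, V, D))
    for v in range(V):
        seasonal = base_level[v] + base_amp[v] * np.sin(2 * np.pi * d + phase[v])
        for j in range(k):
            own = _smooth_curve(rng, d, 0.3)
            ar = np.empty(D)
            ar[0] = rng.normal(0, 0.8)
            innov = rng.normal(0, 0.8, D)
            for t in range(1, D):
                ar[t] = 0.6 * ar[t - 1] + innov[t]
            vals[j, v] = seasonal + loadings[v] * common[j] + own + ar
    names = list(WEATHER_VARIABLE_NAMES[:V]) if V <= 4 else [f"wv{v+1}" for v in range(V)]
    return DailyWeatherPanel(vals, names, [f"env{j+1}" for j in range(k)]), common


def generate(config: GeneratorConfig) -> tuple[IntegratedDataset, GeneratedTruth]:
    """Simulate one multi-environment dataset plus its generating truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    t, k, P, R = cfg.n_lines, cfg.n_envs, cfg.n_secondary, cfg.n_snps
    n = t * k

    # markers: per-locus MAF ~ U(0.1, 0.5), dosage Binomial(2, maf) per line
    maf = rng.uniform(0.1, 0.5, R)
    geno = rng.binomial(2, maf, size=(t, R)).astype(float)
    geno_std = _zscore(geno)

    panel, common = _weather_panel(cfg, rng)
    b, e = cfg.window
    win_idx = common[:, b - 1:e].mean(axis=1)  # window mean of the common mode
    win_idx_z = _zscore(win_idx)

    env_of_obs = np.repeat(np.arange(k), t)   # env-major ordering
    line_of_obs = np.tile(np.arange(t), k)

    # secondary traits: weather + marker confounding + intrinsic latent + noise
    snp_conf = np.zeros((t, P))
    conf_loci = rng.choice(R, size=(P, 10), replace=True)
    for p in range(P):
        wts = rng.normal(0, 1, 10)
        score = geno_std[:, conf_loci[p]] @ wts
        snp_conf[:, p] = _zscore(score).ravel()
    latent = rng.normal(0, 1, size=(n, P))
    secondary = (cfg.confounding_weather * win_idx_z[env_of_obs][:, None]
                 + cfg.confounding_snp * snp_conf[line_of_obs]
                 + latent
                 + rng.normal(0, 0.3, size=(n, P)))

    # main trait: y_ij = mu + G_i + E_j + intrinsic + error
    snp_eff = np.zeros(R)
    snp_eff[list(cfg.snp_support)] = cfg.snp_effects
    G = geno_std @ snp_eff
    E = cfg.window_effect * win_idx_z
    intrinsic = latent @ np.asarray(cfg.secondary_intrinsic_effects)
    y = cfg.mu + G[line_of_obs] + E[env_of_obs] + intrinsic + rng.normal(0, cfg.noise_sd, n)

    labels = discretize_trait(y, "three_class_percentile")

    weather_cols = [f"{v}_d{d}" for v in panel.variable_names for d in range(1, cfg.n_days + 1)]
    weather_obs = panel.values.reshape(k, -1)[env_of_obs]
    dataset = IntegratedDataset(
        response=labels,
        secondary=PredictorBlock("secondary", secondary, [f"trait{p+1}" for p in range(P)]),
        weather=PredictorBlock("weather", weather_obs, weather_cols),
        genomic=PredictorBlock("genomic", geno[line_of_obs], [f"snp{r+1}" for r in range(R)]),
        environment_id=np.array(panel.env_ids)[env_of_obs],
        line_id=np.array([f"line{i+1}" for i in range(t)])[line_of_obs],
        weather_panel=panel,
        continuous_trait=y,
    )
    truth = GeneratedTruth(snp_eff, cfg.window, np.asarray(cfg.secondary_intrinsic_effects),
                           y, labels, latent)
    return dataset, truth


def discretize_trait(trait, scheme: str = "three_class_percentile") -> np.ndarray:
    """Discretize a continuous trait.

    ``three_class_percentile``: rank-based bands — bottom 25% -> class 1,
    top 25% -> class 3, and a 25%-wide percentile band centered on the
    mean's percentile -> class 2; everything else is unlabeled (0).
    ``binary_median``: 0/1 split at the median.
    """
    y = np.asarray(trait, dtype=float)
    n = len(y)
    if n < 8:
        raise ValueError("trait too short to discretize")
    order = np.argsort(y, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)

    if scheme == "binary_median":
        return (y > np.median(y)).astype(int)
    if scheme != "three_class_percentile":
        raise ValueError(f"unknown scheme {scheme!r}")

    n_band = int(round(0.25 * n))
    if n_band == 0 or len(np.unique(y)) < 4:
        raise ValueError("trait has too few distinct values for percentile bands")
    labels = np.zeros(n, dtype=int)
    labels[ranks < n_band] = 1
    labels[ranks >= n - n_band] = 3
    center_frac = float(np.mean(y < y.mean()))
    lo = int(round((center_frac - 0.125) * n))
    lo = min(max(lo, n_band), n - n_band - n_band)  # keep the band inside the gap
    labels[(ranks >= lo) & (ranks < lo + n_band)] = 2
    if not np.all(np.bincount(labels, minlength=4)[1:] > 0):
        raise ValueError("a percentile band is empty (heavy ties?)")
    return labels


def sample_balance(labels, balance, n_sample: int = 280, seed: int = 0) -> np.ndarray:
    """Class-balanced sample of labeled observations, without replacement.

    ``balance`` is a name like ``"10-80-10"`` or a percentage tuple; class
    counts are apportioned by largest remainder (ties to the lower class), so
    280 at 33-34-33 gives (93, 95, 92), at 40-40-20 gives (112, 112, 56), and
    at 10-80-10 gives (28, 224, 28).
    """
    if isinstance(balance, str):
        if balance not in BALANCES:
            raise ValueError(f"unknown balance {balance!r}; use one of {sorted(BALANCES)}")
        pct = BALANCES[balance]
    else:
        pct = tuple(balance)
    labels = np.asarray(labels)
    counts = _largest_remainder(n_sample, pct)
    rng = np.random.default_rng(seed)
    chosen = []
    for c, m in zip(range(1, len(pct) + 1), counts):
        members = np.where(labels == c)[0]
        if len(members) < m:
            raise ValueError(f"class {c} has only {len(members)} labeled observations, need {m}")
        chosen.append(rng.choice(members, size=m, replace=False))
    return np.concatenate(chosen)


def replicate(config: GeneratorConfig, balance, n_reps: int, base_seed: int = 0,
              n_sample: int = 280, train_n: int = 200, test_n: int = 80,
              dataset: IntegratedDataset | None = None) -> list[tuple[SplitPlan, np.ndarray]]:
    """n_reps class-balanced samples with stratified 200/80 splits.

    Returns a list of (SplitPlan, sampled index set); replication r uses seed
    base_seed + r.  A pre-generated dataset may be passed to avoid regeneration.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if dataset is None:
        dataset, _ = generate(config)
    out = []
    for r in range(n_reps):
        s = base_seed + r
        idx = sample_balance(dataset.response, balance, n_sample=n_sample, seed=s)
        plan = make_split(dataset, n_sample=n_sample, train_n=train_n, test_n=test_n,
                          optimization_n=0, seed=s, stratify=True,
                          labels=dataset.response, candidate_idx=idx)
        out.append((plan, idx))
    return out
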