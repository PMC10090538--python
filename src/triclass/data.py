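"""Data containers, ingestion, alignment, and standardization.

Observations are line × environment combinations.  Three predictor blocks
(secondary traits, daily weather, genome-wide markers) share one row order
with the categorical response.  Standardization is always computed on
training rows and applied to held-out rows with the training statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

BLOCK_NAMES = ("secondary", "weather", "genomic")


@dataclass
class PredictorBlock:
    """A named numeric predictor matrix with column labels.

    Parameters
    ----------
    name : str
        One of ``{"secondary", "weather", "genomic"}``.
    values : ndarray of shape (n, m)
        Dense numeric matrix, no missing values.
    column_labels : list of str
    """

    name: str
    values: np.ndarray
    column_labels: list[str]

    def __post_init__(self):
        if self.name not in BLOCK_NAMES:
            raise ValueError(f"block name must be one of {BLOCK_NAMES}, got {self.name!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("block values must be 2-D")
        if self.values.shape[1] != len(self.column_labels):
            raise ValueError("column_labels length does not match value width")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"block {self.name!r} contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class DailyWeatherPanel:
    """Environment-level daily weather: shape (k environments, V variables, D days)."""

    values: np.ndarray
    variable_names: list[str]
    env_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("panel must be (k, V, D)")
        if self.values.shape[1] != len(self.variable_names):
            raise ValueError("variable_names length mismatch")
        if self.values.shape[0] != len(self.env_ids):
            raise ValueError("env_ids length mismatch")

    @property
    def n_envs(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    @property
    def n_days(self) -> int:
        return self.values.shape[2]

    def normalized(self) -> "DailyWeatherPanel":
        """Per-variable normalization across all environment × day cells."""
        v = self.values
        mu = v.mean(axis=(0, 2), keepdims=True)
        sd = v.std(axis=(0, 2), ddof=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        return DailyWeatherPanel((v - mu) / sd, list(self.variable_names), list(self.env_ids))


@dataclass
class IntegratedDataset:
    """Aligned response and the three predictor blocks.

    ``response`` uses a contiguous integer class coding 1..C; a value of 0
    marks observations left unlabeled by the discretization scheme (they are
    excluded from class-balanced sampling).
    """

    response: np.ndarray
    secondary: PredictorBlock
    weather: PredictorBlock
    genomic: PredictorBlock
    environment_id: np.ndarray
    line_id: np.ndarray
    weather_panel: DailyWeatherPanel | None = None
    continuous_trait: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.response)
        for blk in (self.secondary, self.weather, self.genomic):
            if blk.n != n:
                raise ValueError(f"block {blk.name!r} has {blk.n} rows, expected {n}")
        if len(self.environment_id) != n or len(self.line_id) != n:
            raise ValueError("environment_id / line_id length mismatch")

    @property
    def n(self) -> int:
        return len(self.response)

    @property
    def n_classes(self) -> int:
        labels = self.response[self.response > 0]
        return int(labels.max()) if labels.size else 0

    @property
    def P(self) -> int:
        return self.secondary.width

    @property
    def Q(self) -> int:
        return self.weather.width

    @property
    def R(self) -> int:
        return self.genomic.width

    @property
    def T(self) -> int:
        """Full stage-2 predictor dimension after residual duplication: 2P + Q + R."""
        return 2 * self.P + self.Q + self.R

    def subset(self, idx) -> "IntegratedDataset":
        idx = np.asarray(idx)
        return IntegratedDataset(
            response=self.response[idx],
            secondary=replace(self.secondary, values=self.secondary.values[idx]),
            weather=replace(self.weather, values=self.weather.values[idx]),
            genomic=replace(self.genomic, values=self.genomic.values[idx]),
            environment_id=np.asarray(self.environment_id)[idx],
            line_id=np.asarray(self.line_id)[idx],
            weather_panel=self.weather_panel,
            continuous_trait=None if self.continuous_trait is None else self.continuous_trait[idx],
        )


@dataclass
class SplitPlan:
    """Disjoint train / optimization / test index sets."""

    train_idx: np.ndarray
    optimization_idx: np.ndarray
    test_idx: np.ndarray
    seed: int = 0

    def __post_init__(self):
        parts = [np.asarray(p, dtype=int) for p in (self.train_idx, self.optimization_idx, self.test_idx)]
        self.train_idx, self.optimization_idx, self.test_idx = parts
        allidx = np.concatenate(parts)
        if len(np.unique(allidx)) != len(allidx):
            raise ValueError("split index sets are not pairwise disjoint")


class Standardizer:
    """Column-wise standardization to mean 0, sample sd 1 (ddof=1).

    Constant columns are excluded and recorded in ``dropped_``.  Fitted on
    training rows only; ``transform`` reuses the training statistics so held-out
    rows never contribute to centering or scaling.
    """

    def __init__(self):
        self.means_ = None
        self.sds_ = None
        self.keep_ = None
        self.dropped_ = None

    def fit(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("standardization needs n >= 2 rows")
        self.means_ = X.mean(axis=0)
        self.sds_ = X.std(axis=0, ddof=1)
        self.keep_ = self.sds_ > 0
        self.dropped_ = np.where(~self.keep_)[0]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X[:, self.keep_] - self.means_[self.keep_]) / self.sds_[self.keep_]

    def fit_transform(self, X):
        return self.fit(X).transform(X)


def standardize(block: PredictorBlock) -> tuple[PredictorBlock, Standardizer]:
    """Standardize a block's columns; returns the new block and the fitted transform.

    Zero-variance columns are dropped (their labels disappear from the block);
    the transform records their indices in ``dropped_``.
    """
    sc = Standardizer().fit(block.values)
    labels = [lab for lab, k in zip(block.column_labels, sc.keep_) if k]
    return PredictorBlock(block.name, sc.transform(block.values), labels), sc


def _largest_remainder(total: int, fractions) -> np.ndarray:
    """Apportion ``total`` by ``fractions``; ties in remainders go to the lower index."""
    fractions = np.asarray(fractions, dtype=float)
    raw = fractions / fractions.sum() * total
    base = np.floor(raw).astype(int)
    rem = raw - base
    short = total - base.sum()
    order = np.lexsort((np.arange(len(raw)), -rem))
    base[order[:short]] += 1
    return base


def make_split(
    dataset: IntegratedDataset | None,
    n_sample: int,
    train_n: int,
    test_n: int,
    optimization_n: int = 0,
    seed: int = 0,
    stratify: bool = False,
    labels: np.ndarray | None = None,
    candidate_idx: np.ndarray | None = None,
) -> SplitPlan:
    """Reproducible train / optimization / test split.

    ``candidate_idx`` restricts the pool (e.g. a class-balanced sample of 280);
    otherwise all dataset rows are candidates.  With ``stratify``, class
    proportions are preserved within ±1 observation per class using
    largest-remainder allocation.
    """
    if train_n + test_n + optimization_n != n_sample:
        raise ValueError("train_n + test_n + optimization_n must equal n_sample")
    if labels is None:
        if dataset is None:
            raise ValueError("need a dataset or explicit labels")
        labels = dataset.response
    labels = np.asarray(labels)
    pool = np.arange(len(labels)) if candidate_idx is None else np.asarray(candidate_idx, dtype=int)
    if n_sample > len(pool):
        raise ValueError(f"n_sample={n_sample} exceeds pool of {len(pool)}")
    rng = np.random.default_rng(seed)

    if not stratify:
        chosen = rng.choice(pool, size=n_sample, replace=False)
        return SplitPlan(chosen[:train_n], chosen[train_n:train_n + optimization_n],
                         chosen[train_n + optimization_n:], seed=seed)

    classes = np.unique(labels[pool])
    counts = np.array([(labels[pool] == c).sum() for c in classes])
    sample_per = _largest_remainder(n_sample, counts)
    sizes = np.array([train_n, optimization_n, test_n])
    if np.any(sample_per < (sizes > 0).sum()):
        raise ValueError("infeasible stratification: a class has fewer members than split parts")
    tr, op, te = [], [], []
    for c, m in zip(classes, sample_per):
        members = pool[labels[pool] == c]
        chosen = rng.choice(members, size=m, replace=False)
        parts = _largest_remainder(m, sizes + 1e-12)
        tr.append(chosen[:parts[0]])
        op.append(chosen[parts[0]:parts[0] + parts[1]])
        te.append(chosen[parts[0] + parts[1]:])
    return SplitPlan(np.concatenate(tr), np.concatenate(op), np.concatenate(te), seed=seed)


# ---------------------------------------------------------------------------
# CSV ingestion


_DEFAULT_SCHEMA = {
    "line_col": "line_id",
    "env_col": "env_id",
    "response_col": "response",
    "trait_col": "trait",
}


def _read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    # round_trip: the default float converter can be off in the last ulp
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _check_numeric(df: pd.DataFrame, path, key_cols):
    body = df.drop(columns=[c for c in key_cols if c in df.columns])
    for col in body.columns:
        vals = pd.to_numeric(body[col], errors="coerce")
        if vals.isna().any():
            row = int(np.where(vals.isna())[0][0])
            raise ValueError(f"{path}: non-numeric cell at row {row}, column {col!r}")


def load_dataset(secondary_path, weather_path, genomic_path, response_path,
                 schema: dict | str | None = None) -> IntegratedDataset:
    """Load and align the three predictor blocks and the response from CSV/TSV.

    Secondary and response files are keyed by (line_id, env_id); the genomic
    file by line_id (markers replicate across environments); the weather file
    by env_id with columns ``<variable>_d<day>`` (replicated across lines).
    ``schema`` may be a dict or path to a YAML file overriding key column names.
    """
    if isinstance(schema, (str, bytes)) or hasattr(schema, "read_text"):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    sch = dict(_DEFAULT_SCHEMA, **(schema or {}))
    lc, ec = sch["line_col"], sch["env_col"]

    sec = _read_table(secondary_path)
    wea = _read_table(weather_path)
    gen = _read_table(genomic_path)
    res = _read_table(response_path)
    for df, p, keys in ((sec, secondary_path, (lc, ec)), (wea, weather_path, (ec,)),
                        (gen, genomic_path, (lc,)), (res, response_path, (lc, ec))):
        _check_numeric(df, p, keys)

    res_keys = list(zip(res[lc], res[ec]))
    sec_map = {k: i for i, k in enumerate(zip(sec[lc], sec[ec]))}
    gen_map = {k: i for i, k in enumerate(gen[lc])}
    wea_map = {k: i for i, k in enumerate(wea[ec])}
    missing = [k for k in res_keys if k not in sec_map]
    missing += [(k, e) for k, e in res_keys if k not in gen_map]
    missing += [(k, e) for k, e in res_keys if e not in wea_map]
    if missing:
        raise ValueError(f"alignment error: keys missing from predictor files: {sorted(set(missing))[:10]}")

    sec_cols = [c for c in sec.columns if c not in (lc, ec)]
    gen_cols = [c for c in gen.columns if c != lc]
    wea_cols = [c for c in wea.columns if c != ec]

    sec_vals = sec[sec_cols].to_numpy(float)[[sec_map[k] for k in res_keys]]
    gen_vals = gen[gen_cols].to_numpy(float)[[gen_map[k] for k, _ in res_keys]]
    wea_rows = wea[wea_cols].to_numpy(float)
    wea_vals = wea_rows[[wea_map[e] for _, e in res_keys]]

    # reconstruct the (k, V, D) panel from <var>_d<day> column names
    panel = None
    try:
        parsed = [c.rsplit("_d", 1) for c in wea_cols]
        var_names = list(dict.fromkeys(v for v, _ in parsed))
        days = sorted({int(d) for _, d in parsed})
        if len(var_names) * len(days) == len(wea_cols):
            k = wea_rows.shape[0]
            arr = np.empty((k, len(var_names), len(days)))
            for ci, (v, d) in enumerate(parsed):
                arr[:, var_names.index(v), days.index(int(d))] = wea_rows[:, ci]
            panel = DailyWeatherPanel(arr, var_names, list(wea[ec]))
    except (ValueError, IndexError):
        panel = None

    rcol = sch["response_col"]
    trait = res[sch["trait_col"]].to_numpy(float) if sch["trait_col"] in res.columns else None
    return IntegratedDataset(
        response=res[rcol].to_numpy(int),
        secondary=PredictorBlock("secondary", sec_vals, sec_cols),
        weather=PredictorBlock("weather", wea_vals, wea_cols),
        genomic=PredictorBlock("genomic", gen_vals, gen_cols),
        environment_id=res[ec].to_numpy(),
        line_id=res[lc].to_numpy(),
        weather_panel=panel,
        continuous_trait=trait,
    )


def write_dataset(dataset: IntegratedDataset, outdir, schema: dict | None = None) -> dict:
    """Write a dataset to the CSV schema ``load_dataset`` reads; returns the paths."""
    import os

    sch = dict(_DEFAULT_SCHEMA, **(schema or {}))
    lc, ec = sch["line_col"], sch["env_col"]
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    sec = pd.DataFrame(dataset.secondary.values, columns=dataset.secondary.column_labels)
    sec.insert(0, ec, dataset.environment_id)
    sec.insert(0, lc, dataset.line_id)
    paths["secondary"] = os.path.join(outdir, "secondary.csv")
    sec.to_csv(paths["secondary"], index=False, float_format="%.17g")

    lines, first = np.unique(dataset.line_id, return_index=True)
    gen = pd.DataFrame(dataset.genomic.values[first], columns=dataset.genomic.column_labels)
    gen.insert(0, lc, lines)
    paths["genomic"] = os.path.join(outdir, "genomic.csv")
    gen.to_csv(paths["genomic"], index=False, float_format="%.17g")

    panel = dataset.weather_panel
    if panel is not None:
        cols = [f"{v}_d{d}" for v in panel.variable_names for d in range(1, panel.n_days + 1)]
        wea = pd.DataFrame(panel.values.reshape(panel.n_envs, -1), columns=cols)
        wea.insert(0, ec, panel.env_ids)
    else:
        envs, first_e = np.unique(dataset.environment_id, return_index=True)
        wea = pd.DataFrame(dataset.weather.values[first_e], columns=dataset.weather.column_labels)
        wea.insert(0, ec, envs)
    paths["weather"] = os.path.join(outdir, "weather.csv")
    wea.to_csv(paths["weather"], index=False, float_format="%.17g")

    res = pd.DataFrame({lc: dataset.line_id, ec: dataset.environment_id,
                        sch["response_col"]: dataset.response})
    if dataset.continuous_trait is not None:
        res[sch["trait_col"]] = dataset.continuous_trait
    paths["response"] = os.path.join(outdir, "response.csv")
    res.to_csv(paths["response"], index=False, float_format="%.17g")
    return paths
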