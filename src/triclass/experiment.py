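"""Experiment runner for the MC0/MC1/MC2/MT1/MT2/SVM/RF model grid.

Each replication samples a class-balanced subset, splits it 200/80, runs
stage 1 on the training rows, fits the one-vs-all forward-selection
classifier (or an off-the-shelf baseline), and evaluates on the held-out
test rows.  The MT rows replace the full weather block with the optimal
FW-window block and force lambda_weather = 0.

Model grid (per-block penalties; "var" is resolved by cross-validated grid
search over candidate lambda triples):

    MC0  G + E + P            0    0    0    full weather
    MC1  PenG + PenE + P      0    var  var  full weather
    MC2  PenG + PenE + PenP   var  var  var  full weather
    MT1  PenG + FWE + P       0    0    var  window weather
    MT2  PenG + FWE + PenP    var  0    var  window weather
    SVM / RF                  baselines on the raw standardized blocks
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import IntegratedDataset, Standardizer
from .fw import build_fwe_block, find_optimal_window
from .metrics import ClassificationReport, evaluate
from .multiclass import OneVsAllForwardSelection
from .residualize import SecondaryTraitResidualizer
from .solver import BLOCK_GENOMIC, BLOCK_SECONDARY, BLOCK_WEATHER
from .synthetic import GeneratorConfig, generate, replicate

MODEL_GRID = {
    "MC0": {"lambda1": 0, "lambda2": 0, "lambda3": 0, "weather_mode": "full"},
    "MC1": {"lambda1": 0, "lambda2": "varying", "lambda3": "varying", "weather_mode": "full"},
    "MC2": {"lambda1": "varying", "lambda2": "varying", "lambda3": "varying", "weather_mode": "full"},
    "MT1": {"lambda1": 0, "lambda2": 0, "lambda3": "varying", "weather_mode": "fwe"},
    "MT2": {"lambda1": "varying", "lambda2": 0, "lambda3": "varying", "weather_mode": "fwe"},
    "SVM": {"baseline": "svm"},
    "RF": {"baseline": "rf"},
}

# candidate (lambda1, lambda2, lambda3) triples for the "varying" entries;
# the diagonal keeps replicated desk-scale runs affordable, the full coarse
# product subgrid is available by passing it explicitly
DIAGONAL_CANDIDATES = [(1, 1, 1), (5, 5, 5), (10, 10, 10)]
COARSE_SUBGRID = [(a, b, c) for a in (1, 3, 5, 10) for b in (1, 3, 5, 10) for c in (1, 3, 5, 10)]


@dataclass
class Design:
    """Standardized stage-2 design matrices for one train/test split."""

    Z_train: np.ndarray
    Z_test: np.ndarray
    block_index: np.ndarray
    raw_train: np.ndarray  # standardized [secondary | weather | genomic] for baselines
    raw_test: np.ndarray
    window: tuple | None = None


def build_design(dataset: IntegratedDataset, train_idx, test_idx,
                 weather_mode: str = "full", stage1_penalty: str = "ridge",
                 stage1_lam: float | None = 1.0, seed: int = 0) -> Design:
    """Standardize blocks on training rows, run stage 1, assemble stage-2 matrices.

    With ``weather_mode="fwe"`` the optimal window is found from the training
    observations' environmental means and the weather block is restricted to it
    (stage 1 still residualizes against the full weather block).
    """
    tr = np.asarray(train_idx)
    te = np.asarray(test_idx)
    blocks = {}
    for name in ("secondary", "weather", "genomic"):
        vals = getattr(dataset, name).values
        sc = Standardizer().fit(vals[tr])
        blocks[name] = (sc.transform(vals[tr]), sc.transform(vals[te]))

    res = SecondaryTraitResidualizer(penalty=stage1_penalty, lam=stage1_lam, seed=seed)
    res.fit(blocks["secondary"][0], blocks["weather"][0], blocks["genomic"][0])
    Zu_tr = res.transform(blocks["secondary"][0], blocks["weather"][0], blocks["genomic"][0])
    Zu_te = res.transform(blocks["secondary"][1], blocks["weather"][1], blocks["genomic"][1])

    window = None
    if weather_mode == "fwe":
        if dataset.continuous_trait is None:
            raise ValueError("FW window search needs the continuous trait")
        scan = find_optimal_window(dataset.subset(tr))
        window = scan.best_window
        fwe = build_fwe_block(dataset, window)
        sc = Standardizer().fit(fwe.values[tr])
        w_tr, w_te = sc.transform(fwe.values[tr]), sc.transform(fwe.values[te])
    elif weather_mode == "full":
        w_tr, w_te = blocks["weather"]
    else:
        raise ValueError("weather_mode must be 'full' or 'fwe'")

    g_tr, g_te = blocks["genomic"]
    block_index = np.concatenate([
        np.full(Zu_tr.shape[1], BLOCK_SECONDARY),
        np.full(w_tr.shape[1], BLOCK_WEATHER),
        np.full(g_tr.shape[1], BLOCK_GENOMIC),
    ])
    return Design(
        Z_train=np.hstack([Zu_tr, w_tr, g_tr]),
        Z_test=np.hstack([Zu_te, w_te, g_te]),
        block_index=block_index,
        raw_train=np.hstack([blocks["secondary"][0], blocks["weather"][0], g_tr]),
        raw_test=np.hstack([blocks["secondary"][1], blocks["weather"][1], g_te]),
        window=window,
    )


def _resolve_candidates(model_spec: dict, candidates) -> list[tuple]:
    """Map shared lambda candidates onto a model's varying/zero pattern."""
    fixed = [model_spec[f"lambda{i}"] for i in (1, 2, 3)]
    out = []
    for cand in candidates:
        trip = tuple(cand[i] if fixed[i] == "varying" else fixed[i] for i in range(3))
        if trip not in out:
            out.append(trip)
    return out


def tune_lambdas(Z, y, block_index, model_spec: dict, candidates=None,
                 n_folds: int = 3, seed: int = 0, **solver_kw) -> tuple:
    """Cross-validated grid search over lambda triples, shared across OVA sub-fits.

    Selection is by weighted macro TPR, then accuracy (weights from each
    fold's training labels).  Returns the winning (lambda1, lambda2, lambda3).
    """
    cands = _resolve_candidates(model_spec, candidates or COARSE_SUBGRID)
    if len(cands) == 1:
        return cands[0]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = []
    for trip in cands:
        mtpr, acc = [], []
        for tr, va in skf.split(Z, y):
            ova = OneVsAllForwardSelection(
                lambda_secondary=trip[0], lambda_weather=trip[1], lambda_genomic=trip[2],
                block_index=block_index, **solver_kw).fit(Z[tr], y[tr])
            rep = evaluate(y[va], ova.predict(Z[va]), y[tr])
            mtpr.append(rep.weighted_macro_tpr)
            acc.append(rep.accuracy)
        scores.append((np.mean(mtpr), np.mean(acc)))
    best = max(range(len(cands)), key=lambda i: scores[i])
    return cands[best]


def run_baselines(train, test, model: str, seed: int = 0) -> ClassificationReport:
    """RF / SVM comparators on the raw standardized concatenated blocks.

    ``train`` and ``test`` are (X, y) pairs.  RF: 200 trees, sqrt features;
    model size is the count of distinct split features across trees.  SVM:
    RBF kernel with sklearn defaults; model size is undefined (reported None).
    """
    (Xtr, ytr), (Xte, yte) = train, test
    if model == "rf":
        clf = RandomForestClassifier(n_estimators=200, random_state=seed).fit(Xtr, ytr)
    elif model == "svm":
        clf = SVC(kernel="rbf", random_state=seed).fit(Xtr, ytr)
    else:
        raise ValueError("model must be 'rf' or 'svm'")
    return evaluate(yte, clf.predict(Xte), ytr, model=clf)


def run_model(dataset: IntegratedDataset, train_idx, test_idx, model: str,
              candidates=None, n_folds: int = 3, seed: int = 0,
              stage1_penalty: str = "ridge", stage1_lam: float | None = 1.0,
              design: Design | None = None, **solver_kw):
    """Fit and evaluate one grid model on one split; returns (report, fitted, design)."""
    spec = MODEL_GRID[model]
    y = dataset.response
    ytr, yte = y[np.asarray(train_idx)], y[np.asarray(test_idx)]
    if "baseline" in spec:
        if design is None:
            design = build_design(dataset, train_idx, test_idx, "full",
                                  stage1_penalty, stage1_lam, seed)
        rep = run_baselines((design.raw_train, ytr), (design.raw_test, yte),
                            spec["baseline"], seed=seed)
        return rep, None, design
    if design is None or (spec["weather_mode"] == "fwe") != (design.window is not None):
        design = build_design(dataset, train_idx, test_idx, spec["weather_mode"],
                              stage1_penalty, stage1_lam, seed)
    trip = tune_lambdas(design.Z_train, ytr, design.block_index, spec,
                        candidates=candidates or DIAGONAL_CANDIDATES,
                        n_folds=n_folds, seed=seed, **solver_kw)
    ova = OneVsAllForwardSelection(
        lambda_secondary=trip[0], lambda_weather=trip[1], lambda_genomic=trip[2],
        block_index=design.block_index, **solver_kw).fit(design.Z_train, ytr)
    rep = evaluate(yte, ova.predict(design.Z_test), ytr, model=ova)
    return rep, ova, design


def run_grid(config: GeneratorConfig | None = None, dataset: IntegratedDataset | None = None,
             balances=("33-34-33", "40-40-20", "10-80-10"),
             n_reps: int = 20, models=("MC0", "MC1", "MC2", "MT1", "MT2", "SVM", "RF"),
             seed: int = 0, candidates=None, n_folds: int = 3,
             n_sample: int = 280, train_n: int = 200, test_n: int = 80,
             **solver_kw) -> pd.DataFrame:
    """Full balance x replication x model sweep; returns per-replication rows.

    Per-model failures are caught and recorded (column ``error``), the sweep
    continues.  Use :func:`summarize` for the averaged table.
    """
    if dataset is None:
        if config is None:
            config = GeneratorConfig.test_scale(seed=seed)
        dataset, _ = generate(config)
    rows = []
    for balance in balances:
        plans = replicate(config or GeneratorConfig.test_scale(seed=seed), balance,
                          n_reps, base_seed=seed, n_sample=n_sample,
                          train_n=train_n, test_n=test_n, dataset=dataset)
        for r, (plan, _idx) in enumerate(plans):
            designs = {}
            for model in models:
                spec = MODEL_GRID[model]
                mode = spec.get("weather_mode", "full")
                try:
                    rep, _, design = run_model(
                        dataset, plan.train_idx, plan.test_idx, model,
                        candidates=candidates, n_folds=n_folds, seed=seed + r,
                        design=designs.get(mode), **solver_kw)
                    designs[mode] = design
                    rows.append({"balance": balance, "model": model, "rep": r,
                                 "Acc": rep.accuracy, "mTPR": rep.weighted_macro_tpr,
                                 "mTNR": rep.weighted_macro_tnr, "MDS": rep.model_size,
                                 "error": None})
                except Exception as exc:  # surface, keep sweeping
                    rows.append({"balance": balance, "model": model, "rep": r,
                                 "Acc": np.nan, "mTPR": np.nan, "mTNR": np.nan,
                                 "MDS": None, "error": str(exc)})
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Average metrics over replications, with standard errors."""
    def se(x):
        x = x.dropna()
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    grp = results.groupby(["balance", "model"], sort=False)
    out = grp.agg(Acc=("Acc", "mean"), Acc_se=("Acc", se),
                  mTPR=("mTPR", "mean"), mTPR_se=("mTPR", se),
                  mTNR=("mTNR", "mean"), mTNR_se=("mTNR", se),
                  MDS=("MDS", "mean"), n_reps=("rep", "count")).reset_index()
    return out


def save_results(results: pd.DataFrame, outdir, manifest: dict | None = None):
    import os

    os.makedirs(outdir, exist_ok=True)
    results.to_csv(os.path.join(outdir, "replications.csv"), index=False)
    summarize(results).to_csv(os.path.join(outdir, "summary.csv"), index=False)
    if manifest:
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
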