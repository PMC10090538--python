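# Methods

This note documents the statistical model behind `triclass`, the numerical
choices in its solver, what the synthetic-trial generator does and does not
emulate, and the design decisions taken where the method left room.

## Problem setting

Observations are line × environment combinations from a multi-environment
trial. Three predictor blocks of very different widths describe each
observation: P secondary phenotypes, Q = V·D daily weather covariates
(V variables over a D-day season, identical for all lines in an
environment), and R marker dosages (identical for a line across
environments). The response is an ordered categorical trait, coded 1..C,
typically obtained by discretizing a quantitative trait. Two asymmetries
drive the design: the marker block outnumbers the secondary block by three
orders of magnitude, and the weather and marker blocks also influence the
secondary traits themselves.

## Stage 1: residualization

Each standardized secondary trait is regressed on the (standardized)
weather block and, separately, on the marker block, minimizing
RSS + λ·pen(b). The residual pairs û^W, û^V carry the trait's *intrinsic*
signal and enter the classifier as its first 2P predictors.

Choices:

- **Default penalty: ridge.** Stage 1 is a nuisance regression — prediction
  of the trait from the confounder block — not a selection problem, and
  ridge is stable when Q or R approaches or exceeds n. All of
  none/ridge/lasso/adaptive-lasso/elastic-net are supported; `kind="none"`
  is refused when the predictor block has as many columns as observations
  (rank deficiency).
- **λ units.** The API's λ multiplies the penalty against the plain residual
  sum of squares; conversions to scikit-learn's per-solver parameterizations
  happen internally (`Lasso`: α = λ/2n; `Ridge`: α = λ). When λ is omitted
  it is chosen by 5-fold cross-validation over a log grid.
- **Residuals are re-standardized** (training statistics) before entering
  stage 2, which assumes unit-variance predictors throughout.
- **Adaptive-lasso weights** default to 1/|ridge pilot coefficients| floored
  at 10⁻⁶.
- Held-out rows are residualized with the training coefficients and
  training scaling only; no test information enters any transform.
- A caution on a tempting sanity check: even with zero true confounding, an
  unpenalized stage-1 regression erodes the traits by fitting noise
  (R² ≈ Q/n), so "residuals ≈ original traits" only holds when Q/n is a few
  percent or less. The test suite instantiates that check in such a regime.

## Stage 2: block-ordered penalized forward selection

The binary classifier is logistic, fit by maximizing the penalized
log-likelihood

    PLL(θ) = Σᵢ [yᵢηᵢ − log(1+e^{ηᵢ})] − λ₁Σ|α| − λ₂Σ|β| − λ₃Σ|γ|,

with each λ applied only to its own block's coefficients. All coefficients
start at zero and the model grows greedily in three phases — secondary
residuals, then weather, then markers — so narrow blocks claim explainable
variation before wide blocks are allowed in.

Per pass, every candidate coordinate (current block plus everything already
selected, which permits refinement) receives a one-dimensional
Newton–Raphson update on the appropriate side of the L1 kink:
θᴸ = θ − s(f′+λ)/f″ and θᴿ = θ − s(f′−λ)/f″, resolved as θᴸ if θᴸ<0, θᴿ if
θᴿ>0, else 0. At θ = 0 this reduces to the subgradient screening rule: the
coordinate moves iff |f′| > λ. The single candidate with the largest PLL
gain is applied (ties broken to the lowest column index for determinism).
A gain must be positive and exceed ε_block·|PLL| to be accepted; otherwise
the step size is halved down the schedule s = 1, ½, …, 2⁻¹⁰, and the phase
ends when no candidate is accepted at any step. The per-block defaults
ε = 10⁻³/10⁻⁵/10⁻⁸ make entry progressively harder for wider blocks.

Numerical choices:

- **Unpenalized intercept**, refined by an exact Newton step (halved until
  non-decreasing) after every accepted update. Class imbalance makes a free
  intercept necessary; it is initialized at logit(ȳ).
- **Linear predictors are clipped to ±30** before exponentiation; the
  sigmoid saturates at ~10⁻¹³ beyond that, and with λ = 0 and T > n
  (separable data) the likelihood would otherwise diverge.
- Coordinates whose curvature |f″| falls below 10⁻¹² (e.g. saturated or
  constant columns) are skipped for the pass.
- A `max_steps` cap (default 3000 accepted updates) bounds pathological
  runs; ε-based convergence is the operative stop in practice.
- With all λ = 0, low dimension, and tightened ε, the solver converges to
  the ordinary maximum-likelihood logistic fit (verified against
  independent oracles to 10⁻⁴ in the tests).
- λ tuning is a cross-validated grid search (stratified 3-fold) selecting
  by weighted macro TPR, then accuracy. The tuner's default candidate set
  is the coarse product subgrid {1,3,5,10}³; the replicated experiment
  runner defaults to the diagonal {(1,1,1),(5,5,5),(10,10,10)} because the
  product grid multiplies each replication's cost 64-fold. Tuning reuses
  the stage-1 design computed on the full training split (the folds re-fit
  only the classifier); re-residualizing per fold would multiply stage-1
  cost by the fold count for a nuisance regression that uses no labels.

## Stage 3: decision rule

For binary traits a probability threshold is tuned on a held-out
optimization set by maximizing balanced accuracy (selectable: Youden's J,
accuracy, F1) over a grid of step 0.01, ties resolved toward 0.5;
classification is strict (`p > t`). The suggested three-way split is
140/60/80 (train/optimization/test) of a 280-observation sample.

For K-class traits the problem is decomposed one-vs-all into K binary
fits sharing one configuration and predictor layout; prediction is the
argmax of the K *raw* positive-class probabilities (no softmax
renormalization — the sub-fits already output probabilities), ties to the
lower class label. Thresholding is dropped: argmax is threshold-free. A
2-class problem is a single binary classifier under either decomposition.

## Optimal weather window

The quantitative trait decomposes as y₍ᵢⱼ₎ = μ + Gᵢ + Eⱼ + e₍ᵢⱼ₎; the
environmental means ȳ.ⱼ estimate μ + Eⱼ up to O(1/√t) noise. For each day,
the first principal component of the k×V normalized weather slice (sign
fixed so the largest-magnitude loading is positive) gives one environmental
index score per environment; the window (b, e) maximizing
cor(ȳ.ⱼ, window mean of the index)² is selected by exhaustive scan.

- Window means use the true arithmetic mean (denominator e−b+1). Since
  correlation is invariant to scaling, any fixed alternative denominator
  would select the identical window; the tests assert this invariance.
- R² values are clipped to [0,1] and values within 10⁻¹² of 1 (floating
  residue of an exact linear fit) are snapped to exactly 1.
- Ties break toward the earliest start, then the shortest window;
  zero-variance window means score 0 and are flagged.
- `min_len` defaults to 2. With k = 8 environments every correlation rests
  on 8 points and the scan maximizes over ~D²/2 windows, so short windows
  are easily spurious; the full R² surface is returned precisely so users
  can judge stability, and raising `min_len` to a week is a reasonable
  guard.
- The window is searched on the *continuous* trait's environmental means
  (the decomposition above is quantitative); the discretized class means
  are available behind a flag.
- In the MT1/MT2 configurations the weather block is restricted to all V
  variables over the selected window and λ₂ is forced to 0: the window
  search *was* the weather selection step. One shared PCA-index window is
  used rather than one window per variable.

## Metrics

Confusion matrix rows are truth, columns prediction, labels 1..K.
TPR_k = TP/(TP+FN), TNR_k = TN/(TN+FP) from the one-vs-rest collapse.
Weighted macro rates use training-split class proportions (Σw_k = 1):
mTPR = Σ w_k·TPR_k. A `/K` variant is provided but is not the default: with
weights summing to one, dividing by K caps the macro rate at 1/K, which is
inconsistent with macro rates near 0.8 under three classes. Undefined
per-class rates (empty denominator) are dropped with weight
renormalization and logged. Model size is the count of distinct predictors
with nonzero coefficients (union over OVA sub-fits); for random forests,
the count of distinct split features over all trees; undefined for SVMs.

## Synthetic-trial generator

The generator emulates the structure the method assumes, at a configurable
scale (defaults: 749 lines × 8 environments, 6 secondary traits, 4 weather
variables × 100 days, 10,000 markers; `test_scale()` shrinks to 150 lines
and 500 markers without touching the structure):

- **Markers**: per-locus MAF ~ U(0.1, 0.5), dosages Binomial(2, MAF) per
  line, constant across a line's environments.
- **Weather**: per variable, a seasonal sinusoid plus an
  environment-specific *common mode* (smooth three-harmonic curve,
  sd 4.0, loadings U(0.8, 1.2) shared across variables), a smaller
  variable-specific environment curve (sd 0.3), and AR(1) day-to-day noise
  (φ = 0.6, innovation sd 0.8). The common mode makes the weather
  variables co-vary across sites — as real temperature/moisture regimes do
  — and is what the daily first-PC index estimates; its amplitude is set so
  the dominant mode carries most cross-site variance, the operating point
  at which a planted window is recoverable through the PC index with only
  8 environments.
- **Secondary traits**: confounded by construction —
  0.5·(window-mean common mode) + 0.5·(score of 10 random markers) +
  intrinsic latent N(0,1) + measurement noise (sd 0.3).
- **Main trait**: y = μ + G + E + intrinsic + noise, with G from a sparse
  marker support (default five effects of 0.4), E the standardized
  window mean of the common mode over the true window (default days
  35–55, effect 1.0), intrinsic = latent × (1.0, 0.8, 0, 0, 0, 0), noise
  sd 1.0.
- **Discretization**: rank-based — bottom 25% → class 1, top 25% → class 3,
  a 25%-wide percentile band centered on the mean's percentile → class 2;
  the remaining ~25% are unlabeled (class 0) and excluded from sampling.
  The binary scheme splits at the median.
- **Class-balanced sampling**: 280 observations apportioned by largest
  remainder (ties to the lower class): 33-34-33 → (93, 95, 92),
  40-40-20 → (112, 112, 56), 10-80-10 → (28, 224, 28); stratified 200/80
  train/test splits, replicated with consecutive seeds.

What it does **not** emulate: linkage disequilibrium, population structure
or kinship among lines, genotype × environment interaction beyond the
additive decomposition, non-Gaussian weather (e.g. zero-inflated rainfall),
missing data, or spatial field trends. Passing tests therefore demonstrate
that the pipeline recovers the structure it assumes — confounding removal,
window recovery, block-ordered sparse selection — not that real chickpea
data would yield any particular accuracy.

## Experiment grid

Models: MC0 (no penalties), MC1 (penalized weather+markers), MC2 (all
penalized), MT1/MT2 (window weather with λ₂ = 0), and RF/SVM baselines fit
on the standardized raw concatenated blocks (P+Q+R; baselines are
comparators to the whole pipeline, so they do not receive stage-1
residuals). RF: 200 trees, sklearn defaults otherwise; SVM: RBF kernel,
sklearn defaults; both documented as such since no canonical settings
exist for this comparison. Replications share one generated dataset and
differ in the sampled 280 observations and split (seeds base+r); results
are averaged with standard errors. Runs are sequential and reproducible:
identical seeds give identical outputs.

Default desk-scale problem sizes (150 lines, 500 markers, 5 replications,
diagonal λ candidates) were chosen so a full two-balance, three-model sweep
completes in a few minutes on one CPU; `--scale full` and `--grid-search`
restore the full dimensions and the product λ grid.

## Known limitations

- The greedy one-coordinate-per-pass solver has no optimality guarantee for
  the penalized likelihood; it implements a forward-selection path with
  refinement, which is the point of the method, not a convex-solver
  replacement.
- With 8 environments the window scan's argmax has high variance; windows
  adjacent to the optimum are often statistically indistinguishable
  (inspect `r2_surface` before interpreting a single window).
- OVA sub-fit probabilities are compared unrenormalized; they are not a
  calibrated joint distribution over classes.
- The ε defaults couple convergence to the PLL scale (≈ n·log 2 at the
  null); very small or very large n shifts their effective strictness.
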