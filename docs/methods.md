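# Methods

## Model and assumptions

The pipeline models the TBARS index (percent of the day-0 value) of minced
beef stored at constant temperature as first-order growth,
`TBARS(t) = TBARS₀·e^{kt}` with `TBARS₀ = 100 %`. This assumes the
secondary-oxidation products accumulate at a rate proportional to the
current level over the storage window, which holds well for raw ground
meat over 5–13 days; it ignores any induction phase or late-stage plateau.
Fitting is done on the log scale (natural logarithm throughout), where the
model is a straight line and multiplicative measurement error becomes
additive — the OLS slope is then the maximum-likelihood estimate of `k`.

Two estimators of `k` are exposed:

* **free intercept** (default): `k` is the slope of the unconstrained
  log-linear OLS. This is the reading that matches model selection by
  regression quality of the logarithmic plot, and it is robust to a day-0
  normalization that is itself noisy.
* **fixed intercept**: the line is forced through `ln 100` at day 0,
  taking `TBARS₀ ≡ 100 %` literally; `k = Σ t·(ln y − ln 100) / Σ t²`.

Replicate series are fitted separately and aggregated to mean ± sample SD
per (treatment, temperature), because that is the statistic the published
rate-constant table reports. Secondary models consume the mean `k` by
default; this reproduces the published activation energies within ≤ 0.5 %
for the internally consistent rows, so whatever the original replicate
handling was, the mean-k route is the reproducible one.

## Secondary models

**Arrhenius.** `ln k = ln k₀ − Eₐ/(R T)` is fitted by OLS of ln k on 1/T
with `R = 8.314 J mol⁻¹ K⁻¹` exactly. Temperatures are stored in °C and
converted to kelvin only here; the offset is configurable
(`KELVIN_OFFSET = 273.15` by default, `273.0` to reproduce the published
integer-rounded kelvins 277/281/289/293 exactly). A two-point fit is
allowed (exact interpolation, R² reported as 1); R² is only meaningful
from three temperatures up.

**Log-logistic.** `k = m′·ln(1 + e^{c(T−T_c)})` with `T` in °C and
`m′ = 1` unless released. The objective is unweighted squared error on the
k scale (the model is stated for `k` directly, and the published control
parameters reproduce the printed k's on that scale). The fit is
initialized by a deterministic coarse grid (60 × 101 points over
`c ∈ [0.01, 0.6] °C⁻¹`, `T_c ∈ [−10, 90] °C`) and refined with a
Levenberg–Marquardt local solver — no random starts, so results are fully
reproducible. `T_c` carries units of °C; the "°C⁻¹" sometimes printed for
it is treated as a typographical slip, since values of 20–58 °C are only
coherent as temperatures. For `c(T−T_c) ≫ 0` the curve approaches the
line `c(T−T_c)`; for `c(T−T_c) ≪ 0` it decays like `e^{c(T−T_c)}`, so `k`
stays positive at all temperatures.

**Known inconsistencies in the published parameter table.** Two printed
entries cannot be reproduced from the printed rate constants they sit next
to: the clove activation energy is printed negative (−122,721 J/mol) while
the clove k's rise monotonically with temperature and recompute to
≈ +51.6 kJ/mol; and the control `k₀ = 1.7 × 10¹¹ day⁻¹` is inconsistent
with its own `Eₐ` and k's (it would imply k(4 °C) ≈ 0.73 rather than the
printed 0.147), recomputing to ≈ 3.2 × 10¹⁰. The package ships the printed
table verbatim as a fixture but asserts the recomputed values; caraway and
onion recompute 3–10 % away from their printed Eₐ (plausibly a
replicate-level versus mean-k difference) and are excluded from the exact
recomputation checks.

## Integrated prediction and external validation

Substituting the secondary model into the primary one gives
`TBARS = 100·exp(k(T)·t)` for any time–temperature pair. Predictions are
deliberately not clipped: overestimation at high temperature is reported,
not corrected. The holdout pipeline drops one storage temperature
(default 12 °C) entirely, fits primary + secondary models on the rest
(≥ 3 temperatures required), predicts every held-out observation, and
reports:

* `r2_adj` — adjusted R² of the observed-on-predicted OLS with one
  predictor, `1 − (1−R²)(n−1)/(n−2)`;
* `rmse` — root-mean-square of the raw paired errors
  `observed − predicted`, not of regression residuals.

Both are computed on the same pairs, matching the usual
scatter-plot-plus-RMSE presentation. Per-treatment metrics are attached
where a treatment has ≥ 3 held-out pairs; they have no published
counterpart and are reported for diagnostics only. A shelf-life inversion
(`days until TBARS = X %`) is provided as a convenience helper and is not
validated against any published figure.

## Synthetic data

The generator emulates the study design: 14 arms (control + 13 extracts),
3 replicates, storage at 4/8/12/16/20 °C, sampled daily for 13 days at
≤ 12 °C and 5 days at 16/20 °C (the source reports only total durations;
the daily grid is this package's choice and is configurable).
Measurements are drawn as `100·e^{k(T)t}·e^{ε}` with
`ε ~ N(0, σ²)` independent across records and day-0 values pinned at
exactly 100. Noise is multiplicative lognormal with σ = 0.05 by default —
additive on the log scale, so the log-linear primary fit is correctly
specified, and a 5 % coefficient of variation is typical of TBARS assay
triplicates. The default truth (`published_like_truth`) uses per-arm
activation energies recomputed from the published rate constants
(27–132 kJ/mol) with `k₀` back-solved so that k(4 °C) matches the
published value per arm.

What the generator does **not** emulate: replicate correlation from shared
meat batches (independence is assumed), heteroscedastic or autocorrelated
assay error, induction phases, and any departure from exact first-order
kinetics. Passing recovery tests therefore demonstrate estimator
correctness under the assumed model, not robustness to real-data
violations of it. Under the default design the worst-case activation-energy
recovery error across the 14 arms is typically 3–5 % — dominated by the
low-rate arms (caraway, bay leaf, allspice) whose k at 4 °C is small
relative to the fixed absolute noise on the fitted slope.

## MLP comparator

The network is a single-hidden-layer perceptron with 16 inputs (day,
temperature, 14 one-hot treatment indicators), 3–10 hidden units (tanh,
logistic or exponential activation) and one output (identity or
exponential). Training minimizes the sum-of-squares error with BFGS and
analytic gradients for at most 200 iterations; the 2:1:1
train/validation/test split is seed-reproducible (random by default,
stratified optional), the validation subset selects the best iterate
(patience 25), and model selection trains 20 architectures on a shared
split and keeps the 5 with the lowest validation error. Continuous inputs
are z-scored for quasi-Newton stability; indicators stay 0/1; the target
is raw TBARS(%), with the output bias initialized at the (log) training
mean so the first iterate is sane. Subset "performance" is the Pearson
correlation between observed and predicted within the subset — on a
regression task with values near 0.99 this is the only consistent reading
of a subset accuracy. Exponential pre-activations are clipped at ±50 (and
logistic at ±500) to keep line searches finite; the clip is far outside
the operating range of a converged fit. Radial-basis-function networks and
the cross-entropy error are intentionally out of scope.

## MLR treatment comparison

`ln TBARS(%)` is regressed on day, temperature (in °C — with kelvin the
published coefficient magnitudes would force an impossible intercept) and
13 treatment dummies, control uncoded as the reference. The natural-log
response is the reading consistent with a published intercept near
`ln 100 ≈ 4.6`. Per-coefficient two-sided t-tests are reported raw at
p ≤ 0.05, mirroring the original analysis; a Holm-adjusted column is
emitted alongside for users who want family-wise control, but plays no
role in the ranking. All temperatures present in the dataset are pooled,
including the validation temperature. The published coefficient values
themselves require the deposited raw dataset (Mendeley,
doi:10.17632/cs942c8rw3.1) and are not recomputation targets; an optional
loader accepts a manually supplied export.

## Numerical choices and degenerate inputs

* OLS fits delegate to `scipy.stats.linregress` / `statsmodels` and agree
  with the closed-form normal-equation solutions to 1e-10 or better.
* A flat (constant) TBARS series yields `k = 0` with R² defined as 1 when
  the fit is exact and 0 otherwise (zero total variance).
* Groups failing fit preconditions (< 3 points, nonpositive values,
  duplicate days) are collected per group in the rate table rather than
  aborting the run.
* Rank-deficient MLR designs raise an error naming the removable columns.
* Report artifacts serialize numbers at ≥ 6 significant digits; dataset
  CSVs use shortest-round-trip float formatting so read∘write is exact.

## Problem sizes

Default analyses run on the full study design (2,268 records with
triplicates, 756 noiseless). The architecture-selection grid trains 20
networks; simulation-based checks use single datasets at σ = 0.05 and a
60-replication batch for the MLR unbiasedness check — sizes chosen so the
whole suite completes in seconds while leaving estimator standard errors
well below the tolerances being asserted.
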