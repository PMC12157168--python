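# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of `formubo`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The workflow

The package implements an iterative, surrogate-driven formulation-development
loop: fit surrogates to the screening data collected so far, cross-validate
and select the best one, use a Gaussian-process surrogate with a
Lower-Confidence-Bound acquisition to propose the next batch of experiments,
measure them, append the results, optionally prune non-influential features
by Shapley importance, and stop when the cross-validated R² target is met or
the experimental budget is spent. Every step is logged (data size, model
type, hyperparameters, RMSE ± sd, R²) so a campaign run reads like the audit
table a formulation team would report.

## Gaussian-process surrogate

The GP models the (internally minimized) response on unit-scaled inputs with
a constant mean and the Matérn ν = 5/2 covariance

K(x, x′) = s² (1 + √5 d/ℓ + 5 d²/(3ℓ²)) exp(−√5 d/ℓ),   d = ‖x − x′‖₂.

Choices and rationale:

* **Unit scaling.** Each feature is affinely mapped onto [0, 1] by its design
  bounds before any kernel evaluation; a single isotropic length-scale is
  meaningless across mg/mL, % w/v and log10 PFU/mL otherwise. Per-dimension
  (ARD) scales are deliberately not the default: one ℓ matches the printed
  kernel form and keeps the fit stable at screening sample sizes.
* **Standardization.** Responses are standardized to zero mean / unit
  variance for fitting; predictions are de-standardized. The constant GP
  mean is therefore the training mean, and the signal variance s² is an
  explicit fitted amplitude. If all responses are equal the scale divisor is
  set to 1 so the fit remains defined.
* **Hyperparameters** (ℓ, s², noise σₙ²) maximize the log marginal likelihood
  via L-BFGS-B on log-parameters, 8 starts (one anchored at ℓ=0.5, s²=1,
  σₙ²=10⁻², seven seeded log-uniform draws), bounds ℓ ∈ [10⁻², 10],
  s² ∈ [10⁻³, 10³], σₙ² ∈ [10⁻⁸, 10]. Deterministic given the seed. The noise
  variance can be pinned (`fix_noise`) for noise-free interpolation.
* **Jitter.** Replicated formulations produce exactly duplicated rows, so
  the Gram matrix is factorized with a diagonal jitter starting at 10⁻¹⁰ and
  escalating tenfold up to 10⁻⁶ before failing.
* Posterior variances are clipped at zero against round-off; predictions at
  training points with pinned zero noise reproduce the observations to 1e-8.

## Acquisition

LCB(x) = μ(x) − κ σ(x) is minimized. Strategy presets map to κ:
exploitation 0.1, balanced 1.96, exploration 8.0 (the preset values are
package conventions; only the qualitative roles of small and large κ are
inherent). Maximize-direction responses (Tg′) are negated at the engine
boundary so minimizing LCB is always correct.

Candidates are a seeded scrambled-Sobol pool (default 4096) mapped into the
bounds and rejection-filtered against linear constraints — the guard against
nonsensical suggestions such as concentrations beyond solubility. Batches
use the constant-liar rule: after each selection the GP is temporarily
augmented with (candidate, predicted mean) under unchanged hyperparameters
and re-scored, which spreads a batch across the space and prevents
duplicates.

**Local polish.** A pool alone cannot optimize in 9–19 dimensions: with 4096
points the best pool member is only ~3.4 pooled standard deviations below
the landscape mean, far from a corner optimum that requires every coordinate
near its best value simultaneously. Each selected candidate is therefore
refined by L-BFGS-B on the LCB within the unit box, starting from the best
pool point, accepted only if feasible and better, and kept distinct from
earlier batch members. The polish is deterministic and can be disabled
(`local_polish=False`), which makes selection an exact argmin over the pool
(the property tests use this mode).

## Tree and linear surrogates

* `randomized_split_ensemble` — extremely randomized trees: full sample per
  tree (no bootstrap), all features considered at every split with one
  random threshold each, best split by variance reduction; prediction is the
  across-tree mean. Defaults: 30 trees, depth 20 (the workflow's fixed
  reporting model). Backed by scikit-learn's `ExtraTreesRegressor`.
* `gradient_boosted` — stagewise shrinkage boosting (XGBoost), defaults
  depth 3, 100 rounds, learning rate 0.1, L2 leaf penalty 1.0, base score =
  training mean. `boosting_rounds=0` is the null model predicting the
  training mean.
* `LinearModelSpec` — ordinary least squares with intercept, no
  regularization.

Hyperparameters are deliberately not tuned anywhere: the workflow improves
models by adding data and pruning features, which keeps every campaign step
comparable. Model selection runs k-fold CV with identical folds for every
candidate and picks the lowest mean RMSE, breaking ties toward the simpler
model (linear < randomized ensemble < boosted), then input order. Fitted
models serialize to JSON (trees as explicit node arrays; boosters as the
native JSON payload) and reload into prediction-equivalent objects.

Tree ensembles expose the across-tree prediction sd as an uncertainty
*proxy* (`predict_std`) for experimentation; the campaign's acquisition is
GP-driven by default because the tree proxy is not a calibrated posterior.

## Evaluation

* k-fold CV: seeded shuffle, k = 5 contiguous folds, RMSE reported as
  mean ± population sd across folds; R² computed once on the pooled
  out-of-fold predictions (per-fold R² is unstable on small folds).
* **Replicate-aware folds.** Replicates of the same formulation (identical
  feature rows) are kept in one fold. Splitting them leaks the held-out
  formulation into training; an interpolating ensemble then memorizes its
  duplicate, which inflates CV R² and — more damagingly — erases the
  performance drop that wrapper elimination relies on (the model "survives"
  any single-feature removal by re-finding the twin through the remaining
  columns). With unreplicated data the grouping is a no-op.
* Holdout accuracy: a prediction is correct iff |predicted − observed| ≤ a
  caller-supplied tolerance in response units. The tolerance is a required
  user parameter; for synthetic checks the package convention is 2× the
  generator's noise sd. Prediction-error deltas are signed as
  predicted − observed.

## Attribution

Shapley values use the interventional value function: v(S) is the mean model
output over a background sample (the training set, subsampled to 100 rows
when larger) with the features in S taken from the explained instance.
`shap_exact` enumerates all 2^M coalitions and is refused above M = 14
(2^M × background evaluations stay desk-scale below that). `shap_sampled`
averages marginal contributions over seeded random permutations drawn in
antithetic pairs (a permutation and its reverse), which roughly halves the
estimator variance; each permutation telescopes from the background mean to
the model prediction, so local accuracy Σφ + base = f(x) holds exactly at
any sample size. Global importance is mean |φ| over (a seeded subsample of)
the dataset rows; feature selection keeps features at or above 5% of the top
feature's mean |φ| by default and never returns an empty set.

Wrapper backward elimination re-runs CV with identical folds for the full
model and for each feature (or feature-group) removal, ranking groups by
ΔR² = R²(full) − R²(reduced). Permutation importance reports the mean ± sd
RMSE increase over seeded within-column shuffles of the dataset the caller
provides — held-out data is recommended, since shuffling training columns
under an interpolating model is optimistic. A feature the model never reads
degrades by exactly zero.

## Synthetic landscapes

The generators exist so the whole loop is testable end to end with a known
ground truth; their defaults define the package's study conditions.

**Titer-loss screen** (liquid formulation, minimize, log10 PFU/mL):

loss = clip₀[ base − a·sat(c_res; 0.2) + b·sat(c_sp; 2.0) + Σᵢ βᵢ xᵢ
        + γ (x_g − 0.35)² + (interaction) + 0.05·(titer − 6.9) ] ,

with sat(c; k) = min(c, k)/k piecewise linear — saturations are deliberately
not smoothed so knee-recovery checks have an unambiguous ground truth.
Defaults: base 1.5, protective residual-rHSA effect a = 0.8 saturating at
0.2 mg/mL on bounds [0, 0.6] mg/mL, destabilizing spiked-rHSA effect b = 0.4
saturating at 2 mg/mL on bounds [0, 5] mg/mL (the range the focused rHSA
experiments actually varied), six linear excipient effects with
|β| = 0.40–0.60 on [0, 1], one curved excipient (γ = 1.5, optimum 0.35), an
optional starting-titer covariate on [6.9, 7.9] log10 PFU/mL (coefficient
0.05), and any number of null features. Effect sizes follow one design
principle, fixed before the test suite was written: every designed effect
contributes at least one assay-noise sd (0.1 log10) of response variation,
so "impactful" features are genuinely impactful. `screening_landscape()` is the
19-feature screen (9 designed + 10 nulls); `reduced_landscape()` is the
9-feature designed-effects space a campaign optimizes after feature
reduction. The noiseless minimum of the separable landscape is analytic
(coordinate-wise), clipped at zero.

**Tg′ mixture** (freeze-dried formulation, maximize, °C): the Fox rule on
absolute temperature, 1/T_mix = Σ wᵢ/Tᵢ with solute mass fractions wᵢ,
chosen over the binary Gordon–Taylor form for multicomponent tractability;
optional pairwise deviation terms (k·wᵢwⱼ, °C) reintroduce Gordon–Taylor-like
non-ideality. The nine default components span a buffer, amino acids, sugars,
a polysaccharide, a polyol and the polymer PVP (−26 °C); all component Tg′
values except PVP's are plausible placeholders for anonymized excipients and
are labeled as such. DSC-style measurement noise defaults to 1.5 °C — half
of a ±3 °C determination envelope read as ~2 sd.

Measurement noise is Gaussian, keyed to (seed, formulation bytes,
replicate), so re-querying the same replicate reproduces the identical
value; samples default to duplicates for the titer screen. Noisy
observations are not clipped at zero even though the noiseless loss is
(an assay can read a small negative loss).

**What the generators do not emulate:** batch/operator effects, plate
layout, upstream-process drift, non-Gaussian assay error, censoring at the
assay's limit of detection, and the historical-data structure of a real
legacy screen (few excipients varied at a time). Passing tests on these
landscapes show the machinery is correct and that the loop works under
idealized screening statistics — not that any particular real screen will
reach the same numbers.

## Study-analog experiment sizes

The benchmark experiments (`formubo.benchmarks`) use: 200 latin-hypercube
formulations (single measurement) for the screening analyses; global Shapley
rankings from 128 antithetic permutations on 80 instances against a 100-row
background; campaigns with 40 initial formulations, a 40-experiment budget
in batches of 5 under the balanced strategy with the R² stopping target
disabled (set to 1.0) so the fixed budget defines the comparison; ten seeds
per experiment. Campaign success is measured one-sidedly —
best observed − true minimum ≤ 0.15 log10 — because observations carry
N(0, 0.1) noise and the best observed value routinely undershoots the
noiseless minimum near the optimum.

## Findings the tests record honestly

Two behaviors of the fixed 30-tree/depth-20 ensemble at screening sample
sizes are worth knowing:

* With replicate-aware (leakage-free) CV, out-of-fold R² on the synthetic
  screen sits well below what row-shuffled CV reports on duplicated data;
  the boosted surrogate is consistently the stronger of the two tree models
  there, and plain OLS is competitive because the landscape is largely
  additive.
* At n = 200 with 19 features, every surrogate genuinely attributes a few
  percent of the top feature's Shapley importance to null features (spurious
  sample correlations of order 1/√n are real structure to the model). The
  designed-vs-null *ordering* is recovered essentially always; an absolute
  5%-of-top selection cut, however, lands inside the null tail and keeps an
  occasional null feature. The acceptance suite asserts both versions and
  reports the outcome as computed.

## Limitations

* Single isotropic length-scale; no ARD, no non-Gaussian likelihoods, no
  sparse approximations (datasets are at most a few hundred rows).
* Only LCB acquisition; no expected improvement or knowledge gradient.
* Exact Shapley is exponential in features (capped at 14); the sampled
  estimator's per-feature error scales as the marginal-contribution sd over
  √permutations.
* The campaign cannot reconstruct which historical observations came from
  which design source; user-injected (empirically designed) observations are
  tagged but otherwise treated identically.
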