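# formubo

Bayesian-optimization workflows for (bio)pharmaceutical formulation
development, built for screens where each data point is an expensive wet-lab
experiment: stabilizing a liquid live-virus formulation (minimize one-week
infectious-titer loss, log10 PFU/mL) or composing a freeze-dried formulation
(maximize the glass-transition temperature Tg′ of the freeze concentrate,
°C). It is a library first — the importable API plus the narrative scripts
in `examples/` are the interface — with a thin `formubo` CLI for the three
steps users actually run from a shell (simulate / suggest / campaign).

## What it implements

* **Gaussian-process surrogate** with the Matérn ν = 5/2 kernel on
  unit-scaled inputs, K(x,x′) = s²(1 + √5d/ℓ + 5d²/3ℓ²)·exp(−√5d/ℓ),
  hyperparameters by multi-start marginal-likelihood maximization.
* **Lower-Confidence-Bound acquisition**, LCB(x) = μ(x) − κσ(x), with
  exploitation / balanced / exploration presets (κ = 0.1 / 1.96 / 8),
  seeded Sobol candidate pools, linear-constraint rejection, constant-liar
  batching and deterministic local polish.
* **Tree-ensemble and linear surrogates** with fixed hyperparameters
  (30-tree / depth-20 extremely randomized trees; depth-3 boosted trees;
  OLS) plus CV-based automatic model selection.
* **Evaluation**: replicate-aware k-fold CV (RMSE ± sd across folds, pooled
  out-of-fold R²), tolerance-based holdout accuracy, signed
  prediction-error tables.
* **Attribution**: exact (M ≤ 14) and permutation-sampled interventional
  Shapley values, global mean-|φ| rankings and dependence data, thresholded
  feature selection, wrapper backward elimination, permutation importance.
* **Campaign orchestration**: fit → cross-validate → suggest → measure →
  augment → (optionally) prune features → stop, with a step-by-step audit
  log.
* **Response maps**: grid predictions over two features and optimal-zone
  extraction by threshold.
* **Synthetic landscapes** with known ground truth — a titer-loss screen
  with saturating protective (residual rHSA, knee 0.2 mg/mL) and
  destabilizing (spiked rHSA, knee 2 mg/mL) effects plus designed and null
  excipients, and a Tg′ mixture following the Fox rule with DSC-scale
  noise — so the entire loop is testable without any external data.

See `docs/methods.md` for the models, defaults, and design rationale.

## Worked example

`python examples/06_tg_holdout_errors.py` summarizes prediction errors on
the bundled 20-formulation Tg′ validation table (experimental DSC values vs
two surrogates that never saw them):

```
boosted  mean signed error +0.335 °C, mean |error| 0.535 °C, max |error| 1.90 °C
linear   mean signed error -2.450 °C, mean |error| 2.530 °C, max |error| 5.90 °C
```

The boosted surrogate's average signed error of ~0.33 °C is a fraction of
the ±3 °C DSC determination uncertainty — the model is accurate and nearly
unbiased — while the linear model systematically underestimates Tg′ by up
to 5.9 °C.

`python examples/01_simulate_and_crossvalidate.py` simulates a 150-point
synthetic titer screen and cross-validates three surrogates under identical
folds:

```
screen: 150 observations, 9 features
Linear             RMSE = 0.23 ± 0.02, R² = 0.79
Extra trees        RMSE = 0.30 ± 0.05, R² = 0.63
Gradient boosting  RMSE = 0.26 ± 0.04, R² = 0.72
selected by CV: Linear (lowest mean RMSE, ties to the simpler model)
```

RMSE is in log10 PFU/mL of titer loss; at this sample size the largely
additive landscape keeps plain least squares competitive with the tree
ensembles — one of the honest findings the package documents.

The other examples cover GP-driven experiment suggestion (`02`), Shapley
feature analysis and 19 → 9 feature selection (`03`), a full BO campaign
against the synthetic oracle (`04`), and response-surface zone extraction
(`05`).

## CLI

```sh
formubo simulate --landscape titer --n 200 --replicates 2 --seed 3 --out screen.csv
formubo suggest  --model gp.json --space space.json --strategy balanced --batch 5 --seed 7 --out next.csv
formubo campaign --data screen.csv --oracle synthetic-titer-reduced --budget 40 --seed 11 --out rundir/
```
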