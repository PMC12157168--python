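"""Scaled-down study-analog experiments on the synthetic landscapes.

Three end-to-end exercises, each deterministic given its seed, shared by the
test suite and the acceptance script:

* **Feature recovery** — on the 19-feature screen (9 designed effects, 10
  nulls; 200 formulations, assay noise 0.1 log10), select the surrogate by
  cross-validation, rank features by global Shapley importance, and apply the
  5%-of-top selection rule.  Reports whether exactly the 9 designed features
  survive and whether every designed feature outranks every null.
* **Optimization campaign** — 40 initial formulations + a 40-experiment
  budget of LCB-suggested batches of 5 on the 9-feature designed-effects
  landscape, against an equal-budget random-sampling baseline with the same
  measurement noise.  Reports the gap between the best observed loss and the
  landscape's known minimum (one-sided: observations carry noise, so the
  best observed value can undershoot the noiseless minimum).
* **Wrapper dominance** — single-feature backward elimination on the
  9-feature landscape; reports whether removing the dominant designed effect
  (the saturating protective one) produces the largest ΔR².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attribution import global_shap, select_features, wrapper_elimination
from .campaign import CampaignConfig, run_campaign
from .evaluation import kfold_cv
from .models import LinearModelSpec, TreeEnsembleSpec, fit_model, select_model
from .synthetic import screening_landscape, generate_dataset, reduced_landscape, sample_design

__all__ = [
    "feature_recovery_trial",
    "campaign_trial",
    "wrapper_trial",
    "surrogate_cv_trial",
]

N_FORMULATIONS = 200
RECOVERY_THRESHOLD = 0.05
SHAP_PERMUTATIONS = 128
SHAP_INSTANCES = 80
CAMPAIGN_INITIAL = 40
CAMPAIGN_BUDGET = 40
CAMPAIGN_BATCH = 5


def _screen_dataset(landscape, seed: int, n: int = N_FORMULATIONS, replicates: int = 1):
    design = sample_design(landscape.space, n, scheme="latin", seed=seed)
    return generate_dataset(landscape.oracle(seed), design, replicates=replicates,
                            seed=seed, response_name=landscape.response.name,
                            space=landscape.space)


def feature_recovery_trial(seed: int) -> dict:
    """One seeded 19→9 feature-selection exercise (CV-selected surrogate)."""
    land = screening_landscape()
    ds = _screen_dataset(land, seed)
    names = land.space.names
    candidates = [LinearModelSpec(), TreeEnsembleSpec.extra_trees(seed=seed),
                  TreeEnsembleSpec.gradient_boosted(seed=seed)]
    best, _ = select_model(candidates, ds, seed=seed)
    model = fit_model(best, ds.frame[names], ds.y, feature_names=names, seed=seed)
    ranking = global_shap(model, ds, mode="sampled", n_permutations=SHAP_PERMUTATIONS,
                          max_instances=SHAP_INSTANCES, seed=seed)
    selected = select_features(ranking, RECOVERY_THRESHOLD)
    designed = set(land.designed_features)
    nulls = land.null_features
    d = ranking.mean_abs_phi
    return {
        "model": best.label,
        "selected": selected,
        "exact": set(selected) == designed,
        "rank_separated": float(d[list(designed)].min()) > float(d[nulls].max()),
        "weakest_designed_phi": float(d[list(designed)].min()),
        "top_null_phi": float(d[nulls].max()),
        "threshold": RECOVERY_THRESHOLD * float(d.iloc[0]),
    }


def campaign_trial(seed: int) -> dict:
    """One seeded BO campaign vs an equal-budget random baseline."""
    land = reduced_landscape()
    init = _screen_dataset(land, seed, n=CAMPAIGN_INITIAL)
    cfg = CampaignConfig(budget=CAMPAIGN_BUDGET, batch_size=CAMPAIGN_BATCH,
                         strategy="balanced", r2_target=1.0, seed=seed)
    log = run_campaign(init, land.space, land.oracle(seed), cfg)
    rand_extra = sample_design(land.space, CAMPAIGN_BUDGET, scheme="uniform", seed=seed + 10_000)
    rand_ds = generate_dataset(land.oracle(seed), rand_extra, replicates=1,
                               seed=seed + 20_000, response_name=land.response.name,
                               space=land.space)
    true_min = land.true_minimum()
    bo_best = float(log.best_so_far[-1])
    random_best = float(min(init.y.min(), rand_ds.y.min()))
    return {
        "true_minimum": true_min,
        "bo_best": bo_best,
        "bo_gap": bo_best - true_min,
        "random_best": random_best,
        "random_gap": random_best - true_min,
        "n_steps": len(log.steps),
    }


def wrapper_trial(seed: int) -> dict:
    """One seeded wrapper backward-elimination exercise."""
    land = reduced_landscape()
    ds = _screen_dataset(land, seed)
    report = wrapper_elimination(TreeEnsembleSpec.extra_trees(seed=seed), ds, seed=seed)
    top = str(report.rows.iloc[0]["group"])
    return {
        "baseline_r2": float(report.baseline.r2),
        "top_removal": top,
        "dominant_is_top": top == "residual_rhsa",
        "top_delta_r2": float(report.rows.iloc[0]["delta_r2"]),
    }


def surrogate_cv_trial(seed: int) -> dict:
    """Cross-validated surrogate quality on the 9-feature screen."""
    land = reduced_landscape()
    ds = _screen_dataset(land, seed)
    et = kfold_cv(TreeEnsembleSpec.extra_trees(seed=seed), ds, k=5, seed=seed)
    xgb = kfold_cv(TreeEnsembleSpec.gradient_boosted(seed=seed), ds, k=5, seed=seed)
    lin = kfold_cv(LinearModelSpec(), ds, k=5, seed=seed)
    return {
        "extra_trees_r2": et.r2, "extra_trees_rmse": et.rmse_mean,
        "boosted_r2": xgb.r2, "boosted_rmse": xgb.rmse_mean,
        "linear_r2": lin.r2, "linear_rmse": lin.rmse_mean,
    }
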