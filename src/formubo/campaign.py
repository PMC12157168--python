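"""Iterative model-optimization campaigns: fit → cross-validate → suggest →
measure → augment → (optionally) reduce features → stop.

Each step fits the candidate surrogates, selects the best by k-fold CV, and
logs a step record (data size, model type, hyperparameters, RMSE ± sd, R²) —
the audit trail a formulation team reports.  Acquisition is always driven by
the GP surrogate with LCB (tree models serve reporting and attribution); a
config switch allows the across-tree-sd proxy instead, as an extension.

Stopping: the campaign ends when the cross-validated R² reaches its target
or the experiment budget is exhausted.  Feature reduction (global Shapley
ranking + thresholded selection) triggers once, after a configured number of
augmentation steps, and only when more than ``min_features`` remain.  Runs
are bit-reproducible given the master seed and a deterministic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .acquisition import AcquisitionConfig, suggest_batch
from .attribution import global_shap, select_features
from .design import Dataset, DesignSpace
from .evaluation import CVConfig, EvalMetrics
from .gp import GPFitConfig, fit_gp
from .models import TreeEnsembleSpec, fit_model, select_model
from .synthetic import GroundTruthOracle

__all__ = ["FeatureReduction", "CampaignConfig", "StepRecord", "CampaignLog",
           "run_campaign", "stopping_rule", "StopDecision"]


@dataclass(frozen=True)
class FeatureReduction:
    enabled: bool = False
    trigger_after_augmentations: int = 2
    threshold_fraction: float = 0.05
    min_features: int = 10
    n_permutations: int = 128
    max_instances: int = 100


@dataclass(frozen=True)
class CampaignConfig:
    budget: int = 0                  # max new observations
    batch_size: int = 5
    strategy: str = "balanced"
    r2_target: float = 0.9
    feature_reduction: FeatureReduction = FeatureReduction()
    seed: int = 0
    cv: CVConfig = CVConfig()
    candidates: tuple = ()           # model specs; default: 30-tree depth-20 ensemble
    candidate_pool_size: int = 4096
    local_polish: bool = True
    replicates_per_query: int = 1

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValueError("budget must be >= 0")
        if not 0 < self.r2_target <= 1:
            raise ValueError("r2_target must be in (0, 1]")


@dataclass
class StepRecord:
    step_index: int
    data_size: int
    model_type: str
    hyperparameters: dict
    metrics: EvalMetrics
    action: str  # trained | augmented | features_reduced | validated


@dataclass
class StopDecision:
    stop: bool
    reason: str


def stopping_rule(metrics: EvalMetrics, config: CampaignConfig, budget_left: int) -> StopDecision:
    """Stop when R² meets the target or no experiment budget remains."""
    if metrics.r2 >= config.r2_target:
        return StopDecision(True, f"r2_target reached ({metrics.r2:.3f} >= {config.r2_target})")
    if budget_left <= 0:
        return StopDecision(True, "budget exhausted")
    return StopDecision(False, "continue")


@dataclass
class CampaignLog:
    steps: list[StepRecord]
    best_so_far: list[float]
    final_model: object
    active_features: list[str]
    config: CampaignConfig
    dataset: Dataset
    stop_reason: str

    def table(self) -> pd.DataFrame:
        """Step log in report shape: data size, model, hyperparameters, metrics."""
        return pd.DataFrame([
            {
                "step": s.step_index,
                "data_size": s.data_size,
                "model_type": s.model_type,
                "hyperparameters": "; ".join(f"{k}={v}" for k, v in s.hyperparameters.items()),
                "rmse": f"{s.metrics.rmse_mean:.2f} ± {s.metrics.rmse_sd:.2f}",
                "r2": round(s.metrics.r2, 3),
                "action": s.action,
            }
            for s in self.steps
        ])


def _best_observed(data: Dataset) -> float:
    y = data.y
    return float(y.min() if data.response.direction == "minimize" else y.max())


def run_campaign(initial: Dataset, space: DesignSpace, oracle: GroundTruthOracle,
                 config: CampaignConfig) -> CampaignLog:
    """Run the iterative optimization loop against a ground-truth oracle.

    The oracle answers any in-bounds formulation with a (noisy) measurement;
    new observations are appended with source_tag='bo_suggested'.  The
    maximize direction is handled by negating responses at the GP/acquisition
    boundary, so the engine always minimizes.
    """
    if len(initial) == 0:
        raise ValueError("initial dataset must be non-empty")
    data = initial
    active = list(space.base_names)
    candidates = list(config.candidates) or [TreeEnsembleSpec.extra_trees(seed=config.seed)]
    ss = np.random.SeedSequence(config.seed)
    step_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4096)]

    steps: list[StepRecord] = []
    best_trace: list[float] = []
    spent = 0
    augmentations = 0
    reduced = False
    step_idx = 0
    sign = 1.0 if data.response.direction == "minimize" else -1.0
    model = None
    reason = ""

    while True:
        # (1) fit candidate surrogates, select the best by CV on active features
        best_spec, _ = select_model(candidates, data, cv=config.cv,
                                    seed=config.cv.seed, feature_names=active)
        model = fit_model(best_spec, data.frame[active], data.y,
                          feature_names=active, seed=step_seeds[3 * step_idx])
        from .evaluation import kfold_cv

        metrics = kfold_cv(best_spec, data, k=config.cv.k, seed=config.cv.seed,
                           feature_names=active)
        action = "trained" if step_idx == 0 else "augmented"

        # (2) optional one-shot feature reduction
        if (config.feature_reduction.enabled and not reduced
                and augmentations >= config.feature_reduction.trigger_after_augmentations
                and len(active) > config.feature_reduction.min_features):
            fr = config.feature_reduction
            ranking = global_shap(model, data, mode="auto",
                                  n_permutations=fr.n_permutations,
                                  max_instances=fr.max_instances,
                                  seed=step_seeds[3 * step_idx + 1])
            active = select_features(ranking, fr.threshold_fraction)
            reduced = True
            model = fit_model(best_spec, data.frame[active], data.y,
                              feature_names=active, seed=step_seeds[3 * step_idx])
            metrics = kfold_cv(best_spec, data, k=config.cv.k, seed=config.cv.seed,
                               feature_names=active)
            action = "features_reduced"

        steps.append(StepRecord(step_idx, len(data), best_spec.label,
                                dict(best_spec.hyperparameters), metrics, action))
        best_trace.append(_best_observed(data))

        decision = stopping_rule(metrics, config, config.budget - spent)
        if decision.stop:
            reason = decision.reason
            break

        # (3) GP + LCB suggestion on the active subspace
        sub = space.subspace(active)
        U = sub.to_unit(data.frame[active].to_numpy(dtype=float), active)
        gp = fit_gp(U, sign * data.y, GPFitConfig(seed=step_seeds[3 * step_idx + 2]))
        n_new = min(config.batch_size, config.budget - spent)
        batch = suggest_batch(gp, sub, AcquisitionConfig(
            strategy=config.strategy, batch_size=n_new,
            candidate_pool_size=config.candidate_pool_size,
            seed=step_seeds[3 * step_idx + 2], local_polish=config.local_polish,
        ), feature_names=active)

        # (4) measure through the oracle and augment; inactive features sit at
        # their mid-bounds reference values
        full = pd.DataFrame(index=range(len(batch.candidates)))
        for f in space.features:
            if f.role == "derived":
                continue
            if f.name in batch.candidates.columns:
                full[f.name] = batch.candidates[f.name].to_numpy()
            else:
                full[f.name] = 0.5 * (f.lower + f.upper)
        measured = oracle.query(full, replicates=config.replicates_per_query)
        measured = measured.rename(columns={"response": data.response.name})
        measured["source_tag"] = "bo_suggested"
        for f in space.features:
            if f.role == "derived":
                measured[f.name] = measured[list(f.parents)].sum(axis=1)
        data = data.with_rows(measured)
        spent += len(measured)
        augmentations += 1
        step_idx += 1

    return CampaignLog(steps=steps, best_so_far=best_trace, final_model=model,
                       active_features=active, config=config, dataset=data,
                       stop_reason=reason)
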