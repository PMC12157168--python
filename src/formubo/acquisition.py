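"""Lower-Confidence-Bound acquisition and batch experiment suggestion.

LCB(x) = μ(x) − κ·σ(x) is minimized over the design space.  κ sets the
exploration/exploitation trade-off: a small κ chases the predicted optimum,
a large κ chases posterior uncertainty.  The engine's canonical direction is
minimization; maximize-direction responses are negated upstream, so
minimizing LCB is always correct.

Candidates come from a seeded scrambled-Sobol pool mapped into the bounds and
rejection-filtered against linear constraints (honouring solubility-style
limits so no nonsensical experiment is suggested).  Batches use the
constant-liar rule: each selected candidate is temporarily added to the GP
with its predicted mean before re-scoring, which spreads the batch out.  An
optional local polish (L-BFGS-B started from the best pool point) refines the
winner within bounds; it can be disabled to make selection an exact argmin
over the pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .design import DesignSpace
from .gp import GPState, PosteriorPrediction, predict_gp

__all__ = ["AcquisitionConfig", "SuggestionBatch", "lcb", "suggest_batch", "KAPPA_PRESETS"]

KAPPA_PRESETS = {"exploitation": 0.1, "balanced": 1.96, "exploration": 8.0}


@dataclass(frozen=True)
class AcquisitionConfig:
    """Strategy presets map to κ (exploitation 0.1, balanced 1.96,
    exploration 8.0); ``custom`` uses the given κ."""

    strategy: str = "balanced"
    kappa: float | None = None
    batch_size: int = 1
    candidate_pool_size: int = 4096
    seed: int = 0
    local_polish: bool = True

    def __post_init__(self) -> None:
        if self.strategy not in (*KAPPA_PRESETS, "custom"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "custom" and self.kappa is None:
            raise ValueError("custom strategy requires kappa")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @property
    def effective_kappa(self) -> float:
        k = self.kappa if self.strategy == "custom" else KAPPA_PRESETS[self.strategy]
        if k < 0:
            raise ValueError("kappa must be non-negative")
        return float(k)


@dataclass
class SuggestionBatch:
    """Suggested formulations (original units) with their acquisition values."""

    candidates: pd.DataFrame
    acquisition_values: np.ndarray
    strategy_used: str
    seed: int

    def save_csv(self, path) -> None:
        out = self.candidates.copy()
        out["acquisition_value"] = self.acquisition_values
        out.to_csv(path, index=False, float_format="%.12g")


def lcb(pred: PosteriorPrediction, kappa: float):
    """μ − κ·σ for a posterior prediction (scalar or vectorized)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    return pred.mean - kappa * pred.sd


def _candidate_pool(space: DesignSpace, names: Sequence[str], size: int, seed: int) -> np.ndarray:
    """Seeded scrambled-Sobol pool in the unit box, constraint-filtered.

    Returns unit-scaled coordinates for the named (non-derived) features.
    """
    d = len(names)
    sampler = qmc.Sobol(d=d, scramble=True, seed=seed)
    accepted: list[np.ndarray] = []
    total_drawn = 0
    while sum(len(a) for a in accepted) < size:
        u = sampler.random(max(size, 64))
        total_drawn += len(u)
        if space.constraints:
            X = space.from_unit(u, names)
            mask = np.array([
                space.satisfies_constraints(dict(zip(names, row))) for row in X
            ])
            u = u[mask]
        accepted.append(u)
        if total_drawn > 200 * size and sum(len(a) for a in accepted) == 0:
            raise ValueError("feasibility error: constraints rejected the entire candidate pool")
    return np.concatenate(accepted)[:size]


def suggest_batch(
    state: GPState,
    space: DesignSpace,
    config: AcquisitionConfig,
    feature_names: Sequence[str] | None = None,
) -> SuggestionBatch:
    """Suggest the next ``batch_size`` experiments by LCB over a seeded pool.

    ``feature_names`` are the non-derived features the GP was trained on (in
    training order); defaults to the space's non-derived features.  The GP is
    assumed to be fitted on unit-scaled inputs of exactly those features.
    """
    names = list(feature_names) if feature_names is not None else space.base_names
    if len(names) != state.dim:
        raise ValueError(f"GP expects {state.dim} features, got {len(names)}")
    kappa = config.effective_kappa

    pool = _candidate_pool(space, names, config.candidate_pool_size, config.seed)
    bounds01 = [(0.0, 1.0)] * len(names)

    def score(st: GPState, U: np.ndarray) -> np.ndarray:
        return np.asarray(lcb(predict_gp(st, U), kappa))

    def feasible(u: np.ndarray) -> bool:
        x = space.from_unit(u, names)
        return space.satisfies_constraints(dict(zip(names, x)))

    work = state
    chosen_u: list[np.ndarray] = []
    chosen_val: list[float] = []
    taken = np.zeros(len(pool), dtype=bool)
    for _ in range(config.batch_size):
        vals = score(work, pool)
        vals[taken] = np.inf
        idx = int(np.argmin(vals))
        u_best, v_best = pool[idx].copy(), float(vals[idx])
        if config.local_polish:
            res = optimize.minimize(
                lambda u: float(score(work, u[None, :])[0]),
                u_best, method="L-BFGS-B", bounds=bounds01,
            )
            if res.fun < v_best and feasible(res.x):
                cand = np.clip(res.x, 0.0, 1.0)
                # keep batch members distinct
                if all(np.linalg.norm(cand - c) > 1e-9 for c in chosen_u):
                    u_best, v_best = cand, float(res.fun)
        taken[idx] = True
        chosen_u.append(u_best)
        chosen_val.append(v_best)
        # constant liar: pretend the predicted mean was observed there
        mu_std = float((predict_gp(work, u_best).mean - work.y_mean) / work.y_sd)
        work = work.with_data(
            np.vstack([work.X, u_best[None, :]]), np.append(work.y, mu_std)
        )

    U = np.array(chosen_u)
    X = space.from_unit(U, names)
    frame = pd.DataFrame(X, columns=names)
    return SuggestionBatch(
        candidates=frame,
        acquisition_values=np.array(chosen_val),
        strategy_used=config.strategy,
        seed=config.seed,
    )
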