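"""Synthetic formulation landscapes with known ground truth.

Two generators emulate the statistical structure of the two screens the
package is built around, so every other module is testable without any
external data:

* **Liquid-formulation titer-loss landscape** — response in log10 PFU/mL,
  built from a baseline loss plus (i) a saturating *protective* residual-rHSA
  effect (piecewise-linear, plateau at a knee near 0.2 mg/mL), (ii) a
  saturating *destabilizing* spiked-rHSA effect (plateau near 2 mg/mL),
  (iii) linear effects for designed excipients, an optional quadratic
  excipient and pairwise interaction, (iv) an optional starting-titer
  covariate on [6.9, 7.9] log10 PFU/mL, and (v) any number of null features.
  The noiseless loss is clipped at 0 from below.  Saturations are piecewise
  linear (not smoothed) so knee recovery has an unambiguous ground truth.
* **Freeze-dried Tg' mixture** — Tg' of the maximally freeze-concentrated
  solution from component Tg' values via the Fox rule on absolute
  temperature, 1/T_mix = Σ wᵢ/Tᵢ with solute mass fractions wᵢ, plus optional
  pairwise deviation terms for Gordon–Taylor-like non-ideality.  PVP's
  component value is −26 °C; the remaining component values are plausible
  placeholders for anonymized excipients.

Assay noise defaults: 0.1 log10 for titer loss (plausible plaque-assay
precision) and 1.5 °C for Tg' (half of a ±3 °C DSC determination envelope).
Samples are measured in duplicate by default.  Noise is keyed to (seed,
formulation, replicate), so re-querying the same formulation/replicate
reproduces the identical noisy value.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .design import Dataset, DesignSpace, FeatureSpec, ResponseSpec

__all__ = [
    "TiterLandscapeParams",
    "TgMixtureParams",
    "GroundTruthOracle",
    "titer_loss_truth",
    "tg_truth",
    "sample_design",
    "generate_dataset",
    "screening_landscape",
    "reduced_landscape",
    "tg_mixture",
]

_KELVIN = 273.15


# ---------------------------------------------------------------------------
# Titer-loss landscape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TiterLandscapeParams:
    """Ground-truth parameters of the liquid-screen titer-loss landscape.

    Effects are in log10 PFU/mL.  ``residual_effect`` is protective (loss
    drops by that amount from concentration 0 to the knee); ``spiked_effect``
    is destabilizing (loss rises up to its knee).
    """

    baseline_loss: float = 1.5
    residual_knee: float = 0.2   # mg/mL
    residual_effect: float = 0.8
    spiked_knee: float = 2.0     # mg/mL
    spiked_effect: float = 0.4
    linear_coeffs: tuple[tuple[str, float], ...] = ()
    quadratic_feature: tuple[str, float, float] | None = None  # (name, optimum, curvature)
    interaction: tuple[str, str, float] | None = None
    n_null_features: int = 0
    starting_titer_coeff: float = 0.05
    starting_titer_range: tuple[float, float] = (6.9, 7.9)
    include_starting_titer: bool = False
    noise_sd: float = 0.1
    replicates: int = 2

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.residual_knee <= 0 or self.spiked_knee <= 0:
            raise ValueError("knees must be positive")


def _saturating(c: np.ndarray, knee: float) -> np.ndarray:
    """min(c, knee)/knee — linear ramp to 1 at the knee, flat beyond."""
    return np.minimum(c, knee) / knee


def titer_loss_truth(params: TiterLandscapeParams, formulation: Mapping[str, float]):
    """Noiseless titer loss (log10 PFU/mL) for one formulation mapping.

    loss = baseline − a·sat(residual) + b·sat(spiked) + Σ linear + quadratic
           + interaction + titer term, clipped at 0 from below.
    """
    def get(name):
        if name not in formulation:
            raise KeyError(f"missing feature {name!r}")
        return np.asarray(formulation[name], dtype=float)

    loss = params.baseline_loss * np.ones_like(get("residual_rhsa"), dtype=float)
    loss = loss - params.residual_effect * _saturating(get("residual_rhsa"), params.residual_knee)
    loss = loss + params.spiked_effect * _saturating(get("spiked_rhsa"), params.spiked_knee)
    for name, coeff in params.linear_coeffs:
        loss = loss + coeff * get(name)
    if params.quadratic_feature is not None:
        name, opt, curv = params.quadratic_feature
        loss = loss + curv * (get(name) - opt) ** 2
    if params.interaction is not None:
        a, b, coeff = params.interaction
        loss = loss + coeff * get(a) * get(b)
    if params.include_starting_titer:
        lo = params.starting_titer_range[0]
        loss = loss + params.starting_titer_coeff * (get("starting_titer") - lo)
    return np.clip(loss, 0.0, None)


def _titer_space(params: TiterLandscapeParams) -> DesignSpace:
    feats = [
        FeatureSpec("residual_rhsa", 0.0, 0.6, "mg/mL"),
        FeatureSpec("spiked_rhsa", 0.0, 5.0, "mg/mL"),
    ]
    for name, _ in params.linear_coeffs:
        feats.append(FeatureSpec(name, 0.0, 1.0, "% w/v"))
    if params.quadratic_feature is not None:
        feats.append(FeatureSpec(params.quadratic_feature[0], 0.0, 1.0, "% w/v"))
    for i in range(params.n_null_features):
        feats.append(FeatureSpec(f"null_{i + 1}", 0.0, 1.0, "% w/v"))
    if params.include_starting_titer:
        feats.append(FeatureSpec("starting_titer", *params.starting_titer_range,
                                 "log10 PFU/mL", role="covariate"))
    return DesignSpace(feats)


# The canonical designed-effect set: two saturating rHSA effects, six linear
# excipients and one curved excipient.  Every designed effect contributes a
# response standard deviation at least as large as the assay noise sd (0.1),
# so "impactful" features are genuinely impactful and cleanly separable from
# the nulls — the regime the screen this emulates operated in.
_DESIGNED_LINEAR = (
    ("excipient_a", 0.60),
    ("excipient_b", -0.55),
    ("excipient_c", 0.50),
    ("excipient_d", -0.45),
    ("excipient_e", 0.45),
    ("excipient_f", 0.40),
)
_DESIGNED_QUADRATIC = ("excipient_g", 0.35, 1.5)


def reduced_landscape(noise_sd: float = 0.1) -> "TiterLandscape":
    """The 9-feature landscape of designed effects only (the post-feature-
    reduction screen a campaign optimizes over)."""
    params = TiterLandscapeParams(
        linear_coeffs=_DESIGNED_LINEAR,
        quadratic_feature=_DESIGNED_QUADRATIC,
        n_null_features=0,
        noise_sd=noise_sd,
    )
    return TiterLandscape(params)


def screening_landscape(n_null_features: int = 10, noise_sd: float = 0.1) -> "TiterLandscape":
    """The 19-feature screening landscape: 9 designed effects + 10 nulls."""
    params = TiterLandscapeParams(
        linear_coeffs=_DESIGNED_LINEAR,
        quadratic_feature=_DESIGNED_QUADRATIC,
        n_null_features=n_null_features,
        noise_sd=noise_sd,
    )
    return TiterLandscape(params)


class TiterLandscape:
    """Bundle of params + design space + truth function for the titer screen."""

    def __init__(self, params: TiterLandscapeParams):
        self.params = params
        self.space = _titer_space(params)
        self.response = ResponseSpec("titer_loss", "log10 PFU/mL", "minimize")

    @property
    def designed_features(self) -> list[str]:
        names = ["residual_rhsa", "spiked_rhsa"] + [n for n, _ in self.params.linear_coeffs]
        if self.params.quadratic_feature is not None:
            names.append(self.params.quadratic_feature[0])
        return names

    @property
    def null_features(self) -> list[str]:
        return [f"null_{i + 1}" for i in range(self.params.n_null_features)]

    def truth(self, formulation: Mapping[str, float]):
        return titer_loss_truth(self.params, formulation)

    def truth_frame(self, frame: pd.DataFrame) -> np.ndarray:
        return np.asarray(titer_loss_truth(self.params, {c: frame[c].to_numpy() for c in frame}))

    def true_minimum(self) -> float:
        """Analytic minimum of the noiseless loss (separable landscapes only)."""
        p = self.params
        if p.interaction is not None:
            raise ValueError("true minimum is only analytic without interactions")
        total = p.baseline_loss - p.residual_effect  # residual at/above its knee
        # spiked at 0 contributes 0
        for name, coeff in p.linear_coeffs:
            lo, hi = self.space[name].lower, self.space[name].upper
            total += min(coeff * lo, coeff * hi)
        # quadratic optimum inside bounds contributes 0
        return max(0.0, total)

    def oracle(self, seed: int = 0) -> "GroundTruthOracle":
        return GroundTruthOracle(
            truth=self.truth_frame, noise_sd=self.params.noise_sd,
            seed=seed, direction="minimize", feature_names=self.space.names,
        )


# ---------------------------------------------------------------------------
# Tg' mixture landscape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TgMixtureParams:
    """Components of a freeze-dried screen: (name, component Tg' in °C,
    lower bound, upper bound in mg/mL).  Mixture Tg' follows the Fox rule on
    kelvin with solute mass fractions; optional pairwise ``deviation_terms``
    ((name_i, name_j, k_ij) adding k_ij·wᵢ·wⱼ °C) model non-ideal mixing."""

    components: tuple[tuple[str, float, float, float], ...]
    deviation_terms: tuple[tuple[str, str, float], ...] = ()
    noise_sd: float = 1.5  # °C, DSC measurement uncertainty
    replicates: int = 1

    def __post_init__(self) -> None:
        for name, tg, lo, hi in self.components:
            if not -80.0 < tg < 0.0:
                raise ValueError(f"{name}: component Tg' must lie in (-80, 0) °C")
            if not 0 <= lo < hi:
                raise ValueError(f"{name}: bad concentration bounds")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def tg_truth(params: TgMixtureParams, formulation: Mapping[str, float]):
    """Noiseless mixture Tg' (°C) via the Fox rule in kelvin.

    Single-component limit returns that component's Tg' exactly; an all-zero
    formulation is an undefined mixture and raises.
    """
    names = [c[0] for c in params.components]
    conc = np.array([np.asarray(formulation[n], dtype=float) for n in names])
    total = conc.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("undefined mixture: total solute concentration must be > 0")
    w = conc / total
    t_k = np.array([c[1] + _KELVIN for c in params.components])
    t_mix = 1.0 / np.tensordot(1.0 / t_k, w, axes=1)
    tg_c = t_mix - _KELVIN
    for a, b, k in params.deviation_terms:
        tg_c = tg_c + k * w[names.index(a)] * w[names.index(b)]
    return tg_c


# Component Tg' values: PVP −26 °C is literature-anchored; the rest are
# plausible placeholders for the anonymized excipients of a real screen
# (disaccharides ≈ −30, polyols ≈ −44, amino acids ≈ −50 to −60 °C).
_TG_COMPONENTS = (
    ("buffer", -55.0, 0.0, 10.0),
    ("histidine", -33.0, 0.0, 20.0),
    ("proline", -52.0, 0.0, 30.0),
    ("dextran", -11.0, 0.0, 50.0),
    ("sucrose", -32.0, 0.0, 50.0),
    ("trehalose", -29.0, 0.0, 50.0),
    ("sorbitol", -44.0, 0.0, 30.0),
    ("pvp10", -26.0, 0.0, 50.0),
    ("glycine", -62.0, 0.0, 20.0),
)


def tg_mixture(noise_sd: float = 1.5) -> "TgMixture":
    """Nine-solute freeze-dried screen with a buffer, two amino acids, a
    polysaccharide, sugars, a polyol and the polymer PVP."""
    return TgMixture(TgMixtureParams(components=_TG_COMPONENTS, noise_sd=noise_sd))


class TgMixture:
    def __init__(self, params: TgMixtureParams):
        self.params = params
        feats = [FeatureSpec(n, lo, hi, "mg/mL") for n, _, lo, hi in params.components]
        self.space = DesignSpace(feats)
        self.response = ResponseSpec("tg_prime", "degC", "maximize")

    def truth(self, formulation: Mapping[str, float]):
        return tg_truth(self.params, formulation)

    def truth_frame(self, frame: pd.DataFrame) -> np.ndarray:
        return np.asarray(tg_truth(self.params, {c: frame[c].to_numpy() for c in frame}))

    def oracle(self, seed: int = 0) -> "GroundTruthOracle":
        return GroundTruthOracle(
            truth=self.truth_frame, noise_sd=self.params.noise_sd,
            seed=seed, direction="maximize", feature_names=self.space.names,
        )


# ---------------------------------------------------------------------------
# Oracles, designs, datasets
# ---------------------------------------------------------------------------

def _noise_for(seed: int, row: np.ndarray, replicate: int, sd: float) -> float:
    """Measurement noise keyed to (seed, formulation bytes, replicate): the
    same replicate of the same formulation always reproduces its value."""
    h = hashlib.blake2b(digest_size=8)
    h.update(np.int64(seed).tobytes())
    h.update(np.asarray(row, dtype=np.float64).tobytes())
    h.update(np.int64(replicate).tobytes())
    sub = int.from_bytes(h.digest(), "little") % (2**31)
    return float(np.random.default_rng(sub).normal(0.0, sd))


@dataclass
class GroundTruthOracle:
    """Deterministic noiseless truth + seeded per-replicate Gaussian noise."""

    truth: callable
    noise_sd: float
    seed: int
    direction: str
    feature_names: list[str]

    def query(self, formulations: pd.DataFrame, replicates: int = 1) -> pd.DataFrame:
        """Noisy measurements for each formulation row × replicate."""
        rows = []
        clean = self.truth(formulations[self.feature_names])
        for i in range(len(formulations)):
            base = formulations.iloc[i]
            for r in range(1, replicates + 1):
                noise = _noise_for(self.seed, base[self.feature_names].to_numpy(dtype=float),
                                   r, self.noise_sd)
                row = dict(base)
                row["response"] = float(clean[i]) + noise
                row["replicate_id"] = r
                rows.append(row)
        return pd.DataFrame(rows)


def sample_design(space: DesignSpace, n: int, scheme: str = "latin",
                  seed: int = 0) -> pd.DataFrame:
    """Seeded in-bounds, constraint-respecting designs over the non-derived
    features.  ``latin`` stratifies every dimension; ``uniform`` draws iid."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if scheme not in ("latin", "uniform"):
        raise ValueError("scheme must be 'latin' or 'uniform'")
    names = space.base_names
    d = len(names)
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    attempts = 0
    while sum(len(a) for a in accepted) < n:
        if scheme == "latin":
            u = qmc.LatinHypercube(d=d, seed=rng.integers(2**31)).random(n)
        else:
            u = rng.random((n, d))
        X = space.from_unit(u, names)
        if space.constraints:
            mask = np.array([space.satisfies_constraints(dict(zip(names, row))) for row in X])
            X = X[mask]
        accepted.append(X)
        attempts += 1
        if attempts > 200 and sum(len(a) for a in accepted) == 0:
            raise ValueError("infeasible constraints: no design points accepted")
    out = np.concatenate(accepted)[:n]
    return pd.DataFrame(out, columns=names)


def generate_dataset(oracle: GroundTruthOracle, formulations: pd.DataFrame,
                     replicates: int = 2, seed: int | None = None,
                     response_name: str = "response",
                     response_unit: str = "", space: DesignSpace | None = None) -> Dataset:
    """Measure every formulation ``replicates`` times through the oracle.

    ``seed`` overrides the oracle's noise seed for this batch.  Returns a
    Dataset tagged source_tag='synthetic'.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    work = oracle if seed is None else GroundTruthOracle(
        truth=oracle.truth, noise_sd=oracle.noise_sd, seed=seed,
        direction=oracle.direction, feature_names=oracle.feature_names)
    measured = work.query(formulations, replicates=replicates)
    measured = measured.rename(columns={"response": response_name})
    measured["source_tag"] = "synthetic"
    if space is None:
        feats = [FeatureSpec(c, float(min(measured[c].min(), 0.0)),
                             float(measured[c].max()) + 1e-9)
                 for c in oracle.feature_names]
        space = DesignSpace(feats)
    direction = "minimize" if work.direction == "minimize" else "maximize"
    return Dataset(space, measured, ResponseSpec(response_name, response_unit, direction))
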