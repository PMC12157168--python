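"""Feature attribution: interventional Shapley values, permutation importance,
and wrapper backward elimination.

Shapley values decompose a single prediction additively over features,

    φᵢ = Σ_{S ⊆ F\\{i}} |S|!(M−|S|−1)!/M! · [v(S∪{i}) − v(S)],

with the interventional value function v(S) = mean over background rows of
the model evaluated with features in S taken from the instance and the rest
from the background row.  ``shap_exact`` enumerates all 2^M coalitions
(refused above M=14); ``shap_sampled`` averages marginal contributions over
seeded random permutations (antithetic pairs), each of which telescopes, so
local accuracy Σφᵢ + base = f(x) holds exactly for any number of draws.

A zero φ means that input value does not move the prediction away from the
background-average output.  Global importance is the mean |φ| over a dataset;
feature selection keeps features above a fraction of the top feature's mean
|φ|, mirroring the pruning of non-influential excipients from a screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .evaluation import CVConfig, EvalMetrics, kfold_cv, rmse

__all__ = [
    "ShapExplanation",
    "GlobalShapRanking",
    "WrapperReport",
    "PermutationImportanceReport",
    "shap_exact",
    "shap_sampled",
    "global_shap",
    "shap_dependence",
    "select_features",
    "wrapper_elimination",
    "permutation_importance",
]

_EXACT_MAX_FEATURES = 14
_DEFAULT_BACKGROUND = 100


@dataclass
class ShapExplanation:
    instance: np.ndarray
    phi: np.ndarray
    base_value: float
    feature_names: list[str]

    @property
    def prediction(self) -> float:
        return float(self.base_value + self.phi.sum())


@dataclass
class GlobalShapRanking:
    """Per-feature mean |φ| over a dataset, ordered non-increasing."""

    mean_abs_phi: pd.Series  # index: feature names, sorted descending
    phi_matrix: np.ndarray   # (n_instances, M) in original feature order
    feature_names: list[str]
    instance_index: np.ndarray

    @property
    def ordering(self) -> list[str]:
        return list(self.mean_abs_phi.index)


@dataclass
class WrapperReport:
    baseline: EvalMetrics
    rows: pd.DataFrame  # group, rmse_mean, rmse_sd, r2, delta_r2 (desc)


@dataclass
class PermutationImportanceReport:
    rows: pd.DataFrame  # feature, mean_degradation, sd_degradation
    baseline_metric: float


def _background_matrix(background, feature_names, seed: int = 0) -> np.ndarray:
    if isinstance(background, pd.DataFrame):
        B = background[feature_names].to_numpy(dtype=float)
    else:
        B = np.asarray(background, dtype=float)
    if B.ndim != 2 or len(B) == 0:
        raise ValueError("background must be a non-empty matrix")
    if len(B) > _DEFAULT_BACKGROUND:
        idx = np.random.default_rng(seed).choice(len(B), _DEFAULT_BACKGROUND, replace=False)
        B = B[np.sort(idx)]
    return B


def _instance_vector(instance, feature_names) -> np.ndarray:
    if isinstance(instance, (pd.Series, dict)):
        return np.array([float(instance[n]) for n in feature_names])
    x = np.asarray(instance, dtype=float).ravel()
    if len(x) != len(feature_names):
        raise ValueError("instance length does not match feature count")
    return x


def shap_exact(model, instance, background, background_seed: int = 0) -> ShapExplanation:
    """Exact interventional Shapley values by coalition enumeration (M ≤ 14)."""
    names = model.feature_names
    M = len(names)
    if M > _EXACT_MAX_FEATURES:
        raise ValueError(
            f"exact enumeration refused for M={M} > {_EXACT_MAX_FEATURES}; use shap_sampled")
    B = _background_matrix(background, names, background_seed)
    x = _instance_vector(instance, names)
    nB = len(B)

    # v(S) for every coalition mask, evaluated in chunks
    n_masks = 1 << M
    v = np.empty(n_masks)
    chunk = max(1, 200_000 // max(nB, 1))
    for start in range(0, n_masks, chunk):
        masks = np.arange(start, min(start + chunk, n_masks))
        onoff = (masks[:, None] >> np.arange(M)[None, :]) & 1  # (m, M)
        Z = np.where(onoff[:, None, :].astype(bool), x[None, None, :], B[None, :, :])
        preds = model.predict(Z.reshape(-1, M)).reshape(len(masks), nB)
        v[start:start + chunk] = preds.mean(axis=1)

    # Shapley weights by coalition size
    fact = [math.factorial(k) for k in range(M + 1)]
    w = np.array([fact[s] * fact[M - s - 1] / fact[M] for s in range(M)])
    sizes = np.array([bin(m).count("1") for m in range(n_masks)])
    phi = np.zeros(M)
    for i in range(M):
        bit = 1 << i
        without = np.flatnonzero((np.arange(n_masks) & bit) == 0)
        phi[i] = np.sum(w[sizes[without]] * (v[without | bit] - v[without]))
    return ShapExplanation(instance=x, phi=phi, base_value=float(v[0]), feature_names=list(names))


def shap_sampled(model, instance, background, n_permutations: int = 128,
                 seed: int = 0, background_seed: int = 0) -> ShapExplanation:
    """Permutation-sampling Shapley estimate (antithetic pairs).

    Unbiased; each permutation's marginal contributions telescope from the
    background mean to f(x), so efficiency holds exactly at any sample size.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    names = model.feature_names
    M = len(names)
    B = _background_matrix(background, names, background_seed)
    x = _instance_vector(instance, names)
    nB = len(B)

    rng = np.random.default_rng(seed)
    perms = []
    while len(perms) < n_permutations:
        p = rng.permutation(M)
        perms.append(p)
        if len(perms) < n_permutations:
            perms.append(p[::-1])  # antithetic partner
    perms = np.array(perms)

    base = float(model.predict(B).mean())
    fx = float(model.predict(x[None, :])[0])
    if M == 1:
        return ShapExplanation(x, np.array([fx - base]), base, list(names))

    # interior coalitions: for each permutation, prefixes of length 1..M-1
    P = len(perms)
    prefix_mask = np.zeros((P, M - 1, M), dtype=bool)
    for pi, p in enumerate(perms):
        for k in range(M - 1):
            prefix_mask[pi, k, p[: k + 1]] = True
    Z = np.where(prefix_mask[:, :, None, :], x[None, None, None, :], B[None, None, :, :])
    preds = model.predict(Z.reshape(-1, M)).reshape(P, M - 1, nB)
    v_interior = preds.mean(axis=2)  # (P, M-1)

    phi = np.zeros(M)
    for pi, p in enumerate(perms):
        v_seq = np.concatenate(([base], v_interior[pi], [fx]))
        contrib = np.diff(v_seq)
        phi[p] += contrib
    phi /= P
    return ShapExplanation(x, phi, base, list(names))


def global_shap(model, dataset, background=None, mode: str = "auto",
                n_permutations: int = 128, max_instances: int | None = None,
                seed: int = 0) -> GlobalShapRanking:
    """Mean |φ| per feature across dataset rows, ordered non-increasing.

    ``mode``: "exact", "sampled", or "auto" (exact when M ≤ 14).  The
    background defaults to the dataset's own feature matrix (subsampled to
    100 rows).  ``max_instances`` subsamples the explained rows (seeded).
    """
    names = model.feature_names
    X = dataset.frame[names] if hasattr(dataset, "frame") else pd.DataFrame(
        np.asarray(dataset, dtype=float), columns=names)
    Xm = X.to_numpy(dtype=float)
    if background is None:
        background = Xm
    if mode == "auto":
        mode = "exact" if len(names) <= _EXACT_MAX_FEATURES else "sampled"

    rng = np.random.default_rng(seed)
    idx = np.arange(len(Xm))
    if max_instances is not None and len(idx) > max_instances:
        idx = np.sort(rng.choice(len(Xm), max_instances, replace=False))

    phis = np.empty((len(idx), len(names)))
    for row, i in enumerate(idx):
        if mode == "exact":
            exp = shap_exact(model, Xm[i], background, background_seed=seed)
        else:
            exp = shap_sampled(model, Xm[i], background,
                               n_permutations=n_permutations,
                               seed=int(rng.integers(2**31)), background_seed=seed)
        phis[row] = exp.phi
    mean_abs = pd.Series(np.abs(phis).mean(axis=0), index=names).sort_values(
        ascending=False, kind="stable")
    return GlobalShapRanking(mean_abs_phi=mean_abs, phi_matrix=phis,
                             feature_names=list(names), instance_index=idx)


def shap_dependence(model, dataset, background, feature: str,
                    mode: str = "auto", n_permutations: int = 128,
                    seed: int = 0) -> pd.DataFrame:
    """(feature value, φ) pairs per dataset row — the dependence-plot data."""
    if feature not in model.feature_names:
        raise ValueError(f"unknown feature {feature!r}")
    ranking = global_shap(model, dataset, background, mode=mode,
                          n_permutations=n_permutations, seed=seed)
    j = model.feature_names.index(feature)
    X = dataset.frame[model.feature_names] if hasattr(dataset, "frame") else pd.DataFrame(
        np.asarray(dataset, dtype=float), columns=model.feature_names)
    vals = X.to_numpy(dtype=float)[ranking.instance_index, j]
    return pd.DataFrame({"value": vals, "phi": ranking.phi_matrix[:, j]})


def select_features(ranking: GlobalShapRanking, threshold_fraction: float = 0.05) -> list[str]:
    """Keep features with mean|φ| ≥ threshold_fraction × max mean|φ|.

    Never empty: the top feature is always kept.  Preserves the design-space
    order of the surviving features.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    top = float(ranking.mean_abs_phi.iloc[0])
    cutoff = threshold_fraction * top
    keep = {n for n, v in ranking.mean_abs_phi.items() if v >= cutoff}
    keep.add(ranking.mean_abs_phi.index[0])
    return [n for n in ranking.feature_names if n in keep]


def wrapper_elimination(spec, dataset, groups: Sequence[Sequence[str]] | None = None,
                        cv: CVConfig | None = None, seed: int = 0) -> WrapperReport:
    """Single-feature (or feature-group) backward elimination.

    Fits the full model and, for each group, the model with that group's
    columns removed, all with identical CV folds; ranks groups by ΔR²
    (baseline − reduced) descending — a larger drop means a stronger feature.
    """
    cv = cv or CVConfig(seed=seed)
    names = dataset.design_space.names
    if groups is None:
        groups = [[n] for n in names]
    for g in groups:
        if not g:
            raise ValueError("empty feature group")
        unknown = [n for n in g if n not in names]
        if unknown:
            raise ValueError(f"unknown feature(s) in group: {unknown}")
    baseline = kfold_cv(spec, dataset, k=cv.k, seed=cv.seed, feature_names=names)
    records = []
    for g in groups:
        remaining = [n for n in names if n not in set(g)]
        if not remaining:
            raise ValueError("cannot remove all features")
        m = kfold_cv(spec, dataset, k=cv.k, seed=cv.seed, feature_names=remaining)
        records.append({
            "group": " + ".join(g),
            "rmse_mean": m.rmse_mean, "rmse_sd": m.rmse_sd, "r2": m.r2,
            "delta_r2": baseline.r2 - m.r2,
        })
    rows = pd.DataFrame(records).sort_values(
        "delta_r2", ascending=False, kind="stable").reset_index(drop=True)
    return WrapperReport(baseline=baseline, rows=rows)


def permutation_importance(model, dataset, metric: Callable = rmse,
                           n_repeats: int = 10, seed: int = 0) -> PermutationImportanceReport:
    """Metric degradation under seeded within-column shuffles.

    Computed on the dataset given (use held-out data to avoid optimism).  A
    feature the model never reads degrades the metric by exactly 0.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    names = model.feature_names
    X = dataset.frame[names].to_numpy(dtype=float)
    y = dataset.y
    base = float(metric(y, model.predict(X)))
    rng = np.random.default_rng(seed)
    records = []
    for j, name in enumerate(names):
        degr = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            degr.append(float(metric(y, model.predict(Xp))) - base)
        records.append({"feature": name,
                        "mean_degradation": float(np.mean(degr)),
                        "sd_degradation": float(np.std(degr))})
    rows = pd.DataFrame(records).sort_values(
        "mean_degradation", ascending=False, kind="stable").reset_index(drop=True)
    return PermutationImportanceReport(rows=rows, baseline_metric=base)
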