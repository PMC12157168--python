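"""Cross-validation metrics, holdout accuracy, and prediction-error tables.

Conventions: k-fold CV uses a seeded shuffle into k contiguous folds; the
reported RMSE is mean ± population sd across folds, while R² is computed once
on the pooled out-of-fold predictions (small folds make per-fold R² unstable).
Holdout accuracy counts a prediction as correct when |predicted − observed|
is within a caller-supplied tolerance in response units.  Prediction-error
deltas are signed as predicted − observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EvalMetrics",
    "HoldoutReport",
    "PredictionErrorTable",
    "CVConfig",
    "rmse",
    "r_squared",
    "fold_indices",
    "kfold_cv",
    "holdout_accuracy",
    "prediction_error_summary",
]


@dataclass(frozen=True)
class CVConfig:
    k: int = 5
    seed: int = 0


@dataclass(frozen=True)
class EvalMetrics:
    rmse_mean: float
    rmse_sd: float
    r2: float
    k: int
    seed: int

    def __str__(self) -> str:
        return f"RMSE = {self.rmse_mean:.2f} ± {self.rmse_sd:.2f}, R² = {self.r2:.2f}"


@dataclass
class HoldoutReport:
    n_correct: int
    n_total: int
    tolerance: float
    per_row: pd.DataFrame  # columns: observed, predicted, abs_error, correct

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total


@dataclass
class PredictionErrorTable:
    rows: pd.DataFrame  # columns: observed, predicted, delta
    mean_signed_error: float
    mean_abs_error: float
    max_abs_error: float


def rmse(y, yhat) -> float:
    """√(Σ(yᵢ−ŷᵢ)²/n)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between y and yhat")
    if y.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y, yhat) -> float:
    """1 − SSres/SStot; undefined (error) for constant y."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between y and yhat")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        raise ValueError("undefined metric: y is constant")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sstot


def fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle into k contiguous folds.  Shared across candidates and
    wrapper rows so comparisons use identical splits."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def kfold_cv(spec, dataset, k: int = 5, seed: int = 0,
             feature_names: Sequence[str] | None = None,
             return_predictions: bool = False,
             group_replicates: bool = True):
    """k-fold cross-validation of a model spec on a Dataset (or (X, y) pair).

    Per-fold RMSE on the held-out rows gives rmse_mean ± rmse_sd; R² is pooled
    over all out-of-fold predictions.  Deterministic given the seed.

    Replicate measurements of the same formulation (identical full feature
    rows) are kept in the same fold by default: splitting them leaks the test
    formulation into training, and an interpolating ensemble then memorizes
    its duplicate, inflating every CV metric.
    """
    from .models import fit_model

    if isinstance(dataset, tuple):
        X, y = dataset
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        X_all = X
    else:
        names = feature_names if feature_names is not None else dataset.design_space.names
        X = dataset.X(names)
        y = dataset.y
        feature_names = names
        # group on the full design-space row so feature-subset CV (wrapper,
        # feature reduction) still keeps replicates together
        X_all = dataset.X(dataset.design_space.names)
    n = len(y)
    if group_replicates:
        _, group_of = np.unique(X_all, axis=0, return_inverse=True)
        n_groups = int(group_of.max()) + 1
        if n_groups < k:
            raise ValueError(f"need at least k={k} distinct formulations, got {n_groups}")
        gfolds = fold_indices(n_groups, k, seed)
        folds = [np.flatnonzero(np.isin(group_of, gf)) for gf in gfolds]
    else:
        folds = fold_indices(n, k, seed)
    pooled = np.empty(n)
    fold_rmse = []
    for j, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        model = fit_model(spec, X[train_idx], y[train_idx],
                          feature_names=feature_names, seed=seed * 1000 + j)
        pred = model.predict(X[test_idx])
        pooled[test_idx] = pred
        fold_rmse.append(rmse(y[test_idx], pred))
    metrics = EvalMetrics(
        rmse_mean=float(np.mean(fold_rmse)),
        rmse_sd=float(np.std(fold_rmse)),  # population sd across folds
        r2=r_squared(y, pooled),
        k=k,
        seed=seed,
    )
    if return_predictions:
        return metrics, pooled
    return metrics


def holdout_accuracy(model, test, tolerance: float) -> HoldoutReport:
    """Fraction of holdout rows with |predicted − observed| ≤ tolerance.

    The test set must be disjoint from all training/selection data — that is
    the caller's responsibility.
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be positive")
    if len(test) == 0:
        raise ValueError("empty test set")
    X = test.frame[model.feature_names]
    observed = test.y
    predicted = model.predict(X)
    err = np.abs(predicted - observed)
    correct = err <= tolerance
    per_row = pd.DataFrame({
        "observed": observed, "predicted": predicted,
        "abs_error": err, "correct": correct,
    })
    return HoldoutReport(
        n_correct=int(correct.sum()), n_total=len(test),
        tolerance=float(tolerance), per_row=per_row,
    )


def prediction_error_summary(rows) -> PredictionErrorTable:
    """Signed per-row delta = predicted − observed, with summary statistics.

    ``rows`` is a sequence of (observed, predicted) pairs or a DataFrame with
    ``observed`` / ``predicted`` columns.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows[["observed", "predicted"]].copy()
    else:
        frame = pd.DataFrame(rows, columns=["observed", "predicted"])
    if len(frame) == 0:
        raise ValueError("need at least one row")
    frame["delta"] = frame["predicted"] - frame["observed"]
    return PredictionErrorTable(
        rows=frame,
        mean_signed_error=float(frame["delta"].mean()),
        mean_abs_error=float(frame["delta"].abs().mean()),
        max_abs_error=float(frame["delta"].abs().max()),
    )
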