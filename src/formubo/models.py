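"""Tree-ensemble and linear surrogates with fixed hyperparameters.

Two tree modes are provided:

* ``randomized_split_ensemble`` — extremely randomized trees: every tree sees
  the full sample (no bootstrap), every split considers all features with one
  random threshold each and keeps the best by variance reduction; prediction
  is the mean over trees.  Defaults n_estimators=30, max_depth=20.
* ``gradient_boosted`` — stagewise depth-limited trees on residuals with
  shrinkage (XGBoost), defaults depth 3, 100 rounds, learning rate 0.1,
  L2 leaf penalty 1.0.

Hyperparameters are deliberately not tuned: the workflow improves models by
adding data and pruning features, not by hyperparameter search.  All fits are
seeded and refitting with the same seed reproduces predictions bit-identically.
"""

from __future__ import annotations

import json
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor

__all__ = [
    "TreeEnsembleSpec",
    "LinearModelSpec",
    "FittedModel",
    "fit_model",
    "select_model",
    "save_model",
    "load_model",
    "model_complexity",
]


@dataclass(frozen=True)
class TreeEnsembleSpec:
    mode: str = "randomized_split_ensemble"
    n_estimators: int = 30
    max_depth: int = 20
    learning_rate: float = 0.1
    boosting_rounds: int = 100
    min_samples_split: int = 2
    reg_lambda: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("randomized_split_ensemble", "gradient_boosted"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_estimators <= 0 or self.max_depth <= 0:
            raise ValueError("config error: n_estimators and max_depth must be positive")
        if self.boosting_rounds < 0:
            raise ValueError("config error: boosting_rounds must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("config error: learning_rate must be positive")

    @classmethod
    def extra_trees(cls, seed: int = 0, **kw) -> "TreeEnsembleSpec":
        return cls(mode="randomized_split_ensemble", seed=seed, **kw)

    @classmethod
    def gradient_boosted(cls, seed: int = 0, max_depth: int = 3, **kw) -> "TreeEnsembleSpec":
        return cls(mode="gradient_boosted", max_depth=max_depth, seed=seed, **kw)

    @property
    def label(self) -> str:
        return "Extra trees" if self.mode == "randomized_split_ensemble" else "Gradient boosting"

    @property
    def hyperparameters(self) -> dict:
        if self.mode == "randomized_split_ensemble":
            return {"n_estimators": self.n_estimators, "max_depth": self.max_depth}
        return {
            "boosting_rounds": self.boosting_rounds,
            "max_depth": self.max_depth,
            "learning_rate": self.learning_rate,
            "reg_lambda": self.reg_lambda,
        }


@dataclass(frozen=True)
class LinearModelSpec:
    """Ordinary least squares, no regularization."""

    intercept: bool = True

    @property
    def label(self) -> str:
        return "Linear"

    @property
    def hyperparameters(self) -> dict:
        return {"intercept": self.intercept}


def model_complexity(spec) -> int:
    """Tie-break order for model selection: linear < randomized ensemble < boosted."""
    if isinstance(spec, LinearModelSpec):
        return 0
    if isinstance(spec, TreeEnsembleSpec):
        return 1 if spec.mode == "randomized_split_ensemble" else 2
    return 3


class FittedModel:
    """A fitted surrogate: deterministic ``predict`` over named features.

    ``predict`` accepts an ndarray with columns in ``feature_names`` order or
    a DataFrame (columns looked up by name).
    """

    def __init__(self, spec, feature_names: Sequence[str], _predict, _predict_per_tree=None,
                 _payload=None):
        self.spec = spec
        self.feature_names = list(feature_names)
        self._predict = _predict
        self._predict_per_tree = _predict_per_tree
        self._payload = _payload  # serialization hook

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        return X

    def predict(self, X) -> np.ndarray:
        return self._predict(self._matrix(X))

    def predict_std(self, X) -> np.ndarray:
        """Across-tree prediction sd — an uncertainty *proxy* for ensembles
        (tree surrogates have no calibrated posterior)."""
        if self._predict_per_tree is None:
            raise ValueError("per-tree predictions unavailable for this model type")
        per_tree = self._predict_per_tree(self._matrix(X))
        return per_tree.std(axis=0)


def _fit_linear(spec: LinearModelSpec, X: np.ndarray, y: np.ndarray,
                feature_names: Sequence[str]) -> FittedModel:
    A = np.hstack([X, np.ones((len(X), 1))]) if spec.intercept else X
    coef_full, *_ = np.linalg.lstsq(A, y, rcond=None)
    if spec.intercept:
        coef, intercept = coef_full[:-1], float(coef_full[-1])
    else:
        coef, intercept = coef_full, 0.0
    payload = {"type": "linear", "coef": coef.tolist(), "intercept": intercept}
    return FittedModel(spec, feature_names,
                       _predict=lambda M: M @ coef + intercept, _payload=payload)


def _fit_extra_trees(spec: TreeEnsembleSpec, X, y, feature_names, seed) -> FittedModel:
    est = ExtraTreesRegressor(
        n_estimators=spec.n_estimators,
        max_depth=spec.max_depth,
        min_samples_split=spec.min_samples_split,
        max_features=None,  # consider all features at every split
        bootstrap=False,    # full sample per tree
        random_state=int(seed),
    )
    est.fit(X, y)

    def per_tree(M):
        return np.array([t.predict(M) for t in est.estimators_])

    payload = {"type": "extra_trees", "trees": [_tree_arrays(t) for t in est.estimators_]}
    return FittedModel(spec, feature_names, _predict=est.predict,
                       _predict_per_tree=per_tree, _payload=payload)


def _fit_boosted(spec: TreeEnsembleSpec, X, y, feature_names, seed) -> FittedModel:
    if spec.boosting_rounds == 0:
        mean = float(np.mean(y))
        payload = {"type": "constant", "value": mean}
        return FittedModel(spec, feature_names,
                           _predict=lambda M: np.full(len(M), mean), _payload=payload)
    import xgboost as xgb

    est = xgb.XGBRegressor(
        n_estimators=spec.boosting_rounds,
        max_depth=spec.max_depth,
        learning_rate=spec.learning_rate,
        reg_lambda=spec.reg_lambda,
        base_score=float(np.mean(y)),
        random_state=int(seed),
        n_jobs=1,
        tree_method="exact",
        verbosity=0,
    )
    est.fit(X, y)
    raw = est.get_booster().save_raw(raw_format="json").decode("utf-8")
    payload = {"type": "xgboost", "booster_json": raw}
    return FittedModel(spec, feature_names, _predict=est.predict, _payload=payload)


def fit_model(spec, X, y, feature_names: Sequence[str] | None = None,
              seed: int | None = None) -> FittedModel:
    """Fit a surrogate given its spec.  ``seed`` overrides ``spec.seed``."""
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns) if feature_names is None else list(feature_names)
        X = X[feature_names].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    if len(X) < 2:
        raise ValueError("need at least 2 rows to fit a model")
    if isinstance(spec, LinearModelSpec):
        return _fit_linear(spec, X, y, feature_names)
    if isinstance(spec, TreeEnsembleSpec):
        use_seed = spec.seed if seed is None else seed
        if spec.mode == "randomized_split_ensemble":
            return _fit_extra_trees(spec, X, y, feature_names, use_seed)
        return _fit_boosted(spec, X, y, feature_names, use_seed)
    raise TypeError(f"unknown model spec {type(spec).__name__}")


def select_model(candidates: Sequence, dataset, cv=None, seed: int = 0,
                 feature_names: Sequence[str] | None = None):
    """k-fold-CV model selection over candidate specs with identical folds.

    Returns ``(best_spec, metrics_by_label)`` where the winner has the lowest
    mean CV RMSE; ties break toward lower model complexity, then input order.
    """
    from .evaluation import CVConfig, kfold_cv

    if not candidates:
        raise ValueError("need at least one candidate spec")
    cv = cv or CVConfig()
    results = []
    errors = []
    for i, spec in enumerate(candidates):
        try:
            m = kfold_cv(spec, dataset, k=cv.k, seed=seed, feature_names=feature_names)
            results.append((m.rmse_mean, model_complexity(spec), i, spec, m))
        except Exception as exc:  # noqa: BLE001 — selection tolerates individual failures
            errors.append(f"{spec!r}: {exc}")
    if not results:
        raise RuntimeError("cross-validation failed for every candidate: " + "; ".join(errors))
    results.sort(key=lambda t: t[:3])
    best = results[0]
    metrics = {f"{t[3].label}#{t[2]}": t[4] for t in results}
    return best[3], metrics


# ---------------------------------------------------------------------------
# JSON save/load.  Trees are serialized as explicit node arrays so a saved
# model is portable and reloads into a pure-numpy predictor.
# ---------------------------------------------------------------------------

def _tree_arrays(tree) -> dict:
    t = tree.tree_
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "value": t.value.ravel().tolist(),
    }


def _predict_tree_arrays(tree: dict, M: np.ndarray) -> np.ndarray:
    left = np.asarray(tree["children_left"])
    right = np.asarray(tree["children_right"])
    feat = np.asarray(tree["feature"])
    thr = np.asarray(tree["threshold"])
    val = np.asarray(tree["value"])
    node = np.zeros(len(M), dtype=np.int64)
    active = feat[node] >= 0
    while active.any():
        f = feat[node[active]]
        go_left = M[active, f] <= thr[node[active]]
        nxt = np.where(go_left, left[node[active]], right[node[active]])
        node[active] = nxt
        active = feat[node] >= 0
    return val[node]


def save_model(model: FittedModel, path: str | Path) -> None:
    if model._payload is None:
        raise ValueError("model is not serializable")
    doc = {
        "feature_names": model.feature_names,
        "spec": {"class": type(model.spec).__name__, **model.spec.__dict__},
        "model": model._payload,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> FittedModel:
    doc = json.loads(Path(path).read_text())
    spec_doc = dict(doc["spec"])
    cls_name = spec_doc.pop("class")
    spec = LinearModelSpec(**spec_doc) if cls_name == "LinearModelSpec" else TreeEnsembleSpec(**spec_doc)
    names = doc["feature_names"]
    payload = doc["model"]
    kind = payload["type"]
    if kind == "linear":
        coef = np.asarray(payload["coef"], dtype=float)
        intercept = float(payload["intercept"])
        return FittedModel(spec, names, _predict=lambda M: M @ coef + intercept,
                           _payload=payload)
    if kind == "constant":
        v = float(payload["value"])
        return FittedModel(spec, names, _predict=lambda M: np.full(len(M), v),
                           _payload=payload)
    if kind == "extra_trees":
        trees = payload["trees"]

        def predict(M):
            return np.mean([_predict_tree_arrays(t, M) for t in trees], axis=0)

        def per_tree(M):
            return np.array([_predict_tree_arrays(t, M) for t in trees])

        return FittedModel(spec, names, _predict=predict, _predict_per_tree=per_tree,
                           _payload=payload)
    if kind == "xgboost":
        import xgboost as xgb

        booster = xgb.Booster()
        booster.load_model(bytearray(payload["booster_json"], "utf-8"))

        def predict(M):
            return booster.predict(xgb.DMatrix(np.asarray(M, dtype=float)))

        return FittedModel(spec, names, _predict=predict, _payload=payload)
    raise ValueError(f"unknown serialized model type {kind!r}")
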