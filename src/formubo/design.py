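"""Formulation design spaces and screening datasets.

A :class:`DesignSpace` names the variables of a formulation screen — excipient
concentrations, process covariates such as the starting titer, and derived
features (sums of other features, e.g. total rHSA = residual + spiked rHSA) —
together with their units and bounds.  A :class:`Dataset` holds one measured
response per observation (row), with replicate bookkeeping, and round-trips
losslessly through CSV.

Units are metadata only: the screen may mix mg/mL and % w/v and no conversion
is attempted.  Replicates are stored as separate observations, never averaged,
because each measured data point carries its own assay error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "LinearConstraint",
    "DesignSpace",
    "ResponseSpec",
    "Dataset",
    "load_dataset",
    "save_dataset",
    "scale_to_unit",
    "add_derived_feature",
]

_ROLES = ("excipient", "covariate", "derived")


@dataclass(frozen=True)
class FeatureSpec:
    """One named formulation variable with unit, bounds and role.

    ``derived`` features are computed from ``parents`` (by summation; see
    :func:`add_derived_feature`) rather than measured directly.
    """

    name: str
    lower: float
    upper: float
    unit: str = ""
    role: str = "excipient"
    parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("feature name must be non-empty")
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError(f"{self.name}: bounds must be finite")
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: require lower < upper, got [{self.lower}, {self.upper}]")
        if self.role not in _ROLES:
            raise ValueError(f"{self.name}: role must be one of {_ROLES}")
        if self.role == "derived" and len(self.parents) < 1:
            raise ValueError(f"{self.name}: derived feature needs at least one parent")
        if self.role != "derived" and self.parents:
            raise ValueError(f"{self.name}: only derived features may list parents")


@dataclass(frozen=True)
class LinearConstraint:
    """sum_i coeffs[f_i] * x[f_i] <= bound, on original (unscaled) units."""

    coeffs: tuple[tuple[str, float], ...]
    bound: float

    @classmethod
    def from_dict(cls, coeffs: Mapping[str, float], bound: float) -> "LinearConstraint":
        return cls(tuple(sorted(coeffs.items())), float(bound))

    def satisfied(self, values: Mapping[str, float], atol: float = 1e-9) -> bool:
        total = sum(c * float(values[name]) for name, c in self.coeffs)
        return total <= self.bound + atol


class DesignSpace:
    """Ordered collection of :class:`FeatureSpec` plus linear constraints."""

    def __init__(
        self,
        features: Sequence[FeatureSpec],
        constraints: Sequence[LinearConstraint] = (),
    ) -> None:
        names = [f.name for f in features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        by_name = {f.name: f for f in features}
        for f in features:
            for p in f.parents:
                if p not in by_name:
                    raise ValueError(f"derived feature {f.name!r}: unknown parent {p!r}")
        for c in constraints:
            for name, _ in c.coeffs:
                if name not in by_name:
                    raise ValueError(f"constraint references unknown feature {name!r}")
        self.features: tuple[FeatureSpec, ...] = tuple(features)
        self.constraints: tuple[LinearConstraint, ...] = tuple(constraints)
        self._by_name = by_name

    # -- introspection -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def base_names(self) -> list[str]:
        """Names of non-derived features (the free variables of the screen)."""
        return [f.name for f in self.features if f.role != "derived"]

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> FeatureSpec:
        return self._by_name[name]

    def bounds(self, names: Sequence[str] | None = None) -> np.ndarray:
        """(d, 2) array of [lower, upper] for the requested features."""
        names = self.names if names is None else list(names)
        return np.array([[self._by_name[n].lower, self._by_name[n].upper] for n in names])

    def subspace(self, names: Sequence[str]) -> "DesignSpace":
        """Restriction to the named features; constraints touching dropped
        features are dropped with them."""
        keep = set(names)
        feats = [f for f in self.features if f.name in keep]
        cons = [c for c in self.constraints if all(n in keep for n, _ in c.coeffs)]
        return DesignSpace(feats, cons)

    def with_feature(self, spec: FeatureSpec) -> "DesignSpace":
        if spec.name in self._by_name:
            raise ValueError(f"feature {spec.name!r} already exists")
        return DesignSpace((*self.features, spec), self.constraints)

    def satisfies_constraints(self, values: Mapping[str, float]) -> bool:
        return all(c.satisfied(values) for c in self.constraints)

    # -- unit scaling --------------------------------------------------
    def to_unit(self, X: np.ndarray, names: Sequence[str] | None = None) -> np.ndarray:
        """Affine map of each column onto [0, 1] via its bounds."""
        b = self.bounds(names)
        X = np.asarray(X, dtype=float)
        return (X - b[:, 0]) / (b[:, 1] - b[:, 0])

    def from_unit(self, U: np.ndarray, names: Sequence[str] | None = None) -> np.ndarray:
        b = self.bounds(names)
        U = np.asarray(U, dtype=float)
        return b[:, 0] + U * (b[:, 1] - b[:, 0])

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "features": [
                {
                    "name": f.name,
                    "unit": f.unit,
                    "lower": f.lower,
                    "upper": f.upper,
                    "role": f.role,
                    "parents": list(f.parents),
                }
                for f in self.features
            ],
            "constraints": [
                {"coeffs": dict(c.coeffs), "bound": c.bound} for c in self.constraints
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DesignSpace":
        payload = json.loads(text)
        feats = [
            FeatureSpec(
                name=f["name"],
                lower=float(f["lower"]),
                upper=float(f["upper"]),
                unit=f.get("unit", ""),
                role=f.get("role", "excipient"),
                parents=tuple(f.get("parents", ())),
            )
            for f in payload["features"]
        ]
        cons = [
            LinearConstraint.from_dict(c["coeffs"], c["bound"])
            for c in payload.get("constraints", ())
        ]
        return cls(feats, cons)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "DesignSpace":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class ResponseSpec:
    """The measured response of a screen and its optimization direction.

    ``direction`` is configured, never inferred: ``minimize`` for a titer loss,
    ``maximize`` for a glass-transition temperature.
    """

    name: str
    unit: str = ""
    direction: str = "minimize"

    def __post_init__(self) -> None:
        if self.direction not in ("minimize", "maximize"):
            raise ValueError("direction must be 'minimize' or 'maximize'")


_META_COLS = ("replicate_id", "source_tag")


class Dataset:
    """A formulation screening dataset: design space + observations + response.

    Internally a pandas DataFrame with one column per feature, the response
    column, and optional ``replicate_id`` / ``source_tag`` metadata columns.
    """

    def __init__(self, design_space: DesignSpace, frame: pd.DataFrame, response: ResponseSpec):
        missing = [n for n in design_space.names if n not in frame.columns]
        if missing:
            raise ValueError(f"frame lacks feature columns: {missing}")
        if response.name not in frame.columns:
            raise ValueError(f"frame lacks response column {response.name!r}")
        frame = frame.copy()
        if "replicate_id" not in frame.columns:
            frame["replicate_id"] = 1
        if "source_tag" not in frame.columns:
            frame["source_tag"] = "historical"
        frame["replicate_id"] = frame["replicate_id"].astype(int)
        if (frame["replicate_id"] < 1).any():
            raise ValueError("replicate_id must be >= 1")
        self.design_space = design_space
        self.response = response
        cols = design_space.names + [response.name] + list(_META_COLS)
        self.frame = frame[cols].reset_index(drop=True)

    # -- views ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def X(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = self.design_space.names if names is None else list(names)
        return self.frame[names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.response.name].to_numpy(dtype=float)

    def validate_bounds(self, strict: bool = False) -> list[str]:
        """Check every non-derived value against its bounds.

        Historical data may predate the bounds definition, so the default is
        warn-and-keep; ``strict=True`` raises instead.
        """
        problems: list[str] = []
        for f in self.design_space.features:
            if f.role == "derived":
                continue
            col = self.frame[f.name].to_numpy(dtype=float)
            bad = np.flatnonzero((col < f.lower) | (col > f.upper))
            for i in bad:
                problems.append(f"row {i}: {f.name}={col[i]} outside [{f.lower}, {f.upper}]")
        if problems:
            if strict:
                raise ValueError("out-of-bounds values: " + "; ".join(problems))
            warnings.warn(f"{len(problems)} out-of-bounds value(s) kept", stacklevel=2)
        return problems

    def with_rows(self, rows: pd.DataFrame) -> "Dataset":
        """New Dataset with extra observation rows appended."""
        frame = pd.concat([self.frame, rows], ignore_index=True)
        return Dataset(self.design_space, frame, self.response)

    def subset_features(self, names: Sequence[str]) -> "Dataset":
        """Restrict to a feature subset (the response and metadata survive)."""
        space = self.design_space.subspace(names)
        cols = list(space.names) + [self.response.name] + list(_META_COLS)
        return Dataset(space, self.frame[cols], self.response)

    def save_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.12g")


def load_dataset(
    path: str | Path,
    design_space: DesignSpace,
    response_name: str,
    response_unit: str = "",
    direction: str = "minimize",
    strict_bounds: bool = False,
) -> Dataset:
    """Read a screening CSV into a :class:`Dataset`.

    The CSV must have a header with one column per non-derived feature plus the
    response column.  Derived-feature columns are recomputed from their parents
    when absent.  Unknown columns are ignored with a warning; a missing
    response column or a non-numeric cell is an error.
    """
    frame = pd.read_csv(path)
    if response_name not in frame.columns:
        raise ValueError(f"schema error: response column {response_name!r} missing from {path}")
    known = set(design_space.names) | {response_name} | set(_META_COLS)
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        warnings.warn(f"ignoring unknown column(s) {unknown}", stacklevel=2)
        frame = frame.drop(columns=unknown)
    missing_base = [n for n in design_space.base_names if n not in frame.columns]
    if missing_base:
        raise ValueError(f"schema error: missing feature column(s) {missing_base}")
    for col in frame.columns:
        if col in _META_COLS:
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise ValueError(
                f"parse error: non-numeric value in column {col!r}, row {int(bad[0])}"
            )
        if coerced.isna().any():
            raise ValueError(f"parse error: missing value in column {col!r}")
        frame[col] = coerced
    for f in design_space.features:
        if f.role == "derived" and f.name not in frame.columns:
            frame[f.name] = frame[list(f.parents)].sum(axis=1)
    ds = Dataset(design_space, frame, ResponseSpec(response_name, response_unit, direction))
    ds.validate_bounds(strict=strict_bounds)
    return ds


def save_dataset(dataset: Dataset, path: str | Path) -> None:
    dataset.save_csv(path)


def scale_to_unit(dataset: Dataset, strict: bool = False):
    """Unit-scale the dataset's feature matrix.

    Returns ``(U, inverse)`` where ``U`` has every column mapped affinely onto
    [0, 1] by its bounds and ``inverse(U)`` restores original units.  One GP
    length-scale is only meaningful across mg/mL, % w/v and log10 PFU/mL
    columns after this map.
    """
    X = dataset.X()
    U = dataset.design_space.to_unit(X)
    if strict and ((U < -1e-12) | (U > 1 + 1e-12)).any():
        raise ValueError("range error: value outside feature bounds in strict mode")

    def inverse(u: np.ndarray) -> np.ndarray:
        return dataset.design_space.from_unit(u)

    return U, inverse


def add_derived_feature(
    dataset: Dataset,
    spec: FeatureSpec,
    combiner: Callable[[pd.DataFrame], pd.Series] | str = "sum",
) -> Dataset:
    """Append a derived feature computed from its parents (summation).

    Mirrors folding correlated process/excipient variables into one feature,
    e.g. total rHSA = residual rHSA + spiked rHSA.
    """
    if spec.role != "derived":
        raise ValueError("spec.role must be 'derived'")
    if spec.name in dataset.design_space:
        raise ValueError(f"name collision: {spec.name!r} already in design space")
    if combiner not in ("sum",) and not callable(combiner):
        raise ValueError("only summation combiners are supported")
    space = dataset.design_space.with_feature(spec)
    frame = dataset.frame.copy()
    parents = list(spec.parents)
    if callable(combiner):
        frame[spec.name] = combiner(frame[parents])
    else:
        frame[spec.name] = frame[parents].sum(axis=1)
    return Dataset(space, frame, dataset.response)
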