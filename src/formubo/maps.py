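"""Response-surface maps over two features and optimal-zone extraction.

A fitted surrogate is evaluated on a rectangular grid over two chosen
features (all other features pinned at fixed context values, mid-bounds by
default).  A zone collects the grid cells whose prediction is at or below a
threshold (for minimization) — the heatmap region a team would adopt as its
operating window — reported both as the cell set and as a bounding box.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import DesignSpace

__all__ = ["GridMap", "Zone", "grid_predict", "extract_zone"]


@dataclass
class GridMap:
    feature_x: str
    feature_y: str
    x_values: np.ndarray
    y_values: np.ndarray
    matrix: np.ndarray  # row = y index, column = x index
    fixed_context: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.y_values, columns=self.x_values)

    def save(self, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, float_format="%.12g")
        if sidecar_path is not None:
            Path(sidecar_path).write_text(json.dumps({
                "feature_x": self.feature_x, "feature_y": self.feature_y,
                "x_values": self.x_values.tolist(), "y_values": self.y_values.tolist(),
                "fixed_context": self.fixed_context,
            }, indent=2))


@dataclass
class Zone:
    threshold: float
    cells: set  # (i, j) = (y index, x index)
    x_range: tuple[float, float] | None
    y_range: tuple[float, float] | None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_json(self) -> str:
        return json.dumps({
            "threshold": self.threshold,
            "n_cells": self.n_cells,
            "cells": sorted(self.cells),
            "x_range": self.x_range,
            "y_range": self.y_range,
        })


def grid_predict(model, space: DesignSpace, feature_x: str, feature_y: str,
                 fixed_context: Mapping[str, float] | None = None,
                 resolution: int = 50) -> GridMap:
    """resolution×resolution surrogate predictions over two features' bounds.

    ``fixed_context`` must cover every other model feature; missing entries
    default to the mid-point of the feature's bounds.
    """
    names = model.feature_names
    for f in (feature_x, feature_y):
        if f not in names:
            raise ValueError(f"feature {f!r} is not a model input")
    context = dict(fixed_context or {})
    for n in names:
        if n in (feature_x, feature_y):
            continue
        if n not in context:
            if n not in space:
                raise ValueError(f"missing context feature {n!r}")
            fs = space[n]
            context[n] = 0.5 * (fs.lower + fs.upper)
    bx = space[feature_x]
    by = space[feature_y]
    xs = np.linspace(bx.lower, bx.upper, resolution)
    ys = np.linspace(by.lower, by.upper, resolution)
    XX, YY = np.meshgrid(xs, ys)
    frame = pd.DataFrame({feature_x: XX.ravel(), feature_y: YY.ravel()})
    for n, v in context.items():
        frame[n] = v
    preds = model.predict(frame[names])
    return GridMap(feature_x=feature_x, feature_y=feature_y, x_values=xs,
                   y_values=ys, matrix=np.asarray(preds).reshape(resolution, resolution),
                   fixed_context=context)


def extract_zone(gmap: GridMap, threshold: float | None = None,
                 direction: str = "minimize") -> Zone:
    """Cells with prediction ≤ threshold (minimize) or ≥ threshold (maximize).

    Default threshold is the 20th percentile of grid predictions (80th for
    maximization).  An empty zone is allowed.  Monotone in the threshold:
    relaxing it can only grow the zone.
    """
    if threshold is None:
        q = 20 if direction == "minimize" else 80
        threshold = float(np.percentile(gmap.matrix, q))
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if direction == "minimize":
        mask = gmap.matrix <= threshold
    else:
        mask = gmap.matrix >= threshold
    idx = np.argwhere(mask)
    cells = {(int(i), int(j)) for i, j in idx}
    if cells:
        x_range = (float(gmap.x_values[idx[:, 1].min()]), float(gmap.x_values[idx[:, 1].max()]))
        y_range = (float(gmap.y_values[idx[:, 0].min()]), float(gmap.y_values[idx[:, 0].max()]))
    else:
        x_range = y_range = None
    return Zone(threshold=float(threshold), cells=cells, x_range=x_range, y_range=y_range)
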