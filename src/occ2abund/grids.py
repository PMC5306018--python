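"""Gridded containers and raster I/O.

A landscape is a regular grid of square cells (1 km by default) with its
origin at the lower-left corner. Cell ``(ix, iy)`` covers the half-open box
``[x0 + ix*s, x0 + (ix+1)*s) x [y0 + iy*s, y0 + (iy+1)*s)``; arrays are stored
``(ny, nx)`` with row 0 the southernmost. Stacks are written as multi-page
float32 TIFF rasters with a JSON grid sidecar and a CSV layer manifest
(name, kind, priority).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid (origin at lower-left)."""

    nx: int
    ny: int
    cell_size: float = 1000.0
    x0: float = 0.0
    y0: float = 0.0

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def cell_index(self, x, y):
        """Map coordinates to (ix, iy) under the half-open cell convention."""
        ix = np.floor((np.asarray(x, dtype=float) - self.x0) / self.cell_size).astype(int)
        iy = np.floor((np.asarray(y, dtype=float) - self.y0) / self.cell_size).astype(int)
        return ix, iy

    def contains(self, x, y):
        ix, iy = self.cell_index(x, y)
        return (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)

    def cell_centers(self):
        """Easting/northing of every cell center, in cell-id order (iy*nx+ix)."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.cell_size
        gx, gy = np.meshgrid(xs, ys)
        return gx.ravel(), gy.ravel()

    def cell_id(self, ix, iy):
        return np.asarray(iy) * self.nx + np.asarray(ix)

    def to_dict(self) -> dict:
        return {"nx": self.nx, "ny": self.ny, "cell_size": self.cell_size,
                "x0": self.x0, "y0": self.y0}

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(nx=int(d["nx"]), ny=int(d["ny"]), cell_size=float(d["cell_size"]),
                   x0=float(d["x0"]), y0=float(d["y0"]))


@dataclass
class CovariateStack:
    """Named raster layers sharing one grid.

    ``kinds[name]`` is ``continuous`` or ``categorical``; categorical layers
    hold integer category codes and never enter correlation pruning.
    ``priority[name]`` ranks importance (1 = most important); it breaks
    collinearity ties during pruning.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)
    priority: dict[str, int] = field(default_factory=dict)

    def add_layer(self, name: str, data: np.ndarray, kind: str = CONTINUOUS,
                  priority: int | None = None) -> None:
        data = np.asarray(data)
        if data.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"layer {name!r} shape {data.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})")
        if kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown layer kind {kind!r}")
        self.layers[name] = data
        self.kinds[name] = kind
        self.priority[name] = len(self.layers) if priority is None else priority

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def continuous_names(self) -> list[str]:
        return [n for n in self.layers if self.kinds[n] == CONTINUOUS]

    def categorical_names(self) -> list[str]:
        return [n for n in self.layers if self.kinds[n] == CATEGORICAL]

    def subset(self, names) -> "CovariateStack":
        out = CovariateStack(self.grid)
        for n in names:
            out.add_layer(n, self.layers[n], self.kinds[n], self.priority[n])
        return out

    def as_table(self) -> pd.DataFrame:
        """One row per cell (cell-id order) with coordinates and all layers."""
        x, y = self.grid.cell_centers()
        data = {"cell_id": np.arange(self.grid.n_cells), "easting": x, "northing": y}
        for n, arr in self.layers.items():
            data[n] = arr.ravel()
        return pd.DataFrame(data)


def write_stack(path, stack: CovariateStack) -> None:
    """Write a stack as multi-page float32 TIFF + manifest CSV + grid JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.stack([np.asarray(stack.layers[n], dtype=np.float32)
                      for n in stack.names])
    tifffile.imwrite(path, pages, photometric="minisblack")
    manifest = pd.DataFrame({
        "name": stack.names,
        "kind": [stack.kinds[n] for n in stack.names],
        "priority": [stack.priority[n] for n in stack.names],
    })
    manifest.to_csv(path.with_suffix(".manifest.csv"), index=False)
    path.with_suffix(".grid.json").write_text(json.dumps(stack.grid.to_dict()))


def read_stack(path) -> CovariateStack:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    manifest = pd.read_csv(path.with_suffix(".manifest.csv"))
    grid = GridSpec.from_dict(json.loads(path.with_suffix(".grid.json").read_text()))
    stack = CovariateStack(grid)
    for page, row in zip(pages, manifest.itertuples()):
        data = page.astype(float)
        if row.kind == CATEGORICAL:
            data = np.round(page).astype(int)
        stack.add_layer(row.name, data, row.kind, int(row.priority))
    return stack


def write_map(path, grid: GridSpec, data: np.ndarray) -> None:
    """Write a single-band raster (float32) with its grid sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32),
                     photometric="minisblack")
    path.with_suffix(".grid.json").write_text(json.dumps(grid.to_dict()))


def read_map(path) -> tuple[GridSpec, np.ndarray]:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    grid = GridSpec.from_dict(json.loads(path.with_suffix(".grid.json").read_text()))
    return grid, data
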