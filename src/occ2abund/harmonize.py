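"""Harmonize heterogeneous abundance records to hectares covered per km².

Abundance is expressed as hectares covered by a species per square kilometer,
numerically equal to percent cover of the 1-km cell. Two survey dialects are
supported:

* ``patch_source`` — percent cover of the species *within a woodland patch*;
  converted by multiplying by the proportion of the 1-km cell that is woodland.
* ``plot_source`` — separate percent-cover estimates from linear-feature plots
  (hedgerows etc.) and from ordinary (nonlinear) plots; combined as
  ``linear% * linear_fraction + nonlinear% * (1 - linear_fraction)``.

The module also derives the woodland-edge cover layer: edge is any woodland
within a fixed distance (50 m default) of nonwoodland, aggregated to the
fraction of each 1-km cell that is edge.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

PATCH_SOURCE = "patch_source"
PLOT_SOURCE = "plot_source"


def _check_range(name, value, lo, hi):
    v = np.asarray(value, dtype=float)
    if np.any(v < lo) or np.any(v > hi):
        raise ValueError(f"{name} must lie in [{lo}, {hi}]")
    return v


def rescale_patch_cover(patch_percent, woodland_fraction):
    """Within-patch percent cover -> ha/km², via the cell's woodland fraction."""
    p = _check_range("patch_percent", patch_percent, 0, 100)
    w = _check_range("woodland_fraction", woodland_fraction, 0, 1)
    return np.clip(p * w, 0.0, 100.0)


def weight_linear_features(linear_percent, linear_fraction, nonlinear_percent):
    """Combine linear-feature and ordinary plot cover into ha/km².

    A convex combination weighted by the fraction of the cell occupied by
    linear features, so the result always lies between the two plot values.
    """
    lp = _check_range("linear_percent", linear_percent, 0, 100)
    lf = _check_range("linear_fraction", linear_fraction, 0, 1)
    np_ = _check_range("nonlinear_percent", nonlinear_percent, 0, 100)
    return np.clip(lp * lf + np_ * (1.0 - lf), 0.0, 100.0)


def merge_sources(patch_records: pd.DataFrame, plot_records: pd.DataFrame,
                  woodland_fraction: np.ndarray,
                  linear_fraction: np.ndarray | None = None) -> pd.DataFrame:
    """Convert both raw dialects into one harmonized record table.

    ``patch_records`` columns: species, cell_id, patch_percent.
    ``plot_records`` columns: species, cell_id, linear_percent,
    nonlinear_percent and optionally linear_fraction (otherwise looked up in
    the ``linear_fraction`` layer).

    Returns rows (species, cell_id, cover, source). Duplicate (species, cell)
    records are kept as independent rows. Records in cells lacking a required
    layer value are dropped (with a warning reporting the count).
    """
    wf = np.asarray(woodland_fraction, dtype=float).ravel()
    out = []
    n_dropped = 0
    if len(patch_records):
        cells = patch_records["cell_id"].to_numpy(dtype=int)
        valid = (cells >= 0) & (cells < wf.size)
        valid &= np.isfinite(wf[np.clip(cells, 0, wf.size - 1)])
        n_dropped += int((~valid).sum())
        kept = patch_records.loc[valid]
        cover = rescale_patch_cover(kept["patch_percent"].to_numpy(float),
                                    wf[kept["cell_id"].to_numpy(int)])
        out.append(pd.DataFrame({"species": kept["species"].to_numpy(),
                                 "cell_id": kept["cell_id"].to_numpy(int),
                                 "cover": cover, "source": PATCH_SOURCE}))
    if len(plot_records):
        cells = plot_records["cell_id"].to_numpy(dtype=int)
        if "linear_fraction" in plot_records.columns:
            lf_vals = plot_records["linear_fraction"].to_numpy(float)
            valid = np.isfinite(lf_vals)
        else:
            if linear_fraction is None:
                raise ValueError("plot records lack linear_fraction and no layer given")
            lf = np.asarray(linear_fraction, dtype=float).ravel()
            valid = (cells >= 0) & (cells < lf.size)
            lf_vals = np.where(valid, lf[np.clip(cells, 0, lf.size - 1)], np.nan)
            valid &= np.isfinite(lf_vals)
        n_dropped += int((~valid).sum())
        kept = plot_records.loc[valid]
        cover = weight_linear_features(kept["linear_percent"].to_numpy(float),
                                       lf_vals[valid],
                                       kept["nonlinear_percent"].to_numpy(float))
        out.append(pd.DataFrame({"species": kept["species"].to_numpy(),
                                 "cell_id": kept["cell_id"].to_numpy(int),
                                 "cover": cover, "source": PLOT_SOURCE}))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} records lacking layer values")
    if not out:
        return pd.DataFrame(columns=["species", "cell_id", "cover", "source"])
    return pd.concat(out, ignore_index=True)


def compute_edge_cover(woodland_mask: np.ndarray, distance: float = 50.0,
                       fine_cellsize: float = 10.0,
                       out_cellsize: float = 1000.0) -> np.ndarray:
    """Fraction of each coarse cell that is woodland edge.

    Edge = woodland fine cells whose center-to-center Euclidean distance to
    the nearest nonwoodland cell is <= ``distance`` (meters). The fine binary
    mask is aggregated to coarse cells of ``out_cellsize``; partial coarse
    cells at the margin use their actual fine-cell count.
    """
    mask = np.asarray(woodland_mask, dtype=bool)
    if fine_cellsize > distance:
        raise ValueError("fine grid resolution must not exceed the edge distance")
    if mask.all() or not mask.any():
        # no woodland/nonwoodland boundary exists anywhere
        edge = np.zeros_like(mask, dtype=bool)
    else:
        # distance from each woodland cell to the nearest nonwoodland cell
        dist = ndimage.distance_transform_edt(mask) * fine_cellsize
        edge = mask & (dist <= distance)
    factor = int(round(out_cellsize / fine_cellsize))
    ny, nx = mask.shape
    cy = -(-ny // factor)
    cx = -(-nx // factor)
    out = np.zeros((cy, cx), dtype=float)
    for iy in range(cy):
        for ix in range(cx):
            block = edge[iy * factor:(iy + 1) * factor, ix * factor:(ix + 1) * factor]
            out[iy, ix] = block.mean()
    return out
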