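"""Covariate assembly: collinearity pruning and per-site extraction.

Environmental predictor sets are screened so that no retained pair of
continuous layers has |Pearson r| above a threshold (0.7 by default); within
each violating pair the lower-priority layer is dropped, resolving the most
collinear pair first. Categorical layers pass through untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import CATEGORICAL, CONTINUOUS, CovariateStack


@dataclass
class PruneReport:
    """Record of each resolved collinear pair (for audit export)."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["layer_a", "layer_b", "r", "removed"])


def _pairwise_r(stack: CovariateStack, names: list[str]) -> dict[tuple[str, str], float]:
    """|-finite-masked Pearson r for every continuous pair."""
    cols = {}
    for n in names:
        cols[n] = np.asarray(stack.layers[n], dtype=float).ravel()
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ok = np.isfinite(cols[a]) & np.isfinite(cols[b])
            va, vb = cols[a][ok], cols[b][ok]
            r = np.corrcoef(va, vb)[0, 1]
            out[(a, b)] = float(r)
    return out


def prune_correlated(stack: CovariateStack, threshold: float = 0.7,
                     report: PruneReport | None = None) -> CovariateStack:
    """Drop continuous layers until all pairwise |r| <= threshold (strict rule:
    only pairs with |r| strictly above the threshold are violations).

    Greedy by descending |r|: the most collinear violating pair is resolved
    first by removing its lower-priority member. Zero-variance layers are
    excluded from the correlation computation (warned) but retained.
    Idempotent: pruning a pruned stack changes nothing.
    """
    cont = stack.continuous_names()
    if not cont:
        raise ValueError("stack has no continuous layers")
    usable = []
    for n in cont:
        v = np.asarray(stack.layers[n], dtype=float).ravel()
        v = v[np.isfinite(v)]
        if v.size == 0 or np.ptp(v) == 0:
            warnings.warn(f"layer {n!r} is constant; excluded from correlation pruning")
        else:
            usable.append(n)

    corr = _pairwise_r(stack, usable)
    alive = set(usable)
    # resolve worst pair first, then re-scan among survivors; the strict
    # "higher than" rule gets a tiny tolerance so float noise cannot flip
    # a pair sitting exactly on the threshold
    for (a, b), r in sorted(corr.items(), key=lambda kv: -abs(kv[1])):
        if abs(r) <= threshold + 1e-9:
            break
        if a not in alive or b not in alive:
            continue
        loser = a if stack.priority[a] > stack.priority[b] else b
        alive.remove(loser)
        if report is not None:
            report.rows.append({"layer_a": a, "layer_b": b, "r": r, "removed": loser})

    keep = [n for n in stack.names
            if stack.kinds[n] == CATEGORICAL or n not in usable or n in alive]
    return stack.subset(keep)


def extract_site_covariates(stack: CovariateStack, easting, northing) -> pd.DataFrame:
    """Look up all layers at site coordinates (one row per site).

    Cell assignment follows the half-open convention of the grid: a site on a
    shared edge belongs to the cell whose interval contains it. Categorical
    layers come through as integer category codes.
    """
    x = np.asarray(easting, dtype=float)
    y = np.asarray(northing, dtype=float)
    inside = stack.grid.contains(x, y)
    if not inside.all():
        i = int(np.flatnonzero(~inside)[0])
        raise ValueError(f"site ({x[i]}, {y[i]}) falls outside the grid extent")
    ix, iy = stack.grid.cell_index(x, y)
    data = {"easting": x, "northing": y, "cell_id": stack.grid.cell_id(ix, iy)}
    for n in stack.names:
        vals = stack.layers[n][iy, ix]
        data[n] = vals.astype(int) if stack.kinds[n] == CATEGORICAL else vals
    return pd.DataFrame(data)
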