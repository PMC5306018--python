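"""Stage 2: random-forest regression of abundance on occupancy predictions.

For each focal species, percent-cover abundance (ha covered per km²) is
regressed on the ensemble occupancy predictions of *all* species — so biotic
effects such as competition can be absorbed — plus four tree-cover covariates:
all-tree cover (C_A), woodland-tree cover (C_W), cover from trees outside
woodland (C_O) and woodland-edge cover (C_E):

    Abundance_focal ~ P_focal + P_sp2 + ... + P_spN + C_A + C_W + C_O + C_E

Random forests are used because the abundance data are heavily zero-inflated
and the occupancy–abundance relationship need not follow any parametric form.
Model skill is reported as RMSE and MAE from k-fold cross-validation, with k
chosen to keep an average of five nonzero data points per fold; species with
too few nonzero records are refused rather than fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from . import metrics

COVER_NAMES = ("C_A", "C_W", "C_O", "C_E")

DEFAULT_RF_PARAMS = {"n_estimators": 500, "max_features": 1 / 3}


@dataclass(eq=False)
class AbundanceModel:
    """Fitted per-species abundance forest."""

    focal: str
    covariates: list[str]            # focal P first, others, then cover layers
    forest: RandomForestRegressor
    n_rows: int
    n_nonzero: int
    seed: int
    constant_value: float | None = None  # degenerate all-constant shortcut

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.covariates if c not in features.columns]
        if missing:
            raise ValueError(f"missing covariates: {missing}")
        if self.constant_value is not None:
            return np.full(len(features), self.constant_value)
        pred = self.forest.predict(features[self.covariates].to_numpy())
        return np.clip(pred, 0.0, None)


@dataclass
class CVReport:
    """k-fold cross-validation summary for one species' abundance model.

    ``r_squared`` always travels with ``r_squared_caveat=True``: with heavily
    zero-inflated cover data R² depends on the spread of the response and
    penalizes near-zero predictions at true zeros, so RMSE/MAE are the
    headline skill measures.
    """

    k: int
    fold_rmse: list[float]
    fold_mae: list[float]
    pooled_rmse: float
    pooled_mae: float
    r_squared: float
    r_squared_caveat: bool = True
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fold": np.arange(1, self.k + 1),
                             "rmse": self.fold_rmse, "mae": self.fold_mae})


@dataclass
class FoldRefusal:
    """Too few nonzero records to cross-validate; model not fitted."""

    n_nonzero: int
    reason: str


def assemble_features(occupancy_maps: dict[str, np.ndarray],
                      cover_layers: dict[str, np.ndarray], focal: str,
                      cell_ids: np.ndarray | None = None) -> pd.DataFrame:
    """Build the stage-2 feature table.

    Column order: focal species' occupancy first, remaining species in
    canonical (sorted) name order, then C_A, C_W, C_O, C_E. One row per cell
    (all grid cells, or ``cell_ids`` if given); rows with no-data occupancy
    or cover are excluded and the exclusion count is reported as an attr.
    """
    if focal not in occupancy_maps:
        raise ValueError(f"missing occupancy map for focal species {focal!r}")
    others = sorted(n for n in occupancy_maps if n != focal)
    for c in COVER_NAMES:
        if c not in cover_layers:
            raise ValueError(f"missing cover layer {c}")
    cols = {}
    cols[f"P_{focal}"] = np.asarray(occupancy_maps[focal], dtype=float).ravel()
    for name in others:
        cols[f"P_{name}"] = np.asarray(occupancy_maps[name], dtype=float).ravel()
    for c in COVER_NAMES:
        cols[c] = np.asarray(cover_layers[c], dtype=float).ravel()
    table = pd.DataFrame(cols)
    table.insert(0, "cell_id", np.arange(len(table)))
    if cell_ids is not None:
        table = table.iloc[np.asarray(cell_ids, dtype=int)].reset_index(drop=True)
    ok = np.isfinite(table.drop(columns="cell_id").to_numpy()).all(axis=1)
    out = table.loc[ok].reset_index(drop=True)
    out.attrs["n_excluded_nodata"] = int((~ok).sum())
    return out


def choose_fold_count(n_nonzero: int, per_fold: int = 5, max_k: int = 10,
                      min_nonzero: int = 30) -> int | FoldRefusal:
    """Fold count keeping an average of ``per_fold`` nonzero points per fold.

    >= per_fold*max_k nonzero points -> the full ``max_k`` folds; otherwise
    k = floor(n_nonzero / per_fold), provided at least ``min_nonzero`` points
    exist; below that the species is refused (a value, not an error).
    """
    if n_nonzero >= per_fold * max_k:
        return max_k
    if n_nonzero >= min_nonzero:
        return n_nonzero // per_fold
    return FoldRefusal(n_nonzero=n_nonzero,
                       reason=f"only {n_nonzero} nonzero abundance records "
                              f"(< {min_nonzero}); model not fitted")


def _make_forest(params: dict | None, seed: int) -> RandomForestRegressor:
    p = dict(DEFAULT_RF_PARAMS)
    if params:
        p.update(params)
    return RandomForestRegressor(random_state=seed, **p)


def fit_abundance_rf(features: pd.DataFrame, abundance, focal: str,
                     hyperparameters: dict | None = None,
                     seed: int = 0) -> AbundanceModel:
    """Fit the per-species abundance forest; predictions are clipped >= 0."""
    y = np.asarray(abundance, dtype=float)
    if np.any(y < 0) or np.any(y > 100):
        raise ValueError("abundance must lie in [0, 100] ha/km²")
    covs = [c for c in features.columns if c != "cell_id"]
    x = features[covs].to_numpy()
    if len(y) != len(x):
        raise ValueError("feature/abundance length mismatch")
    n_nonzero = int(np.count_nonzero(y))
    constant = None
    forest = _make_forest(hyperparameters, seed)
    if np.ptp(y) == 0:
        warnings.warn(f"abundance is constant ({y[0]}); degenerate model")
        constant = float(y[0])
    forest.fit(x, y)
    return AbundanceModel(focal=focal, covariates=covs, forest=forest,
                          n_rows=len(y), n_nonzero=n_nonzero, seed=seed,
                          constant_value=constant)


def cross_validate(features: pd.DataFrame, abundance, k: int, focal: str = "",
                   hyperparameters: dict | None = None, seed: int = 0) -> CVReport:
    """Unstratified random k-fold CV; pooled RMSE/MAE over all held-out rows."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(abundance, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    fold_rmse, fold_mae = [], []
    pooled_obs, pooled_pred = [], []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        model = fit_abundance_rf(features.iloc[train_idx], y[train_idx], focal,
                                 hyperparameters, seed=seed + i + 1)
        pred = model.predict(features.iloc[test_idx])
        fold_rmse.append(metrics.rmse(y[test_idx], pred))
        fold_mae.append(metrics.mae(y[test_idx], pred))
        pooled_obs.append(y[test_idx])
        pooled_pred.append(pred)
    obs = np.concatenate(pooled_obs)
    pred = np.concatenate(pooled_pred)
    return CVReport(k=k, fold_rmse=fold_rmse, fold_mae=fold_mae,
                    pooled_rmse=metrics.rmse(obs, pred),
                    pooled_mae=metrics.mae(obs, pred),
                    r_squared=metrics.r_squared(obs, pred),
                    r_squared_caveat=True, seed=seed)


def variable_importance(model: AbundanceModel, features: pd.DataFrame,
                        abundance, n_repeats: int = 5,
                        seed: int = 0) -> pd.DataFrame:
    """Permutation importance of each covariate, descending; ties broken by
    the model's covariate order."""
    x = features[model.covariates]
    y = np.asarray(abundance, dtype=float)
    result = permutation_importance(model.forest, x.to_numpy(), y,
                                    n_repeats=n_repeats, random_state=seed)
    order = {c: i for i, c in enumerate(model.covariates)}
    df = pd.DataFrame({"covariate": model.covariates,
                       "importance": result.importances_mean})
    df["_order"] = df["covariate"].map(order)
    df = df.sort_values(["importance", "_order"], ascending=[False, True])
    return df.drop(columns="_order").reset_index(drop=True)


def predict_abundance_map(model: AbundanceModel,
                          occupancy_maps: dict[str, np.ndarray],
                          cover_layers: dict[str, np.ndarray],
                          zero_cutoff: float | None = None) -> np.ndarray:
    """Gridded abundance prediction (ha/km², >= 0) for the focal species.

    ``zero_cutoff``, if set, coerces predictions below it to exactly zero —
    useful when the forest predicts slightly-above-zero cover at true zeros.
    No-data cells (NaN inputs) propagate as NaN.
    """
    shapes = {m.shape for m in occupancy_maps.values()} | \
             {c.shape for c in cover_layers.values()}
    if len(shapes) != 1:
        raise ValueError(f"grid mismatch among input layers: {shapes}")
    shape = shapes.pop()
    table = assemble_features(occupancy_maps, cover_layers, model.focal)
    out = np.full(shape[0] * shape[1], np.nan)
    pred = model.predict(table)
    if zero_cutoff is not None:
        pred = np.where(pred < zero_cutoff, 0.0, pred)
    out[table["cell_id"].to_numpy()] = pred
    return out.reshape(shape)
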