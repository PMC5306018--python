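"""Stage 1: ensemble species distribution models.

Six algorithm families (GLM, spline-basis GAM, classification tree, gradient
boosting, random forest, and a MaxEnt-style penalized logistic model on
expanded features) are each fitted on repeated random 70/30 splits of the
presence–absence table. Members are scored on their held-out 30% by ROC AUC
and TSS, selected either as a "leading group" (scores a clear step above the
remainder on both metrics) or as the top 20 by ROC, screened for committee
consistency against the cellwise-median map, and finally combined as a
ROC-weighted mean to predict a gridded probability of occupancy.

The MaxEnt member is a surrogate: with presence–absence (not presence-only
background) input, a penalized logistic regression on linear + quadratic +
pairwise-product features captures the same response-surface flexibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import (OneHotEncoder, PolynomialFeatures,
                                   SplineTransformer, StandardScaler)
from sklearn.tree import DecisionTreeClassifier

from . import metrics
from .grids import CovariateStack

ALGORITHM_NAMES = ("glm", "gam", "cta", "gbm", "rf", "maxent_like")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "glm": {"max_iter": 2000, "C": 1e6},          # effectively unpenalized
    "gam": {"n_knots": 5, "degree": 3, "C": 1.0, "max_iter": 2000},
    "cta": {"max_depth": 8, "min_samples_leaf": 10},
    "gbm": {"n_estimators": 100, "max_depth": 3},
    "rf": {"n_estimators": 500},
    "maxent_like": {"C": 1.0, "max_iter": 2000},
}


@dataclass
class ModelScore:
    """Held-out skill of one fitted member."""

    roc_auc: float
    tss: float
    tss_threshold: float


@dataclass(eq=False)
class FittedSDM:
    """One algorithm x repeat fit; ``predict`` maps covariates to [0, 1]."""

    algorithm: str
    repeat: int
    seed: int
    pipeline: Pipeline
    feature_names: list[str]
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None
    score: ModelScore | None = None
    selected: bool = False
    rejected: bool = False

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"covariates missing from input: {missing}")
        p = self.pipeline.predict_proba(features[self.feature_names])[:, 1]
        return np.clip(p, 0.0, 1.0)


@dataclass(eq=False)
class EnsembleSDM:
    """ROC-weighted committee of fitted members."""

    members: list[FittedSDM]
    weights: np.ndarray

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        preds = np.stack([m.predict(features) for m in self.members])
        return np.tensordot(self.weights, preds, axes=(0, 0))


def split_data(n_rows: int, fraction: float = 0.7, seed: int = 0):
    """Random disjoint exhaustive train/test split; train = round(fraction*n)."""
    if n_rows < 10:
        raise ValueError(f"too few rows to split meaningfully: {n_rows}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    n_train = int(round(fraction * n_rows))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _build_pipeline(name: str, params: dict, continuous: list[str],
                    categorical: list[str], seed: int) -> Pipeline:
    onehot = OneHotEncoder(handle_unknown="ignore", sparse_output=False)
    if name == "glm":
        pre = ColumnTransformer([("num", StandardScaler(), continuous),
                                 ("cat", onehot, categorical)])
        clf = LogisticRegression(C=params["C"], max_iter=params["max_iter"])
    elif name == "gam":
        spline = Pipeline([
            ("scale", StandardScaler()),
            ("spline", SplineTransformer(n_knots=params["n_knots"],
                                         degree=params["degree"]))])
        pre = ColumnTransformer([("num", spline, continuous),
                                 ("cat", onehot, categorical)])
        clf = LogisticRegression(C=params["C"], max_iter=params["max_iter"])
    elif name == "cta":
        pre = ColumnTransformer([("num", "passthrough", continuous),
                                 ("cat", onehot, categorical)])
        clf = DecisionTreeClassifier(max_depth=params["max_depth"],
                                     min_samples_leaf=params["min_samples_leaf"],
                                     random_state=seed)
    elif name == "gbm":
        pre = ColumnTransformer([("num", "passthrough", continuous),
                                 ("cat", onehot, categorical)])
        clf = GradientBoostingClassifier(n_estimators=params["n_estimators"],
                                         max_depth=params["max_depth"],
                                         random_state=seed)
    elif name == "rf":
        pre = ColumnTransformer([("num", "passthrough", continuous),
                                 ("cat", onehot, categorical)])
        clf = RandomForestClassifier(n_estimators=params["n_estimators"],
                                     random_state=seed)
    elif name == "maxent_like":
        expand = Pipeline([
            ("poly", PolynomialFeatures(degree=2, include_bias=False)),
            ("scale", StandardScaler())])
        pre = ColumnTransformer([("num", expand, continuous),
                                 ("cat", onehot, categorical)])
        clf = LogisticRegression(C=params["C"], max_iter=params["max_iter"])
    else:
        raise ValueError(f"unknown algorithm {name!r}; registry: {ALGORITHM_NAMES}")
    return Pipeline([("pre", pre), ("clf", clf)])


def fit_algorithm(name: str, features: pd.DataFrame, labels, *,
                  categorical: list[str] | None = None,
                  hyperparameters: dict | None = None,
                  repeat: int = 0, seed: int = 0) -> FittedSDM:
    """Fit one algorithm on training rows; raises on single-class labels."""
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training data contain a single class")
    params = dict(DEFAULT_HYPERPARAMETERS.get(name, {}))
    if name not in ALGORITHM_NAMES:
        raise ValueError(f"unknown algorithm {name!r}; registry: {ALGORITHM_NAMES}")
    if hyperparameters:
        params.update(hyperparameters)
    categorical = list(categorical or [])
    continuous = [c for c in features.columns if c not in categorical]
    pipe = _build_pipeline(name, params, continuous, categorical, seed)
    pipe.fit(features, y)
    return FittedSDM(algorithm=name, repeat=repeat, seed=seed, pipeline=pipe,
                     feature_names=list(features.columns))


def score_model(model: FittedSDM, features: pd.DataFrame, labels) -> ModelScore:
    """Held-out ROC AUC and TSS (attached to the model)."""
    preds = model.predict(features)
    roc = metrics.roc_auc(preds, labels)
    t, thr = metrics.tss(preds, labels)
    model.score = ModelScore(roc_auc=roc, tss=t, tss_threshold=thr)
    return model.score


def select_models(models: list[FittedSDM], gap: float = 0.05,
                  fallback_k: int = 20) -> list[FittedSDM]:
    """Choose ensemble members.

    Sorted by ROC (descending), the smallest top group whose worst member
    beats the best remaining model by >= ``gap`` in ROC *and* in TSS is the
    leading group. Without one, the top ``fallback_k`` by ROC are taken
    (ties at the cut included; everything, if fewer models than that).
    """
    if not models:
        raise ValueError("no scored models to select from")
    scored = sorted(models, key=lambda m: -m.score.roc_auc)
    rocs = np.array([m.score.roc_auc for m in scored])
    tsss = np.array([m.score.tss for m in scored])
    n = len(scored)
    for i in range(1, n):
        roc_gap = rocs[:i].min() - rocs[i:].max()
        tss_gap = tsss[:i].min() - tsss[i:].max()
        if roc_gap >= gap and tss_gap >= gap:
            chosen = scored[:i]
            break
    else:
        if n <= fallback_k:
            chosen = scored
        else:
            cut = rocs[fallback_k - 1]
            chosen = [m for m in scored if m.score.roc_auc >= cut]
    for m in models:
        m.selected = m in chosen
    return chosen


def reject_inconsistent(models: list[FittedSDM], features: pd.DataFrame,
                        deviation_threshold: float = 0.25,
                        min_survivors: int = 2) -> list[FittedSDM]:
    """Drop members whose predicted map strays from the committee consensus.

    The consensus is the cellwise median of all member maps; a member is
    rejected when its mean absolute deviation from that consensus exceeds
    ``deviation_threshold``. At least ``min_survivors`` members are always
    kept (the most consensus-faithful ones).
    """
    if len(models) < 3:
        return list(models)
    maps = np.stack([m.predict(features) for m in models])
    consensus = np.median(maps, axis=0)
    deviation = np.mean(np.abs(maps - consensus[None, :]), axis=1)
    keep = deviation <= deviation_threshold
    if keep.sum() < min_survivors:
        keep = np.zeros(len(models), dtype=bool)
        keep[np.argsort(deviation)[:min_survivors]] = True
    for m, k in zip(models, keep):
        m.rejected = not k
    return [m for m, k in zip(models, keep) if k]


def build_ensemble(models: list[FittedSDM]) -> EnsembleSDM:
    """Weight members proportionally to their held-out ROC AUC (sum to 1)."""
    if not models:
        raise ValueError("cannot build an ensemble from zero members")
    rocs = np.array([m.score.roc_auc for m in models], dtype=float)
    if rocs.sum() <= 0:
        raise ValueError("member ROC scores must be positive")
    return EnsembleSDM(members=list(models), weights=rocs / rocs.sum())


def predict_occupancy(ensemble: EnsembleSDM, stack: CovariateStack) -> np.ndarray:
    """Gridded ensemble probability of occupancy; NaN where covariates are
    missing (no-data cells)."""
    table = stack.as_table()
    needed = ensemble.members[0].feature_names
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"stack lacks covariates used in fitting: {missing}")
    sub = table[needed]
    nodata = ~np.isfinite(sub.to_numpy(dtype=float)).all(axis=1)
    preds = np.full(len(table), np.nan)
    ok = ~nodata
    if ok.any():
        preds[ok] = ensemble.predict(sub.loc[ok])
    return preds.reshape(stack.grid.ny, stack.grid.nx)


def response_curves(model: FittedSDM, features: pd.DataFrame,
                    n_points: int = 25) -> pd.DataFrame:
    """Partial response of a member to each continuous covariate: sweep one
    covariate over its observed range with the others held at their median."""
    rows = []
    base = features.median(numeric_only=True)
    for cov in model.feature_names:
        vals = features[cov]
        sweep = np.linspace(vals.min(), vals.max(), n_points)
        probe = pd.DataFrame({c: np.full(n_points, base[c])
                              for c in model.feature_names})
        probe[cov] = sweep
        rows.append(pd.DataFrame({"covariate": cov, "value": sweep,
                                  "prediction": model.predict(probe)}))
    return pd.concat(rows, ignore_index=True)
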