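"""Evaluation metrics shared by both modeling stages.

All metrics are implemented directly from their definitions so they can be
checked against exhaustive oracles: AUC is the fraction of (presence, absence)
score pairs correctly ordered (ties count one half), and TSS is the maximum of
sensitivity + specificity - 1 over an exhaustive threshold grid.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["roc_auc", "tss", "rmse", "mae", "r_squared"]


def _as_pairs(observed, predicted):
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: {o.shape} vs {p.shape}")
    if o.size == 0:
        raise ValueError("empty input")
    if not (np.isfinite(o).all() and np.isfinite(p).all()):
        raise ValueError("non-finite values in input")
    return o, p


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).ravel().astype(int)
    classes = np.unique(y)
    if not np.isin(classes, [0, 1]).all():
        raise ValueError(f"labels must be binary 0/1, got {classes}")
    if classes.size < 2:
        raise ValueError("both classes required; got a single-class label set")
    return y


def roc_auc(predictions, labels) -> float:
    """Area under the ROC curve by pair counting.

    Equals P(score(presence) > score(absence)) + 0.5 * P(tie), computed via
    the rank-sum (Mann-Whitney U) identity, which is exactly pair counting
    with ties scored one half.
    """
    y = _check_binary(labels)
    p = np.asarray(predictions, dtype=float).ravel()
    if p.shape != y.shape:
        raise ValueError("predictions and labels differ in length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = rankdata(p)  # average ranks handle ties -> half credit
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def tss(predictions, labels) -> tuple[float, float]:
    """True skill statistic: max over thresholds of sensitivity + specificity - 1.

    A cell is classified present when its score is >= the threshold. Candidate
    thresholds are 0, the midpoints between consecutive sorted unique scores,
    and 1. Returns ``(tss, threshold)`` with the smallest maximizing threshold.
    """
    y = _check_binary(labels)
    p = np.asarray(predictions, dtype=float).ravel()
    if p.shape != y.shape:
        raise ValueError("predictions and labels differ in length")
    uniq = np.unique(p)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([0.0], mids, [1.0]))
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    best_tss, best_thr = -np.inf, 0.0
    for thr in candidates:
        pred_pos = p >= thr
        sens = np.count_nonzero(pred_pos & (y == 1)) / n_pos
        spec = np.count_nonzero(~pred_pos & (y == 0)) / n_neg
        score = sens + spec - 1.0
        if score > best_tss + 1e-12:
            best_tss, best_thr = score, thr
    return float(best_tss), float(best_thr)


def rmse(observed, predicted) -> float:
    o, p = _as_pairs(observed, predicted)
    return float(np.sqrt(np.mean((o - p) ** 2)))


def mae(observed, predicted) -> float:
    o, p = _as_pairs(observed, predicted)
    return float(np.mean(np.abs(o - p)))


def r_squared(observed, predicted) -> float:
    """Predictive R² = 1 - SSE/SST; can be negative on held-out data."""
    o, p = _as_pairs(observed, predicted)
    sst = np.sum((o - o.mean()) ** 2)
    if sst == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    sse = np.sum((o - p) ** 2)
    return float(1.0 - sse / sst)
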