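"""Evaluation metrics for the nested-CV reports.

Regression is summarised by MSE/RMSE/MAE per fold with mean +/- std
across folds.  Classification is summarised on the pooled out-of-fold
scores: AUC (Mann-Whitney statistic, ties get half credit) with a 95%
confidence interval by the DeLong method (default) or a stratified
bootstrap, a vertically averaged ROC curve, and an aggregated confusion
matrix at a probability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.metrics import (
    mean_absolute_error,
    mean_squared_error,
    roc_curve,
)

__all__ = [
    "regression_metrics",
    "auc_with_ci",
    "average_roc",
    "aggregate_confusion",
]

FPR_GRID = np.round(np.arange(0.0, 1.0001, 0.01), 2)


def regression_metrics(y_true, y_pred, fold_ids=None) -> dict:
    """MSE/RMSE/MAE; per-fold values and mean +/- std when folds given."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and nonempty")

    def _one(t, p):
        mse = mean_squared_error(t, p)
        return {"mse": mse, "rmse": float(np.sqrt(mse)), "mae": mean_absolute_error(t, p)}

    out = {"pooled": _one(y_true, y_pred)}
    if fold_ids is not None:
        fold_ids = np.asarray(fold_ids)
        per_fold = {}
        for f in np.unique(fold_ids):
            m = fold_ids == f
            if not m.any():
                raise ValueError(f"fold {f} is empty")
            per_fold[int(f)] = _one(y_true[m], y_pred[m])
        out["per_fold"] = per_fold
        for key in ("mse", "rmse", "mae"):
            vals = np.array([v[key] for v in per_fold.values()])
            out[key] = {"mean": float(vals.mean()), "std": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    return out


def _midranks(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based, ties averaged) as used by the DeLong recursion."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def _delong_auc_var(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from the structural components."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midranks(np.concatenate([pos, neg]))
    tx = _midranks(pos)
    ty = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - tx) / n
    v01 = 1.0 - (all_ranks[m:] - ty) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def auc_with_ci(
    labels,
    scores,
    method: str = "delong",
    alpha: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Pooled AUC with a two-sided confidence interval.

    DeLong (default) uses the asymptotic normal interval on the AUC with
    the structural-component variance; "bootstrap" resamples positives
    and negatives separately (stratified) and takes percentile bounds.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must be equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute an AUC")
    auc, var = _delong_auc_var(labels, scores)
    if method == "delong":
        z = norm.ppf(0.5 + alpha / 2.0)
        half = z * np.sqrt(max(var, 0.0))
        return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        stats = np.empty(n_boot)
        for b in range(n_boot):
            p = rng.choice(pos, size=len(pos), replace=True)
            q = rng.choice(neg, size=len(neg), replace=True)
            bl = np.concatenate([np.ones(len(p), int), np.zeros(len(q), int)])
            stats[b], _ = _delong_auc_var(bl, np.concatenate([p, q]))
        lo, hi = np.quantile(stats, [(1 - alpha) / 2, 0.5 + alpha / 2])
        return auc, float(lo), float(hi)
    raise ValueError(f"unknown CI method {method!r}")


def average_roc(per_fold_curves: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """Vertical averaging: mean TPR at a fixed FPR grid (0 to 1, step 0.01).

    Each curve is a (fpr, tpr) pair as returned by an ROC routine; TPR is
    interpolated at every grid point and averaged across folds.
    """
    if not per_fold_curves:
        raise ValueError("need at least one fold curve")
    tprs = []
    for fpr, tpr in per_fold_curves:
        fpr = np.asarray(fpr, dtype=float)
        tpr = np.asarray(tpr, dtype=float)
        t = np.interp(FPR_GRID, fpr, tpr)
        t[0] = 0.0
        t[-1] = 1.0
        tprs.append(t)
    return FPR_GRID.copy(), np.mean(tprs, axis=0)


def fold_roc_curve(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC curve of one fold (thin wrapper, fixed conventions)."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr


def aggregate_confusion(labels, scores, threshold: float = 0.5) -> dict:
    """2x2 counts plus sensitivity/specificity on pooled predictions.

    A score strictly above the probability threshold predicts positive.
    Undefined rates (empty class) are reported as NaN.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return {
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
        "sensitivity": sens,
        "specificity": spec,
        "threshold": threshold,
    }
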