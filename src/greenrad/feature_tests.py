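"""Supervised per-feature screening: discriminant and relevant feature tests.

Each one-dimensional feature is scored by the best split of its dynamic
range into two segments.  For classification (discriminant feature test,
DFT) the loss is the sample-weighted binary Shannon entropy of the two
segments; for regression (relevant feature test, RFT) it is the pooled
root-mean-squared error when each segment is predicted by its own target
mean.  Lower loss means a more discriminative feature.  Features are
ranked by ascending loss, and a robust subset is obtained by
intersecting the top-K prefixes of two independent rankings (internal
training vs internal validation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PartitionGrid",
    "SplitResult",
    "LossRanking",
    "IntersectionSet",
    "rft_loss",
    "dft_loss",
    "rank_features",
    "intersect_top_k",
]


@dataclass(frozen=True)
class PartitionGrid:
    """Candidate-threshold policy for the two-segment partition search.

    ``uniform`` mode places ``n_candidates`` equispaced interior points
    over the feature's [min, max]; ``exhaustive`` mode uses the midpoints
    between consecutive distinct sorted values, which makes the search
    exact.  ``min_segment`` is the minimum number of samples required on
    each side of a split.
    """

    n_candidates: int = 31
    min_segment: int = 2
    mode: str = "uniform"

    def __post_init__(self) -> None:
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.min_segment < 1:
            raise ValueError("min_segment must be >= 1")
        if self.mode not in ("uniform", "exhaustive"):
            raise ValueError(f"unknown grid mode {self.mode!r}")

    def thresholds(self, x_sorted: np.ndarray) -> np.ndarray:
        lo, hi = x_sorted[0], x_sorted[-1]
        if lo == hi:
            return np.empty(0)
        if self.mode == "uniform":
            return np.linspace(lo, hi, self.n_candidates + 2)[1:-1]
        uniq = np.unique(x_sorted)
        return (uniq[:-1] + uniq[1:]) / 2.0


@dataclass(frozen=True)
class SplitResult:
    loss: float
    threshold: float  # NaN when no valid two-segment split exists
    degenerate: bool = False  # single-class labels / constant feature


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    """Base-2 entropy of Bernoulli(p), elementwise, with 0*log0 = 0."""
    p = np.clip(p, 0.0, 1.0)
    out = np.zeros_like(p, dtype=float)
    for q in (p, 1.0 - p):
        nz = q > 0
        out[nz] -= q[nz] * np.log2(q[nz])
    return out


def _valid_splits(x: np.ndarray, grid: PartitionGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sorted order, candidate thresholds, and left-segment sizes.

    Returns (order, thresholds, n_left) with only splits leaving at
    least ``min_segment`` samples on each side.
    """
    n = x.shape[0]
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ts = grid.thresholds(xs)
    if ts.size == 0:
        return order, ts, np.empty(0, dtype=int)
    n_left = np.searchsorted(xs, ts, side="right")
    ok = (n_left >= grid.min_segment) & (n - n_left >= grid.min_segment)
    return order, ts[ok], n_left[ok]


def rft_loss(feature, target, grid: PartitionGrid = PartitionGrid()) -> SplitResult:
    """Relevant feature test: two-segment pooled RMSE of a feature.

    ``loss = min_t sqrt((SSE_left + SSE_right) / n)`` where each side is
    predicted by its own target mean.  A constant feature (or one with
    no split satisfying ``min_segment``) falls back to the
    single-segment loss, i.e. the population standard deviation of the
    target.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("feature and target must be 1-D and equal length")
    n = x.shape[0]
    if n < 2 * grid.min_segment:
        raise ValueError("need at least 2*min_segment samples")
    order, ts, n_left = _valid_splits(x, grid)
    fallback = float(np.std(y))
    if ts.size == 0:
        return SplitResult(fallback, float("nan"), degenerate=True)
    ys = y[order]
    c1 = np.cumsum(ys)
    c2 = np.cumsum(ys**2)
    tot1, tot2 = c1[-1], c2[-1]
    k = n_left
    sse_l = c2[k - 1] - c1[k - 1] ** 2 / k
    sse_r = (tot2 - c2[k - 1]) - (tot1 - c1[k - 1]) ** 2 / (n - k)
    losses = np.sqrt(np.maximum(sse_l + sse_r, 0.0) / n)
    best = int(np.argmin(losses))  # ties -> smallest threshold
    return SplitResult(float(losses[best]), float(ts[best]))


def dft_loss(feature, labels, grid: PartitionGrid = PartitionGrid()) -> SplitResult:
    """Discriminant feature test: two-segment weighted entropy of a feature.

    ``loss = min_t (n_L H(p_L) + n_R H(p_R)) / n`` with H the base-2
    Shannon entropy of the within-segment label distribution.
    Single-class label vectors give loss 0 with the degenerate flag set;
    a constant feature falls back to the whole-vector entropy.
    """
    x = np.asarray(feature, dtype=float)
    lab = np.asarray(labels)
    if x.shape != lab.shape or x.ndim != 1:
        raise ValueError("feature and labels must be 1-D and equal length")
    uniq = np.unique(lab)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if uniq.size == 1:
        return SplitResult(0.0, float("nan"), degenerate=True)
    n = x.shape[0]
    if n < 2 * grid.min_segment:
        raise ValueError("need at least 2*min_segment samples")
    y = lab.astype(float)
    order, ts, n_left = _valid_splits(x, grid)
    fallback = float(_binary_entropy(np.array([y.mean()]))[0])
    if ts.size == 0:
        return SplitResult(fallback, float("nan"), degenerate=True)
    ys = y[order]
    cpos = np.cumsum(ys)
    tot = cpos[-1]
    k = n_left
    p_l = cpos[k - 1] / k
    p_r = (tot - cpos[k - 1]) / (n - k)
    losses = (k * _binary_entropy(p_l) + (n - k) * _binary_entropy(p_r)) / n
    best = int(np.argmin(losses))
    return SplitResult(float(losses[best]), float(ts[best]))


@dataclass(frozen=True)
class LossRanking:
    """Per-feature losses with a deterministic ascending-loss order.

    ``order`` lists feature names from most to least discriminative;
    ties are broken by original column position.  ``rank_of`` maps each
    feature name to its 0-based rank.
    """

    feature_names: tuple[str, ...]
    loss: np.ndarray
    best_threshold: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.loss):
            raise ValueError("loss length mismatch")

    @property
    def order(self) -> list[str]:
        idx = np.argsort(self.loss, kind="stable")
        return [self.feature_names[i] for i in idx]

    def rank_of(self) -> dict[str, int]:
        return {name: r for r, name in enumerate(self.order)}

    def loss_of(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.loss.tolist()))

    def top_k(self, k: int) -> list[str]:
        if k > len(self.feature_names):
            raise ValueError(f"K={k} exceeds {len(self.feature_names)} features")
        return self.order[:k]

    def subset(self, names) -> "LossRanking":
        """Restrict to ``names`` (column order preserved); losses are
        columnwise so they are unchanged by dropping other features."""
        keep = set(names)
        idx = [i for i, f in enumerate(self.feature_names) if f in keep]
        return LossRanking(
            tuple(self.feature_names[i] for i in idx),
            self.loss[idx],
            self.best_threshold[idx],
            self.mode,
        )

    def to_frame(self) -> pd.DataFrame:
        rank = self.rank_of()
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "loss": self.loss,
                "rank": [rank[f] for f in self.feature_names],
                "best_threshold": self.best_threshold,
            }
        )


def rank_features(
    table: pd.DataFrame,
    target,
    mode: str,
    grid: PartitionGrid = PartitionGrid(),
) -> LossRanking:
    """Apply the per-feature loss independently to every column.

    ``mode`` is "dft" (binary labels) or "rft" (continuous target).
    """
    if mode not in ("dft", "rft"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(target)
    if len(y) != len(table):
        raise ValueError("table and target are not aligned")
    fn = dft_loss if mode == "dft" else rft_loss
    losses = np.empty(table.shape[1])
    thresholds = np.empty(table.shape[1])
    x = table.to_numpy(dtype=float)
    for j in range(table.shape[1]):
        res = fn(x[:, j], y, grid)
        losses[j] = res.loss
        thresholds[j] = res.threshold
    return LossRanking(tuple(table.columns), losses, thresholds, mode)


@dataclass(frozen=True)
class IntersectionSet:
    """Features ranked top-K by loss on both of two independent rankings."""

    K: int
    features: frozenset[str]
    ordered: tuple[str, ...]  # intersection members, by training rank

    def __len__(self) -> int:
        return len(self.features)


def intersect_top_k(
    train_ranking: LossRanking, val_ranking: LossRanking, K: int
) -> IntersectionSet:
    """Intersect the top-K prefixes of the training and validation rankings."""
    if set(train_ranking.feature_names) != set(val_ranking.feature_names):
        raise ValueError("rankings cover different feature sets")
    if K > len(train_ranking.feature_names):
        raise ValueError(f"K={K} exceeds the number of features")
    top_train = train_ranking.top_k(K)
    members = set(top_train) & set(val_ranking.top_k(K))
    ordered = tuple(f for f in top_train if f in members)
    return IntersectionSet(K, frozenset(members), ordered)
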