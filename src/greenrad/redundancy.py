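"""Correlation-based redundancy identification and removal.

Radiomic texture features are notoriously collinear: many are affine or
near-affine transforms of one another and carry no independent
information.  The filter computes the absolute Pearson correlation
matrix on the internal training set, flags feature pairs whose |r|
strictly exceeds a threshold as redundant, and resolves each redundancy
in favour of the feature with the lower supervised (DFT/RFT) loss.

Correlation chains (A~B, B~C but A is not redundant with C) are resolved
by a greedy sweep in ascending-loss order: a feature is retained iff no
already-retained feature is correlated with it above the threshold.
Given distinct losses the result is order-independent, every dropped
feature has a retained partner with lower-or-equal loss, and the
retained set is pairwise non-redundant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_tests import LossRanking

__all__ = [
    "CorrelationReport",
    "correlation_matrix",
    "identify_redundant_pairs",
    "resolve_redundancy",
    "retained_dimension_curve",
]


@dataclass(frozen=True)
class CorrelationReport:
    """Absolute Pearson correlations between all feature pairs.

    Constant features (zero variance, Pearson r undefined) are flagged
    and given |r| = 0 against every other feature by convention.
    """

    feature_names: tuple[str, ...]
    abs_corr: np.ndarray
    constant_features: frozenset[str]

    def __post_init__(self) -> None:
        d = len(self.feature_names)
        if self.abs_corr.shape != (d, d):
            raise ValueError("abs_corr must be square over feature_names")

    def lookup(self, a: str, b: str) -> float:
        i = self.feature_names.index(a)
        j = self.feature_names.index(b)
        return float(self.abs_corr[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abs_corr, index=self.feature_names, columns=self.feature_names
        )


def correlation_matrix(table: pd.DataFrame) -> CorrelationReport:
    """Absolute Pearson correlation over all column pairs of ``table``."""
    if len(table) < 2:
        raise ValueError("need at least 2 samples to correlate")
    x = table.to_numpy(dtype=float)
    sd = x.std(axis=0)
    const = sd == 0.0
    if const.all():
        raise ValueError("all features are constant; correlation undefined")
    # corrcoef warns and yields NaN for zero-variance columns; substitute
    # unit-variance noise-free placeholders then zero their rows.
    xs = x.copy()
    xs[:, const] = np.arange(len(table))[:, None]
    r = np.abs(np.corrcoef(xs, rowvar=False))
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    names = tuple(table.columns)
    constant = frozenset(n for n, c in zip(names, const) if c)
    return CorrelationReport(names, r, constant)


def identify_redundant_pairs(
    report: CorrelationReport, threshold: float
) -> list[tuple[str, str]]:
    """All (i, j) pairs, i before j in column order, with |r| > threshold.

    The inequality is strict: at threshold 1.0 no pair is redundant even
    for duplicated columns, at 0.0 every pair with any sample
    correlation is listed.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    i_idx, j_idx = np.nonzero(np.triu(report.abs_corr > threshold, k=1))
    names = report.feature_names
    return [(names[i], names[j]) for i, j in zip(i_idx, j_idx)]


def _loss_map(losses: LossRanking | Mapping[str, float]) -> tuple[dict[str, float], list[str]]:
    if isinstance(losses, LossRanking):
        return losses.loss_of(), list(losses.feature_names)
    return dict(losses), list(losses)


def resolve_redundancy(
    pairs: Sequence[tuple[str, str]],
    losses: LossRanking | Mapping[str, float],
    feature_names: Sequence[str] | None = None,
) -> list[str]:
    """Greedy ascending-loss resolution of redundant pairs.

    Sweeping features from lowest to highest loss (ties by column
    order), a feature is retained iff no already-retained feature is
    redundant with it.  Features not involved in any pair are always
    retained.  Returns retained names in original column order.
    """
    loss_of, order = _loss_map(losses)
    if feature_names is not None:
        order = list(feature_names)
    paired = {f for pair in pairs for f in pair}
    missing = [f for f in paired if f not in loss_of]
    if missing:
        raise ValueError(f"paired features without a loss value: {missing[:5]}")
    adj: dict[str, set[str]] = {f: set() for f in paired}
    for a, b in pairs:
        adj[a].add(b)
        adj[b].add(a)
    col = {f: i for i, f in enumerate(order)}
    retained: set[str] = set(f for f in order if f not in paired)
    for f in sorted(paired, key=lambda f: (loss_of[f], col[f])):
        if not (adj[f] & retained):
            retained.add(f)
    return [f for f in order if f in retained]


def retained_dimension_curve(
    report: CorrelationReport,
    losses: LossRanking | Mapping[str, float],
    thresholds: Iterable[float] = np.arange(0.5, 1.0001, 0.05),
) -> pd.DataFrame:
    """Retained feature dimension as a function of the |r| threshold."""
    rows = []
    for t in thresholds:
        pairs = identify_redundant_pairs(report, float(t))
        kept = resolve_redundancy(pairs, losses, report.feature_names)
        rows.append({"threshold": float(t), "retained_dimension": len(kept)})
    return pd.DataFrame(rows)
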