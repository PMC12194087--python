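"""Least-squares normal transform (LNT) feature generation.

The LNT turns a subgroup of selected raw features into one derived
"complementary" feature: the linear combination that best predicts the
target in the least-squares sense on the internal training samples.
With X the (features x samples) subgroup matrix and T the 1 x samples
target (continuous values for regression, 0/1 labels for
classification), the weight vector solves

    A X = T          =>          A = T X^T (X X^T)^+

where ^+ is the Moore-Penrose pseudoinverse: when the subgroup is larger
than the sample count (the usual radiomics regime) X X^T is singular and
the minimum-norm solution is taken, with a small trace-scaled ridge as a
numerical fallback.  The bias term only shifts the derived feature and
cannot change its discriminative power, so features and target are
centred with training statistics and the bias is fixed at zero.

Subgroups are built from the ascending-loss feature ranking by a strided
round-robin: with g groups, group i takes the features ranked i, i+g,
i+2g, ...  so every group mixes strong and weak ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .feature_tests import LossRanking

__all__ = [
    "SubgroupAssignment",
    "LNTModel",
    "ComplementaryFeatures",
    "assign_subgroups",
    "fit_lnt",
    "apply_lnt",
    "generate_complementary",
    "apply_complementary",
]


@dataclass(frozen=True)
class SubgroupAssignment:
    """Strided partition of a ranked feature list into subgroups."""

    stride_s: int
    n_groups: int
    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.groups) != self.n_groups:
            raise ValueError("group count mismatch")


def assign_subgroups(
    ranked_features: Sequence[str],
    stride_s: int | None = None,
    n_groups: int | None = None,
) -> SubgroupAssignment:
    """Partition ``ranked_features`` (ascending loss) into strided groups.

    Group i (0-based offset) holds the features at ranks i, i+g, i+2g,
    ... where g is the number of groups.  ``n_groups`` is authoritative
    when both are given; a bare ``stride_s`` yields exactly ``stride_s``
    groups, matching the offset-stride construction.
    """
    if stride_s is None and n_groups is None:
        raise ValueError("provide stride_s or n_groups")
    g = int(n_groups) if n_groups is not None else int(stride_s)
    s = int(stride_s) if stride_s is not None else g
    if g < 1 or s < 1:
        raise ValueError("stride and group count must be >= 1")
    feats = list(ranked_features)
    if len(feats) < g:
        raise ValueError(f"{len(feats)} features cannot fill {g} groups")
    groups = tuple(tuple(feats[i::g]) for i in range(g))
    return SubgroupAssignment(stride_s=s, n_groups=g, groups=groups)


@dataclass(frozen=True)
class LNTModel:
    """Fitted weights for one subgroup, with the training standardization."""

    feature_names: tuple[str, ...]
    weights: np.ndarray  # length = group size
    bias: float  # fixed 0 after centring
    mu: np.ndarray  # per-feature training mean
    sd: np.ndarray  # per-feature training sd (1 where constant)
    target_mean: float
    residual_orthogonality: float  # max |X_c r^T| on the fitting data


def _standardize(x: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (x - mu[:, None]) / sd[:, None]


def fit_lnt(
    group_matrix: np.ndarray,
    target,
    feature_names: Sequence[str] | None = None,
    standardize: bool = True,
) -> LNTModel:
    """Solve the least-squares normal equation for one subgroup.

    ``group_matrix`` is features x samples.  By default features are
    z-scored and the target centred with the training statistics before
    the solve (``standardize=False`` solves on the raw matrix); the
    normal-equation solution uses the pseudoinverse of X X^T (ridge
    fallback 1e-8 * trace/d if the pseudoinverse is not finite), which
    is the minimum-norm least-squares solution when the system is
    underdetermined.
    """
    x = np.asarray(group_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("group_matrix must be a nonempty features x samples matrix")
    t = np.asarray(target, dtype=float).ravel()
    if t.shape[0] != x.shape[1]:
        raise ValueError("target length must equal the sample count")
    d = x.shape[0]
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(d)
    )
    if len(names) != d:
        raise ValueError("feature_names length mismatch")
    if standardize:
        mu = x.mean(axis=1)
        sd = x.std(axis=1)
        sd = np.where(sd == 0.0, 1.0, sd)
        tmean = float(t.mean())
    else:
        mu = np.zeros(d)
        sd = np.ones(d)
        tmean = 0.0
    xc = _standardize(x, mu, sd)
    tc = t - tmean
    gram = xc @ xc.T
    a = tc @ xc.T @ np.linalg.pinv(gram)
    if not np.all(np.isfinite(a)):
        lam = 1e-8 * np.trace(gram) / d
        a = tc @ xc.T @ np.linalg.inv(gram + lam * np.eye(d))
    resid = tc - a @ xc
    ortho = float(np.max(np.abs(xc @ resid))) if d else 0.0
    return LNTModel(names, np.asarray(a, dtype=float), 0.0, mu, sd, tmean, ortho)


def apply_lnt(model: LNTModel, group_matrix: np.ndarray) -> np.ndarray:
    """Project samples onto the fitted weights: p = A x (standardized).

    Standardization uses the statistics frozen at fit time, so applying
    to held-out samples leaks nothing from them.
    """
    x = np.asarray(group_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} feature rows, got shape {x.shape}"
        )
    return model.weights @ _standardize(x, model.mu, model.sd) + model.bias


@dataclass(frozen=True)
class ComplementaryFeatures:
    """Derived features (samples x n_groups) with their provenance."""

    values: pd.DataFrame
    assignment: SubgroupAssignment
    models: tuple[LNTModel, ...]
    fold_id: int | None = None

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)


def _comp_names(n: int) -> list[str]:
    return [f"lnt_{i + 1:03d}" for i in range(n)]


def generate_complementary(
    table: pd.DataFrame,
    ranking: LossRanking,
    target,
    stride_s: int | None = None,
    n_groups: int | None = None,
    fold_id: int | None = None,
) -> ComplementaryFeatures:
    """Fit one LNT feature per rank-strided subgroup of ``table``'s columns.

    ``ranking`` must cover every column of ``table``; columns are
    ordered by ascending loss before grouping.  Classification labels
    are passed through as 0/1 reals.
    """
    cols = set(table.columns)
    ranked = [f for f in ranking.order if f in cols]
    if len(ranked) != len(cols):
        raise ValueError("ranking does not cover all table columns")
    assignment = assign_subgroups(ranked, stride_s=stride_s, n_groups=n_groups)
    t = np.asarray(target, dtype=float)
    models = []
    values = np.empty((len(table), assignment.n_groups))
    for gi, group in enumerate(assignment.groups):
        x = table[list(group)].to_numpy(dtype=float).T
        model = fit_lnt(x, t, feature_names=group)
        models.append(model)
        values[:, gi] = apply_lnt(model, x)
    frame = pd.DataFrame(
        values, index=table.index, columns=_comp_names(assignment.n_groups)
    )
    return ComplementaryFeatures(frame, assignment, tuple(models), fold_id)


def apply_complementary(
    comp: ComplementaryFeatures, table: pd.DataFrame
) -> pd.DataFrame:
    """Apply frozen subgroup models to new samples (e.g. a held-out fold)."""
    values = np.empty((len(table), comp.assignment.n_groups))
    for gi, (group, model) in enumerate(zip(comp.assignment.groups, comp.models)):
        x = table[list(group)].to_numpy(dtype=float).T
        values[:, gi] = apply_lnt(model, x)
    return pd.DataFrame(values, index=table.index, columns=comp.names)
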