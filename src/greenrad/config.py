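"""Run configuration: defaults, validation, and YAML round-tripping.

A ``RunConfig`` captures every knob of an end-to-end run -- task,
correlation threshold, partition grid, K grid, LNT group layout, CV
scheme, boosting grid, seed and paths -- and serialises losslessly to
YAML so a run is fully described by one file plus a seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .decision import BoostConfig, CVScheme
from .feature_tests import PartitionGrid

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Full specification of one pipeline run.

    Defaults follow the study protocol this pipeline implements:
    |r| > 0.9 redundancy threshold, 5 outer folds for regression and 10
    stratified folds for classification with a single 80/20 internal
    split, 10 LNT-derived features, boosted trees capped at depth 3 and
    fewer than 500 trees.
    """

    task: str  # "regression" | "classification"
    seed: int = 0
    corr_threshold: float = 0.9
    n_candidates: int = 31
    min_segment: int = 2
    partition_mode: str = "uniform"
    k_grid: tuple[int, ...] = (0,)
    n_groups: int = 10
    stride_s: int | None = None
    outer_folds: int | None = None  # None -> 5 regression / 10 classification
    inner_fraction: float = 0.2
    confusion_threshold: float = 0.5
    ci_method: str = "delong"
    boost_max_depth: tuple[int, ...] = (1, 3)
    boost_n_trees: tuple[int, ...] = (50, 300)
    boost_learning_rate: tuple[float, ...] | None = None  # None -> task default
    features_path: str | None = None
    targets_path: str | None = None
    preset: str | None = None  # synthetic preset when no paths are given
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if not (0.0 < self.corr_threshold <= 1.0):
            raise ValueError("corr_threshold must be in (0, 1]")
        if any(k < 0 for k in self.k_grid) or not self.k_grid:
            raise ValueError("k_grid must be nonempty with K >= 0")
        if self.n_groups < 0:
            raise ValueError("n_groups must be >= 0")

    # -- derived objects ---------------------------------------------------

    def partition_grid(self) -> PartitionGrid:
        return PartitionGrid(self.n_candidates, self.min_segment, self.partition_mode)

    def cv_scheme(self) -> CVScheme:
        folds = self.outer_folds
        if folds is None:
            folds = 10 if self.task == "classification" else 5
        return CVScheme(
            outer_folds=folds,
            inner_fraction=self.inner_fraction,
            stratified=self.task == "classification",
            seed=self.seed,
        )

    def boost_grid(self) -> tuple[BoostConfig, ...]:
        lrs = self.boost_learning_rate
        if lrs is None:
            lrs = (0.001, 0.01, 0.1) if self.task == "regression" else (0.01, 0.1)
        return tuple(
            BoostConfig(d, t, lr)
            for d in self.boost_max_depth
            for t in self.boost_n_trees
            for lr in lrs
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("k_grid", "boost_max_depth", "boost_n_trees", "boost_learning_rate"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("k_grid", "boost_max_depth", "boost_n_trees", "boost_learning_rate"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def with_overrides(self, **kw) -> "RunConfig":
        kw = {k: v for k, v in kw.items() if v is not None}
        for key in ("k_grid", "boost_max_depth", "boost_n_trees", "boost_learning_rate"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return replace(self, **kw)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
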