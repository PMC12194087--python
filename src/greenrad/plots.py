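"""Figure analogues: correlation heat map, retained-dimension curve,
sorted loss curves and train-vs-validation rank scatter.

Each helper writes a CSV of the plotted numbers next to the image so
the figures are reproducible without re-running the pipeline.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .feature_tests import LossRanking
from .redundancy import CorrelationReport

__all__ = [
    "plot_correlation_heatmap",
    "plot_retained_dimension_curve",
    "plot_sorted_losses",
    "plot_rank_scatter",
]


def plot_correlation_heatmap(report: CorrelationReport, path: str | Path) -> None:
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(report.abs_corr, vmin=0, vmax=1, cmap="coolwarm")
    ax.set_xlabel("feature index")
    ax.set_ylabel("feature index")
    ax.set_title("Absolute Pearson correlation")
    fig.colorbar(im, ax=ax, label="|r|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_retained_dimension_curve(curve: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    curve.to_csv(path.with_suffix(".csv"), index=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["threshold"], curve["retained_dimension"], marker="o")
    ax.set_xlabel("|r| threshold")
    ax.set_ylabel("retained feature dimension")
    ax.set_title("Redundancy threshold vs retained dimension")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sorted_losses(ranking: LossRanking, path: str | Path, title: str = "") -> None:
    path = Path(path)
    frame = ranking.to_frame().sort_values("rank")
    frame.to_csv(path.with_suffix(".csv"), index=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(range(len(frame)), frame["loss"].to_numpy())
    ax.set_xlabel("feature rank")
    ax.set_ylabel(f"{ranking.mode.upper()} loss")
    ax.set_title(title or "Sorted per-feature losses")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rank_scatter(
    train_ranking: LossRanking, val_ranking: LossRanking, K: int, path: str | Path
) -> None:
    """Training vs validation ranks; the K x K square marks intersection
    candidates."""
    path = Path(path)
    rt = train_ranking.rank_of()
    rv = val_ranking.rank_of()
    feats = list(train_ranking.feature_names)
    frame = pd.DataFrame(
        {"feature": feats,
         "train_rank": [rt[f] for f in feats],
         "val_rank": [rv[f] for f in feats]}
    )
    frame.to_csv(path.with_suffix(".csv"), index=False)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(frame["train_rank"], frame["val_rank"], s=8, alpha=0.6)
    ax.add_patch(plt.Rectangle((0, 0), K, K, fill=False, edgecolor="red"))
    ax.set_xlabel("internal training rank")
    ax.set_ylabel("internal validation rank")
    ax.set_title(f"Rank robustness (top-{K} intersection square)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
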