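"""End-to-end entry point: inputs -> nested CV -> artifacts on disk.

``run_pipeline`` executes the feed-forward pipeline (load or simulate a
cohort, then per outer fold: redundancy removal, DFT/RFT ranking,
intersection selection, LNT feature generation, constrained boosting)
and writes the run artifacts: ``metrics.json``, ``predictions.csv``,
``roc_points.csv`` (classification), ``selected_features.json`` and the
resolved ``config.yaml``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .cohort import make_preset, simulate_cohort
from .config import RunConfig, save_config
from .decision import CVReport, run_nested_cv
from .io import load_feature_table, load_targets

__all__ = ["run_pipeline", "load_inputs"]

log = logging.getLogger("greenrad")


def load_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Resolve the cohort: files when paths are set, else a synthetic preset."""
    if config.features_path and config.targets_path:
        table = load_feature_table(config.features_path)
        target = load_targets(config.targets_path)
        missing = set(table.index) ^ set(target.index)
        if missing:
            raise ValueError(f"feature/target sample ids differ: {sorted(missing)[:5]}")
        return table, target.loc[table.index]
    if config.preset:
        spec = make_preset(config.preset, seed=config.seed)
        return simulate_cohort(spec)
    raise ValueError("config needs features_path+targets_path or a preset")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> CVReport:
    """Run the configured pipeline and write artifacts under ``out_dir``."""
    table, target = load_inputs(config)
    log.info(
        "cohort: %d samples x %d features, task=%s", *table.shape, config.task
    )
    report = run_nested_cv(
        table,
        target,
        config.task,
        scheme=config.cv_scheme(),
        grid=config.partition_grid(),
        corr_threshold=config.corr_threshold,
        k_grid=config.k_grid,
        n_groups=config.n_groups,
        stride_s=config.stride_s,
        boost_grid=config.boost_grid(),
        confusion_threshold=config.confusion_threshold,
        ci_method=config.ci_method,
        seed=config.seed,
    )
    out = out_dir if out_dir is not None else config.out_dir
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "metrics.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=_json_default)
        report.predictions.to_csv(out / "predictions.csv", index=False)
        if report.roc_curve is not None:
            fpr, tpr = report.roc_curve
            pd.DataFrame({"fpr": fpr, "mean_tpr": tpr}).to_csv(
                out / "roc_points.csv", index=False
            )
        selected = [
            {
                "fold": f.fold,
                "n_retained_after_redundancy": f.n_retained,
                "K": f.K,
                "intersection_members": list(f.raw_features),
                "lnt_group_sizes": list(f.lnt_groups),
                "lnt_models": f.lnt_models,
            }
            for f in report.folds
        ]
        with open(out / "selected_features.json", "w") as fh:
            json.dump(selected, fh, indent=2, sort_keys=True)
        save_config(config, out / "config.yaml")
    return report
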