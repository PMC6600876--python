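"""End-to-end pipeline: cohort on disk -> all result tables.

Chains the four analysis stages — edge-class comparison, global
graph-metric comparison, nodal comparisons with FDR, and the
gene-expression association screen — and writes each stage's table plus
a machine-readable run log sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import DEFAULT_GRID
from .errors import ValidationError
from .exprassoc import (
    cooks_flags,
    fit_expression_regression,
    multi_gene_screen,
    sensitivity_refit,
)
from .groupcomp import (
    NODAL_COMPARISON_METRICS,
    _nodal_auc_per_subject,
    edge_class_comparison,
    global_group_comparison,
    nodal_group_comparison,
)
from .io import read_cohort, read_expression
from .netgen import Cohort, ExpressionProfile

__all__ = ["PipelineConfig", "run_pipeline", "PipelineResults"]

logger = logging.getLogger("strucnet")
if not logger.handlers:
    _handler = logging.StreamHandler(sys.stderr)
    _handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(_handler)
    logger.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, reproducibly.

    The threshold grid is a required, logged choice: there is no
    principled single streamline threshold, so metrics are swept from
    ``grid_start`` to ``grid_stop`` in steps of ``grid_step`` and
    compared as AUC.
    """

    cohort_dir: str
    out_dir: str
    expression_files: dict = field(default_factory=dict)  # gene -> path
    grid_start: float = 0.0
    grid_stop: float = 20.0
    grid_step: float = 1.0
    weight_mode: str = "fa"
    consensus: bool = True
    consensus_scope: str = "joint"
    normality_alpha: float = 0.05
    fdr_alpha: float = 0.05
    n_boot: int = 10_000
    bootstrap_level: float = 0.95
    seed: int = 0

    @property
    def grid(self) -> np.ndarray:
        if self.grid_step <= 0 or self.grid_stop <= self.grid_start:
            raise ValidationError("invalid threshold grid specification")
        return np.arange(
            self.grid_start, self.grid_stop + self.grid_step / 2, self.grid_step
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResults:
    edge_class: pd.DataFrame
    global_metrics: pd.DataFrame
    nodal: dict[str, pd.DataFrame]
    screen: pd.DataFrame | None
    regression_detail: dict | None
    run_log: dict


def _group_mean_regional_metrics(
    cohort: Cohort, grid: np.ndarray
) -> dict[str, dict[str, pd.Series]]:
    """Group-average per-region AUC for each nodal metric.

    The expression regression uses the group-mean regional profile (one
    observation per region), per group and metric.
    """
    labels = list(cohort.parcellation.labels)
    out: dict[str, dict[str, pd.Series]] = {"case": {}, "control": {}}
    for metric in NODAL_COMPARISON_METRICS:
        case, ctrl = _nodal_auc_per_subject(cohort, metric, grid)
        out["case"][metric] = pd.Series(case.mean(axis=0), index=labels)
        out["control"][metric] = pd.Series(ctrl.mean(axis=0), index=labels)
    return out


def _stage(name: str):
    def wrap(func):
        def inner(*args, **kwargs):
            try:
                return func(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

        return inner

    return wrap


def run_pipeline(
    config: PipelineConfig,
    cohort: Cohort | None = None,
    expressions: Mapping[str, ExpressionProfile] | None = None,
) -> PipelineResults:
    """Run every analysis stage and write result tables and a run log.

    ``cohort`` and ``expressions`` may be passed in memory; otherwise
    they are read from ``config.cohort_dir`` and
    ``config.expression_files``.
    """
    grid = config.grid
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    if cohort is None:
        cohort = _stage("read_cohort")(read_cohort)(config.cohort_dir)
    if expressions is None:
        expressions = {
            gene: _stage("read_expression")(read_expression)(path, gene)
            for gene, path in config.expression_files.items()
        }

    logger.info(
        "pipeline start: %d pairs, %d regions, grid %s..%s step %s",
        cohort.n_pairs, cohort.parcellation.n_regions,
        config.grid_start, config.grid_stop, config.grid_step,
    )

    edge_table = _stage("edge_class")(edge_class_comparison)(
        cohort, grid, config.weight_mode
    )
    edge_table.to_csv(out_dir / "edge_class_comparison.csv")

    global_table = _stage("global_metrics")(global_group_comparison)(
        cohort, grid, config.consensus, config.consensus_scope
    )
    global_table.to_csv(out_dir / "global_comparison.csv")

    nodal_tables: dict[str, pd.DataFrame] = {}
    for metric in NODAL_COMPARISON_METRICS:
        table = _stage(f"nodal_{metric}")(nodal_group_comparison)(
            cohort, metric, grid, config.normality_alpha
        )
        nodal_tables[metric] = table
        table.to_csv(out_dir / f"nodal_{metric}.csv")
        n_deg = int(table["degenerate"].sum())
        if n_deg:
            warnings.append(
                f"nodal_{metric}: {n_deg} degenerate region(s) excluded "
                "from the FDR family"
            )

    screen = None
    regression_detail = None
    if expressions:
        cortical = [
            r.label for r in cohort.parcellation.regions
            if r.tissue == "cortical"
        ]
        metrics_by_group = _stage("group_mean_metrics")(
            _group_mean_regional_metrics
        )(cohort, grid)
        screen = _stage("expression_screen")(multi_gene_screen)(
            metrics_by_group, dict(expressions), regions=cortical
        )
        screen.to_csv(out_dir / "expression_screen.csv")

        # influence detail for the top screen cell
        best = screen["p"].idxmin()
        group, gene, metric = best
        fit = fit_expression_regression(
            metrics_by_group[group][metric], expressions[gene], cortical
        )
        flagged = cooks_flags(fit)
        refit = (
            sensitivity_refit(
                metrics_by_group[group][metric], expressions[gene],
                flagged, cortical,
            )
            if flagged and fit.n_obs - len(flagged) >= 3
            else None
        )
        regression_detail = {
            "cell": {"group": group, "gene": gene, "metric": metric},
            "fit": {
                "beta": fit.slope, "r_squared": fit.r_squared,
                "f_stat": fit.f_stat, "df": list(fit.df), "p": fit.p,
            },
            "influential_regions": sorted(flagged),
            "refit": None if refit is None else {
                "beta": refit.slope, "r_squared": refit.r_squared,
                "f_stat": refit.f_stat, "df": list(refit.df), "p": refit.p,
            },
        }
        with open(out_dir / "regression_detail.json", "w") as fh:
            json.dump(regression_detail, fh, indent=2)

    run_log = {
        "strucnet_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "n_pairs": cohort.n_pairs,
        "n_regions": cohort.parcellation.n_regions,
        "genes": sorted(expressions) if expressions else [],
        "warnings": warnings,
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    for w in warnings:
        logger.warning("%s", w)
    logger.info("pipeline done: results in %s", out_dir)

    return PipelineResults(
        edge_class=edge_table,
        global_metrics=global_table,
        nodal=nodal_tables,
        screen=screen,
        regression_detail=regression_detail,
        run_log=run_log,
    )
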