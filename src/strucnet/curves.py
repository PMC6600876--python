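"""Threshold sweeps, area-under-curve reduction and bootstrap intervals.

The streamline-count threshold that defines edge support is arbitrary;
instead of committing to one value, each metric is evaluated over a grid
of thresholds and the trapezoidal area under the resulting curve is the
quantity compared between groups. The default grid is the integer counts
0..20, a required and logged configuration item.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from . import graphmetrics
from .connectome import (
    WeightedNetwork,
    build_weighted_network,
    edge_class_mean_weights,
)
from .errors import ValidationError
from .netgen import Parcellation

__all__ = [
    "ThresholdCurve",
    "DEFAULT_GRID",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
    "threshold_sweep",
    "nodal_threshold_sweep",
    "auc",
    "nodal_auc",
    "bootstrap_median_ci",
]

#: Default streamline-count threshold grid.
DEFAULT_GRID: np.ndarray = np.arange(0.0, 21.0)

#: Named scalar metrics usable in a sweep.
GLOBAL_METRICS: Mapping[str, Callable[[WeightedNetwork], float]] = {
    "mean_degree": lambda net: float(graphmetrics.node_degree(net).mean()),
    "mean_strength": lambda net: float(graphmetrics.node_strength(net).mean()),
    "mean_clustering": lambda net: float(
        graphmetrics.clustering_weighted(net).mean()
    ),
    "global_efficiency": lambda net: graphmetrics.global_efficiency(net),
}

#: Named per-node metrics usable in a nodal sweep.
NODAL_METRICS: Mapping[str, Callable[[WeightedNetwork], np.ndarray]] = {
    "degree": graphmetrics.node_degree,
    "strength": graphmetrics.node_strength,
    "clustering": graphmetrics.clustering_weighted,
    "local_efficiency": graphmetrics.local_efficiency,
}


@dataclass(frozen=True)
class ThresholdCurve:
    """A metric evaluated over a strictly increasing threshold grid."""

    grid: np.ndarray
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if grid.ndim != 1 or len(grid) < 2:
            raise ValidationError("grid needs at least 2 points")
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("grid must be strictly increasing")
        if len(values) != len(grid):
            raise ValidationError("values/grid length mismatch")


def _resolve_metric(metric, parcellation: Parcellation | None):
    if callable(metric):
        return metric, getattr(metric, "__name__", "custom")
    if metric in GLOBAL_METRICS:
        return GLOBAL_METRICS[metric], metric
    if isinstance(metric, str) and metric.startswith("class_mean:"):
        cls = metric.split(":", 1)[1]

        def class_mean(net: WeightedNetwork) -> float:
            return edge_class_mean_weights(net).get(cls, 0.0)

        return class_mean, metric
    raise ValidationError(f"unknown metric {metric!r}")


def threshold_sweep(
    counts: np.ndarray,
    fa: np.ndarray,
    grid: Sequence[float],
    metric,
    parcellation: Parcellation,
    weight_mode: str = "fa",
    **build_kwargs,
) -> ThresholdCurve:
    """Evaluate a scalar metric at every threshold of the grid.

    ``metric`` is a name from :data:`GLOBAL_METRICS`, a string
    ``"class_mean:<edge class>"``, or any callable mapping a
    :class:`WeightedNetwork` to a float.
    """
    grid = np.asarray(grid, dtype=float)
    func, name = _resolve_metric(metric, parcellation)
    values = np.empty(len(grid))
    for t, tau in enumerate(grid):
        net = build_weighted_network(
            counts, fa, tau, parcellation, weight_mode, **build_kwargs
        )
        values[t] = func(net)
    return ThresholdCurve(grid=grid, values=values, metric_name=name)


def nodal_threshold_sweep(
    counts: np.ndarray,
    fa: np.ndarray,
    grid: Sequence[float],
    metric: str,
    parcellation: Parcellation,
    weight_mode: str = "fa",
) -> np.ndarray:
    """Per-node metric over the grid; shape ``(len(grid), n_regions)``."""
    if metric not in NODAL_METRICS:
        raise ValidationError(f"unknown nodal metric {metric!r}")
    grid = np.asarray(grid, dtype=float)
    func = NODAL_METRICS[metric]
    out = np.empty((len(grid), parcellation.n_regions))
    for t, tau in enumerate(grid):
        net = build_weighted_network(counts, fa, tau, parcellation, weight_mode)
        out[t] = func(net)
    return out


def auc(curve: ThresholdCurve) -> float:
    """Trapezoidal area under the curve over its grid.

    Exact for piecewise-linear curves; this is the scalar compared
    between groups in all threshold-sweep statistics.
    """
    return float(np.trapezoid(curve.values, curve.grid))


def nodal_auc(grid: Sequence[float], values: np.ndarray) -> np.ndarray:
    """Trapezoidal AUC per node for a nodal sweep array."""
    return np.trapezoid(np.asarray(values, dtype=float), np.asarray(grid), axis=0)


def bootstrap_median_ci(
    values: Sequence[float],
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval around the median."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValidationError("need at least 2 values to bootstrap")
    if not 0.0 < level < 1.0:
        raise ValidationError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    medians = np.median(vals[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(medians, [alpha, 1.0 - alpha])
    return float(low), float(high)
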