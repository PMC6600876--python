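"""Regression of regional graph metrics on regional gene expression.

Expression tables from multiple postmortem donors are z-scored within
donor (across regions) and averaged; each (group, gene, metric) cell of
the specificity screen is a simple ordinary-least-squares regression of
the regional metric on the normalized expression profile, with an
intercept. Influence is quantified with Cook's distance; flagged regions
are removed in a sensitivity refit. The screen's family-wise Bonferroni
correction uses m = groups x genes x metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .errors import DegenerateDataError, ValidationError
from .netgen import ExpressionProfile

__all__ = [
    "RegressionResult",
    "normalize_expression",
    "fit_expression_regression",
    "cooks_flags",
    "sensitivity_refit",
    "multi_gene_screen",
]


@dataclass(frozen=True)
class RegressionResult:
    """Simple-regression fit with per-observation influence diagnostics."""

    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    f_stat: float
    df: tuple[int, int]
    p: float
    residuals: np.ndarray
    leverage: np.ndarray
    cooks: np.ndarray
    regions: tuple[str, ...]

    @property
    def n_obs(self) -> int:
        return len(self.regions)

    def confint_slope(self, level: float = 0.95) -> tuple[float, float]:
        """t-based confidence interval for the slope."""
        from scipy import stats as _st

        tcrit = _st.t.ppf(0.5 + level / 2, self.df[1])
        return (
            self.slope - tcrit * self.slope_se,
            self.slope + tcrit * self.slope_se,
        )


def _donor_frame(donor_tables) -> pd.DataFrame:
    """Coerce donor input to a (donor x region) wide frame."""
    if isinstance(donor_tables, pd.DataFrame):
        if {"donor", "region", "value"} <= set(donor_tables.columns):
            wide = donor_tables.pivot(
                index="donor", columns="region", values="value"
            )
        else:
            wide = donor_tables.copy()
    elif isinstance(donor_tables, Mapping):
        wide = pd.DataFrame(
            {donor: pd.Series(vals) for donor, vals in donor_tables.items()}
        ).T
    else:
        raise ValidationError("unsupported donor table input")
    if wide.empty:
        raise ValidationError("need at least one donor")
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValidationError(f"regions missing for some donor: {missing}")
    return wide


def normalize_expression(donor_tables, gene: str = "GENE") -> ExpressionProfile:
    """Standardize each donor's regional values, then average across donors.

    Within each donor the regional expression vector is z-scored (zero
    mean, unit sample variance across regions), removing donor-specific
    scale and offset; the standardized profiles are then averaged region
    by region. Input is either ``{donor: {region: value}}``, a wide
    (donor x region) frame, or a long frame with columns
    ``donor, region, value``.
    """
    wide = _donor_frame(donor_tables)
    sds = wide.std(axis=1, ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0].tolist()
        raise DegenerateDataError(f"zero-variance donor(s): {bad}")
    z = wide.sub(wide.mean(axis=1), axis=0).div(sds, axis=0)
    mean = z.mean(axis=0)
    return ExpressionProfile(
        gene=gene,
        labels=tuple(mean.index),
        values=mean.to_numpy(),
        donor_count=wide.shape[0],
    )


def _align(metric_by_region, expression: ExpressionProfile,
           regions: Sequence[str] | None):
    if isinstance(metric_by_region, pd.Series):
        y_map = metric_by_region
    elif isinstance(metric_by_region, Mapping):
        y_map = pd.Series(metric_by_region)
    else:
        arr = np.asarray(metric_by_region, dtype=float)
        if len(arr) != len(expression.labels):
            raise ValidationError(
                "array metric input must align with expression labels"
            )
        y_map = pd.Series(arr, index=list(expression.labels))
    expr_map = pd.Series(expression.values, index=list(expression.labels))
    if regions is None:
        regions = [lab for lab in expression.labels if lab in y_map.index]
    else:
        missing = [r for r in regions if r not in y_map.index
                   or r not in expr_map.index]
        if missing:
            raise ValidationError(f"regions missing from inputs: {missing}")
    y = y_map.loc[list(regions)].to_numpy(dtype=float)
    x = expr_map.loc[list(regions)].to_numpy(dtype=float)
    return x, y, tuple(regions)


def fit_expression_regression(
    metric_by_region,
    expression: ExpressionProfile,
    regions: Sequence[str] | None = None,
) -> RegressionResult:
    """OLS fit of a regional graph metric on normalized expression.

    ``metric = slope * expression + intercept``; F has df (1, n - 2).
    Residuals, leverages and Cook's distances are populated for every
    observation. ``regions`` restricts the fit (e.g. to cortical
    regions, the default scope of atlas expression maps, chosen by the
    caller).
    """
    x, y, used = _align(metric_by_region, expression, regions)
    n = len(used)
    if n < 3:
        raise ValidationError("need at least 3 regions to fit")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant predictor")
    if np.ptp(y) == 0:
        raise DegenerateDataError("constant outcome")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    infl = OLSInfluence(model)
    leverage = infl.hat_matrix_diag
    if model.ssr <= 1e-14 * max(model.centered_tss, 1.0):
        # numerically perfect fit: no observation influences it
        cooks = np.zeros_like(leverage)
    else:
        cooks = infl.cooks_distance[0]
        cooks = np.where(np.isclose(leverage, 1.0), np.inf, cooks)
    return RegressionResult(
        slope=float(model.params[1]),
        slope_se=float(model.bse[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_stat=float(model.fvalue),
        df=(1, n - 2),
        p=float(model.f_pvalue),
        residuals=np.asarray(model.resid),
        leverage=np.asarray(leverage),
        cooks=np.asarray(cooks),
        regions=used,
    )


def cooks_flags(
    result: RegressionResult,
    cutoff_rule="four_over_n",
) -> frozenset[str]:
    """Regions whose Cook's distance exceeds the influence cutoff.

    ``cutoff_rule`` is the conventional ``"four_over_n"`` (cutoff
    ``4 / n_obs``) or a fixed numeric cutoff. Exact leverage points
    (h = 1) carry infinite distance and are always flagged.
    """
    if cutoff_rule == "four_over_n":
        cutoff = 4.0 / result.n_obs
    else:
        cutoff = float(cutoff_rule)
        if cutoff <= 0:
            raise ValidationError("cutoff must be positive")
    return frozenset(
        region
        for region, c in zip(result.regions, result.cooks)
        if c > cutoff
    )


def sensitivity_refit(
    metric_by_region,
    expression: ExpressionProfile,
    excluded: Iterable[str],
    regions: Sequence[str] | None = None,
) -> RegressionResult:
    """Re-fit the regression with the given regions removed.

    The residual degrees of freedom shrink by the number of exclusions:
    n regions in, k excluded -> F df (1, n - k - 2).
    """
    excluded = set(excluded)
    _, _, all_regions = _align(metric_by_region, expression, regions)
    keep = [r for r in all_regions if r not in excluded]
    if len(keep) < 3:
        raise ValidationError("fewer than 3 regions remain after exclusion")
    return fit_expression_regression(metric_by_region, expression, keep)


def multi_gene_screen(
    metrics_by_group: Mapping[str, Mapping[str, object]],
    expressions: Mapping[str, ExpressionProfile],
    regions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One regression per (group, gene, metric) cell, Bonferroni-corrected.

    The family size is ``m = n_groups * n_genes * n_metrics`` — e.g. a
    2-group, 5-gene, 4-metric screen corrects with m = 40 — applied to
    every cell's p-value.
    """
    if not metrics_by_group or not expressions:
        raise ValidationError("need at least one group, metric and gene")
    n_metrics = {len(m) for m in metrics_by_group.values()}
    if len(n_metrics) != 1 or 0 in n_metrics:
        raise ValidationError("every group must provide the same metrics")
    m_family = (
        len(metrics_by_group) * len(expressions) * n_metrics.pop()
    )
    rows = []
    for group, metric_tables in metrics_by_group.items():
        for metric, table in metric_tables.items():
            for gene, profile in expressions.items():
                fit = fit_expression_regression(table, profile, regions)
                rows.append(
                    {
                        "group": group,
                        "gene": gene,
                        "metric": metric,
                        "beta": fit.slope,
                        "r_squared": fit.r_squared,
                        "f_stat": fit.f_stat,
                        "df1": fit.df[0],
                        "df2": fit.df[1],
                        "p": fit.p,
                        "p_bonf": min(1.0, m_family * fit.p),
                    }
                )
    out = pd.DataFrame(rows).set_index(["group", "gene", "metric"])
    out.attrs["bonferroni_m"] = m_family
    return out
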