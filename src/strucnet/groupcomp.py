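"""Group statistics: paired tests, multiplicity control, and the
edge-class / global / nodal comparisons assembled from them.

The cohort design is age-matched pairs, so the primary comparison is the
paired-sample t-test on per-subject AUC-over-thresholds values, screened
for normality with Shapiro-Wilk. Family-wise corrections: Bonferroni
across the four edge classes and across the four global metrics;
Benjamini-Hochberg FDR across regions for nodal comparisons. Regions
whose paired differences fail the normality screen are flagged — and
excluded from significance claims — rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import graphmetrics
from .connectome import EDGE_CLASSES, edge_class_matrix
from .curves import DEFAULT_GRID
from .errors import DegenerateDataError, ValidationError
from .netgen import Cohort

__all__ = [
    "TestResult",
    "paired_t",
    "welch_t",
    "wilcoxon_signed_rank",
    "shapiro_wilk",
    "fdr_bh",
    "bonferroni",
    "edge_class_comparison",
    "global_group_comparison",
    "nodal_group_comparison",
    "GLOBAL_COMPARISON_METRICS",
    "NODAL_COMPARISON_METRICS",
]

GLOBAL_COMPARISON_METRICS = (
    "mean_degree",
    "mean_strength",
    "mean_clustering",
    "global_efficiency",
)

NODAL_COMPARISON_METRICS = (
    "degree",
    "strength",
    "clustering",
    "local_efficiency",
)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p: float
    test_name: str
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"p-value {self.p} outside [0, 1]")
        if self.df is not None and self.df <= 0:
            raise ValidationError("df must be positive when present")


def paired_t(x, y) -> TestResult:
    """Two-sided paired t-test on differences ``d = y - x``.

    Positive statistic means ``y`` tends to exceed ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 2:
        raise ValidationError("paired t-test needs at least 2 pairs")
    d = y - x
    if np.std(d, ddof=1) == 0:
        raise DegenerateDataError("paired differences have zero variance")
    res = stats.ttest_rel(y, x)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        df=float(n - 1),
        test_name="paired t",
    )


def welch_t(x, y) -> TestResult:
    """Two-sided Welch t-test (unequal variances), Welch-Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("Welch t-test needs >= 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise DegenerateDataError("both samples have zero variance")
    res = stats.ttest_ind(y, x, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        df=float(res.df),
        test_name="Welch t",
    )


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on pairs ``(x_i, y_i)``.

    Zero differences are discarded; the statistic is the smaller of the
    two signed-rank sums. The exact null distribution is used for
    n <= 25 without ties, the normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = y - x
    d = d[d != 0]
    if len(d) < 2:
        raise DegenerateDataError(
            "fewer than 2 nonzero differences for signed-rank test"
        )
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        test_name="Wilcoxon signed-rank",
    )


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValidationError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant sample has no normality test")
    res = stats.shapiro(x)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        test_name="Shapiro-Wilk",
    )


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)``, capped at 1; order
    preserving, so sorting by p sorts by q non-decreasingly.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvals must be 1-d")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value, ``min(1, m * p)``."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError("p must lie in [0, 1]")
    if m < 1:
        raise ValidationError("family size m must be >= 1")
    return min(1.0, m * p)


# ---------------------------------------------------------------------------
# assembled comparisons


def _triu_flat(matrix: np.ndarray, iu) -> np.ndarray:
    return np.asarray(matrix, dtype=float)[iu]


def _shapiro_or_nan(values: np.ndarray) -> tuple[float, float]:
    try:
        res = shapiro_wilk(values)
        return res.statistic, res.p
    except (DegenerateDataError, ValidationError):
        return float("nan"), float("nan")


def _group_columns(case: np.ndarray, control: np.ndarray) -> dict:
    n = len(case)
    return {
        "case_mean": case.mean(),
        "case_se": case.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
        "control_mean": control.mean(),
        "control_se": control.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
    }


def _class_auc_per_subject(
    cohort: Cohort, grid: np.ndarray, weight_mode: str
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """AUC of the class-mean-weight curve, per class and subject group."""
    parc = cohort.parcellation
    iu = np.triu_indices(parc.n_regions, k=1)
    class_flat = edge_class_matrix(parc)[iu]
    selectors = {
        cls: class_flat == cls
        for cls in EDGE_CLASSES
        if np.any(class_flat == cls)
    }

    def subject_auc(subject) -> dict[str, float]:
        counts = _triu_flat(subject.count_matrix, iu)
        if weight_mode == "fa":
            w = _triu_flat(subject.fa_matrix, iu)
        elif weight_mode == "count":
            w = counts
        else:
            raise ValidationError(
                f"edge-class comparison supports fa/count, not {weight_mode!r}"
            )
        masked = (counts[None, :] > grid[:, None]) * w[None, :]
        out = {}
        for cls, sel in selectors.items():
            curve = masked[:, sel].sum(axis=1) / sel.sum()
            out[cls] = float(np.trapezoid(curve, grid))
        return out

    case_rows = [subject_auc(p.case) for p in cohort.pairs]
    ctrl_rows = [subject_auc(p.control) for p in cohort.pairs]
    return {
        cls: (
            np.array([r[cls] for r in case_rows]),
            np.array([r[cls] for r in ctrl_rows]),
        )
        for cls in selectors
    }


def edge_class_comparison(
    cohort: Cohort,
    grid=DEFAULT_GRID,
    weight_mode: str = "fa",
) -> pd.DataFrame:
    """Paired comparison of mean edge weight per anatomical class.

    Per subject and class, the class-mean weight (zeros included for
    absent pairs) is swept over the threshold grid and reduced to its
    AUC; classes are then compared with a paired t-test and Bonferroni
    correction over the four classes.
    """
    if cohort.n_pairs < 2:
        raise ValidationError("need at least 2 pairs")
    grid = np.asarray(grid, dtype=float)
    per_class = _class_auc_per_subject(cohort, grid, weight_mode)
    m = len(per_class)
    rows = []
    for cls, (case_auc, ctrl_auc) in per_class.items():
        res = paired_t(case_auc, ctrl_auc)  # raises DegenerateDataError
        row = {"edge_class": cls, **_group_columns(case_auc, ctrl_auc)}
        row["case_shapiro_w"], row["case_shapiro_p"] = _shapiro_or_nan(case_auc)
        row["control_shapiro_w"], row["control_shapiro_p"] = _shapiro_or_nan(
            ctrl_auc
        )
        row.update(t=res.statistic, df=res.df, p=res.p, p_bonf=bonferroni(res.p, m))
        rows.append(row)
    return pd.DataFrame(rows).set_index("edge_class")


def _mean_clustering_and_efficiency(w: np.ndarray) -> tuple[float, float]:
    return (
        float(graphmetrics.clustering_weighted(w).mean()),
        graphmetrics.global_efficiency(w),
    )


def global_group_comparison(
    cohort: Cohort,
    grid=DEFAULT_GRID,
    consensus: bool = True,
    consensus_scope: str = "joint",
) -> pd.DataFrame:
    """Paired comparison of the four global FA-network metrics.

    Mean degree and mean strength are compared on native (per-subject
    thresholded) networks. Mean clustering and global efficiency are
    density-sensitive, so with ``consensus=True`` they are computed on
    consensus-masked networks: at each grid threshold, only edges
    present in every subject's thresholded network are retained
    (``consensus_scope="joint"``, the default) or in every subject of
    the same group (``"per_group"``). Each metric's per-subject curve is
    reduced to its AUC and compared with a paired t-test,
    Bonferroni-corrected over the four metrics.
    """
    if cohort.n_pairs < 2:
        raise ValidationError("need at least 2 pairs")
    if consensus_scope not in ("joint", "per_group"):
        raise ValidationError(f"unknown consensus_scope {consensus_scope!r}")
    grid = np.asarray(grid, dtype=float)
    subjects = cohort.subjects
    n = cohort.parcellation.n_regions
    counts = np.stack([s.count_matrix for s in subjects])
    fas = np.stack([s.fa_matrix for s in subjects])
    n_subj = len(subjects)
    is_case = np.arange(n_subj) % 2 == 0  # subjects alternate case/control

    # curves: (metric, subject, threshold)
    curves = {name: np.empty((n_subj, len(grid))) for name in
              GLOBAL_COMPARISON_METRICS}
    for t, tau in enumerate(grid):
        masks = counts > tau  # (n_subj, n, n)
        curves["mean_degree"][:, t] = masks.sum(axis=(1, 2)) / n
        curves["mean_strength"][:, t] = (masks * fas).sum(axis=(1, 2)) / n
        if not consensus:
            group_mask = [None] * n_subj
        elif consensus_scope == "joint":
            cmask = masks.all(axis=0)
            group_mask = [cmask] * n_subj
        else:
            case_mask = masks[is_case].all(axis=0)
            ctrl_mask = masks[~is_case].all(axis=0)
            group_mask = [
                case_mask if is_case[s] else ctrl_mask for s in range(n_subj)
            ]
        for s in range(n_subj):
            w = fas[s] * (masks[s] if group_mask[s] is None else group_mask[s])
            clust, eff = _mean_clustering_and_efficiency(w)
            curves["mean_clustering"][s, t] = clust
            curves["global_efficiency"][s, t] = eff

    aucs = {
        name: np.trapezoid(vals, grid, axis=1)
        for name, vals in curves.items()
    }
    case_idx = np.arange(0, n_subj, 2)
    ctrl_idx = case_idx + 1
    rows = []
    for name in GLOBAL_COMPARISON_METRICS:
        case_auc, ctrl_auc = aucs[name][case_idx], aucs[name][ctrl_idx]
        res = paired_t(case_auc, ctrl_auc)
        row = {"metric": name, **_group_columns(case_auc, ctrl_auc)}
        row["case_shapiro_w"], row["case_shapiro_p"] = _shapiro_or_nan(case_auc)
        row["control_shapiro_w"], row["control_shapiro_p"] = _shapiro_or_nan(
            ctrl_auc
        )
        row.update(
            t=res.statistic,
            df=res.df,
            p=res.p,
            p_bonf=bonferroni(res.p, len(GLOBAL_COMPARISON_METRICS)),
            consensus=consensus and name in ("mean_clustering",
                                             "global_efficiency"),
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")


def _nodal_auc_per_subject(
    cohort: Cohort, metric: str, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region AUC arrays of shape (n_pairs, n_regions) for each group."""
    parc = cohort.parcellation
    n = parc.n_regions

    def sweep(subject) -> np.ndarray:
        counts, fa = subject.count_matrix, subject.fa_matrix
        if metric == "degree":
            vals = (counts[None, :, :] > grid[:, None, None]).sum(axis=2)
        elif metric == "strength":
            masks = counts[None, :, :] > grid[:, None, None]
            vals = (masks * fa[None, :, :]).sum(axis=2)
        else:
            func = {
                "clustering": graphmetrics.clustering_weighted,
                "local_efficiency": graphmetrics.local_efficiency,
            }[metric]
            vals = np.empty((len(grid), n))
            for t, tau in enumerate(grid):
                vals[t] = func(fa * (counts > tau))
        return np.trapezoid(vals, grid, axis=0)

    case = np.stack([sweep(p.case) for p in cohort.pairs])
    ctrl = np.stack([sweep(p.control) for p in cohort.pairs])
    return case, ctrl


def nodal_group_comparison(
    cohort: Cohort,
    metric: str = "degree",
    grid=DEFAULT_GRID,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Region-by-region paired comparison of one nodal metric.

    Per subject and region the metric is swept over the threshold grid
    and reduced to its AUC. Per region: Shapiro-Wilk screens each
    group's values at ``normality_alpha``; a paired t-test compares the
    groups; Benjamini-Hochberg FDR adjusts p-values across all
    non-degenerate regions. Regions with zero-variance paired
    differences are marked ``degenerate`` and excluded from the FDR
    family; regions failing the normality screen keep their statistics
    but have ``normality_ok = False`` and should not ground
    significance claims.
    """
    if metric not in NODAL_COMPARISON_METRICS:
        raise ValidationError(f"unknown nodal metric {metric!r}")
    if cohort.n_pairs < 2:
        raise ValidationError("need at least 2 pairs")
    grid = np.asarray(grid, dtype=float)
    case, ctrl = _nodal_auc_per_subject(cohort, metric, grid)
    labels = cohort.parcellation.labels
    rows = []
    for r, label in enumerate(labels):
        ca, co = case[:, r], ctrl[:, r]
        row = {"region": label, **_group_columns(ca, co)}
        row["case_shapiro_w"], row["case_shapiro_p"] = _shapiro_or_nan(ca)
        row["control_shapiro_w"], row["control_shapiro_p"] = _shapiro_or_nan(co)
        d = co - ca
        if np.std(d, ddof=1) == 0:
            row.update(t=np.nan, p=np.nan, degenerate=True)
        else:
            res = paired_t(ca, co)
            row.update(t=res.statistic, p=res.p, degenerate=False)
        shapiro_ps = (row["case_shapiro_p"], row["control_shapiro_p"])
        row["normality_ok"] = bool(
            all(np.isfinite(sp) and sp > normality_alpha for sp in shapiro_ps)
        )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("region")
    table["q"] = np.nan
    valid = ~table["degenerate"]
    if valid.any():
        table.loc[valid, "q"] = fdr_bh(table.loc[valid, "p"].to_numpy())
    return table
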