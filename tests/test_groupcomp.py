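"""Paired statistics, multiplicity control and assembled comparisons."""

import numpy as np
import pytest
from scipy import stats

import _oracles as oracle
from strucnet import (
    DegenerateDataError,
    SyntheticSpec,
    ValidationError,
    bonferroni,
    edge_class_comparison,
    fdr_bh,
    generate_cohort,
    generate_expression_map,
    global_group_comparison,
    nodal_group_comparison,
    paired_t,
    shapiro_wilk,
    welch_t,
    wilcoxon_signed_rank,
)


class TestPairedT:
    def test_zero_differences_are_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7])
        y = np.array([2.0, 2, 5, 5, 6, 6, 9])
        res = paired_t(x, y)
        d = y - x
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_manual = 2 * stats.t.sf(abs(t_manual), len(d) - 1)
        assert res.statistic == pytest.approx(t_manual)
        assert res.statistic == pytest.approx(np.sqrt(10.5))
        assert res.df == 6
        assert res.p == pytest.approx(p_manual)

    def test_swapping_arguments_negates_t(self, rng):
        x, y = rng.normal(size=7), rng.normal(size=7)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)


class TestWelchT:
    def test_identical_samples_give_zero_t_unit_p(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = welch_t(x, x)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_pooled_limit_df(self, rng):
        # equal variances and sizes: Welch df reduces to 2n - 2
        x = rng.normal(size=12)
        y = x + 0.3  # same sample variance
        res = welch_t(x, y)
        assert res.df == pytest.approx(2 * 12 - 2)

    def test_matches_welch_satterthwaite_formulas(self, rng):
        x = rng.normal(0, 1.0, 9)
        y = rng.normal(0.4, 2.0, 14)
        res = welch_t(x, y)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_manual = (y.mean() - x.mean()) / np.sqrt(vx + vy)
        df_manual = (vx + vy) ** 2 / (
            vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1)
        )
        assert res.statistic == pytest.approx(t_manual)
        assert res.df == pytest.approx(df_manual)
        assert res.p == pytest.approx(
            2 * stats.t.sf(abs(t_manual), df_manual)
        )


class TestWilcoxon:
    def test_zero_differences_removed(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.0, 3, 5, 7, 10])  # first pair drops out, n -> 4
        res = wilcoxon_signed_rank(x, y)
        w_manual, p_manual = oracle.wilcoxon_exact_oracle(y - x)
        assert res.statistic == w_manual
        assert res.p == pytest.approx(p_manual)

    def test_seven_positive_differences_exact_tail(self):
        x = np.zeros(7)
        y = np.array([1.0, 2, 3, 4, 5, 6, 7])
        res = wilcoxon_signed_rank(x, y)
        assert res.statistic == 0
        assert res.p == pytest.approx(2 / 2**7)

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_exact_p_equals_sign_pattern_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            d = rng.normal(0.3, 1.0, n)
            d = np.where(d == 0, 0.1, d)
            # avoid ties in |d| so the exact method applies
            d += rng.uniform(0, 1e-6, n) * np.sign(d)
            res = wilcoxon_signed_rank(np.zeros(n), d)
            w_manual, p_manual = oracle.wilcoxon_exact_oracle(d)
            assert res.statistic == w_manual
            assert res.p == pytest.approx(p_manual, abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestShapiroWilk:
    def test_normal_quantile_sample_scores_near_one(self):
        x = stats.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        res = shapiro_wilk(x)
        assert res.statistic > 0.99

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk([2.0, 2.0, 2.0, 2.0])

    def test_size_limits(self):
        with pytest.raises(ValidationError):
            shapiro_wilk([1.0, 2.0])


class TestFdrBh:
    def test_all_equal_pvalues_unchanged(self):
        q = fdr_bh([0.03, 0.03, 0.03])
        assert np.allclose(q, 0.03)

    def test_single_pvalue_identity(self):
        assert fdr_bh([0.2])[0] == pytest.approx(0.2)

    def test_hand_worked_stepup(self):
        q = fdr_bh([0.01, 0.02, 0.03, 0.20])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.20])

    def test_monotone_and_dominates_raw(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            q = fdr_bh(p)
            assert np.all(q >= p - 1e-15)
            assert np.all((q >= 0) & (q <= 1))
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_independent_stepup_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(0, 1, int(rng.integers(1, 60)))
            assert np.allclose(fdr_bh(p), oracle.bh_stepup_oracle(p),
                               atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_bh([0.5, 1.2])


class TestBonferroni:
    def test_scales_and_caps(self):
        assert bonferroni(0.01, 40) == pytest.approx(0.4)
        assert bonferroni(0.1, 40) == 1.0

    def test_family_of_forty_matches_published_correction_scale(self):
        # 2 groups x 5 genes x 4 metrics = 40 comparisons
        assert bonferroni(0.022, 2 * 5 * 4) == pytest.approx(0.88)


@pytest.fixture(scope="module")
def planted_cohort(parc_small):
    expr = generate_expression_map(parc_small, seed=21)
    spec = SyntheticSpec(
        n_pairs=5, density=0.6, global_attenuation=0.6,
        expression_coupling=0.0, subject_noise_sd=0.03, seed=21,
    )
    return generate_cohort(parc_small, expr, spec)


GRID = np.arange(0.0, 16.0, 3.0)


class TestEdgeClassComparison:
    def test_noise_free_null_cohort_is_degenerate(self, parc_small):
        expr = generate_expression_map(parc_small, seed=9)
        spec = SyntheticSpec(
            n_pairs=3, global_attenuation=1.0, expression_coupling=0.0,
            subject_noise_sd=0.0, seed=9,
        )
        cohort = generate_cohort(parc_small, expr, spec)
        with pytest.raises(DegenerateDataError):
            edge_class_comparison(cohort, GRID)

    def test_hand_built_two_pair_cohort_auc(self, parc_small):
        from strucnet.connectome import edge_class_matrix
        from strucnet.netgen import Cohort, Subject, SubjectPair

        n = parc_small.n_regions
        rng = np.random.default_rng(5)

        def subject(sid):
            c = np.round(rng.uniform(0, 10, (n, n)))
            c = np.triu(c, 1)
            c = c + c.T
            f = np.triu(rng.uniform(0.1, 0.9, (n, n)), 1)
            f = f + f.T
            f[c == 0] = 0.0
            return Subject(sid, 20.0, c, f)

        pairs = tuple(
            SubjectPair(case=subject(f"a{i}"), control=subject(f"b{i}"))
            for i in range(2)
        )
        cohort = Cohort(pairs=pairs, parcellation=parc_small)
        table = edge_class_comparison(cohort, GRID)
        # manual recomputation for one class and the case group
        classes = edge_class_matrix(parc_small)
        iu = np.triu_indices(n, k=1)
        sel = classes[iu] == "left"
        manual = []
        for pair in pairs:
            cflat = pair.case.count_matrix[iu]
            fflat = pair.case.fa_matrix[iu]
            curve = [
                ((cflat > tau) * fflat)[sel].sum() / sel.sum() for tau in GRID
            ]
            manual.append(np.trapezoid(curve, GRID))
        assert table.loc["left", "case_mean"] == pytest.approx(
            np.mean(manual)
        )

    def test_planted_attenuation_detected_in_every_class(
        self, planted_cohort
    ):
        table = edge_class_comparison(planted_cohort, GRID)
        assert set(table.index) == {
            "subcortical", "left", "right", "interhemispheric"
        }
        assert (table["t"] > 0).all()  # control exceeds case everywhere
        assert (table["p_bonf"] < 0.05).all()
        assert (table["case_mean"] < table["control_mean"]).all()


class TestGlobalComparison:
    def test_consensus_flag_changes_only_density_sensitive_metrics(
        self, planted_cohort
    ):
        on = global_group_comparison(planted_cohort, GRID, consensus=True)
        off = global_group_comparison(planted_cohort, GRID, consensus=False)
        for metric in ("mean_degree", "mean_strength"):
            assert on.loc[metric, "case_mean"] == pytest.approx(
                off.loc[metric, "case_mean"]
            )
            assert on.loc[metric, "p"] == pytest.approx(off.loc[metric, "p"])
        for metric in ("mean_clustering", "global_efficiency"):
            assert on.loc[metric, "case_mean"] != pytest.approx(
                off.loc[metric, "case_mean"]
            )

    def test_per_group_consensus_scope_runs_and_differs(self, planted_cohort):
        joint = global_group_comparison(
            planted_cohort, GRID, consensus_scope="joint"
        )
        per_group = global_group_comparison(
            planted_cohort, GRID, consensus_scope="per_group"
        )
        # the control-group consensus mask is larger than the joint one,
        # so the control-side values must change
        assert not np.allclose(
            joint.loc["mean_clustering", "control_mean"],
            per_group.loc["mean_clustering", "control_mean"],
        )

    def test_scale_sensitive_metrics_reduced_under_planted_attenuation(
        self, planted_cohort
    ):
        # normalized clustering is invariant to a pure global rescaling,
        # so on a tiny parcellation only the scale-sensitive metrics are
        # guaranteed to detect the attenuation; clustering must at least
        # never report a significant case-side increase
        table = global_group_comparison(planted_cohort, GRID)
        for metric in ("mean_degree", "mean_strength", "global_efficiency"):
            assert table.loc[metric, "t"] > 0
            assert table.loc[metric, "p_bonf"] < 0.05
        clust = table.loc["mean_clustering"]
        assert not (clust["p"] < 0.05 and clust["t"] < 0)


class TestNodalComparison:
    def test_table_covers_all_regions_with_q_dominating_p(
        self, planted_cohort
    ):
        table = nodal_group_comparison(planted_cohort, "degree", GRID)
        assert len(table) == planted_cohort.parcellation.n_regions
        valid = ~table["degenerate"]
        assert np.all(
            table.loc[valid, "q"] >= table.loc[valid, "p"] - 1e-15
        )

    def test_region_without_edges_flagged_degenerate(self, parc_small):
        expr = generate_expression_map(parc_small, seed=31)
        spec = SyntheticSpec(n_pairs=4, density=0.6, seed=31)
        cohort = generate_cohort(parc_small, expr, spec)
        # disconnect region 0 in every subject: its degree AUC is 0
        # in both groups, a zero-variance difference
        for pair in cohort.pairs:
            for subj in (pair.case, pair.control):
                subj.count_matrix[0, :] = subj.count_matrix[:, 0] = 0
                subj.fa_matrix[0, :] = subj.fa_matrix[:, 0] = 0
        table = nodal_group_comparison(cohort, "degree", GRID)
        first = table.iloc[0]
        assert bool(first["degenerate"])
        assert np.isnan(first["q"])
        # remaining family still adjusted
        assert table.loc[~table["degenerate"], "q"].notna().all()

    def test_no_region_reports_case_above_control_under_attenuation(
        self, planted_cohort
    ):
        for metric in ("degree", "strength"):
            table = nodal_group_comparison(planted_cohort, metric, GRID)
            significant = table[(table["q"] < 0.05) & ~table["degenerate"]]
            assert (significant["t"] > 0).all()

    def test_clustering_and_local_efficiency_metrics_run(
        self, planted_cohort
    ):
        short_grid = np.array([0.0, 5.0, 10.0])
        for metric in ("clustering", "local_efficiency"):
            table = nodal_group_comparison(planted_cohort, metric, short_grid)
            assert table["p"].notna().any()

    def test_unknown_metric_rejected(self, planted_cohort):
        with pytest.raises(ValidationError):
            nodal_group_comparison(planted_cohort, "betweenness", GRID)
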