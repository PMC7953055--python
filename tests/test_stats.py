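"""Closed-form, oracle and property checks for the statistical kernel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from langnet.stats import (
    ContingencyTable,
    DegenerateDataError,
    GroupSummary,
    anova_oneway_raw,
    anova_oneway_summary,
    bh_fdr,
    chi_square_independence,
    fisher_z,
    inverse_fisher_z,
    mixed_anova_main_within,
    paired_t,
    pearson_corr,
    tukey_hsd,
    two_sample_t,
)


class TestFisherZ:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.0, 0.0), (0.5, 0.54931), (0.9, 1.47222), (-0.5, -0.54931)],
    )
    def test_closed_form(self, r, expected):
        assert fisher_z(r) == pytest.approx(expected, abs=1e-5)

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=50, derandomize=True)
    def test_odd_and_invertible(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)
        assert inverse_fisher_z(fisher_z(r)) == pytest.approx(r, abs=1e-9)

    def test_strictly_increasing(self):
        rs = np.linspace(-0.99, 0.99, 101)
        assert np.all(np.diff(fisher_z(rs)) > 0)

    def test_domain_error_names_edge(self):
        with pytest.raises(ValueError, match="lIFG--rIFG"):
            fisher_z(1.0, label="lIFG--rIFG")


class TestTwoSampleT:
    def test_identical_samples_statistic_zero(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.df == 4

    def test_hand_formula_on_shifted_triplets(self):
        # means 2 and 3, each var 1 -> pooled se = sqrt(2/3), t = -sqrt(3/2)
        res = two_sample_t([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-np.sqrt(1.5), abs=1e-12)
        assert res.df == 4

    def test_matches_scipy_pooled_and_welch(self, rng):
        a, b = rng.normal(size=20), rng.normal(0.4, 1.3, size=25)
        for equal_var in (True, False):
            ours = two_sample_t(a, b, equal_var=equal_var)
            ref = sps.ttest_ind(a, b, equal_var=equal_var)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_one_tailed_reduction_direction(self, rng):
        a = rng.normal(-1.0, 1.0, size=30)
        b = rng.normal(0.0, 1.0, size=30)
        res = two_sample_t(a, b, tail="less")
        assert res.p < 0.05  # a below b is evidence in the tested direction
        assert two_sample_t(b, a, tail="less").p > 0.5

    def test_null_pvalues_uniform(self):
        gen = np.random.default_rng(123)
        ps = [
            two_sample_t(gen.normal(size=40), gen.normal(size=40)).p
            for _ in range(2000)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_constant_samples(self):
        res = two_sample_t([2.0, 2.0], [2.0, 2.0], tail="less")
        assert res.statistic == 0.0 and res.p == pytest.approx(0.5)
        with pytest.raises(DegenerateDataError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])


class TestPairedT:
    def test_equal_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.df == 2

    def test_constant_nonzero_differences_signalled(self):
        with pytest.raises(DegenerateDataError):
            paired_t([2, 3, 4, 5], [1, 2, 3, 4])

    def test_equals_one_sample_t_on_differences(self, rng):
        a = rng.normal(size=15)
        b = a + rng.normal(0.3, 0.5, size=15)
        ours = paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-10)


class TestAnova:
    def test_identical_groups_f_zero(self):
        res = anova_oneway_raw([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.statistic == 0.0

    def test_matches_scipy(self, rng):
        groups = [rng.normal(m, 1.0, size=n) for m, n in [(0, 10), (0.5, 14), (1, 8)]]
        ours = anova_oneway_raw(groups)
        ref = sps.f_oneway(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_summary_equals_raw_on_exact_summaries(self, rng):
        groups = [rng.normal(m, 1.0, size=n) for m, n in [(0, 9), (0.7, 12), (1, 7)]]
        summary = GroupSummary(
            means=tuple(float(np.mean(g)) for g in groups),
            sds=tuple(float(np.std(g, ddof=1)) for g in groups),
            sizes=tuple(len(g) for g in groups),
        )
        raw = anova_oneway_raw(groups)
        summ = anova_oneway_summary(summary)
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-10)
        assert summ.df == raw.df

    def test_f_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.normal(size=12), rng.normal(0.5, 1.0, size=9)
        f = anova_oneway_raw([a, b])
        t = two_sample_t(a, b)
        assert f.statistic == pytest.approx(t.statistic**2, abs=1e-10)

    def test_equal_means_any_sds_f_zero(self):
        res = anova_oneway_summary(
            GroupSummary(means=(5.0, 5.0, 5.0), sds=(1.0, 2.0, 3.0), sizes=(5, 7, 9))
        )
        assert res.statistic == 0.0

    def test_all_constant_degenerate(self):
        with pytest.raises(DegenerateDataError):
            anova_oneway_raw([[1, 1, 1], [2, 2, 2]])


class TestTukey:
    def test_identical_groups_p_near_one(self):
        res = tukey_hsd([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        assert res[0].p > 0.999

    def test_only_shifted_group_significant(self, rng):
        groups = [
            rng.normal(0, 1, 20),
            rng.normal(0, 1, 20),
            rng.normal(8, 1, 20),
        ]
        res = {tuple(r.extra["pair"]): r for r in tukey_hsd(groups)}
        assert res[("g0", "g2")].extra["reject"]
        assert res[("g1", "g2")].extra["reject"]
        assert not res[("g0", "g1")].extra["reject"]

    def test_matches_scipy_tukey(self, rng):
        groups = [rng.normal(m, 1.0, size=12) for m in (0.0, 0.6, 1.0)]
        ours = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        for r in ours:
            i = int(r.extra["pair"][0][1])
            j = int(r.extra["pair"][1][1])
            assert r.p == pytest.approx(ref.pvalue[i, j], abs=1e-4)

    def test_two_group_case_consistent_with_t(self, rng):
        # balanced 2-group Tukey decision == two-sample t decision
        a, b = rng.normal(size=15), rng.normal(0.9, 1.0, size=15)
        tk = tukey_hsd([a, b])[0]
        tt = two_sample_t(a, b)
        assert tk.p == pytest.approx(tt.p, abs=1e-4)
        # q = sqrt(2) |t| in the balanced 2-group limit
        assert tk.statistic == pytest.approx(np.sqrt(2) * abs(tt.statistic), rel=1e-10)


class TestMixedAnova:
    def test_identical_levels_f_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        group = np.array(["x", "x", "y", "y"])
        res = mixed_anova_main_within(a, a, group)
        assert res.statistic == 0.0

    def test_single_group_equals_paired_t_squared(self, rng):
        a = rng.normal(size=12)
        b = a + rng.normal(0.4, 0.6, size=12)
        mixed = mixed_anova_main_within(a, b, np.zeros(12))
        pt = paired_t(a, b)
        assert mixed.statistic == pytest.approx(pt.statistic**2, abs=1e-10)
        assert mixed.df == (1.0, 11.0)

    def test_matches_pingouin_balanced(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        n, k = 12, 3
        rows = []
        for g in range(k):
            for s in range(n):
                sid = f"{g}_{s}"
                base = rng.normal()
                rows.append({"subject": sid, "group": g, "side": "a",
                             "y": base + rng.normal(0.3, 0.5)})
                rows.append({"subject": sid, "group": g, "side": "b",
                             "y": base + rng.normal()})
        df = pd.DataFrame(rows)
        ref = pg.mixed_anova(df, dv="y", within="side", subject="subject",
                             between="group")
        wide = df.pivot_table(index=["subject", "group"], columns="side", values="y")
        wide = wide.reset_index()
        ours = mixed_anova_main_within(
            wide["a"].to_numpy(), wide["b"].to_numpy(), wide["group"].to_numpy()
        )
        f_ref = float(ref.loc[ref["Source"] == "side", "F"].iloc[0])
        assert ours.statistic == pytest.approx(f_ref, rel=1e-6)

    def test_error_df_contract(self, rng):
        # 109 patients in 4 groups -> error df = 105
        group = np.repeat(["LFG", "LTG", "RFG", "RTG"], [27, 26, 29, 27])
        a = rng.normal(size=109)
        b = rng.normal(size=109)
        res = mixed_anova_main_within(a, b, group)
        assert res.df == (1.0, 105.0)

    def test_missing_level_names_subject(self):
        a = np.array([1.0, np.nan, 2.0])
        b = np.array([1.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="subject index 1"):
            mixed_anova_main_within(a, b, np.zeros(3))

    def test_power_at_moderate_effect(self):
        # 4 groups of 15; within-effect 0.6 with difference-score SD sqrt(2)
        # gives analytic power ~0.90 for the F(1, 56) test
        gen = np.random.default_rng(99)
        group = np.repeat(np.arange(4), 15)
        hits = 0
        reps = 500
        for _ in range(reps):
            base = gen.normal(size=60)
            a = base + gen.normal(0.6, 1.0, size=60)
            b = base + gen.normal(0.0, 1.0, size=60)
            if mixed_anova_main_within(a, b, group).p < 0.05:
                hits += 1
        assert hits / reps >= 0.80


class TestChiSquare:
    def test_perfect_diagonal_2x2(self):
        res = chi_square_independence(ContingencyTable([[10, 0], [0, 10]]))
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_proportional_table_zero(self):
        res = chi_square_independence(ContingencyTable([[10, 20], [30, 60]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_uncorrected(self, rng):
        counts = rng.integers(1, 40, size=(4, 3))
        ours = chi_square_independence(ContingencyTable(counts))
        ref = sps.chi2_contingency(counts, correction=False)
        assert ours.statistic == pytest.approx(ref[0], rel=1e-12)
        assert ours.p == pytest.approx(ref[1], rel=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_independence(ContingencyTable([[0, 0], [3, 4]]))

    def test_cellwise_recomputation(self, rng):
        counts = rng.integers(1, 30, size=(3, 3)).astype(float)
        expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
        by_hand = ((counts - expected) ** 2 / expected).sum()
        res = chi_square_independence(ContingencyTable(counts))
        assert res.statistic == pytest.approx(by_hand, rel=1e-12)


class TestPearson:
    def test_perfect_positive(self):
        res = pearson_corr([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(1.0)

    def test_affine_decreasing(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        res = pearson_corr(x, -2 * x + 3)
        assert res.statistic == pytest.approx(-1.0)

    def test_hand_value_four_points(self):
        res = pearson_corr([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(0.8, abs=1e-12)

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        ours = pearson_corr(x, y)
        ref = sps.pearsonr(x, y)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_zero_variance_error(self):
        with pytest.raises(DegenerateDataError):
            pearson_corr([1, 1, 1], [1, 2, 3])


def _bh_oracle(pvals, alpha):
    """Brute-force scan of every step-up cutoff."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestBhFdr:
    def test_all_ones_no_rejections(self):
        reject, adj = bh_fdr([1.0] * 10)
        assert not reject.any()
        assert np.all(adj == 1.0)

    def test_stepup_boundary_all_rejected(self):
        # p(i) == i*alpha/m exactly for every i
        reject, _ = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05], alpha=0.05)
        assert reject.all()

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_exhaustive_oracle(self, pvals, alpha):
        reject, adj = bh_fdr(pvals, alpha=alpha)
        assert np.array_equal(reject, _bh_oracle(pvals, alpha))
        # monotone: adjusted order matches raw order
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)
        # never rejects more than uncorrected testing
        assert reject.sum() <= np.sum(np.asarray(pvals) <= alpha)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, derandomize=True)
    def test_adding_null_hypothesis_never_increases_rejections(self, pvals):
        before = bh_fdr(pvals)[0].sum()
        after = bh_fdr(list(pvals) + [1.0])[0].sum()
        assert after <= before

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(size=45)
        for method, sm_method in (("bh", "fdr_bh"), ("by", "fdr_by")):
            reject, adj = bh_fdr(p, alpha=0.05, method=method)
            ref_rej, ref_adj, *_ = sm.multipletests(p, alpha=0.05, method=sm_method)
            assert np.array_equal(reject, ref_rej)
            assert np.allclose(adj, ref_adj)
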