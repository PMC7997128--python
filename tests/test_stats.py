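import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from thermocontrast.stats import (
    bh_adjust,
    paired_t,
    pearson_corr,
    rm_anova_1way,
    stat_to_p,
    two_sample_t,
    within_subject_sem,
)


def glm_rm_anova_oracle(x: np.ndarray):
    """Brute-force two-way (subject + condition) GLM decomposition, no interaction.

    Fits nested dummy-coded linear models by least squares and forms the
    condition F from residual sums of squares — independent of the
    sum-of-squares shortcut used by the implementation.
    """
    n, k = x.shape
    y = x.ravel()
    subj = np.repeat(np.arange(n), k)
    cond = np.tile(np.arange(k), n)

    def design(with_cond: bool):
        cols = [np.ones(y.size)]
        cols += [(subj == i).astype(float) for i in range(1, n)]
        if with_cond:
            cols += [(cond == j).astype(float) for j in range(1, k)]
        return np.column_stack(cols)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_full = rss(design(True))
    rss_reduced = rss(design(False))
    df_num, df_den = k - 1, (k - 1) * (n - 1)
    f = ((rss_reduced - rss_full) / df_num) / (rss_full / df_den)
    return f, df_num, df_den


class TestRmAnova:
    def test_degrees_of_freedom_match_design(self):
        rng = np.random.default_rng(0)
        res = rm_anova_1way(rng.normal(size=(21, 3)))
        assert (res.df_num, res.df_den) == (2, 40)

    def test_no_condition_variance_gives_zero_f(self):
        x = np.array([[1.0, 1.0, 1.0], [2.5, 2.5, 2.5], [4.0, 4.0, 4.0]])
        res = rm_anova_1way(x)
        assert res.f_stat == 0.0
        assert res.ss_condition == 0.0

    def test_hand_computed_three_by_three(self):
        # frozen against an independent sum-of-squares hand computation
        res = rm_anova_1way(np.array([[1, 2, 3], [2, 4, 3], [3, 3, 5.0]]))
        assert res.f_stat == pytest.approx(3.454545454545, rel=1e-9)
        assert (res.df_num, res.df_den) == (2, 4)
        assert res.p_raw == pytest.approx(0.134444444444, rel=1e-6)

    def test_sums_of_squares_partition_total(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 4))
        res = rm_anova_1way(x)
        total = float(((x - x.mean()) ** 2).sum())
        assert res.ss_condition + res.ss_subject + res.ss_error == pytest.approx(total)

    def test_matches_glm_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(3, 15))
            k = int(rng.integers(2, 5))
            x = rng.normal(size=(n, k))
            res = rm_anova_1way(x)
            f, dfn, dfd = glm_rm_anova_oracle(x)
            assert res.f_stat == pytest.approx(f, rel=1e-8)
            assert (res.df_num, res.df_den) == (dfn, dfd)

    def test_matches_statsmodels_anova_rm(self):
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 3))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 3),
                "condition": np.tile(["a", "b", "c"], 10),
                "value": x.ravel(),
            }
        )
        sm = AnovaRM(long, "value", "subject", within=["condition"]).fit()
        res = rm_anova_1way(x)
        assert res.f_stat == pytest.approx(sm.anova_table["F Value"].iloc[0], rel=1e-10)
        assert res.p_raw == pytest.approx(sm.anova_table["Pr > F"].iloc[0], rel=1e-10)

    def test_zero_error_variance_flagged_degenerate(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        res = rm_anova_1way(x)
        assert res.degenerate
        assert res.f_stat == np.inf and res.p_raw == 0.0

    def test_missing_cells_rejected(self):
        x = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            rm_anova_1way(x)

    def test_two_condition_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 2))
        res_f = rm_anova_1way(x)
        res_t = paired_t(x[:, 0], x[:, 1])
        assert res_f.f_stat == pytest.approx(res_t.t_stat**2, rel=1e-10)
        assert res_f.p_raw == pytest.approx(res_t.p_raw, rel=1e-10)


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == 0.0 and res.p_raw == 1.0

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(5)
        res = paired_t(rng.normal(size=21), rng.normal(size=21))
        assert res.df == 20

    def test_hand_computed_differences(self):
        # d = (1, 2, 3): t = 2 / (1/√3) = 2√3
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t_stat == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert res.df == 2

    def test_antisymmetry_and_scipy_agreement(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=15), rng.normal(size=15)
        res = paired_t(x, y)
        assert res.t_stat == pytest.approx(-paired_t(y, x).t_stat)
        ref = sps.ttest_rel(x, y)
        assert res.t_stat == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_nonzero_mean_degenerate(self):
        res = paired_t([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert res.degenerate and res.t_stat == np.inf


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == 0.0

    def test_hand_computed_pooled(self):
        res = two_sample_t([0, 0, 1, 1.0], [1, 1, 2, 2.0])
        assert res.t_stat == pytest.approx(-np.sqrt(6), rel=1e-12)  # −2.449
        assert res.df == 6

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=10), rng.normal(scale=3.0, size=7)
        res = two_sample_t(a, b, variant="welch")
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.t_stat == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-12)
        assert res.df == pytest.approx(ref.df, rel=1e-12)

    def test_pooled_matches_scipy(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=22), rng.normal(size=18)
        res = two_sample_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.t_stat == pytest.approx(ref.statistic, rel=1e-12)
        assert res.df == 38  # pooled df for groups of 22 and 18


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_corr(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_raw == 0.0

    def test_hand_computed_r(self):
        res = pearson_corr([1, 2, 3, 4.0], [1, 3, 2, 4.0])
        assert res.r == pytest.approx(0.8, rel=1e-12)

    def test_df_n_minus_two_and_scipy_agreement(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=62), rng.normal(size=62)
        res = pearson_corr(x, y)
        assert res.df == 60
        ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def brute_force_bh(p):
    """Step-up rule applied literally, rank by rank."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        val = min(prev, p[order[rank - 1]] * m / rank, 1.0)
        adj[order[rank - 1]] = val
        prev = val
    return adj


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_family(self):
        out = bh_adjust([0.001, 0.01, 0.03, 0.04])
        assert np.allclose(out, [0.004, 0.02, 0.04, 0.04])

    def test_ties_share_top_rank_value(self):
        # all m tests tied at p: the step-up rule rejects all of them at
        # α = p (largest i with p_(i) ≤ α·i/m is i = m), so every adjusted
        # value is p·m/m = p
        assert np.allclose(bh_adjust([0.02, 0.02, 0.02]), [0.02, 0.02, 0.02])
        assert np.allclose(brute_force_bh([0.02, 0.02, 0.02]), [0.02, 0.02, 0.02])

    def test_output_order_matches_input(self):
        out = bh_adjust([0.04, 0.001])
        assert out[1] < out[0]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_matches_brute_force_and_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests

        out = bh_adjust(ps)
        assert np.allclose(out, brute_force_bh(ps))
        _, sm_adj, *_ = multipletests(ps, method="fdr_bh")
        assert np.allclose(out, sm_adj)
        assert np.all(out <= np.minimum(1.0, np.asarray(ps) * len(ps)) + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestStatToP:
    def test_t_zero_gives_one(self):
        assert stat_to_p(0.0, "t", 20) == pytest.approx(1.0)

    def test_f_reproduces_printed_raw_anova_p(self):
        assert stat_to_p(3.72, "F", (2, 40)) == pytest.approx(0.033, abs=5e-4)

    def test_large_t_below_reporting_threshold(self):
        assert stat_to_p(4.57, "t", 20) < 0.001

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            stat_to_p(1.0, "t", 0)
        with pytest.raises(ValueError):
            stat_to_p(1.0, "F", (0, 10))


class TestWithinSubjectSem:
    def test_pure_subject_offsets_give_zero(self):
        profile = np.array([1.0, 2.0, 4.0])
        x = profile + np.array([[0.0], [3.0], [-1.5], [10.0]])
        assert np.allclose(within_subject_sem(x), 0.0)

    def test_two_by_two_hand_computation(self):
        assert np.allclose(within_subject_sem(np.array([[1.0, 2.0], [3.0, 4.0]])), 0.0)

    def test_invariant_to_shifting_one_subject(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(9, 3))
        base = within_subject_sem(x)
        x2 = x.copy()
        x2[4] += 17.3
        assert np.allclose(within_subject_sem(x2), base)
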