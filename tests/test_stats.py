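"""Statistical layer: ANOVA (raw and summary), LSD, BH-FDR, Pearson."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from tbiconn import (
    anova_from_summary,
    anova_oneway,
    bh_fdr,
    lsd_posthoc,
    pearson_correlation,
    ttest_two_sample,
)


def random_groups(rng, k=3, n=(8, 6, 5), shift=0.0):
    return [rng.normal(10 + shift * i, 2, size=n[i % len(n)]) for i in range(k)]


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = anova_oneway([g, g, g])
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_groups_f_is_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 9), rng.normal(0.7, 1, 7)
        res = anova_oneway([a, b])
        t, df, p = ttest_two_sample(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        assert res.F == pytest.approx(t**2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)
        assert res.df_within == df

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        groups = random_groups(rng, shift=0.5)
        res = anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_summary_statistics_are_sufficient(self, seed):
        rng = np.random.default_rng(seed)
        groups = random_groups(rng, shift=rng.uniform(0, 1))
        raw = anova_oneway(groups)
        summ = anova_from_summary(
            [g.mean() for g in groups],
            [g.std(ddof=1) for g in groups],
            [len(g) for g in groups],
        )
        assert summ.F == pytest.approx(raw.F, abs=1e-10, rel=1e-10)
        assert summ.p == pytest.approx(raw.p, abs=1e-10)
        assert (summ.df_between, summ.df_within) == (raw.df_between, raw.df_within)

    def test_equal_means_any_sds_give_zero_f(self):
        res = anova_from_summary([5.0, 5.0, 5.0], [1.0, 2.0, 3.0], [10, 10, 10])
        assert res.F == 0.0

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            anova_from_summary([1.0, 1.0], [0.0, 0.0], [5, 5])

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        groups = random_groups(rng, shift=0.8)
        shifted = [g + 137.0 for g in groups]
        assert anova_oneway(groups).F == pytest.approx(anova_oneway(shifted).F)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        groups = random_groups(rng, shift=0.8)
        scaled = [g * 3.5 for g in groups]
        assert anova_oneway(groups).F == pytest.approx(anova_oneway(scaled).F)


class TestTtest:
    def test_equal_means(self):
        t, df, p = ttest_two_sample(5.0, 1.0, 10, 5.0, 2.0, 8)
        assert t == 0.0
        assert p == pytest.approx(1.0)
        assert df == 16

    def test_t_squared_equals_summary_f(self):
        t, df, p = ttest_two_sample(3.7, 1.8, 12, 2.5, 1.6, 10)
        res = anova_from_summary([3.7, 2.5], [1.8, 1.6], [12, 10])
        assert res.F == pytest.approx(t**2, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-10)


class TestLsd:
    def test_identical_pair_p_is_one(self):
        rng = np.random.default_rng(5)
        g = rng.normal(0, 1, 8)
        out = lsd_posthoc([g, g.copy(), g + 2])
        assert out.p[(0, 1)] == pytest.approx(1.0)

    def test_two_groups_reduce_to_pooled_t(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 9), rng.normal(1, 1, 7)
        out = lsd_posthoc([a, b])
        t, df, p = ttest_two_sample(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        assert out.t[(0, 1)] == pytest.approx(t, rel=1e-12)
        assert out.p[(0, 1)] == pytest.approx(p, rel=1e-12)
        assert out.df_within == df

    def test_shifted_group_has_smaller_pvalues(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 10), rng.normal(0.1, 1, 10)
        c = rng.normal(8, 1, 10)
        out = lsd_posthoc([a, b, c])
        assert out.p[(0, 2)] < out.p[(0, 1)]
        assert out.p[(1, 2)] < out.p[(0, 1)]


class TestBhFdr:
    def test_single_p_equals_q(self):
        out = bh_fdr([0.031])
        assert out.q[0] == pytest.approx(0.031)

    def test_all_equal_flagged_iff_below_alpha(self):
        assert bh_fdr([0.04] * 6, alpha=0.05).significant.all()
        assert not bh_fdr([0.06] * 6, alpha=0.05).significant.any()

    def test_hand_enumerated_step_up(self):
        # p sorted: .005<=1/4*.05, .009<=2/4*.05, .05>3/4*.05, .5>4/4*.05
        # -> largest passing index is 2, so the two smallest are flagged
        out = bh_fdr([0.005, 0.009, 0.05, 0.5], alpha=0.05)
        assert list(out.significant) == [True, True, False, False]
        assert np.allclose(out.q, [0.018, 0.018, 0.05 * 4 / 3, 0.5])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 40) ** 2
        out = bh_fdr(p, alpha=0.05)
        reject, q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(out.q, q)
        assert np.array_equal(out.significant, reject)

    def test_q_at_least_p_and_flags_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 25)
        out = bh_fdr(p)
        assert np.all(out.q >= p - 1e-15)
        # lowering one p never unflags previously flagged hypotheses
        lowered = p.copy()
        lowered[np.argmax(p)] = 0.001
        out2 = bh_fdr(lowered)
        assert np.all(out2.significant[out.significant])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=15), rng.normal(size=15)
        res = pearson_correlation(x, y)
        cov = ((x - x.mean()) * (y - y.mean())).sum()
        denom = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert res.r == pytest.approx(cov / denom, rel=1e-12)
        t = res.r * np.sqrt((15 - 2) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 13), rel=1e-10)

    def test_r_invariant_under_positive_affine_maps(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=12), rng.normal(size=12)
        base = pearson_correlation(x, y).r
        assert pearson_correlation(3 * x + 5, 0.5 * y - 2).r == pytest.approx(base)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance|undefined"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
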