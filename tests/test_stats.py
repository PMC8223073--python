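"""Summaries, CV machinery, ANOVA + LSD, Cohen's d, and Pearson r."""

import numpy as np
import pytest
from scipy import stats as sps

from weightgrade.errors import DomainError
from weightgrade.stats import (
    anova_lsd,
    cohens_d,
    cohens_d_from_moments,
    compare_cv,
    cv_reduction,
    pearson,
    summarize,
)


class TestSummarize:
    def test_constant_vector(self):
        s = summarize([1, 1, 1, 1])
        assert (s.mean, s.sd, s.cv) == (1.0, 0.0, 0.0)

    def test_hand_example(self):
        s = summarize([8, 10, 12])
        assert s.mean == 10.0
        assert s.sd == pytest.approx(2.0)
        assert s.cv == pytest.approx(20.0)
        assert s.median == 10.0
        assert s.range == (8.0, 12.0)

    def test_oracle_equivalence_on_lognormal_sample(self, rng):
        x = rng.lognormal(3.0, 0.4, size=500)
        s = summarize(x)
        n = x.size
        mean = x.sum() / n
        sd = np.sqrt(((x - mean) ** 2).sum() / (n - 1))
        assert s.mean == pytest.approx(mean, rel=1e-12)
        assert s.sd == pytest.approx(sd, rel=1e-12)
        assert s.cv == pytest.approx(sd / mean * 100, rel=1e-12)

    def test_too_small_and_zero_mean(self):
        with pytest.raises(DomainError):
            summarize([1.0])
        with pytest.raises(DomainError):
            summarize([-1.0, 1.0])

    def test_cv_scale_invariance(self, rng):
        x = rng.gamma(4.0, 2.0, size=200)
        assert summarize(7.3 * x).cv == pytest.approx(summarize(x).cv, rel=1e-12)


class TestCvReduction:
    @pytest.mark.parametrize(
        "ref, alt, expected", [(23.7, 10.8, 54.4), (16.9, 9.9, 41.4), (5.0, 5.0, 0.0)]
    )
    def test_printed_style_reductions(self, ref, alt, expected):
        assert cv_reduction(ref, alt) == pytest.approx(expected, abs=0.05)

    def test_nonpositive_reference(self):
        with pytest.raises(DomainError):
            cv_reduction(0.0, 1.0)


class TestCompareCv:
    def test_identical_samples_give_unit_f(self, rng):
        x = rng.normal(50, 5, size=80)
        res = compare_cv(x, x)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_large_cv_gap_detected(self, rng):
        a = rng.normal(40.0, 40 * 0.24, size=500)
        b = rng.normal(40.0, 40 * 0.11, size=500)
        assert compare_cv(a, b).p_value < 1e-3

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(42)
        alpha, n, reps = 0.05, 100, 2000
        rejections = 0
        for _ in range(reps):
            a = rng.normal(30.0, 4.5, size=n)
            b = rng.normal(60.0, 9.0, size=n)  # equal CVs, different scales
            if compare_cv(a, b).p_value < alpha:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065

    def test_power_increases_with_cv_gap(self):
        rng = np.random.default_rng(7)
        n, reps = 60, 300
        rates = []
        for cv_b in (0.10, 0.14, 0.20):
            hits = 0
            for _ in range(reps):
                a = rng.normal(50.0, 5.0, size=n)  # CV 10%
                b = rng.normal(50.0, 50 * cv_b, size=n)
                if compare_cv(a, b).p_value < 0.05:
                    hits += 1
            rates.append(hits / reps)
        assert rates[0] < rates[1] < rates[2]


class TestAnovaLsd:
    def test_identical_groups(self):
        res = anova_lsd([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_anova(self):
        res = anova_lsd([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(13.5)
        assert res.df == (1, 4)

    def test_matches_brute_force_sums_of_squares(self, rng):
        for _ in range(20):
            groups = [rng.normal(rng.uniform(-1, 1), 1.0, size=rng.integers(5, 30))
                      for _ in range(3)]
            res = anova_lsd(groups)
            allx = np.concatenate(groups)
            grand = allx.mean()
            ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            f = (ssb / 2) / (ssw / (allx.size - 3))
            assert res.statistic == pytest.approx(f, abs=1e-10)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(m, 1.5, size=40) for m in (0.0, 0.4, 1.1)]
        ours = anova_lsd(groups)
        ref = sps.f_oneway(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_two_group_f_equals_squared_t(self, rng):
        a, b = rng.normal(0, 1, 25), rng.normal(0.5, 1, 30)
        res = anova_lsd([a, b])
        t = sps.ttest_ind(a, b).statistic
        assert res.statistic == pytest.approx(t**2, rel=1e-10)

    def test_lsd_pairwise_uses_pooled_mse(self, rng):
        groups = [rng.normal(m, 1.0, size=15) for m in (0.0, 0.2, 1.5)]
        res = anova_lsd(groups)
        lsd = res.extra["lsd"]
        assert set(lsd) == {(0, 1), (0, 2), (1, 2)}
        # pair (0,2) separated by 1.5 SD should dominate pair (0,1)
        assert lsd[(0, 2)]["p"] < lsd[(0, 1)]["p"]

    def test_single_group_rejected(self):
        with pytest.raises(DomainError):
            anova_lsd([[1.0, 2.0]])


class TestCohensD:
    def test_identical_samples(self, rng):
        x = rng.normal(10, 2, 30)
        assert cohens_d(x, x) == 0.0

    def test_pooled_sd_hand_example(self):
        # moments from the reference summaries: weight means 51.8 vs 47.8
        d = cohens_d_from_moments(51.8, 4.4, 194, 47.8, 11.6, 260)
        assert d == pytest.approx(0.433, abs=5e-4)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 25)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a), rel=1e-12)

    def test_zero_pooled_sd(self):
        with pytest.raises(DomainError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson(x, x).statistic == pytest.approx(1.0)
        assert pearson(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        x = rng.normal(size=200)
        y = 0.6 * x + rng.normal(size=200)
        res = pearson(x, y)
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res.statistic == pytest.approx(r, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DomainError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
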