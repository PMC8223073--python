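"""Coverage ellipses, two-group Wilks' lambda, and Box's M."""

import numpy as np
import pytest
from scipy import stats as sps

from weightgrade.bivariate import box_m, compare_models, normal_ellipse, wilks_two_group
from weightgrade.errors import DomainError


def _cloud(rng, n, mean=(0.0, 0.0), cov=((1.0, 0.0), (0.0, 1.0))):
    return rng.multivariate_normal(mean, cov, size=n)


class TestNormalEllipse:
    def test_identity_covariance_semi_axes(self, rng):
        pts = _cloud(rng, 200_000)
        ell = normal_ellipse(pts, coverage=0.95)
        expected = np.sqrt(sps.chi2.ppf(0.95, 2))
        assert ell.semi_axes[0] == pytest.approx(expected, rel=0.02)
        assert ell.semi_axes[1] == pytest.approx(expected, rel=0.02)

    def test_zero_coverage_degenerates_to_point(self, rng):
        ell = normal_ellipse(_cloud(rng, 50), coverage=0.0)
        assert ell.semi_axes == (0.0, 0.0)

    def test_monte_carlo_coverage(self):
        rng = np.random.default_rng(1234)
        pts = rng.standard_normal((100_000, 2))
        ell = normal_ellipse(pts, coverage=0.95)
        frac = ell.contains(pts).mean()
        assert 0.948 <= frac <= 0.952

    def test_area_equals_eigenvalue_product_formula(self, rng):
        cov = [[2.0, 0.7], [0.7, 1.0]]
        pts = _cloud(rng, 5000, cov=cov)
        ell = normal_ellipse(pts, coverage=0.95)
        q = sps.chi2.ppf(0.95, 2)
        sample_cov = np.cov(pts, rowvar=False)
        assert ell.area == pytest.approx(np.pi * q * np.sqrt(np.linalg.det(sample_cov)), rel=1e-9)

    def test_polyline_vertices_lie_on_boundary(self, rng):
        pts = _cloud(rng, 500, mean=(3.0, -1.0), cov=[[2.0, 0.5], [0.5, 0.6]])
        ell = normal_ellipse(pts)
        poly = ell.polyline(64)
        assert poly.shape == (65, 2)
        # boundary points are inside (closed ellipse) but scaled-out ones are not
        center = np.asarray(ell.center)
        assert ell.contains(poly).all()
        assert not ell.contains(center + 1.001 * (poly[:10] - center)).any()

    def test_degenerate_covariance_rejected(self):
        line = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(DomainError):
            normal_ellipse(line)


class TestWilks:
    def test_identical_groups_lambda_one(self, rng):
        pts = _cloud(rng, 40)
        res = wilks_two_group(pts, pts.copy())
        assert res.extra["lambda"] == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0)

    def test_hotelling_equivalence_on_small_instances(self, rng):
        # lambda = 1 / (1 + T^2/(N-2)) for two groups
        for _ in range(50):
            n, m = int(rng.integers(4, 12)), int(rng.integers(4, 12))
            a = _cloud(rng, n, mean=rng.normal(size=2))
            b = _cloud(rng, m, mean=rng.normal(size=2))
            res = wilks_two_group(a, b)
            d = a.mean(axis=0) - b.mean(axis=0)
            sp = ((n - 1) * np.cov(a, rowvar=False) + (m - 1) * np.cov(b, rowvar=False)) / (
                n + m - 2
            )
            t2 = (n * m / (n + m)) * d @ np.linalg.solve(sp, d)
            lam = 1.0 / (1.0 + t2 / (n + m - 2))
            assert res.extra["lambda"] == pytest.approx(lam, abs=1e-10)

    def test_separated_clusters_significant(self, rng):
        a = _cloud(rng, 100)
        b = _cloud(rng, 100, mean=(3.0, 3.0))
        assert wilks_two_group(a, b).p_value < 1e-6

    def test_affine_invariance(self, rng):
        a = _cloud(rng, 30, mean=(1.0, 0.0))
        b = _cloud(rng, 35, mean=(0.0, 1.0))
        lam = wilks_two_group(a, b).extra["lambda"]
        M = np.array([[2.0, 0.3], [-0.5, 1.2]])
        shift = np.array([10.0, -4.0])
        lam2 = wilks_two_group(a @ M.T + shift, b @ M.T + shift).extra["lambda"]
        assert lam2 == pytest.approx(lam, rel=1e-9)


class TestBoxM:
    def test_identical_covariances_give_zero(self, rng):
        pts = _cloud(rng, 50)
        res = box_m(pts, pts.copy())
        assert res.extra["M"] == pytest.approx(0.0, abs=1e-9)

    def test_unequal_spread_detected(self, rng):
        a = _cloud(rng, 200)
        b = _cloud(rng, 200, cov=((4.0, 0.0), (0.0, 4.0)))
        assert box_m(a, b).p_value < 1e-3

    def test_matches_direct_formula(self, rng):
        a = _cloud(rng, 12)
        b = _cloud(rng, 17, cov=((2.0, 0.4), (0.4, 1.0)))
        res = box_m(a, b)
        s1, s2 = np.cov(a, rowvar=False), np.cov(b, rowvar=False)
        v1, v2 = 11, 16
        sp = (v1 * s1 + v2 * s2) / (v1 + v2)
        m = (v1 + v2) * np.log(np.linalg.det(sp)) - v1 * np.log(
            np.linalg.det(s1)
        ) - v2 * np.log(np.linalg.det(s2))
        assert res.extra["M"] == pytest.approx(m, abs=1e-10)

    def test_minimum_group_size_enforced(self, rng):
        with pytest.raises(DomainError):
            box_m(_cloud(rng, 3), _cloud(rng, 10))


class TestCompareModels:
    def test_identical_member_sets(self, rng):
        pts = _cloud(rng, 60, mean=(4.0, 15.0))
        comp = compare_models(pts, pts.copy())
        assert comp.wilks.extra["lambda"] == pytest.approx(1.0)
        assert comp.box.extra["M"] == pytest.approx(0.0, abs=1e-9)

    def test_age_groups_more_correlated_than_weight_groups(self, small_profile):
        from weightgrade.grading import default_scheme, label_cohort

        scheme = default_scheme()
        df = label_cohort(small_profile, scheme)
        for age_label, w_label in zip(scheme.age_labels, scheme.weight_labels):
            a = df.loc[df.age_cat == age_label, ["bfmi", "ffmi"]].to_numpy()
            w = df.loc[df.weight_cat == w_label, ["bfmi", "ffmi"]].to_numpy()
            comp = compare_models(a, w)
            assert comp.pearson_a.statistic > comp.pearson_b.statistic

    def test_wilks_detects_centroid_shift_across_seeds(self):
        # the U11 pair's centroids differ under the calibrated generator; a
        # majority of replicates should reject at the 5% level
        from weightgrade import simulate
        from weightgrade.composition import profile_cohort
        from weightgrade.grading import default_scheme, label_cohort

        scheme = default_scheme()
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            df = label_cohort(
                profile_cohort(simulate.generate(simulate.default_spec(seed).with_n(250))),
                scheme,
            )
            a = df.loc[df.age_cat == "U11", ["bfmi", "ffmi"]].to_numpy()
            w = df.loc[df.weight_cat == "W30-44.9", ["bfmi", "ffmi"]].to_numpy()
            if wilks_two_group(a, w).p_value < 0.05 or box_m(a, w).p_value < 0.05:
                hits += 1
        assert hits > n_seeds / 2
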