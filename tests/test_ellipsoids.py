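"""Ellipsoid envelopes: CVAE/MVE fitting, containment, volume, oracles."""

import itertools
from math import pi

import numpy as np
import pytest
from scipy.stats import chi2

import paleoniche as pn
from paleoniche.ellipsoids import minimum_enclosing_ellipsoid
from paleoniche.errors import DegenerateGeometryError


class TestCVAE:
    def test_unit_square_hand_computation(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        ell = pn.fit_cvae(pts, coverage=0.95)
        assert np.allclose(ell.centroid, [0.5, 0.5])
        assert np.allclose(ell.shape, np.diag([1 / 3, 1 / 3]))

    def test_radius_is_chisquare_quantile(self, rng):
        pts = rng.standard_normal((30, 3))
        ell = pn.fit_cvae(pts, coverage=0.95)
        assert np.isclose(ell.radius2, chi2.ppf(0.95, 3))
        assert np.isclose(ell.radius2, 7.8147, atol=1e-3)

    def test_too_few_points_degenerate(self, rng):
        with pytest.raises(DegenerateGeometryError):
            pn.fit_cvae(rng.standard_normal((3, 3)))

    def test_collinear_points_degenerate(self):
        t = np.linspace(0, 1, 10)
        pts = np.column_stack([t, 2 * t])
        with pytest.raises(DegenerateGeometryError, match="singular|collinear"):
            pn.fit_cvae(pts)


class TestContainment:
    def test_centroid_inside_distance_zero(self, rng):
        ell = pn.fit_cvae(rng.standard_normal((20, 2)))
        assert pn.contains(ell, ell.centroid[None, :])[0]
        assert np.isclose(pn.mahalanobis2(ell, ell.centroid[None, :])[0], 0)

    def test_boundary_counts_as_inside(self):
        ell = pn.Ellipsoid(np.zeros(2), np.eye(2), 4.0)
        assert pn.contains(ell, np.array([[2.0, 0.0]]))[0]          # form = radius2
        assert not pn.contains(ell, np.array([[2.0 * np.sqrt(1.01), 0.0]]))[0]

    def test_dimension_mismatch(self):
        ell = pn.Ellipsoid(np.zeros(2), np.eye(2), 1.0)
        with pytest.raises(Exception, match="dimension"):
            pn.mahalanobis2(ell, np.zeros((1, 3)))


class TestVolume:
    def test_unit_disc(self):
        assert np.isclose(pn.volume(pn.Ellipsoid(np.zeros(2), np.eye(2), 1.0)), pi)

    def test_radius_two_ball(self):
        ell = pn.Ellipsoid(np.zeros(3), np.eye(3), 4.0)
        assert np.isclose(pn.volume(ell), (4 / 3) * pi * 8)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_doubling_radius2_scaling_law(self, k, rng):
        A = rng.standard_normal((k, k))
        shape = A @ A.T + k * np.eye(k)
        v1 = pn.volume(pn.Ellipsoid(np.zeros(k), shape, 1.5))
        v2 = pn.volume(pn.Ellipsoid(np.zeros(k), shape, 3.0))
        assert np.isclose(v2 / v1, 2 ** (k / 2))


class TestMVEE:
    def test_triangle_matches_steiner_circumellipse(self):
        """MVEE of 3 points is the Steiner ellipse: area = 4π/(3√3) · tri area."""
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        ell = minimum_enclosing_ellipsoid(tri, tol=1e-8)
        assert np.allclose(pn.mahalanobis2(ell, tri), ell.radius2, rtol=1e-6)
        assert np.isclose(pn.volume(ell), 4 * pi / (3 * np.sqrt(3)) * 0.5, rtol=1e-6)

    def test_all_points_enclosed(self, rng):
        pts = rng.standard_normal((25, 3))
        ell = minimum_enclosing_ellipsoid(pts)
        assert pn.contains(ell, pts).all()

    def test_degenerate_rank_deficient(self):
        t = np.linspace(0, 1, 8)
        with pytest.raises(DegenerateGeometryError):
            minimum_enclosing_ellipsoid(np.column_stack([t, t + 1, 2 * t]))


class TestMVE:
    def test_outlier_excluded_and_matches_subset_enumeration(self, rng):
        """10 tight points + 1 far outlier at coverage 10/11: the MVE drops
        the outlier and equals the best C(11,10) subset wrap."""
        cluster = rng.standard_normal((10, 2))
        pts = np.vstack([cluster, [40.0, 40.0]])
        ell = pn.fit_mve(pts, coverage=10 / 11, seed=0)
        assert not pn.contains(ell, pts[-1:])[0]
        best = min((pn.volume(minimum_enclosing_ellipsoid(pts[list(sub)]))
                    for sub in itertools.combinations(range(11), 10)))
        assert np.isclose(pn.volume(ell), best, rtol=1e-6)

    def test_coverage_one_is_enclosing_ellipsoid(self):
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        ell = pn.fit_mve(tri, coverage=1.0)
        assert pn.contains(ell, tri).all()
        assert np.allclose(pn.mahalanobis2(ell, tri), ell.radius2, rtol=1e-6)

    def test_few_outside_at_five_percent_error(self, rng):
        """With E = 5% and n = 40 fitting points, at most 2 fall outside."""
        pts = rng.standard_normal((40, 3))
        ell = pn.fit_mve(pts, coverage=0.95, seed=1)
        assert (~pn.contains(ell, pts)).sum() <= 2

    def test_volume_never_exceeds_cvae(self, rng, occ_env, pca):
        pc = pn.project(pca, occ_env).values
        mve = pn.fit_mve(pc, 0.95, seed=2)
        cvae = pn.fit_cvae(pc, 0.95)
        assert pn.volume(mve) <= pn.volume(cvae)

    def test_seeded_reproducibility_on_search_path(self, rng):
        pts = np.random.default_rng(5).standard_normal((40, 3))
        a = pn.fit_mve(pts, 0.8, seed=9)   # h=32, search path
        b = pn.fit_mve(pts, 0.8, seed=9)
        assert np.array_equal(a.centroid, b.centroid)
        assert a.fit_info["subset"] == b.fit_info["subset"]

    def test_coverage_guarantee(self, rng):
        for seed in range(3):
            pts = np.random.default_rng(seed).standard_normal((30, 3))
            ell = pn.fit_mve(pts, 0.9, seed=seed)
            assert pn.contains(ell, pts).sum() >= int(np.ceil(0.9 * 30))

    def test_subset_beats_mincovdet_determinant(self):
        """Independent cross-check: our h-subset's covariance det is no worse
        than the support found by sklearn's FAST-MCD."""
        from sklearn.covariance import MinCovDet

        pts = np.random.default_rng(3).standard_normal((60, 3))
        pts[:5] += 8.0
        h = int(np.ceil(0.8 * 60))
        ell = pn.fit_mve(pts, 0.8, seed=0, n_starts=500)
        sub = pts[ell.fit_info["subset"]]
        mcd = MinCovDet(support_fraction=0.8, random_state=0).fit(pts)
        det_ours = np.linalg.det(np.cov(sub, rowvar=False, ddof=0))
        sup = pts[mcd.support_]
        det_mcd = np.linalg.det(np.cov(sup[:h], rowvar=False, ddof=0))
        assert det_ours <= det_mcd * 1.05

    def test_affine_equivariance(self, rng):
        """An invertible affine map transports the fitted MVE and scales its
        volume by |det|."""
        pts = np.random.default_rng(8).standard_normal((12, 2))
        A = np.array([[2.0, 0.5], [-0.3, 1.5]])
        b = np.array([3.0, -1.0])
        e0 = pn.fit_mve(pts, coverage=11 / 12, seed=0)
        e1 = pn.fit_mve(pts @ A.T + b, coverage=11 / 12, seed=0)
        assert np.allclose(e1.centroid, A @ e0.centroid + b, atol=1e-5)
        assert np.isclose(pn.volume(e1), pn.volume(e0) * abs(np.linalg.det(A)),
                          rtol=1e-5)

    def test_h_below_dimension_rejected(self, rng):
        with pytest.raises(DegenerateGeometryError):
            pn.fit_mve(rng.standard_normal((20, 3)), coverage=0.1)
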