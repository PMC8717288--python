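from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemspat import (
    DistanceBins,
    IntertypeMoran,
    MoranCorrelogram,
    dbh_mantel,
    intertype_moran,
    mantel_test,
    mark_permutation_envelope,
    moran_correlogram,
)

ONE_CLASS = DistanceBins(np.array([0.0, 100.0]))


def brute_force_moran(points, marks, bins):
    """Direct double-loop evaluation of the distance-class Moran index."""
    n = len(points)
    z = np.asarray(marks, float) - np.mean(marks)
    denom = np.sum(z**2)
    out = np.full(bins.n_classes, np.nan)
    for c in range(bins.n_classes):
        lo, hi = bins.edges[c], bins.edges[c + 1]
        s = w = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = np.hypot(*(points[i] - points[j]))
                if lo < d <= hi:
                    s += z[i] * z[j]
                    w += 1
        if w:
            out[c] = n / w * s / denom
    return out


class TestMoranCorrelogram:
    def test_two_point_instance_is_minus_one(self):
        pts = np.array([[0.0, 0.0], [50.0, 0.0]])
        i_vals, n_pairs = moran_correlogram(pts, [10.0, 30.0], ONE_CLASS)
        assert n_pairs[0] == 2
        assert i_vals[0] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_on_six_points(self, rng):
        pts = rng.uniform(0, 250, size=(6, 2))
        marks = pts[:, 0] + rng.normal(0, 5, 6)  # x-gradient marks
        bins = DistanceBins(np.array([0.0, 80.0, 160.0, 400.0]))
        i_vals, _ = moran_correlogram(pts, marks, bins)
        np.testing.assert_allclose(i_vals, brute_force_moran(pts, marks, bins), atol=1e-12)

    def test_gradient_marks_give_positive_short_range_i(self, rng):
        pts = np.column_stack([np.linspace(0, 500, 60), np.zeros(60)])
        marks = pts[:, 0] + rng.normal(0, 10, 60)
        bins = DistanceBins(np.array([0.0, 60.0, 500.0]))
        i_vals, _ = moran_correlogram(pts, marks, bins)
        assert i_vals[0] > 0 > i_vals[1]

    def test_permutation_null_mean(self, rng):
        """Randomizing marks over locations gives E[I] = -1/(N-1)."""
        n = 30
        pts = rng.uniform(0, 300, size=(n, 2))
        marks = rng.lognormal(3, 0.4, n)
        bins = DistanceBins(np.array([0.0, 100.0, 200.0, 500.0]))
        sims = []
        for _ in range(4000):
            i_vals, _ = moran_correlogram(pts, rng.permutation(marks), bins)
            sims.append(i_vals)
        sims = np.asarray(sims)
        se = sims.std(axis=0, ddof=1) / np.sqrt(len(sims))
        assert np.all(np.abs(sims.mean(axis=0) + 1 / (n - 1)) < 4 * se)

    def test_zero_variance_rejected(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        with pytest.raises(ValueError, match="zero variance"):
            moran_correlogram(pts, [5.0, 5.0, 5.0], ONE_CLASS)

    def test_empty_class_is_missing(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        bins = DistanceBins(np.array([0.0, 30.0, 1000.0]))
        with pytest.warns(UserWarning, match="missing"):
            i_vals, n_pairs = moran_correlogram(pts, [1.0, 2.0, 4.0], bins)
        assert n_pairs[1] == 0 and np.isnan(i_vals[1])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_affine_mark_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 400, size=(25, 2))
        marks = rng.lognormal(3, 0.5, 25)
        bins = DistanceBins(np.array([0.0, 150.0, 600.0]))
        i1, _ = moran_correlogram(pts, marks, bins)
        i2, _ = moran_correlogram(pts, a * marks + b, bins)
        np.testing.assert_allclose(i1, i2, rtol=1e-9, atol=1e-9)


class TestIntertypeMoran:
    @pytest.mark.parametrize("seed", range(5))
    def test_self_copy_identity(self, seed):
        """I12 against an exact copy equals the within-species I everywhere
        (self pairs drop out because classes are open at 0)."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 2000, size=(200, 2))
        marks = rng.lognormal(3.2, 0.5, 200)
        bins = DistanceBins(np.arange(0.0, 2100.0, 100.0))
        i_within, _ = moran_correlogram(pts, marks, bins)
        i_cross, _ = intertype_moran(pts, marks, pts, marks, bins)
        np.testing.assert_allclose(i_cross, i_within, atol=1e-10)

    def test_negated_copy_flips_sign(self, rng):
        pts = rng.uniform(0, 500, size=(40, 2))
        marks = rng.lognormal(3, 0.4, 40)
        bins = DistanceBins(np.array([0.0, 200.0, 800.0]))
        i_within, _ = moran_correlogram(pts, marks, bins)
        i_cross, _ = intertype_moran(pts, marks, pts, -marks, bins)
        np.testing.assert_allclose(i_cross, -i_within, atol=1e-10)

    def test_symmetric_in_species_order(self, rng):
        p1, p2 = rng.uniform(0, 500, (2, 30, 2))
        m1 = rng.lognormal(3, 0.4, 30)
        m2 = rng.lognormal(3.5, 0.3, 30)
        bins = DistanceBins(np.array([0.0, 150.0, 800.0]))
        i12, n12 = intertype_moran(p1, m1, p2, m2, bins)
        i21, n21 = intertype_moran(p2, m2, p1, m1, bins)
        np.testing.assert_allclose(i12, i21, atol=1e-12)
        np.testing.assert_array_equal(n12, n21)

    def test_independent_marks_stay_in_envelope(self, rng):
        p1, p2 = rng.uniform(0, 800, (2, 60, 2))
        m1, m2 = rng.lognormal(3, 0.5, (2, 60))
        bins = DistanceBins(np.arange(0.0, 900.0, 150.0))
        est = IntertypeMoran(bins=bins, n_perm=199, random_state=11).fit(p1, m1, p2, m2)
        assert est.significant_.mean() <= 0.34  # ~alpha with 6 classes


class TestPermutationEnvelope:
    def test_bounds_ordered_and_iid_coverage(self, rng):
        pts = rng.uniform(0, 600, size=(80, 2))
        marks = rng.lognormal(3, 0.5, 80)
        bins = DistanceBins(np.arange(0.0, 700.0, 100.0))
        lo, hi = mark_permutation_envelope(pts, marks, bins, n_perm=199, seed=5)
        assert np.all(lo <= hi)
        i_vals, _ = moran_correlogram(pts, marks, bins)
        outside = (i_vals > hi) | (i_vals < lo)
        assert outside.mean() <= 0.34

    def test_cohort_marks_detected(self, rng):
        """Patch-structured diameters push short-range I above the envelope."""
        from stemspat import TransectWindow, assign_cohort_dbh, sim_thomas

        w = TransectWindow.study_design(2, 2000.0)
        pts, parents = sim_thomas(w, 1.0, 25.0, 30.0, rng, return_parents=True)
        ages = rng.uniform(20, 120, len(parents))
        marks = assign_cohort_dbh(pts, parents, ages, noise_sd=5.0, rng=rng)
        bins = DistanceBins(np.arange(0.0, 1100.0, 100.0))
        est = MoranCorrelogram(bins=bins, n_perm=199, mantel=False, random_state=2).fit(
            pts, marks
        )
        assert est.i_[0] > est.env_hi_[0]

    def test_requires_enough_permutations(self, rng):
        pts = rng.uniform(0, 100, size=(10, 2))
        with pytest.raises(ValueError, match="n_perm"):
            mark_permutation_envelope(pts, rng.normal(size=10), ONE_CLASS, n_perm=10)


class TestMantel:
    def test_identical_matrices(self, rng):
        A = rng.normal(size=(8, 8))
        A = A + A.T
        r, p = mantel_test(A, A, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200, abs=1e-9)

    def test_matches_exhaustive_enumeration(self, rng):
        """Sampled p agrees with the exact p over all 120 permutations."""
        A = rng.normal(size=(5, 5))
        A = A + A.T
        B = rng.normal(size=(5, 5))
        B = B + B.T
        iu = np.triu_indices(5, 1)
        r_obs = np.corrcoef(A[iu], B[iu])[0, 1]
        exact = np.mean(
            [
                abs(np.corrcoef(A[iu], B[np.ix_(p, p)][iu])[0, 1]) >= abs(r_obs) - 1e-12
                for p in permutations(range(5))
            ]
        )
        r, p_hat = mantel_test(A, B, n_perm=4999, seed=3)
        assert r == pytest.approx(r_obs)
        assert p_hat == pytest.approx(exact, abs=0.03)

    def test_constant_matrix_rejected(self):
        A = np.ones((4, 4))
        with pytest.raises(ValueError, match="constant"):
            mantel_test(A, A, n_perm=99)


class TestDbhMantel:
    def test_four_point_hand_instance(self):
        """Exact agreement with the direct formula on 4 points."""
        pts = np.array([[0.0, 0.0], [30.0, 0.0], [0.0, 40.0], [30.0, 40.0]])
        marks = np.array([10.0, 12.0, 30.0, 33.0])
        z = (marks - marks.mean()) / marks.std()
        d = np.hypot(
            pts[:, 0][:, None] - pts[None, :, 0], pts[:, 1][:, None] - pts[None, :, 1]
        )
        iu = np.triu_indices(4, 1)
        r_expect = np.corrcoef(np.outer(z, z)[iu], np.log(d[iu]))[0, 1]
        r, p = dbh_mantel(pts, marks, n_perm=199, seed=1)
        assert r == pytest.approx(r_expect, abs=1e-12)
        assert 0 < p <= 1

    def test_cohort_marks_give_negative_r(self, rng):
        from stemspat import TransectWindow, assign_cohort_dbh, sim_thomas

        w = TransectWindow.study_design(1, 2000.0)
        pts, parents = sim_thomas(w, 1.5, 25.0, 25.0, rng, return_parents=True)
        marks = assign_cohort_dbh(
            pts, parents, rng.uniform(20, 120, len(parents)), noise_sd=4.0, rng=rng
        )
        r, p = dbh_mantel(pts, marks, n_perm=199, seed=8)
        assert r < 0
        assert p < 0.05

    def test_coincident_points_warn(self, rng):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 0.0], [20.0, 5.0]])
        with pytest.warns(UserWarning, match="coincident"):
            dbh_mantel(pts, [10.0, 20.0, 15.0, 30.0], n_perm=99, seed=0)
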