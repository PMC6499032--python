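"""Riemannian and Euclidean SPD-matrix machinery."""

import numpy as np
import pytest
import scipy.optimize

from rasr import spd

from conftest import random_spd


class TestSymSqrt:
    def test_diagonal(self):
        M = spd.sym_sqrt(np.diag([4.0, 9.0]))
        assert np.allclose(M, np.diag([2.0, 3.0]), atol=1e-12)

    def test_identity(self):
        assert np.allclose(spd.sym_sqrt(np.eye(24)), np.eye(24), atol=1e-12)

    def test_reconstruction_error(self, rng):
        for _ in range(20):
            U = random_spd(rng, 24)
            M = spd.sym_sqrt(U)
            err = np.linalg.norm(M @ M.T - U) / np.linalg.norm(U)
            assert err < 1e-10
            assert np.allclose(M, M.T, atol=1e-10)

    def test_rejects_indefinite(self):
        with pytest.raises(spd.InvalidCovarianceError):
            spd.sym_sqrt(np.diag([1.0, -1.0]))
        with pytest.raises(spd.InvalidCovarianceError):
            spd.sym_sqrt(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestGeodesicDistance:
    def test_zero_iff_equal(self, rng):
        A = random_spd(rng, 4)
        assert spd.geodesic_distance(A, A) == pytest.approx(0.0, abs=1e-7)
        B = random_spd(rng, 4)
        assert spd.geodesic_distance(A, B) > 0

    def test_commuting_closed_form(self):
        # d(I, e^2 I_2) = sqrt(2^2 + 2^2) = 2 sqrt(2)
        d = spd.geodesic_distance(np.eye(2), np.diag([np.e ** 2, np.e ** 2]))
        assert d == pytest.approx(2.0 * np.sqrt(2.0), rel=1e-12)

    def test_symmetry(self, rng):
        A, B = random_spd(rng, 5), random_spd(rng, 5)
        assert spd.geodesic_distance(A, B) == pytest.approx(
            spd.geodesic_distance(B, A), rel=1e-10)

    def test_congruence_invariance(self, rng):
        for _ in range(10):
            A, B = random_spd(rng, 4), random_spd(rng, 4)
            W = rng.standard_normal((4, 4)) + 0.5 * np.eye(4)
            d0 = spd.geodesic_distance(A, B)
            d1 = spd.geodesic_distance(W @ A @ W.T, W @ B @ W.T)
            assert abs(d0 - d1) < 1e-8 * max(1.0, d0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            spd.geodesic_distance(np.eye(2), np.eye(3))


class TestExpLogMaps:
    def test_log_at_identity_is_matrix_log(self):
        V = spd.log_map(np.eye(2), np.diag([np.e, np.e]))
        assert np.allclose(V, np.eye(2), atol=1e-12)

    def test_log_of_base_is_zero(self, rng):
        B = random_spd(rng, 5)
        assert np.linalg.norm(spd.log_map(B, B)) < 1e-8 * np.linalg.norm(B)

    def test_exp_of_zero_is_base(self, rng):
        B = random_spd(rng, 5)
        assert np.allclose(spd.exp_map(B, np.zeros((5, 5))), B, atol=1e-10)

    def test_round_trip(self, rng):
        for _ in range(50):
            base, P = random_spd(rng, 4), random_spd(rng, 4)
            P2 = spd.exp_map(base, spd.log_map(base, P))
            assert np.linalg.norm(P2 - P) / np.linalg.norm(P) < 1e-8


class TestKarcherMean:
    def test_repeated_matrix(self, rng):
        A = random_spd(rng, 3)
        assert np.allclose(spd.karcher_mean([A, A]), A, rtol=1e-8)

    def test_identity_and_scaled(self):
        K = spd.karcher_mean([np.eye(2), np.diag([4.0, 4.0])])
        assert np.allclose(K, np.diag([2.0, 2.0]), rtol=1e-8)

    def test_commuting_pair(self):
        K = spd.karcher_mean([np.diag([1.0, 4.0]), np.diag([4.0, 1.0])])
        assert np.allclose(K, np.diag([2.0, 2.0]), rtol=1e-8)

    def test_two_point_matches_closed_form(self, rng):
        A, B = random_spd(rng, 5), random_spd(rng, 5)
        K = spd.karcher_mean([A, B])
        mid = spd.geodesic_interpolate(A, B, 0.5)
        assert np.linalg.norm(K - mid) / np.linalg.norm(mid) < 1e-8

    def test_midpoint_determinant_is_geometric_mean(self, rng):
        A, B = random_spd(rng, 4), random_spd(rng, 4)
        K = spd.karcher_mean([A, B])
        expected = np.sqrt(np.linalg.det(A) * np.linalg.det(B))
        assert np.linalg.det(K) == pytest.approx(expected, rel=1e-8)

    def test_congruence_invariance(self, rng):
        A, B = random_spd(rng, 4), random_spd(rng, 4)
        W = rng.standard_normal((4, 4)) + 0.5 * np.eye(4)
        K = spd.karcher_mean([A, B])
        Kw = spd.karcher_mean([W @ A @ W.T, W @ B @ W.T])
        assert np.linalg.norm(Kw - W @ K @ W.T) < 1e-8 * np.linalg.norm(Kw)

    def test_first_order_optimality_many(self, rng):
        mats = [random_spd(rng, 4) for _ in range(5)]
        K = spd.karcher_mean(mats, tol=1e-10, max_iter=200)
        grad = sum(spd.log_map(K, C) for C in mats) / len(mats)
        assert np.linalg.norm(grad) < 1e-8 * np.trace(K) / 4

    def test_weighted_interpolation(self):
        # commuting diagonals: elementwise geometric interpolation
        A, B = np.diag([1.0, 8.0]), np.diag([4.0, 2.0])
        K = spd.karcher_mean([A, B], weights=[0.25, 0.75])
        expected = np.diag([1.0 ** 0.25 * 4.0 ** 0.75,
                            8.0 ** 0.25 * 2.0 ** 0.75])
        assert np.allclose(K, expected, rtol=1e-8)

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            spd.karcher_mean([np.eye(2), np.eye(2)], weights=[0.7, 0.7])


def test_swelling_effect(rng):
    """det(Euclidean mean) >= det(Karcher mean); strict when non-commuting."""
    strict = 0
    for _ in range(200):
        A, B = random_spd(rng, 4), random_spd(rng, 4)
        det_euc = np.linalg.det((A + B) / 2.0)
        det_kar = np.linalg.det(spd.karcher_mean([A, B]))
        assert det_euc >= det_kar * (1.0 - 1e-10)
        if np.linalg.norm(A @ B - B @ A) > 1e-8:
            assert det_euc > det_kar
            strict += 1
    assert strict == 200  # random pairs essentially never commute


class TestGeometricMedian:
    @staticmethod
    def objective(mats, U):
        return sum(np.linalg.norm(C - U) for C in mats)

    def test_single_matrix(self, rng):
        A = random_spd(rng, 3)
        assert np.allclose(spd.geometric_median_euclidean([A]), A)

    def test_majority_point(self, rng):
        A, B = random_spd(rng, 2), random_spd(rng, 2)
        med = spd.geometric_median_euclidean([A, A, B])
        # with a 2-to-1 majority the L1 median is the majority point
        assert np.linalg.norm(med - A) < 1e-6 * np.linalg.norm(A)

    def test_beats_elementwise_mean(self, rng):
        mats = [random_spd(rng, 3) for _ in range(7)]
        med = spd.geometric_median_euclidean(mats)
        assert self.objective(mats, med) <= \
            self.objective(mats, np.mean(mats, axis=0)) + 1e-12

    def test_matches_general_purpose_minimizer(self, rng):
        for _ in range(5):
            mats = [random_spd(rng, 3) for _ in range(6)]
            med = spd.geometric_median_euclidean(mats, tol=1e-12,
                                                 max_iter=500)
            iu = np.triu_indices(3)

            def obj(v):
                S = np.zeros((3, 3))
                S[iu] = v
                S[(iu[1], iu[0])] = v
                return self.objective(mats, S)

            x0 = np.mean(mats, axis=0)[iu]
            ref = scipy.optimize.minimize(obj, x0, method="Nelder-Mead",
                                          options={"xatol": 1e-10,
                                                   "fatol": 1e-12,
                                                   "maxiter": 20000})
            assert self.objective(mats, med) <= ref.fun + 1e-6


class TestPGA:
    def test_geodesic_family_is_one_dimensional(self, rng):
        base = random_spd(rng, 4)
        V = rng.standard_normal((4, 4))
        V = (V + V.T) / 2.0
        mats = [spd.exp_map(base, t * V) for t in (-0.4, -0.2, 0.0, 0.2, 0.4)]
        _, variances = spd.pga(mats, base="karcher")
        assert variances[0] / variances.sum() >= 0.99

    def test_identical_inputs_zero_variance(self, rng):
        A = random_spd(rng, 3)
        _, variances = spd.pga([A] * 4, base=A)
        assert np.all(variances < 1e-16 * np.trace(A) ** 2)

    def test_variances_sorted_nonnegative(self, rng):
        mats = [random_spd(rng, 3) for _ in range(8)]
        _, variances = spd.pga(mats)
        assert np.all(variances >= 0)
        assert np.all(np.diff(variances) <= 1e-12)

    def test_commuting_family_diagonal_directions(self, rng):
        mats = [np.diag(np.exp(rng.standard_normal(3))) for _ in range(6)]
        directions, variances = spd.pga(mats, base=np.eye(3))
        for W, var in zip(directions, variances):
            if var > 1e-12 * variances[0]:
                off = W - np.diag(np.diag(W))
                assert np.linalg.norm(off) < 1e-8 * np.linalg.norm(W)

    def test_needs_two_matrices(self, rng):
        with pytest.raises(ValueError):
            spd.pga([random_spd(rng, 3)])


def test_sym_vec_round_trip_preserves_inner_product(rng):
    for _ in range(10):
        S1 = rng.standard_normal((5, 5))
        S1 = (S1 + S1.T) / 2
        S2 = rng.standard_normal((5, 5))
        S2 = (S2 + S2.T) / 2
        v1, v2 = spd.sym_to_vec(S1), spd.sym_to_vec(S2)
        assert v1 @ v2 == pytest.approx(np.sum(S1 * S2), rel=1e-12)
        assert np.allclose(spd.vec_to_sym(v1, 5), S1, atol=1e-12)


class TestSampleCovariance:
    def test_hand_computed(self):
        X = np.array([[1.0, -1.0, 0.0], [0.0, 0.0, 0.0]])
        U = spd.sample_covariance_unbiased(X, regularize=False)
        assert np.allclose(U, [[1.0, 0.0], [0.0, 0.0]])

    def test_zero_segment_regularized(self):
        U = spd.sample_covariance_unbiased(np.zeros((3, 10)))
        assert np.linalg.eigvalsh(U).min() > 0

    def test_law_of_large_numbers(self, rng):
        true = np.array([[2.0, 0.7], [0.7, 1.0]])
        L = np.linalg.cholesky(true)
        X = L @ rng.standard_normal((2, 10_000))
        U = spd.sample_covariance_unbiased(X)
        assert np.all(np.abs(U - true) / np.abs(true) < 0.05)

    def test_too_short(self):
        with pytest.raises(ValueError):
            spd.sample_covariance_unbiased(np.zeros((3, 1)))


# property-based checks over a broader family of SPD matrices
from hypothesis import given, settings, strategies as st


def spd_from(seed: int, c: int, log_range: float) -> np.ndarray:
    r = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(r.standard_normal((c, c)))
    lam = np.exp(r.uniform(-log_range, log_range, c))
    return (Q * lam) @ Q.T


@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2 ** 31 - 1), c=st.integers(2, 8),
       log_range=st.floats(0.1, 2.5))
def test_exp_log_inverse_property(seed, c, log_range):
    r = np.random.default_rng(seed)
    base = spd_from(seed, c, log_range)
    P = spd_from(seed + 1, c, log_range)
    back = spd.exp_map(base, spd.log_map(base, P))
    assert np.linalg.norm(back - P) / np.linalg.norm(P) < 1e-7


@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2 ** 31 - 1), c=st.integers(2, 8),
       w=st.floats(0.0, 1.0))
def test_geodesic_interpolation_distance_property(seed, c, w):
    """The geodesic point at parameter w splits d(A,B) as w : (1-w)."""
    A = spd_from(seed, c, 1.5)
    B = spd_from(seed + 1, c, 1.5)
    G = spd.geodesic_interpolate(A, B, w)
    d = spd.geodesic_distance(A, B)
    assert spd.geodesic_distance(A, G) == pytest.approx(w * d, abs=1e-7)
    assert spd.geodesic_distance(G, B) == pytest.approx((1 - w) * d, abs=1e-7)
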