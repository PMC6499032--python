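"""Streaming correction engines: smoothing, detection, reconstruction."""

import numpy as np
import pytest

from rasr import EEGSegment, calibrate, default_params
from rasr import spd
from rasr.processing import (detect_components, process, process_offline,
                             flush, reconstruct, reconstruction_operator,
                             smooth_covariance_euclidean,
                             smooth_covariance_riemannian)

from conftest import random_spd


def white_segment(seed=0, c=24, seconds=60.0, srate=250.0, scale=10.0):
    rng = np.random.default_rng(seed)
    return EEGSegment(scale * rng.standard_normal((c, int(seconds * srate))),
                      srate)


class TestSmoothing:
    def test_euclidean_weight_one(self, rng):
        A, B = random_spd(rng, 3), random_spd(rng, 3)
        assert np.array_equal(smooth_covariance_euclidean(A, B, 1.0), A)

    def test_euclidean_half(self):
        out = smooth_covariance_euclidean(np.diag([1.0, 1.0]),
                                          np.diag([3.0, 3.0]), 0.5)
        assert np.allclose(out, np.diag([2.0, 2.0]))

    def test_empty_prev_returns_current(self, rng):
        A = random_spd(rng, 3)
        assert np.array_equal(smooth_covariance_euclidean(A, None, 0.3), A)
        assert np.array_equal(smooth_covariance_riemannian(A, None, 0.3), A)

    def test_riemannian_midpoint(self):
        out = smooth_covariance_riemannian(np.eye(2), np.diag([4.0, 4.0]), 0.5)
        assert np.allclose(out, np.diag([2.0, 2.0]), rtol=1e-10)

    def test_riemannian_weighted_commuting(self):
        w = 0.3
        cur, prev = np.diag([4.0, 1.0]), np.diag([1.0, 4.0])
        out = smooth_covariance_riemannian(cur, prev, w)
        expected = np.diag([1.0 ** (1 - w) * 4.0 ** w,
                            4.0 ** (1 - w) * 1.0 ** w])
        assert np.allclose(out, expected, rtol=1e-10)

    def test_determinant_ordering(self, rng):
        # Euclidean averaging swells the determinant; Karcher does not
        for _ in range(20):
            A, B = random_spd(rng, 4), random_spd(rng, 4)
            det_g = np.sqrt(np.linalg.det(A) * np.linalg.det(B))
            det_r = np.linalg.det(smooth_covariance_riemannian(A, B, 0.5))
            det_e = np.linalg.det(smooth_covariance_euclidean(A, B, 0.5))
            assert det_r == pytest.approx(det_g, rel=1e-8)
            assert det_e >= det_g * (1 - 1e-10)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            smooth_covariance_euclidean(np.eye(2), np.eye(3), 0.5)


@pytest.fixture(scope="module")
def white_state():
    seg = white_segment()
    p = default_params("asr")
    return seg, p, calibrate(seg, p)


class TestDetectComponents:
    def test_calibration_covariance_is_clean(self, white_state):
        _, _, calib = white_state
        _, _, clean = detect_components(calib.covariance(), calib)
        assert clean.all()

    def test_rank_one_perturbation(self, white_state, rng):
        _, _, calib = white_state
        c = calib.n_channels
        v = rng.standard_normal(c)
        v /= np.linalg.norm(v)
        kappa = 100.0 * np.trace(calib.covariance())
        V, D, clean = detect_components(
            calib.covariance() + kappa * np.outer(v, v), calib)
        assert (~clean).sum() == 1
        assert not clean[-1]  # the inflated direction is the top eigenvalue
        assert abs(V[:, -1] @ v) > 0.999

    def test_infinite_cutoff_all_clean(self, white_state, rng):
        seg, p, _ = white_state
        calib_inf = calibrate(seg, p.replace(cutoff=1e9))
        cov = random_spd(rng, seg.n_channels, spread=2.0)
        _, _, clean = detect_components(cov * np.trace(calib_inf.covariance()),
                                        calib_inf)
        assert clean.all()

    def test_maxdims_forces_low_components_kept(self, white_state):
        _, _, calib = white_state
        c = calib.n_channels
        _, _, clean = detect_components(1e9 * calib.covariance(), calib,
                                        maxdims=4)
        assert clean[:c - 4].all()
        assert not clean[c - 4:].any()


class TestReconstruct:
    def test_all_clean_is_bit_identical(self, rng):
        X = EEGSegment(rng.standard_normal((3, 100)), 100.0)
        out = reconstruct(X, np.eye(3), np.eye(3), np.ones(3, bool))
        assert out is X

    def test_canonical_flag_zeroes_row(self, rng):
        X = EEGSegment(rng.standard_normal((2, 50)), 100.0)
        out = reconstruct(X, np.eye(2), np.eye(2), np.array([True, False]))
        assert np.allclose(out.data[1], 0.0)
        assert np.allclose(out.data[0], X.data[0])

    def test_energy_non_expansion(self, white_state, rng):
        _, _, calib = white_state
        c = calib.n_channels
        for _ in range(10):
            Q, _ = np.linalg.qr(rng.standard_normal((c, c)))
            mask = rng.random(c) > 0.3
            if not mask.any():
                mask[0] = True
            R = reconstruction_operator(calib.M, Q, mask)
            assert np.linalg.norm(R, 2) <= 1.0 + 1e-9

    def test_no_clean_components_raises(self, rng):
        X = EEGSegment(rng.standard_normal((2, 10)), 100.0)
        with pytest.raises(ValueError):
            reconstruct(X, np.eye(2), np.eye(2), np.zeros(2, bool))


class TestProcess:
    def test_range_arithmetic(self, white_state):
        seg, p, calib = white_state
        _, state = process_offline(seg, calib, p)
        assert state.range_samples == 125  # 250 Hz * 0.5 s

    def test_output_length_and_determinism(self, white_state):
        seg, p, calib = white_state
        out1, _ = process_offline(seg, calib, p)
        out2, _ = process_offline(seg, calib, p)
        assert out1.n_samples == seg.n_samples
        assert np.array_equal(out1.data, out2.data)

    @pytest.mark.parametrize("method", ["asr", "rasr"])
    def test_chunked_equals_offline(self, method):
        seg = white_segment(seconds=8.0, seed=11)
        p = default_params(method)
        calib = calibrate(white_segment(seconds=30.0, seed=12), p)
        offline, _ = process_offline(seg, calib, p)
        state = None
        parts = []
        for i in range(0, seg.n_samples, 250):
            chunk = seg.with_data(seg.data[:, i:i + 250])
            out, state = process(chunk, calib, p, state)
            parts.append(out.data)
        parts.append(flush(state, seg).data)
        online = np.concatenate(parts, axis=1)
        assert online.shape == offline.data.shape
        rms = np.sqrt(np.mean((online - offline.data) ** 2))
        assert rms < 1e-6

    def test_montage_mismatch(self, white_state):
        seg, p, calib = white_state
        other = EEGSegment(seg.data[:10], seg.srate)
        with pytest.raises(ValueError, match="incompatible"):
            process(other, calib, p)

    @pytest.mark.parametrize("method,expected_interval",
                             [("asr", 32), ("rasr", 75)])
    def test_decomposition_count(self, method, expected_interval):
        seg = white_segment(seconds=10.0, seed=21)
        p = default_params(method)
        calib = calibrate(white_segment(seconds=30.0, seed=22), p)
        _, state = process_offline(seg, calib, p)
        assert state.n_eigendecompositions == seg.n_samples // expected_interval

    def test_riemannian_fewer_decompositions_same_params(self):
        """With identical window/stepsize the riemannian engine decomposes
        range/stepsize-fold less often."""
        seg = white_segment(seconds=10.0, seed=31)
        counts = {}
        for method in ("asr", "rasr"):
            p = default_params(method, window=0.5, stepsize=25)
            calib = calibrate(white_segment(seconds=30.0, seed=32), p)
            _, state = process_offline(seg, calib, p)
            counts[method] = state.n_eigendecompositions
        assert counts["asr"] == counts["rasr"] * (125 // 25)
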