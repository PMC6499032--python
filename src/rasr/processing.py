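"""Streaming artifact correction: the ASR / rASR processing loop.

Both engines walk the recording causally and keep a smoothed estimate of
the short-time channel covariance.  At every update point the smoothed
covariance is eigendecomposed, each component's variance is compared
against the calibration threshold operator projected onto the new basis,
and flagged components are reprojected onto the clean subspace through the
calibration mixing matrix:

    X_clean = M (V_clean^T M)^+ V^T X

The two geometries differ exactly where the covariance matrices are
touched:

* euclidean (classic ASR) — a moving-average covariance over the analysis
  window, updated and decomposed every ``stepsize`` samples (many
  decompositions per window), smoothed with a weighted Euclidean average;
* riemannian (rASR) — one unbiased estimator covariance per analysis
  window (``X X^T / (t-1)``), smoothed with the previous estimate by a
  two-point Karcher mean along the geodesic, decomposed once per window.

Successive reconstruction operators are cross-faded with a raised-cosine
ramp over a ``stepsize``-sample overlap, so corrections switch on and off
without steps.  Output is emitted with a fixed latency of half an analysis
window, which centres each window on the samples it corrects — detection
and artifact then coincide instead of the correction trailing the artifact
by a window.  No sample ever depends on data beyond its own analysis
window, and the streaming API is exact: feeding the recording in chunks
(plus the carried state) produces bit-identical output to one offline
call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal

from . import spd
from .calibration import CalibrationState, apply_shaping, design_shaping_filter
from .params import ASRParams
from .segments import EEGSegment

__all__ = [
    "ProcessingState",
    "smooth_covariance_euclidean",
    "smooth_covariance_riemannian",
    "detect_components",
    "reconstruction_operator",
    "reconstruct",
    "process",
    "process_offline",
]


def smooth_covariance_euclidean(current: np.ndarray,
                                prev: np.ndarray | None,
                                weight: float) -> np.ndarray:
    """Weighted Euclidean average ``weight*current + (1-weight)*prev``."""
    if prev is None:
        return np.asarray(current, float)
    current = np.asarray(current, float)
    prev = np.asarray(prev, float)
    if current.shape != prev.shape:
        raise ValueError("covariance dimensions differ")
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    return weight * current + (1.0 - weight) * prev


def smooth_covariance_riemannian(current: np.ndarray,
                                 prev: np.ndarray | None,
                                 weight: float) -> np.ndarray:
    """Two-point weighted Karcher mean of {current, prev}.

    The point at parameter ``weight`` on the geodesic from ``prev`` to
    ``current``; for equal weights the geometric (midpoint) mean, whose
    determinant is sqrt(det(prev) * det(current)) — no swelling.
    """
    if prev is None:
        return np.asarray(current, float)
    if np.asarray(current).shape != np.asarray(prev).shape:
        raise ValueError("covariance dimensions differ")
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    if weight == 1.0:
        return np.asarray(current, float)
    if weight == 0.0:
        return np.asarray(prev, float)
    return spd.geodesic_interpolate(spd.regularize_spd(prev),
                                    spd.regularize_spd(current), weight)


def detect_components(cov: np.ndarray, calib: CalibrationState,
                      maxdims: int | None = None):
    """Eigendecompose a covariance and test components against T.

    Components are ordered by ascending eigenvalue.  Component j is
    artifactual when its eigenvalue exceeds the squared projected
    threshold ``sum_i (T @ V_new)_{ij}**2``.  Only the top ``maxdims``
    components are eligible for reconstruction; lower components are kept
    unconditionally (removing too many dimensions is unrepairable).

    Returns ``(V_new, D_new, clean_mask)``.
    """
    cov = np.asarray(cov, float)
    c = calib.n_channels
    if cov.shape != (c, c):
        raise ValueError(f"covariance shape {cov.shape} does not match "
                         f"calibration ({c} channels)")
    D_new, V_new = np.linalg.eigh((cov + cov.T) / 2.0)
    limits = np.sum((calib.T @ V_new) ** 2, axis=0)
    clean = D_new <= limits
    if maxdims is not None:
        forced = np.arange(c) < (c - int(maxdims))
        clean = clean | forced
    return V_new, D_new, clean


def reconstruction_operator(M: np.ndarray, V: np.ndarray,
                            clean_mask: np.ndarray) -> np.ndarray | None:
    """Operator R with ``X_clean = R @ X``; identity when all clean.

    ``R = M ((clean * V^T M))^+ V^T`` — flagged components' rows of V^T M
    are zeroed before the pseudoinverse, so their variance is reprojected
    onto the span of the clean components as seen through the calibration
    mixing matrix.  When V equals the calibration eigenbasis this is an
    orthogonal projector; for rotated bases the raw formula can amplify
    (the pseudoinverse mixes well- and poorly-expressed calibration
    directions), so the operator is made non-expansive by clipping its
    singular values at 1 — artifact correction must never add energy.

    Returns None when no component is clean (degenerate window; the
    caller holds the previous operator).
    """
    clean_mask = np.asarray(clean_mask, bool)
    if clean_mask.all():
        return np.eye(M.shape[0])
    if not clean_mask.any():
        return None
    VtM = V.T @ M
    R = M @ np.linalg.pinv(clean_mask[:, None] * VtM) @ V.T
    U_, s, Vt_ = np.linalg.svd(R)
    if s[0] > 1.0:
        R = (U_ * np.minimum(s, 1.0)) @ Vt_
    return R


def reconstruct(X: EEGSegment, M: np.ndarray, V: np.ndarray,
                clean_mask: np.ndarray) -> EEGSegment:
    """Apply subspace reconstruction to one segment with a fixed mask.

    When every component is clean the input is returned unchanged (the
    operator is exactly the identity).  When no component is clean the
    input cannot be repaired and a ValueError is raised; the streaming
    engine instead holds the previous window's operator.
    """
    clean_mask = np.asarray(clean_mask, bool)
    if clean_mask.all():
        return X
    R = reconstruction_operator(np.asarray(M, float), np.asarray(V, float),
                                clean_mask)
    if R is None:
        raise ValueError("no clean components; degenerate window")
    return X.with_data(R @ X.data)


@dataclass
class ProcessingState:
    """Carry-over between streaming calls.

    Holds the shaping-filter delay line, the filtered-sample history that
    covariance windows need, the raw samples whose reconstruction operator
    is not yet known, the smoothed covariance U(s-1), and the previous
    reconstruction operator (identity until an artifact is seen).  Also
    carries instrumentation: the number of eigendecompositions performed.
    """

    srate: float
    n_channels: int
    range_samples: int          # analysis window in samples
    update_interval: int        # samples between operator updates
    ramp_samples: int           # raised-cosine cross-fade length (stepsize)
    delay: int                  # output latency: half an analysis window
    weight: float               # forgetting weight of the current covariance
    burst_threshold: float | None  # gate on log lambda_max(U_cal^-1 C_seg)
    calib_cov: np.ndarray | None   # calibration covariance U = M M^T
    geometry: str
    maxdims: int
    shaping_b: np.ndarray | None = None
    zi: np.ndarray | None = None
    fhist: np.ndarray | None = None        # filtered history before pending
    pending_filt: np.ndarray | None = None
    raw_buffer: np.ndarray | None = None   # raw samples awaiting emission
    buf_start: int = 0                     # global index of raw_buffer[:, 0]
    n_received: int = 0                    # raw samples received so far
    next_update: int = 0                   # global index of the next update
    emit_global: int = 0                   # next raw index to emit
    prev_cov: np.ndarray | None = None
    burst_cov: np.ndarray | None = None    # accumulator within a burst run
    prev_R: np.ndarray | None = None       # None encodes exact identity
    n_eigendecompositions: int = 0
    n_updates: int = 0
    n_flagged_updates: int = 0

    @property
    def flag_rate(self) -> float:
        """Fraction of updates with at least one flagged component."""
        return self.n_flagged_updates / self.n_updates if self.n_updates else 0.0


def _init_state(calib: CalibrationState, params: ASRParams) -> ProcessingState:
    rng_samples = params.range_samples(calib.srate)
    if params.geometry == "riemannian":
        update = rng_samples
    else:
        update = min(params.stepsize, rng_samples)
    b = design_shaping_filter(calib.srate) if calib.use_shaping else None
    c = calib.n_channels
    return ProcessingState(
        srate=calib.srate, n_channels=c, range_samples=rng_samples,
        update_interval=update,
        ramp_samples=min(params.stepsize, update),
        burst_threshold=calib.burst_threshold,
        calib_cov=calib.covariance() if params.geometry == "riemannian"
        else None,
        # the calibration covariance is the natural prior for the running
        # estimate: no ramp-in of spurious detections before the smoother
        # has history
        prev_cov=calib.covariance(),
        # euclidean: moving window straddles the samples it corrects
        # (half-window output latency); riemannian: each segment is
        # corrected by its own covariance (block == window, no extra lag)
        delay=0 if params.geometry == "riemannian" else rng_samples // 2,
        weight=params.smoothing_weight(calib.srate),
        geometry=params.geometry, maxdims=params.resolve_maxdims(c),
        shaping_b=b, next_update=update,
        raw_buffer=np.zeros((c, 0)), pending_filt=np.zeros((c, 0)),
        fhist=np.zeros((c, 0)),
    )


def _blend_apply(raw: np.ndarray, R_old: np.ndarray | None,
                 R_new: np.ndarray | None, alpha: np.ndarray) -> np.ndarray:
    """Raised-cosine cross-fade from R_old to R_new across a block.

    ``alpha`` gives the per-sample mix (0 = old operator, 1 = new).
    ``None`` stands for the exact identity; an all-identity block passes
    through bit-identical.
    """
    if R_old is None and R_new is None:
        return raw
    c = raw.shape[0]
    I = np.eye(c)
    A = I if R_old is None else R_old
    B = I if R_new is None else R_new
    return (1.0 - alpha) * (A @ raw) + alpha * (B @ raw)


def process(data: EEGSegment, calib: CalibrationState, params: ASRParams,
            state: ProcessingState | None = None):
    """Feed one chunk through the correction engine.

    Returns ``(cleaned, state)`` where ``cleaned`` contains the corrected
    samples whose reconstruction operator is already committed.  Output
    trails input by a fixed latency of half an analysis window plus at
    most one update interval; :func:`flush` emits the tail.  Repeated
    calls with consecutive chunks reproduce the offline result exactly.
    """
    if data.srate != calib.srate or data.n_channels != calib.n_channels or \
            list(data.labels) != list(calib.labels):
        raise ValueError("recording is incompatible with the calibration "
                         "(montage or sampling rate differs)")
    if state is None:
        state = _init_state(calib, params)

    raw = data.data
    if state.shaping_b is not None:
        filt, state.zi = apply_shaping(raw, state.shaping_b, state.zi)
    else:
        filt = raw
    state.raw_buffer = np.concatenate([state.raw_buffer, raw], axis=1)
    state.pending_filt = np.concatenate([state.pending_filt, filt], axis=1)
    state.n_received += raw.shape[1]

    L = state.update_interval
    N = state.range_samples
    D = state.delay
    out_blocks = []
    while state.n_received >= state.next_update:
        u = state.next_update
        block_filt = state.pending_filt[:, :L]
        # covariance of the analysis window ending at this update
        if state.geometry == "riemannian":
            seg = block_filt           # L == range
            C_cur = spd.regularize_spd(seg @ seg.T / max(seg.shape[1] - 1, 1))
            # burst gate: within the calibration range the running Karcher
            # mean smooths eigenvalue jitter; far outside it (an artifact
            # burst) the current estimator is trusted outright, so the
            # decomposition basis stays aligned with the artifact instead
            # of being warped by the geometric mean of background and burst
            burst = False
            if state.burst_threshold is not None:
                lam_max = scipy.linalg.eigvalsh(C_cur, state.calib_cov)[-1]
                burst = bool(np.log(lam_max) > state.burst_threshold)
            if burst:
                # freeze the background reference (it must not absorb
                # artifact variance) and smooth like with like: within a
                # run of burst segments the current estimator is combined
                # with the previous *burst* covariance, never with the
                # background — the geometric mean of background and burst
                # would warp the decomposition basis away from the artifact
                C_smooth = smooth_covariance_riemannian(
                    C_cur, state.burst_cov, 0.5)
                state.burst_cov = C_smooth
            else:
                state.burst_cov = None
                C_smooth = smooth_covariance_riemannian(
                    C_cur, state.prev_cov, state.weight)
        else:
            need = N - L
            hist = state.fhist[:, max(0, state.fhist.shape[1] - need):]
            win = np.concatenate([hist, block_filt], axis=1)
            # zero-pad the ramp-in: divide by the full window length
            C_cur = win @ win.T / N
            burst = False
            C_smooth = smooth_covariance_euclidean(
                C_cur, state.prev_cov, state.weight)
        if not burst:
            state.prev_cov = C_smooth

        V_new, D_new, clean = detect_components(C_smooth, calib,
                                                maxdims=state.maxdims)
        state.n_eigendecompositions += 1
        state.n_updates += 1
        if not clean.all():
            state.n_flagged_updates += 1
            R_new = reconstruction_operator(calib.M, V_new, clean)
            if R_new is None:          # fully degenerate: hold previous
                R_new = state.prev_R
        else:
            R_new = None               # exact identity

        # emit the raw block this update governs: global (u-L-D, u-D],
        # ramping from the previous operator to the new one across it
        g0, g1 = u - L - D, u - D
        e0 = max(g0, state.emit_global)
        if g1 > e0:
            sl = slice(e0 - state.buf_start, g1 - state.buf_start)
            ramp = _raised_cosine(state.ramp_samples)
            alpha = np.concatenate([ramp, np.ones(L - len(ramp))])
            alpha = alpha[e0 - g0:g1 - g0]
            out_blocks.append(_blend_apply(state.raw_buffer[:, sl],
                                           state.prev_R, R_new, alpha))
            state.emit_global = g1
            state.raw_buffer = state.raw_buffer[:, g1 - state.buf_start:]
            state.buf_start = g1
        state.prev_R = R_new

        state.fhist = np.concatenate([state.fhist, block_filt], axis=1)
        keep = max(N - L, 0)
        state.fhist = state.fhist[:, state.fhist.shape[1] - keep:] if keep \
            else state.fhist[:, :0]
        state.pending_filt = state.pending_filt[:, L:]
        state.next_update = u + L

    out = np.concatenate(out_blocks, axis=1) if out_blocks \
        else np.zeros((data.n_channels, 0))
    return data.with_data(out), state


def _raised_cosine(L: int) -> np.ndarray:
    return (1.0 - np.cos(np.pi * np.arange(1, L + 1) / L)) / 2.0


def flush(state: ProcessingState, template: EEGSegment) -> EEGSegment:
    """Emit the buffered tail with the last committed operator applied."""
    raw = state.raw_buffer
    n_tail = state.n_received - state.emit_global
    if raw is None or n_tail <= 0:
        out = np.zeros((state.n_channels, 0))
    else:
        tail = raw[:, state.emit_global - state.buf_start:]
        out = tail.copy() if state.prev_R is None else state.prev_R @ tail
        state.emit_global = state.n_received
        state.raw_buffer = raw[:, :0]
        state.buf_start = state.n_received
    return template.with_data(out)


def process_offline(data: EEGSegment, calib: CalibrationState,
                    params: ASRParams):
    """One-call correction of a complete recording.

    Internally loops the streaming engine and flushes the tail; output
    length equals input length.  Returns ``(cleaned, state)`` so callers
    can inspect the instrumentation counters.
    """
    cleaned, state = process(data, calib, params)
    tail = flush(state, data)
    out = np.concatenate([cleaned.data, tail.data], axis=1)
    return data.with_data(out), state
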