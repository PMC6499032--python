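"""Pre-correction stages: band-limiting, flatline detection, drift removal.

The cleaning pipeline runs flatline detection first, then drift removal,
then the subspace correction itself.  Offline filtering is zero-phase
(forward-backward) as is standard for ERP work; a causal mode with the
filter's group delay is available for online use.
"""

from __future__ import annotations

import numpy as np
import scipy.signal

from .segments import EEGSegment

__all__ = [
    "bandpass_fir",
    "detect_flatlines",
    "remove_drifts",
    "run_pre_stages",
]


def _apply_fir(data: np.ndarray, taps: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        padlen = min(3 * len(taps), data.shape[1] - 1)
        return scipy.signal.filtfilt(taps, [1.0], data, axis=-1, padlen=padlen)
    return scipy.signal.lfilter(taps, [1.0], data, axis=-1)


def bandpass_fir(data: EEGSegment, lp_hz: float = 40.0, lp_order: int = 166,
                 hp_hz: float = 0.25, hp_order: int = 3300,
                 zero_phase: bool = True) -> EEGSegment:
    """Band-limit a recording with linear-phase FIR filters.

    Defaults: 40 Hz low pass of order 166 and 0.25 Hz high pass of order
    3300 (Hamming-window designs).  Zero-phase application by default.

    Raises
    ------
    ValueError
        If the segment is shorter than the longest filter.
    """
    t = data.n_samples
    max_order = max(lp_order, hp_order)
    if t <= max_order:
        raise ValueError(
            f"segment ({t} samples) shorter than filter order {max_order}")
    ny = data.srate / 2.0
    lp = scipy.signal.firwin(lp_order + 1, lp_hz / ny, window="hamming")
    hp = scipy.signal.firwin(hp_order + 1, hp_hz / ny, window="hamming",
                             pass_zero=False)
    out = _apply_fir(data.data, lp, zero_phase)
    out = _apply_fir(out, hp, zero_phase)
    return data.with_data(out)


def detect_flatlines(data: EEGSegment, max_flat_seconds: float,
                     tol: float = 1e-8) -> np.ndarray:
    """Mask channels containing a long flat stretch.

    A channel is flagged when it has a run of at least
    ``max_flat_seconds * srate`` consecutive samples whose successive
    absolute differences stay below ``tol`` microvolts.  The data are
    never altered.
    """
    if data.duration <= max_flat_seconds:
        raise ValueError("recording shorter than the flatline criterion")
    run_needed = int(np.ceil(max_flat_seconds * data.srate))
    flat = np.abs(np.diff(data.data, axis=1)) < tol  # (c, t-1)
    mask = np.zeros(data.n_channels, dtype=bool)
    for ch in range(data.n_channels):
        f = flat[ch]
        if not f.any():
            continue
        # longest run of True
        edges = np.diff(np.concatenate(([0], f.view(np.int8), [0])))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        longest = int((ends - starts).max())
        # a run of r equal-diff pairs spans r+1 samples
        mask[ch] = (longest + 1) >= run_needed
    return mask


def remove_drifts(data: EEGSegment, transition_band=(0.25, 0.95),
                  zero_phase: bool = True, atten_db: float = 50.0) -> EEGSegment:
    """High-pass with the given transition band (Hz) to suppress drifts.

    A Kaiser-window FIR whose response rises from the stopband edge
    ``transition_band[0]`` to the passband edge ``transition_band[1]``.
    """
    lo, hi = transition_band
    if not 0 <= lo < hi:
        raise ValueError("transition band must satisfy 0 <= lo < hi")
    ny = data.srate / 2.0
    width = (hi - lo) / ny
    numtaps, beta = scipy.signal.kaiserord(atten_db, width)
    numtaps |= 1  # odd for a type-I high pass
    if data.n_samples <= numtaps:
        raise ValueError(
            f"segment ({data.n_samples} samples) shorter than the "
            f"{numtaps}-tap drift filter")
    cutoff = (lo + hi) / 2.0 / ny
    taps = scipy.signal.firwin(numtaps, cutoff, window=("kaiser", beta),
                               pass_zero=False)
    return data.with_data(_apply_fir(data.data, taps, zero_phase))


def run_pre_stages(data: EEGSegment, flatline_seconds: float,
                   hp_band=(0.25, 0.95), zero_phase: bool = True):
    """Flatline detection, then drift removal; the order the pipeline uses.

    Flagged flat channels are dropped from the returned segment (they are
    excluded from covariance estimation rather than interpolated).

    Returns ``(segment, flat_mask)`` where ``flat_mask`` refers to the
    input montage.
    """
    mask = detect_flatlines(data, flatline_seconds)
    if mask.any():
        keep = ~mask
        data = EEGSegment(
            data=data.data[keep], srate=data.srate,
            labels=[l for l, k in zip(data.labels, keep) if k])
    out = remove_drifts(data, hp_band, zero_phase=zero_phase)
    return out, mask
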