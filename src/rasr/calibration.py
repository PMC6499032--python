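"""Calibration: learn the statistical model from clean EEG.

Calibration fits the model every later correction decision rests on.  From
a stretch of artifact-poor EEG (at least the analysis window, ideally a
minute or more) it derives

1. a robust covariance centre U of windowed sample covariances —
   the Euclidean L1 geometric median for classic ASR, the Karcher mean for
   the Riemannian variant;
2. the mixing matrix M = U^{1/2} and the component basis V (eigenvectors,
   ascending);
3. per-component amplitude statistics (location mu_j and scale sigma_j of
   windowed RMS amplitudes of the component activations);
4. the threshold operator T = diag(mu + k * sigma) @ V.T whose squared row
   norms bound "normal" component variance during processing.

Amplitudes are measured after a fixed spectral-shaping filter that
up-weights the bands where artifacts dominate resting EEG (drifts below
~3 Hz, broadband above ~40 Hz); the identical causal filter runs in the
processing stage so calibration and detection statistics are directly
comparable.  A bypass flag is exposed for diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from . import spd
from .params import ASRParams
from .segments import EEGSegment

__all__ = [
    "CalibrationError",
    "CalibrationState",
    "design_shaping_filter",
    "apply_shaping",
    "windowed_covariances",
    "component_statistics",
    "threshold_operator",
    "calibrate",
]


class CalibrationError(ValueError):
    """Calibration data cannot support a model fit."""


def design_shaping_filter(srate: float) -> np.ndarray:
    """Minimum-phase FIR approximating an inverse-EEG-spectrum weighting.

    Amplitude breakpoints (Hz -> gain): 0->3, 2->0.75, 3->0.33, 13->0.33,
    16->1, 40->1, then rising to 3 at the upper edge.  Low-frequency drift
    and high-frequency broadband noise are amplified relative to the alpha
    band, so artifact variance trips the component thresholds sooner.  The
    design is a linear-phase FIR (firwin2) converted to minimum phase, so
    the causal group delay stays small and the same filter can run online.

    Returns the FIR taps ``b`` (denominator is 1).
    """
    ny = srate / 2.0
    f_hi = min(80.0, 0.9 * ny)
    pts = [0.0, 2.0, 3.0, 13.0, 16.0, 40.0, f_hi, ny]
    gains = [3.0, 0.75, 0.33, 0.33, 1.0, 1.0, 3.0, 3.0]
    freqs, amps = [], []
    for f, g in zip(pts, gains):
        if not freqs or f > freqs[-1] + 1e-9:
            freqs.append(min(f, ny))
            amps.append(g)
    freqs[-1] = ny
    numtaps = int(srate) + 1 - (int(srate) % 2)  # odd, ~1 s of taps
    numtaps = int(np.clip(numtaps, 101, 501))
    h = scipy.signal.firwin2(numtaps, freqs, amps, fs=srate)
    b = scipy.signal.minimum_phase(h, method="homomorphic")
    return b


def apply_shaping(data: np.ndarray, b: np.ndarray, zi: np.ndarray | None = None):
    """Causal FIR shaping with carried state; chunked calls == one call.

    ``zi=None`` initialises the delay line with the step response of the
    first sample, suppressing the onset transient.  Returns (filtered, zf).
    """
    data = np.asarray(data, float)
    if zi is None:
        zi0 = scipy.signal.lfilter_zi(b, [1.0])
        zi = zi0[None, :] * data[:, :1]
    y, zf = scipy.signal.lfilter(b, [1.0], data, axis=-1, zi=zi)
    return y, zf


def windowed_covariances(data: np.ndarray, wlen: int, unbiased: bool = False) -> list[np.ndarray]:
    """Sample covariances of consecutive non-overlapping windows.

    Per-sample scale: ``X_w X_w^T / t`` (or ``/(t-1)`` when ``unbiased``).
    """
    c, t = data.shape
    n_win = t // wlen
    if n_win < 1:
        raise CalibrationError("data shorter than one covariance window")
    denom = (wlen - 1) if unbiased else wlen
    covs = []
    for i in range(n_win):
        Xw = data[:, i * wlen:(i + 1) * wlen]
        covs.append(Xw @ Xw.T / denom)
    return covs


def component_statistics(activations: np.ndarray, window: float, srate: float,
                         robust: bool = True):
    """Location and scale of windowed RMS amplitudes, per component.

    RMS is computed in windows of ``window`` seconds with 50% overlap.
    The robust variant (default) uses the median and 1.4826 * MAD, which
    shrug off residual artifacts in the calibration stretch; the plain
    variant uses mean and SD.  Scales are floored at a tiny positive value
    so downstream thresholds remain well defined for perfectly periodic
    components.

    Raises
    ------
    CalibrationError
        If a component is identically zero (degenerate).
    """
    A = np.asarray(activations, float)
    c, t = A.shape
    wlen = max(2, int(round(window * srate)))
    if t < wlen:
        raise CalibrationError("activations shorter than one statistics window")
    step = max(1, wlen // 2)
    starts = range(0, t - wlen + 1, step)
    rms = np.array([[np.sqrt(np.mean(A[j, s:s + wlen] ** 2)) for s in starts]
                    for j in range(c)])
    if robust:
        mu = np.median(rms, axis=1)
        sigma = 1.4826 * np.median(np.abs(rms - mu[:, None]), axis=1)
    else:
        mu = rms.mean(axis=1)
        sigma = rms.std(axis=1, ddof=1) if rms.shape[1] > 1 else np.zeros(c)
    if np.any((mu == 0) & (sigma == 0)):
        bad = int(np.flatnonzero((mu == 0) & (sigma == 0))[0])
        raise CalibrationError(f"component {bad} has zero variance")
    floor = 1e-12 * np.maximum(mu, 1.0)
    sigma = np.maximum(sigma, floor)
    return mu, sigma


def threshold_operator(mu: np.ndarray, sigma: np.ndarray, k: float,
                       V: np.ndarray) -> np.ndarray:
    """Threshold operator ``T = diag(mu + k * sigma) @ V.T``.

    Row j has Euclidean norm mu_j + k * sigma_j (V orthonormal); during
    processing a component of a new eigenbasis V_new is artifactual when
    its covariance eigenvalue exceeds ``sum((T @ V_new)**2, axis=0)``, the
    squared threshold projected onto the new basis.
    """
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return np.diag(mu + k * sigma) @ np.asarray(V, float).T


@dataclass
class CalibrationState:
    """Everything learned from the calibration stretch.

    ``M`` (mixing matrix, M M^T = U), ``V``/``D`` (eigenvectors ascending /
    eigenvalues of M), per-component ``mu``/``sigma``, the threshold
    operator ``T``, the cutoff ``k``, montage metadata, and optional PGA
    diagnostics from riemannian calibration.
    """

    M: np.ndarray
    V: np.ndarray
    D: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    T: np.ndarray
    k: float
    srate: float
    labels: list[str]
    geometry: str = "euclidean"
    use_shaping: bool = True
    pga_variances: np.ndarray | None = None
    # upper bound of the clean-data burst statistic
    # log lambda_max(U^-1 C_window); gates the Karcher smoothing
    burst_threshold: float | None = None

    @property
    def n_channels(self) -> int:
        return self.M.shape[0]

    @property
    def thresholds(self) -> np.ndarray:
        """Per-component amplitude thresholds mu + k * sigma."""
        return self.mu + self.k * self.sigma

    def covariance(self) -> np.ndarray:
        """The calibration covariance U = M M^T."""
        return self.M @ self.M.T

    def to_dict(self) -> dict:
        d = {
            "M": self.M.tolist(), "V": self.V.tolist(), "D": self.D.tolist(),
            "mu": self.mu.tolist(), "sigma": self.sigma.tolist(),
            "T": self.T.tolist(), "k": self.k, "srate": self.srate,
            "labels": list(self.labels), "geometry": self.geometry,
            "use_shaping": self.use_shaping,
        }
        if self.pga_variances is not None:
            d["pga_variances"] = self.pga_variances.tolist()
        if self.burst_threshold is not None:
            d["burst_threshold"] = self.burst_threshold
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationState":
        pv = d.get("pga_variances")
        return cls(
            M=np.array(d["M"], float), V=np.array(d["V"], float),
            D=np.array(d["D"], float), mu=np.array(d["mu"], float),
            sigma=np.array(d["sigma"], float), T=np.array(d["T"], float),
            k=float(d["k"]), srate=float(d["srate"]),
            labels=list(d["labels"]), geometry=d.get("geometry", "euclidean"),
            use_shaping=bool(d.get("use_shaping", True)),
            pga_variances=None if pv is None else np.array(pv, float),
            burst_threshold=d.get("burst_threshold"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "CalibrationState":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def calibrate(calib: EEGSegment, params: ASRParams) -> CalibrationState:
    """Fit the calibration model on clean data.

    Pipeline: spectral shaping -> windowed sample covariances -> robust
    centre (L1 geometric median; Karcher mean in riemannian mode) ->
    M = U^{1/2} -> eigenbasis V -> component activations -> windowed-RMS
    statistics -> threshold operator.

    Raises
    ------
    CalibrationError
        Calibration shorter than one analysis window, or a flat channel.
    """
    wlen = params.range_samples(calib.srate)
    if calib.n_samples < wlen:
        raise CalibrationError(
            f"calibration ({calib.duration:.2f} s) shorter than the analysis "
            f"window ({params.window} s); at least 1 min is recommended")
    stds = calib.data.std(axis=1)
    if np.any(stds == 0):
        bad = calib.labels[int(np.flatnonzero(stds == 0)[0])]
        raise CalibrationError(f"channel {bad} is flat in the calibration data")

    if params.use_shaping:
        b = design_shaping_filter(calib.srate)
        Y, _ = apply_shaping(calib.data, b)
    else:
        Y = calib.data

    riemannian = params.geometry == "riemannian"
    covs = windowed_covariances(Y, wlen, unbiased=riemannian)
    if riemannian and params.riemannian_calibration:
        U = spd.karcher_mean(covs, tol=1e-8, max_iter=100)
    else:
        U = spd.geometric_median_euclidean(covs, tol=1e-8, max_iter=100)
    U = spd.regularize_spd(U)
    M = spd.sym_sqrt(U)
    d_u, V = np.linalg.eigh(U)          # ascending
    D = np.sqrt(np.clip(d_u, 0.0, None))  # eigenvalues of M

    pga_var = None
    burst_threshold = None
    if riemannian and len(covs) >= 2:
        if params.riemannian_calibration:
            _, pga_var = spd.pga(covs, base=U)
        # clean-data distribution of the burst statistic
        # b = log lambda_max(U^-1 C_w): how far the most-inflated direction
        # of a windowed covariance sits from the calibration covariance
        bs = np.array([
            np.log(scipy.linalg.eigvalsh(spd.regularize_spd(C), U)[-1])
            for C in covs])
        med = float(np.median(bs))
        mad = float(np.median(np.abs(bs - med)))
        # b is a maximum statistic (right-skewed); guard the tail with the
        # observed calibration maximum plus an e-fold margin for the
        # in-sample -> out-of-sample shift
        burst_threshold = max(med + 5.0 * 1.4826 * max(mad, 1e-3),
                              float(bs.max()) + 1.0)

    activations = V.T @ Y
    mu, sigma = component_statistics(activations, params.window, calib.srate,
                                     robust=params.robust_stats)
    T = threshold_operator(mu, sigma, params.cutoff, V)
    return CalibrationState(
        M=M, V=V, D=D, mu=mu, sigma=sigma, T=T, k=params.cutoff,
        srate=calib.srate, labels=list(calib.labels),
        geometry=params.geometry, use_shaping=params.use_shaping,
        pga_variances=pga_var, burst_threshold=burst_threshold,
    )
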