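"""Model / results interface over the calibration and processing engines.

Usage follows the fit-then-use pattern of statistical modelling packages::

    model = ASRModel(calibration_segment, method="rasr")
    res = model.fit()
    print(res.summary())
    cleaned = res.process(task_segment)       # offline
    stream = res.stream()                     # online
    for chunk in chunks:
        out = stream.process(chunk)
    tail = stream.flush()

:class:`ASRModel` holds the calibration data and the parameter set;
``fit()`` estimates the mixing matrix, component basis and per-component
thresholds and returns an :class:`ASRResults` carrying those estimates,
diagnostics, and the processing entry points.
"""

from __future__ import annotations

import numpy as np

from . import processing
from .calibration import CalibrationState, calibrate
from .params import ASRParams, default_params
from .segments import EEGSegment

__all__ = ["ASRModel", "ASRResults", "StreamProcessor"]


class ASRModel:
    """Artifact-subspace-reconstruction model for one montage.

    Parameters
    ----------
    calibration : EEGSegment or ndarray
        Clean calibration EEG (channels x samples).  Arrays need ``srate``.
    srate : float, optional
        Sampling rate when ``calibration`` is a bare array.
    labels : list of str, optional
        Channel names when ``calibration`` is a bare array.
    method : str
        ``"asr"`` or ``"rasr"``; selects the published parameter set.
    params : ASRParams, optional
        Full parameter set; overrides ``method``.
    **overrides
        Field-wise overrides of the method defaults (cutoff, window, ...).
    """

    def __init__(self, calibration, srate=None, labels=None,
                 method: str = "asr", params: ASRParams | None = None,
                 **overrides):
        if isinstance(calibration, EEGSegment):
            self.calibration = calibration
        else:
            if srate is None:
                raise ValueError("srate is required for array input")
            self.calibration = EEGSegment(np.asarray(calibration, float),
                                          srate, list(labels or []))
        self.params = params if params is not None \
            else default_params(method, **overrides)
        self.method = "rasr" if self.params.geometry == "riemannian" else "asr"

    @classmethod
    def from_segment(cls, segment: EEGSegment, method: str = "asr",
                     **overrides) -> "ASRModel":
        return cls(segment, method=method, **overrides)

    def fit(self, clean_calibration: bool = True) -> "ASRResults":
        """Estimate the calibration model.

        With ``clean_calibration`` (default, matching standard practice)
        the calibration stretch is first corrected with a model fitted on
        itself, and the final model is fitted on the cleaned stretch — so
        residual artifacts in the "clean" minute cannot inflate the
        thresholds.
        """
        calib_seg = self.calibration
        if clean_calibration:
            pre = calibrate(calib_seg, self.params)
            cleaned, _ = processing.process_offline(calib_seg, pre,
                                                    self.params)
            calib_seg = cleaned
        state = calibrate(calib_seg, self.params)
        return ASRResults(self, state)


class StreamProcessor:
    """Causal chunk-by-chunk processor bound to a fitted model."""

    def __init__(self, results: "ASRResults"):
        self._res = results
        self.state: processing.ProcessingState | None = None
        self._template: EEGSegment | None = None

    def process(self, chunk: EEGSegment) -> EEGSegment:
        """Feed a chunk; returns the samples whose correction is final."""
        self._template = chunk
        out, self.state = processing.process(
            chunk, self._res.calibration_state, self._res.params, self.state)
        return out

    def flush(self) -> EEGSegment:
        """Emit the buffered tail (last committed operator applied)."""
        if self.state is None or self._template is None:
            raise RuntimeError("nothing to flush: no chunk processed yet")
        return processing.flush(self.state, self._template)


class ASRResults:
    """Fitted calibration model plus processing entry points.

    Attributes
    ----------
    calibration_state : CalibrationState
        Mixing matrix M, basis V, eigenvalues D, per-component mu/sigma
        and the threshold operator T.
    params : ASRParams
        The parameter set the model was fitted with.
    last_state : ProcessingState or None
        Instrumented state of the most recent :meth:`process` call
        (decomposition counts, flag rate).
    """

    def __init__(self, model: ASRModel, state: CalibrationState):
        self.model = model
        self.calibration_state = state
        self.params = model.params
        self.last_state: processing.ProcessingState | None = None

    # -- estimates -----------------------------------------------------
    @property
    def mixing_matrix(self) -> np.ndarray:
        return self.calibration_state.M

    @property
    def thresholds(self) -> np.ndarray:
        return self.calibration_state.thresholds

    # -- use -----------------------------------------------------------
    def process(self, data: EEGSegment) -> EEGSegment:
        """Correct a complete recording offline."""
        cleaned, st = processing.process_offline(
            data, self.calibration_state, self.params)
        self.last_state = st
        return cleaned

    def stream(self) -> StreamProcessor:
        """A fresh causal streaming processor."""
        return StreamProcessor(self)

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        """Serialise the calibration state (JSON; bit-exact round trip)."""
        self.calibration_state.save(path)

    @classmethod
    def from_file(cls, path, params: ASRParams | None = None) -> "ASRResults":
        state = CalibrationState.load(path)
        if params is None:
            method = "rasr" if state.geometry == "riemannian" else "asr"
            params = default_params(method)
        dummy = ASRModel.__new__(ASRModel)
        dummy.calibration = None
        dummy.params = params
        dummy.method = "rasr" if params.geometry == "riemannian" else "asr"
        return cls(dummy, state)

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        """Human-readable per-component table of the fitted model."""
        st = self.calibration_state
        c = st.n_channels
        lines = [
            f"{'rASR' if st.geometry == 'riemannian' else 'ASR'} calibration "
            f"({c} channels, {st.srate:g} Hz, cutoff k={st.k:g})",
            "=" * 64,
            f"{'comp':>4} {'eigenvalue':>12} {'mu [uV]':>10} "
            f"{'sigma [uV]':>10} {'threshold':>10}",
            "-" * 64,
        ]
        thr = st.thresholds
        for j in range(c):
            lines.append(
                f"{j:>4} {st.D[j]:>12.4f} {st.mu[j]:>10.4f} "
                f"{st.sigma[j]:>10.4f} {thr[j]:>10.4f}")
        lines.append("-" * 64)
        lines.append(
            f"window {self.params.window:g} s, stepsize "
            f"{self.params.stepsize}, maxdims {self.params.maxdims:g} "
            f"({self.params.resolve_maxdims(c)} of {c} reconstructable)")
        if st.pga_variances is not None:
            total = st.pga_variances.sum()
            lead = st.pga_variances[0] / total if total > 0 else 0.0
            lines.append(
                f"PGA: leading geodesic component carries {100 * lead:.1f}% "
                f"of tangent variance")
        return "\n".join(lines)

    def __repr__(self) -> str:
        st = self.calibration_state
        return (f"<ASRResults {st.geometry} c={st.n_channels} "
                f"srate={st.srate:g} k={st.k:g}>")
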