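"""Parameter sets for ASR and rASR.

The two geometries ship with the per-method defaults evaluated in the
mobile-EEG study the package reproduces, quoted as (rASR, ASR) pairs:
flatline (1, 5) s, drift transition band (0.25, 0.95) Hz for both, window
(0.3, 0.5) s, cutoff (1, 5), stepsize (16, 32) samples, maxdims (1, 0.66).

``maxdims`` values <= 1 are fractions of the channel count (so the rASR
value 1 means "all dimensions reconstructable", not "one dimension");
larger values are absolute component counts.  The wrapper-level ``burst``
parameter seen in some configs duplicates ``cutoff`` and is accepted as an
alias, with ``cutoff`` taking precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

__all__ = ["ASRParams", "default_params"]

_GEOMETRIES = ("euclidean", "riemannian")


@dataclass
class ASRParams:
    """Tunable parameters of the correction engine.

    Parameters
    ----------
    cutoff : float
        Threshold multiplier k in T = mu + k * sigma.  Unitless.
    window : float
        Analysis window length in seconds; ``range = round(srate * window)``
        samples per window.
    stepsize : int
        Update interval in samples for the reconstruction operator.
    maxdims : float
        Reconstructable dimensions: fraction of channels if <= 1, else an
        absolute count.
    geometry : str
        ``"euclidean"`` (classic ASR) or ``"riemannian"`` (rASR).
    flatline : float
        Maximum tolerated flat run in seconds (pre-stage).
    hp_band : tuple of float
        Drift-removal high-pass transition band in Hz (pre-stage).
    use_shaping : bool
        Apply the spectral-shaping filter before covariance estimation
        (both calibration and processing).  Bypass for diagnostics only.
    robust_stats : bool
        Median / scaled-MAD component statistics (default) versus plain
        mean / SD.
    riemannian_calibration : bool
        In riemannian mode, centre the calibration covariances with the
        Karcher mean instead of the Euclidean L1-median.
    """

    cutoff: float = 5.0
    window: float = 0.5
    stepsize: int = 32
    maxdims: float = 0.66
    geometry: str = "euclidean"
    flatline: float = 5.0
    hp_band: tuple = (0.25, 0.95)
    use_shaping: bool = True
    robust_stats: bool = True
    riemannian_calibration: bool = True

    def __post_init__(self) -> None:
        if self.geometry not in _GEOMETRIES:
            raise ValueError(f"geometry must be one of {_GEOMETRIES}")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.stepsize < 1:
            raise ValueError("stepsize must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.maxdims <= 0:
            raise ValueError("maxdims must be positive")
        self.stepsize = int(self.stepsize)
        self.hp_band = tuple(float(x) for x in self.hp_band)

    def resolve_maxdims(self, n_channels: int) -> int:
        """Number of top components eligible for reconstruction."""
        if self.maxdims <= 1:
            n = int(round(self.maxdims * n_channels))
        else:
            n = int(round(self.maxdims))
        return max(1, min(n, n_channels))

    def range_samples(self, srate: float) -> int:
        """Samples per analysis window: round(srate * window), >= 2."""
        return max(2, int(round(srate * self.window)))

    def smoothing_weight(self, srate: float) -> float:
        """Exponential-forgetting weight of the current covariance.

        ``w = 1 - 2**(-stepsize / range)``: the same numeric weight in both
        geometries (for the Euclidean running average and for the two-point
        Karcher mean), so the geometry is the only difference between the
        modes.  A smaller stepsize therefore also means longer covariance
        memory, which is what lets the riemannian mode run with its more
        aggressive cutoff.
        """
        rng = self.range_samples(srate)
        return 1.0 - 2.0 ** (-min(self.stepsize, rng) / rng)

    def replace(self, **kwargs) -> "ASRParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hp_band"] = list(self.hp_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ASRParams":
        d = dict(d)
        # wrapper-level alias: burst duplicates cutoff; cutoff wins
        burst = d.pop("burst", None)
        if burst is not None and "cutoff" not in d and burst > 0:
            d["cutoff"] = burst
        d.pop("method", None)
        return cls(**d)


_DEFAULTS = {
    "asr": dict(cutoff=5.0, window=0.5, stepsize=32, maxdims=0.66,
                geometry="euclidean", flatline=5.0, hp_band=(0.25, 0.95)),
    "rasr": dict(cutoff=1.0, window=0.3, stepsize=16, maxdims=1.0,
                 geometry="riemannian", flatline=1.0, hp_band=(0.25, 0.95)),
}


def default_params(method: str = "asr", **overrides) -> ASRParams:
    """Published per-method defaults, optionally overridden field-wise.

    ``method`` is ``"asr"`` (Euclidean) or ``"rasr"`` (Riemannian).
    """
    key = method.lower()
    if key not in _DEFAULTS:
        raise ValueError(f"unknown method {method!r}; expected 'asr' or 'rasr'")
    cfg = dict(_DEFAULTS[key])
    burst = overrides.pop("burst", None)
    if burst is not None and "cutoff" not in overrides and burst > 0:
        overrides["cutoff"] = burst
    cfg.update(overrides)
    return ASRParams(**cfg)
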