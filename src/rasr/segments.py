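"""Lightweight containers for blocks of multichannel EEG.

The whole package moves data around as :class:`EEGSegment`: a channels x
samples array in microvolts together with its sampling rate and channel
labels.  Nothing here is clever; the class exists so that every operation
can state its contract ("same montage", "srate known") in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EEGSegment"]


@dataclass
class EEGSegment:
    """A finite block of multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (c, t)
        Channel-by-sample voltages in microvolts.
    srate : float
        Sampling rate in Hz.
    labels : list of str, optional
        Channel names (10/20 system).  Defaults to ``ch00 .. chNN``.
    """

    data: np.ndarray
    srate: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if not self.labels:
            self.labels = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.data.shape[1] / self.srate

    def copy(self) -> "EEGSegment":
        return replace(self, data=self.data.copy(), labels=list(self.labels))

    def with_data(self, data: np.ndarray) -> "EEGSegment":
        """Same montage and rate, different samples."""
        return EEGSegment(data=np.asarray(data, float), srate=self.srate,
                          labels=list(self.labels))

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError as err:
            raise KeyError(f"channel {label!r} not in montage") from err

    def compatible_with(self, other: "EEGSegment") -> bool:
        return (self.n_channels == other.n_channels
                and self.srate == other.srate
                and self.labels == other.labels)
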