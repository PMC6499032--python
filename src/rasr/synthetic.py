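"""Synthetic mobile-EEG sessions with ground truth.

The generator emulates the kind of recording the correction engines were
evaluated on: a 24-channel, 250 Hz mobile montage with

* a stationary 1/f^alpha background from a fixed smooth spatial mixing of
  latent sources (resting EEG stand-in),
* frontal eye blinks — a ~300 ms biphasic bump with a mild negative
  rebound, peaking at ~255 uV on Fp1/Fp2 (the indoor mean blink amplitude
  reported for smartphone recordings), falling off smoothly toward
  occipital sites,
* occipital visual-evoked potentials with P1/N1 morphology at O1/O2.

Every generator is a pure function of (config, seed), and the injected
components are kept separately so that task data equal
``background + blinks + VEPs`` exactly — tests can score correction
against the true artifact and the true signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segments import EEGSegment

__all__ = [
    "MONTAGE_24",
    "montage_positions",
    "blink_topography",
    "vep_topography",
    "generate_background",
    "blink_waveform",
    "inject_blinks",
    "vep_waveform",
    "inject_vep",
    "SessionConfig",
    "SyntheticSession",
    "generate_session",
]

# 24-channel mobile 10/20 montage with approximate 2-D scalp positions
# (x toward the right ear, y toward the nasion, unit head radius).
MONTAGE_24 = [
    ("Fp1", -0.31, 0.95), ("Fp2", 0.31, 0.95),
    ("Fz", 0.00, 0.72), ("F7", -0.81, 0.59), ("F8", 0.81, 0.59),
    ("FC1", -0.22, 0.36), ("FC2", 0.22, 0.36),
    ("C3", -0.45, 0.00), ("Cz", 0.00, 0.00), ("C4", 0.45, 0.00),
    ("T7", -0.90, 0.00), ("T8", 0.90, 0.00),
    ("CP5", -0.63, -0.27), ("CP1", -0.22, -0.36),
    ("CP2", 0.22, -0.36), ("CP6", 0.63, -0.27),
    ("TP9", -0.95, -0.31), ("TP10", 0.95, -0.31),
    ("P3", -0.40, -0.55), ("Pz", 0.00, -0.55), ("P4", 0.40, -0.55),
    ("POz", 0.00, -0.81),
    ("O1", -0.31, -0.95), ("O2", 0.31, -0.95),
]


def montage_positions(labels=None) -> np.ndarray:
    """(c, 2) scalp positions for the default montage."""
    table = {name: (x, y) for name, x, y in MONTAGE_24}
    if labels is None:
        labels = [name for name, _, _ in MONTAGE_24]
    return np.array([table[l] for l in labels], float)


def _falloff_topo(center, scale: float, labels=None) -> np.ndarray:
    pos = montage_positions(labels)
    d = np.linalg.norm(pos - np.asarray(center, float), axis=1)
    topo = np.exp(-(d - d.min()) / scale)
    return topo / topo.max()


def blink_topography(labels=None) -> np.ndarray:
    """Frontal scalp map, maximal (1.0) at Fp1/Fp2, decaying occipitally."""
    return _falloff_topo((0.0, 1.10), 0.45, labels)


def vep_topography(labels=None) -> np.ndarray:
    """Bilateral occipital scalp map, maximal (1.0) at O1/O2.

    Sum of two smooth falloffs centred just below the left and right
    occipital electrodes — the classic bilateral pattern of a static
    visual stimulus.
    """
    pos = montage_positions(labels)
    topo = np.zeros(pos.shape[0])
    for cx in (-0.31, 0.31):
        d = np.linalg.norm(pos - np.array([cx, -1.00]), axis=1)
        topo += np.exp(-d / 0.50)
    return topo / topo.max()


def generate_background(c: int = 24, duration_s: float = 60.0,
                        srate: float = 250.0, rms_uV: float = 10.0,
                        spectral_exponent: float = 1.2,
                        sensor_noise_uV: float = 1.0,
                        seed: int = 0) -> EEGSegment:
    """Stationary 1/f^alpha multichannel background.

    ``c`` latent sources with power spectra proportional to f^-alpha
    (flattened below 1 Hz to keep the variance finite) and variances
    log-spaced over 1.5 decades are mixed through a fixed set of smooth
    random scalp maps; each channel is then normalised to ``rms_uV``.
    Independent white sensor noise of ``sensor_noise_uV`` RMS is added per
    channel — the amplifier noise floor of a mobile recording, and what
    keeps the sensor covariance conditioned the way real recordings are
    (spatially mixed sources alone would leave near-null directions no
    amplifier ever shows).
    """
    if duration_s < 1.0:
        raise ValueError("need at least 1 s of background")
    rng = np.random.default_rng(seed)
    t = int(round(duration_s * srate))
    freqs = np.fft.rfftfreq(t, d=1.0 / srate)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    f_eff = np.maximum(freqs[nz], 1.0)
    shape[nz] = f_eff ** (-spectral_exponent / 2.0)
    shape[0] = 0.0

    spec = (rng.standard_normal((c, len(freqs)))
            + 1j * rng.standard_normal((c, len(freqs)))) * shape
    sources = np.fft.irfft(spec, n=t, axis=1)
    sources /= sources.std(axis=1, keepdims=True)
    src_scale = 10.0 ** (-1.5 * np.arange(c) / max(c - 1, 1))
    sources *= src_scale[:, None]

    # fixed smooth mixing: each source is a blend of Gaussian scalp bumps
    pos = montage_positions() if c == len(MONTAGE_24) else None
    if pos is None:
        grid = np.linspace(-1, 1, c)
        pos = np.stack([grid, grid[::-1]], axis=1)
    centers = rng.uniform(-1.0, 1.0, size=(c, 2))
    widths = rng.uniform(0.5, 1.0, size=c)
    A = np.exp(-((pos[:, None, 0] - centers[None, :, 0]) ** 2
                 + (pos[:, None, 1] - centers[None, :, 1]) ** 2)
               / (2 * widths[None, :] ** 2))
    A += 0.05 * rng.standard_normal(A.shape)

    data = A @ sources
    data *= rms_uV / np.sqrt(np.mean(data ** 2, axis=1, keepdims=True))
    if sensor_noise_uV > 0:
        data += sensor_noise_uV * rng.standard_normal(data.shape)
    labels = [name for name, _, _ in MONTAGE_24] if c == len(MONTAGE_24) \
        else None
    return EEGSegment(data=data, srate=srate, labels=labels or [])


def blink_waveform(srate: float, width_s: float = 0.30) -> np.ndarray:
    """Unit-peak biphasic blink: generalized-Gaussian bump + small rebound.

    Spans roughly [-0.3, +0.5] s around the peak; the rebound undershoot
    is ~12% of the peak, 180 ms after it.
    """
    t = np.arange(int(round(-0.3 * srate)), int(round(0.5 * srate))) / srate
    tau = width_s / 2.4
    bump = np.exp(-np.abs(t / tau) ** 2.5)
    rebound = -0.12 * np.exp(-((t - 0.18) / 0.12) ** 2)
    w = bump + rebound
    return w / w.max()


def _draw_event_times(rng, n_samples: int, srate: float, rate_per_min: float,
                      refractory_s: float = 0.8,
                      margin_s: float = 1.0) -> np.ndarray:
    """Jittered event times with a hard refractory gap, in samples."""
    if rate_per_min <= 0:
        return np.array([], dtype=int)
    mean_gap = 60.0 / rate_per_min
    if mean_gap <= refractory_s:
        raise ValueError("rate leaves no refractory gap between events")
    times = []
    t = margin_s + rng.exponential(mean_gap - refractory_s)
    horizon = n_samples / srate - margin_s
    while t < horizon:
        times.append(int(round(t * srate)))
        t += refractory_s + rng.exponential(mean_gap - refractory_s)
    return np.array(times, dtype=int)


def inject_blinks(data: EEGSegment, rate_per_min: float = 40.0,
                  peak_uV: float = 254.92, topo: np.ndarray | None = None,
                  seed: int = 0):
    """Add eye blinks; returns ``(segment, blink_component, blink_times)``.

    Blink peak times are jittered with a >= 800 ms refractory gap.  Peak
    amplitudes vary by ~8% across blinks (mean ``peak_uV``), so the
    blink-locked average at Fp1/Fp2 recovers ``peak_uV`` closely.
    """
    rng = np.random.default_rng(seed)
    topo = blink_topography(data.labels) if topo is None else np.asarray(topo)
    times = _draw_event_times(rng, data.n_samples, data.srate, rate_per_min)
    w = blink_waveform(data.srate)
    pre = int(round(0.3 * data.srate))
    comp = np.zeros_like(data.data)
    kept = []
    for t0 in times:
        start = t0 - pre
        if start < 0 or start + len(w) > data.n_samples:
            continue
        amp = peak_uV * (1.0 + 0.08 * rng.standard_normal())
        comp[:, start:start + len(w)] += amp * topo[:, None] * w[None, :]
        kept.append(t0)
    out = data.with_data(data.data + comp)
    return out, comp, np.array(kept, dtype=int)


def vep_waveform(srate: float, p1_uV: float, n1_uV: float,
                 p1_ms: float = 100.0, n1_ms: float = 170.0) -> np.ndarray:
    """P1/N1 evoked waveform over [0, 400] ms post-stimulus."""
    t = np.arange(int(round(0.4 * srate))) / srate
    p1 = p1_uV * np.exp(-((t - p1_ms / 1000.0) / 0.022) ** 2)
    n1 = n1_uV * np.exp(-((t - n1_ms / 1000.0) / 0.035) ** 2)
    return p1 + n1


def inject_vep(data: EEGSegment, event_times, p1_uV: float = 6.0,
               n1_uV: float = -10.0, p1_ms: float = 100.0,
               n1_ms: float = 170.0, topo: np.ndarray | None = None,
               seed: int = 0):
    """Add stimulus-locked VEPs; returns ``(segment, vep_component)``.

    Single-trial amplitudes vary by ~10% (multiplicative, mean 1), so the
    event-locked average converges to the requested P1/N1 amplitudes.
    """
    rng = np.random.default_rng(seed)
    topo = vep_topography(data.labels) if topo is None else np.asarray(topo)
    w = vep_waveform(data.srate, p1_uV, n1_uV, p1_ms, n1_ms)
    comp = np.zeros_like(data.data)
    for t0 in np.asarray(event_times, int):
        if t0 < 0 or t0 + len(w) > data.n_samples:
            raise ValueError(f"event at sample {t0} outside the recording")
        gain = 1.0 + 0.10 * rng.standard_normal()
        comp[:, t0:t0 + len(w)] += gain * topo[:, None] * w[None, :]
    return data.with_data(data.data + comp), comp


@dataclass
class SessionConfig:
    """Study-condition defaults for a synthetic session."""

    n_channels: int = 24
    srate: float = 250.0
    calibration_s: float = 60.0
    task_s: float = 240.0
    background_rms_uV: float = 10.0
    spectral_exponent: float = 1.2
    blink_rate_per_min: float = 40.0
    blink_peak_uV: float = 254.92
    vep_isi_s: float = 1.5
    vep_p1_uV: float = 6.0
    vep_n1_uV: float = -10.0
    vep_p1_ms: float = 100.0
    vep_n1_ms: float = 170.0


@dataclass
class SyntheticSession:
    """A generated session with full ground truth."""

    calibration: EEGSegment
    task: EEGSegment
    blink_times: np.ndarray
    vep_times: np.ndarray
    blink_topo: np.ndarray
    vep_topo: np.ndarray
    seed: int
    task_background: EEGSegment | None = None
    blink_component: np.ndarray | None = None
    vep_component: np.ndarray | None = None
    config: SessionConfig | None = None


def generate_session(config: SessionConfig | None = None,
                     seed: int = 0) -> SyntheticSession:
    """Calibration stretch (clean) plus a task stretch with blinks + VEPs.

    The calibration block contains background only; the task block is
    background + blink component + VEP component, exactly (linearity), and
    the event lists are the injected ground truth.
    """
    cfg = config or SessionConfig()
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2 ** 31 - 1, size=4)

    calib = generate_background(cfg.n_channels, cfg.calibration_s, cfg.srate,
                                cfg.background_rms_uV, cfg.spectral_exponent,
                                seed=int(sub[0]))
    background = generate_background(cfg.n_channels, cfg.task_s, cfg.srate,
                                     cfg.background_rms_uV,
                                     cfg.spectral_exponent, seed=int(sub[1]))
    task, blink_comp, blink_times = inject_blinks(
        background, cfg.blink_rate_per_min, cfg.blink_peak_uV,
        seed=int(sub[2]))

    vep_rng = np.random.default_rng(int(sub[3]))
    vep_times = _draw_event_times(vep_rng, background.n_samples, cfg.srate,
                                  rate_per_min=60.0 / cfg.vep_isi_s,
                                  refractory_s=max(0.9, 0.6 * cfg.vep_isi_s),
                                  margin_s=1.0)
    task, vep_comp = inject_vep(task, vep_times, cfg.vep_p1_uV, cfg.vep_n1_uV,
                                cfg.vep_p1_ms, cfg.vep_n1_ms,
                                seed=int(sub[3]))
    return SyntheticSession(
        calibration=calib, task=task,
        blink_times=blink_times, vep_times=vep_times,
        blink_topo=blink_topography(task.labels),
        vep_topo=vep_topography(task.labels), seed=seed,
        task_background=background, blink_component=blink_comp,
        vep_component=vep_comp, config=cfg,
    )
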