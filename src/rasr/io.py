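"""Recording, event and session I/O.

Recordings travel as either

* the package's own ``.npz`` container (``data`` channels x samples in uV,
  ``srate``, ``labels``) — compact, lossless, round-trips bit-exactly;
* plain CSV (first column ``time_s``, one column per channel; srate
  inferred from the time column) for interoperability;
* EDF/BDF, read through MNE when available (reading only — EDF export
  needs packages this stack does not carry).

Events are tab-separated text with columns ``sample`` and ``type``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .segments import EEGSegment
from .synthetic import SyntheticSession

__all__ = [
    "load_recording",
    "save_recording",
    "load_events",
    "save_events",
    "save_session",
    "load_session",
]


def save_recording(path, segment: EEGSegment) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        t = np.arange(segment.n_samples) / segment.srate
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s"] + list(segment.labels))
            for i in range(segment.n_samples):
                w.writerow([repr(float(t[i]))]
                           + [repr(float(v)) for v in segment.data[:, i]])
    else:
        np.savez_compressed(path, data=segment.data, srate=segment.srate,
                            labels=np.array(segment.labels))


def load_recording(path) -> EEGSegment:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".edf", ".bdf"):
        import mne  # lazy: optional dependency
        raw = mne.io.read_raw(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        return EEGSegment(data=data, srate=float(raw.info["sfreq"]),
                          labels=list(raw.ch_names))
    if suffix == ".csv":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            rows = [[float(v) for v in row] for row in reader]
        arr = np.array(rows).T
        t, data = arr[0], arr[1:]
        srate = 1.0 / np.median(np.diff(t))
        return EEGSegment(data=data, srate=float(round(srate, 6)),
                          labels=header[1:])
    with np.load(path, allow_pickle=False) as z:
        return EEGSegment(data=z["data"], srate=float(z["srate"]),
                          labels=[str(l) for l in z["labels"]])


def save_events(path, samples, types) -> None:
    """Tab-separated event table: sample<TAB>type."""
    with open(path, "w") as fh:
        fh.write("sample\ttype\n")
        for s, k in zip(samples, types):
            fh.write(f"{int(s)}\t{k}\n")


def load_events(path, kind: str | None = None) -> np.ndarray:
    """Event samples from a TSV table, optionally filtered by type."""
    samples = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        si, ki = header.index("sample"), header.index("type")
        for line in fh:
            parts = line.strip().split("\t")
            if not parts or parts == [""]:
                continue
            if kind is None or parts[ki] == kind:
                samples.append(int(parts[si]))
    return np.array(samples, dtype=int)


def save_session(prefix, session: SyntheticSession) -> dict:
    """Write a synthetic session: calibration + task + event sidecar.

    Returns the paths written, keyed ``calibration``/``task``/``events``.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "calibration": prefix.with_name(prefix.name + "_calibration.npz"),
        "task": prefix.with_name(prefix.name + "_task.npz"),
        "events": prefix.with_name(prefix.name + "_events.tsv"),
    }
    save_recording(paths["calibration"], session.calibration)
    save_recording(paths["task"], session.task)
    samples = np.concatenate([session.blink_times, session.vep_times])
    types = (["blink"] * len(session.blink_times)
             + ["vep"] * len(session.vep_times))
    order = np.argsort(samples, kind="stable")
    save_events(paths["events"], samples[order],
                [types[i] for i in order])
    return {k: str(v) for k, v in paths.items()}


def load_session(prefix) -> dict:
    """Load the pieces written by :func:`save_session`."""
    prefix = Path(prefix)
    return {
        "calibration": load_recording(
            prefix.with_name(prefix.name + "_calibration.npz")),
        "task": load_recording(prefix.with_name(prefix.name + "_task.npz")),
        "blink_times": load_events(
            prefix.with_name(prefix.name + "_events.tsv"), "blink"),
        "vep_times": load_events(
            prefix.with_name(prefix.name + "_events.tsv"), "vep"),
    }
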