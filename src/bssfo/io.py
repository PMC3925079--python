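"""EEG recording and trial I/O.

Continuous multichannel EEG is held in :class:`Recording` (microvolts,
channel x sample).  Recordings are read from EDF (via :mod:`mne`) or from a
plain-text matrix format with a two-line header (``fs=<Hz>`` and
``channels=<comma list>``) followed by whitespace-separated samples, one row
per time point.  Event tables are tab-separated ``sample<TAB>label`` with
0-based sample indices.

The preprocessing chain mirrors standard sensorimotor-rhythm BCI practice:
surface-Laplacian derivation, Chebyshev anti-alias low-pass + decimation to
100 Hz, and epoching of cue-locked imagery trials into a :class:`TrialSet`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .montage import MontageSpec

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "TrialSet",
    "load_recording",
    "write_recording",
    "load_events",
    "write_events",
    "laplacian_derive",
    "downsample",
    "epoch",
]


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    Parameters
    ----------
    channels
        Ordered channel labels (10-20/10-10 names for real caps).
    fs
        Sampling rate in Hz, > 0.
    data
        ``(n_channels, n_samples)`` float array, microvolts.
    annotations
        ``(sample_index, label)`` event markers, indices within range.
    """

    channels: list[str]
    fs: float
    data: np.ndarray
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0] if self.data.ndim == 2 else '?'} rows "
                f"for {len(self.channels)} channels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel labels")
        n = self.data.shape[1]
        for idx, label in self.annotations:
            if not 0 <= idx < n:
                raise ValueError(f"annotation {label!r} at sample {idx} outside [0, {n})")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def pick(self, channels: list[str]) -> "Recording":
        """Sub-recording with the given channels, in the given order."""
        missing = [c for c in channels if c not in self.channels]
        if missing:
            raise ValueError(f"channels not in recording: {missing}")
        idx = [self.channels.index(c) for c in channels]
        return Recording(list(channels), self.fs, self.data[idx], list(self.annotations))


@dataclass
class TrialSet:
    """Epoched two-class imagery trials.

    ``trials`` is ``(n_trials, n_channels, n_samples)`` in microvolts,
    ``labels`` one class label per trial, ``order`` the chronological rank of
    each trial (a permutation of ``0..n_trials-1``).
    """

    trials: np.ndarray
    labels: np.ndarray
    fs: float
    channels: list[str] = field(default_factory=list)
    order: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.trials.ndim != 3:
            raise ValueError("trials must be (n_trials, n_channels, n_samples)")
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.order is None:
            self.order = np.arange(self.trials.shape[0])
        else:
            self.order = np.asarray(self.order)
            if sorted(self.order.tolist()) != list(range(self.trials.shape[0])):
                raise ValueError("order must be a permutation of trial indices")
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.trials.shape[1])]

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, idx: np.ndarray) -> "TrialSet":
        idx = np.asarray(idx)
        sub_order = np.argsort(np.argsort(self.order[idx]))
        return TrialSet(self.trials[idx], self.labels[idx], self.fs,
                        list(self.channels), sub_order)


def _load_matrix(path: Path) -> Recording:
    with open(path) as fh:
        header: dict[str, str] = {}
        pos = fh.tell()
        for _ in range(2):
            line = fh.readline().strip()
            if "=" not in line:
                raise ValueError(f"{path}: expected 'fs=' and 'channels=' header lines")
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
            pos = fh.tell()
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    if "fs" not in header or "channels" not in header:
        raise ValueError(f"{path}: missing fs= or channels= header")
    channels = [c.strip() for c in header["channels"].split(",")]
    return Recording(channels, float(header["fs"]), data.T)


def _load_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts; recordings hold microvolts
    annotations = []
    for ann in raw.annotations:
        annotations.append((int(round(ann["onset"] * raw.info["sfreq"])), ann["description"]))
    return Recording(list(raw.ch_names), float(raw.info["sfreq"]), data, annotations)


def load_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from EDF or matrix+header text.

    ``format`` is ``"edf"`` or ``"matrix"``; by default it is inferred from
    the file extension (``.edf`` -> EDF, anything else -> matrix).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return _load_edf(path)
    if format == "matrix":
        return _load_matrix(path)
    raise ValueError(f"unknown format {format!r}")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording in the matrix+header text format."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"fs={rec.fs:g}\n")
        fh.write("channels=" + ",".join(rec.channels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.8g")


def load_events(path: str | Path) -> list[tuple[int, str]]:
    """Read a ``sample<TAB>label`` event table (0-based sample indices)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"])
    return [(int(s), str(l)) for s, l in zip(df["sample"], df["label"])]


def write_events(events: list[tuple[int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for idx, label in events:
            fh.write(f"{idx}\t{label}\n")


def laplacian_derive(rec: Recording, montage: MontageSpec) -> Recording:
    """Surface-Laplacian derivation: center minus mean of its neighbors.

    Returns a recording containing only the montage centers, in montage
    order.  Linear in the input by construction.
    """
    missing = [c for c in montage.required_channels() if c not in rec.channels]
    if missing:
        raise ValueError(f"montage {montage.name!r} needs channels missing "
                         f"from recording: {missing}")
    rows = []
    for center, neigh in montage.laplacian_map.items():
        c = rec.data[rec.channels.index(center)]
        nbr = rec.data[[rec.channels.index(x) for x in neigh]]
        rows.append(c - nbr.mean(axis=0))
    return Recording(montage.centers, rec.fs, np.array(rows), list(rec.annotations))


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-alias low-pass and decimate to ``target_fs``.

    Chebyshev type-I low-pass (order 8, 0.05 dB ripple, cutoff at
    0.4 * target_fs) applied forward-backward for zero phase, then every
    ``fs / target_fs``-th sample kept.  ``target_fs`` must divide ``fs``.
    """
    if target_fs > rec.fs:
        raise ValueError("target_fs must not exceed fs")
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"decimation factor {factor} is not an integer")
    factor = int(round(factor))
    if factor == 1:
        return Recording(list(rec.channels), rec.fs, rec.data.copy(),
                         list(rec.annotations))
    sos = signal.cheby1(8, 0.05, 0.4 * target_fs, btype="low", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    out = filtered[:, ::factor]
    annotations = [(idx // factor, label) for idx, label in rec.annotations]
    return Recording(list(rec.channels), target_fs, out, annotations)


def epoch(
    rec: Recording,
    annotations: list[tuple[int, str]] | None = None,
    window: tuple[float, float] = (0.0, 4.0),
    keep_labels: tuple[str, ...] = ("L", "R"),
) -> TrialSet:
    """Cut cue-locked trials out of a continuous recording.

    ``window`` is in seconds relative to the cue sample.  Events whose window
    falls outside the recording are dropped with a warning; only events with
    a label in ``keep_labels`` (left/right imagery by default) are retained.
    """
    if annotations is None:
        annotations = rec.annotations
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    start_off = int(round(t0 * rec.fs))
    length = int(round((t1 - t0) * rec.fs))
    if length < 1:
        raise ValueError("window shorter than one sample")
    trials, labels = [], []
    for idx, label in annotations:
        if label not in keep_labels:
            continue
        lo = idx + start_off
        hi = lo + length
        if lo < 0 or hi > rec.n_samples:
            logger.warning("event %r at sample %d: window [%d, %d) out of bounds; dropped",
                           label, idx, lo, hi)
            continue
        trials.append(rec.data[:, lo:hi])
        labels.append(label)
    if not trials:
        raise ValueError("no events retained after windowing")
    return TrialSet(np.array(trials), np.array(labels), rec.fs, list(rec.channels))
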