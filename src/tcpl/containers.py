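"""Data containers for raw recordings and epoched trials, with per-subject I/O.

The on-disk layout is one file per subject holding ``data`` (n_trials x C x T,
float32), ``labels`` (int), ``fs`` (scalar), ``channel_names`` (strings) and
``subject_id``. HDF5 is the native format; an ``.npz`` archive with the same
member names is the fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RawRecording",
    "EpochedTrial",
    "SubjectTrials",
    "save_subject",
    "load_subject",
    "trials_to_arrays",
    "arrays_to_trials",
]


@dataclass
class RawRecording:
    """A continuous cued recording: channels x samples in microvolts."""

    signal: np.ndarray
    fs: float
    channel_names: list[str]
    events: list[tuple[int, int]]  # (cue_sample_index, class_label)
    subject_id: str

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.shape[0] < 1:
            raise ValueError("at least one channel required")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match channel count")


@dataclass
class EpochedTrial:
    """One epoch: C x T matrix with its class label and provenance."""

    data: np.ndarray
    label: int
    subject_id: str
    fs: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("trial data must be C x T")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SubjectTrials:
    """All trials of one subject in array form (n_trials x C x T)."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    subject_id: str
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be n_trials x C x T")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must match trial count")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]

    def to_trials(self) -> list[EpochedTrial]:
        return [EpochedTrial(d, int(l), self.subject_id, self.fs)
                for d, l in zip(self.data, self.labels)]


def trials_to_arrays(trials: list[EpochedTrial]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a homogeneous trial list into (n x C x T, labels)."""
    if not trials:
        raise ValueError("empty trial list")
    X = np.stack([t.data for t in trials])
    y = np.array([t.label for t in trials], dtype=np.int64)
    return X, y


def arrays_to_trials(X: np.ndarray, y: np.ndarray, subject_id: str,
                     fs: float) -> list[EpochedTrial]:
    return [EpochedTrial(x, int(l), subject_id, fs) for x, l in zip(X, y)]


def save_subject(path: str | Path, subject: SubjectTrials) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=subject.data.astype(np.float32))
            f.create_dataset("labels", data=subject.labels)
            f.create_dataset("fs", data=float(subject.fs))
            f.create_dataset(
                "channel_names",
                data=np.array(subject.channel_names, dtype=object),
                dtype=h5py.string_dtype())
            f.create_dataset("subject_id", data=str(subject.subject_id),
                             dtype=h5py.string_dtype())
    elif path.suffix == ".npz":
        np.savez_compressed(
            path,
            data=subject.data.astype(np.float32),
            labels=subject.labels,
            fs=float(subject.fs),
            channel_names=np.array(subject.channel_names),
            subject_id=str(subject.subject_id))
    else:
        raise ValueError(f"unsupported container extension: {path.suffix}")


def load_subject(path: str | Path) -> SubjectTrials:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            return SubjectTrials(
                data=f["data"][()].astype(np.float64),
                labels=f["labels"][()],
                fs=float(f["fs"][()]),
                subject_id=_as_str(f["subject_id"][()]),
                channel_names=[_as_str(c) for c in f["channel_names"][()]])
    elif path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            return SubjectTrials(
                data=f["data"].astype(np.float64),
                labels=f["labels"],
                fs=float(f["fs"]),
                subject_id=str(f["subject_id"]),
                channel_names=[str(c) for c in f["channel_names"]])
    raise ValueError(f"unsupported container extension: {path.suffix}")


def _as_str(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)
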