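"""Core data model for accelerometer windows and the on-disk dataset format.

A :class:`Dataset` is an ordered collection of fixed-length, multi-axis
:class:`SignalWindow` objects, each labelled with an activity, a subject
identifier and a trial index.  Windows are stored as ``n_timesteps x n_axes``
arrays of acceleration in m/s²; by convention timestep ``i`` corresponds to
time ``i / sample_rate_hz`` seconds.

On disk a dataset is a directory with three files:

``windows.npy``
    float32 array of shape ``(n_windows, n_timesteps, n_axes)``.
``meta.tsv``
    tab-separated table with header ``index\tactivity\tsubject\ttrial``,
    one row per window, in window order.
``schema.json``
    ``n_timesteps``, ``n_axes``, ``sample_rate_hz``, ``activity_vocabulary``,
    ``subject_roster``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io

__all__ = [
    "SignalWindow",
    "Dataset",
    "ValidationReport",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "load_external_archive",
    "DatasetFormatError",
]

DEFAULT_N_TIMESTEPS = 151
DEFAULT_N_AXES = 3
DEFAULT_SAMPLE_RATE_HZ = 50.0


class DatasetFormatError(ValueError):
    """Raised when an on-disk dataset or archive does not match its declared shape."""


@dataclass
class SignalWindow:
    """One fixed-length tri-axial (by default) accelerometer window.

    Parameters
    ----------
    values
        Array of shape ``(n_timesteps, n_axes)``, acceleration in m/s².
    activity
        Activity label (e.g. ``"Walking"``).
    subject
        Integer subject identifier.
    trial
        Non-negative trial index within the (subject, activity) pair.
    sample_rate_hz
        Sampling rate; the sampling interval is ``1 / sample_rate_hz``.
    """

    values: np.ndarray
    activity: str
    subject: int
    trial: int = 0
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(
                f"window values must be 2-D (timesteps x axes), got shape {self.values.shape}"
            )
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[0]

    @property
    def n_axes(self) -> int:
        return self.values.shape[1]

    @property
    def sampling_interval_s(self) -> float:
        """Elapsed time between consecutive samples, in seconds."""
        return 1.0 / self.sample_rate_hz

    def times(self) -> np.ndarray:
        """Timestamps of the samples in seconds (timestep i at i/rate)."""
        return np.arange(self.n_timesteps) / self.sample_rate_hz


@dataclass
class Dataset:
    """Ordered collection of windows sharing shape, rate and label vocabularies."""

    windows: list[SignalWindow]
    activity_vocabulary: list[str]
    subject_roster: list[int]

    def __post_init__(self) -> None:
        self.activity_vocabulary = list(self.activity_vocabulary)
        self.subject_roster = sorted(int(s) for s in self.subject_roster)

    def __len__(self) -> int:
        return len(self.windows)

    def __getitem__(self, i: int) -> SignalWindow:
        return self.windows[i]

    def __iter__(self):
        return iter(self.windows)

    @property
    def n_timesteps(self) -> int:
        return self.windows[0].n_timesteps if self.windows else DEFAULT_N_TIMESTEPS

    @property
    def n_axes(self) -> int:
        return self.windows[0].n_axes if self.windows else DEFAULT_N_AXES

    @property
    def sample_rate_hz(self) -> float:
        return self.windows[0].sample_rate_hz if self.windows else DEFAULT_SAMPLE_RATE_HZ

    def values(self) -> np.ndarray:
        """Stacked window values, shape ``(n_windows, n_timesteps, n_axes)``."""
        if not self.windows:
            return np.zeros((0, self.n_timesteps, self.n_axes))
        return np.stack([w.values for w in self.windows])

    def activities(self) -> np.ndarray:
        return np.array([w.activity for w in self.windows], dtype=object)

    def subjects(self) -> np.ndarray:
        return np.array([w.subject for w in self.windows], dtype=np.int64)

    def trials(self) -> np.ndarray:
        return np.array([w.trial for w in self.windows], dtype=np.int64)

    def indices_for_activity(self, activity: str) -> np.ndarray:
        return np.flatnonzero(self.activities() == activity)

    def subset(self, indices: Iterable[int]) -> "Dataset":
        """New dataset containing the selected windows (vocabularies preserved)."""
        idx = np.asarray(list(indices), dtype=np.int64)
        return Dataset(
            windows=[self.windows[i] for i in idx],
            activity_vocabulary=list(self.activity_vocabulary),
            subject_roster=list(self.subject_roster),
        )

    def copy(self) -> "Dataset":
        return Dataset(
            windows=[
                SignalWindow(
                    values=w.values.copy(),
                    activity=w.activity,
                    subject=w.subject,
                    trial=w.trial,
                    sample_rate_hz=w.sample_rate_hz,
                )
                for w in self.windows
            ],
            activity_vocabulary=list(self.activity_vocabulary),
            subject_roster=list(self.subject_roster),
        )

    def equals(self, other: "Dataset", atol: float = 0.0) -> bool:
        if (
            self.activity_vocabulary != other.activity_vocabulary
            or self.subject_roster != other.subject_roster
            or len(self) != len(other)
        ):
            return False
        for a, b in zip(self.windows, other.windows):
            if (a.activity, a.subject, a.trial) != (b.activity, b.subject, b.trial):
                return False
            if a.sample_rate_hz != b.sample_rate_hz:
                return False
            if not np.allclose(a.values, b.values, atol=atol, rtol=0):
                return False
        return True


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`: ``ok`` iff no issues were found."""

    ok: bool
    issues: list[tuple[str, str, int]] = field(default_factory=list)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset directory (``windows.npy``, ``meta.tsv``, ``schema.json``).

    Overwrites existing files; two writes of the same dataset produce
    byte-identical metadata.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    values = dataset.values().astype(np.float32)
    np.save(path / "windows.npy", values)

    meta = pd.DataFrame(
        {
            "index": np.arange(len(dataset)),
            "activity": dataset.activities() if len(dataset) else [],
            "subject": dataset.subjects() if len(dataset) else [],
            "trial": dataset.trials() if len(dataset) else [],
        }
    )
    meta.to_csv(path / "meta.tsv", sep="\t", index=False, lineterminator="\n")

    schema = {
        "n_timesteps": int(dataset.n_timesteps),
        "n_axes": int(dataset.n_axes),
        "sample_rate_hz": float(dataset.sample_rate_hz),
        "activity_vocabulary": list(dataset.activity_vocabulary),
        "subject_roster": [int(s) for s in dataset.subject_roster],
    }
    (path / "schema.json").write_text(json.dumps(schema, indent=2) + "\n", encoding="utf-8")


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    for name in ("windows.npy", "meta.tsv", "schema.json"):
        if not (path / name).exists():
            raise FileNotFoundError(f"dataset directory {path} is missing {name}")

    schema = json.loads((path / "schema.json").read_text(encoding="utf-8"))
    values = np.load(path / "windows.npy")
    meta = pd.read_csv(path / "meta.tsv", sep="\t")

    if values.ndim != 3:
        raise DatasetFormatError(
            f"windows.npy must be 3-D (windows x timesteps x axes), got {values.shape}"
        )
    if values.shape[0] != len(meta):
        raise DatasetFormatError(
            f"meta.tsv has {len(meta)} rows but windows.npy holds {values.shape[0]} windows"
        )

    rate = float(schema["sample_rate_hz"])
    windows = [
        SignalWindow(
            values=values[i].astype(np.float64),
            activity=str(meta["activity"].iloc[i]),
            subject=int(meta["subject"].iloc[i]),
            trial=int(meta["trial"].iloc[i]),
            sample_rate_hz=rate,
        )
        for i in range(values.shape[0])
    ]
    return Dataset(
        windows=windows,
        activity_vocabulary=[str(a) for a in schema["activity_vocabulary"]],
        subject_roster=[int(s) for s in schema["subject_roster"]],
    )


def validate_dataset(dataset: Dataset) -> ValidationReport:
    """Check every dataset invariant, reporting violations rather than raising.

    Issue codes: ``LENGTH_MISMATCH`` (window length differs from the first
    window's), ``AXES_MISMATCH``, ``RATE_MISMATCH``, ``MISSING_VALUES``
    (NaN/inf entries), ``UNKNOWN_LABEL`` (activity outside the vocabulary),
    ``UNKNOWN_SUBJECT`` (subject outside the roster).
    """
    issues: list[tuple[str, str, int]] = []
    if dataset.windows:
        ref = dataset.windows[0]
        vocab = set(dataset.activity_vocabulary)
        roster = set(dataset.subject_roster)
        for i, w in enumerate(dataset.windows):
            if w.n_timesteps != ref.n_timesteps:
                issues.append(
                    ("LENGTH_MISMATCH", f"window has {w.n_timesteps} timesteps, expected {ref.n_timesteps}", i)
                )
            if w.n_axes != ref.n_axes:
                issues.append(("AXES_MISMATCH", f"window has {w.n_axes} axes, expected {ref.n_axes}", i))
            if w.sample_rate_hz != ref.sample_rate_hz:
                issues.append(
                    ("RATE_MISMATCH", f"window sampled at {w.sample_rate_hz} Hz, expected {ref.sample_rate_hz}", i)
                )
            if not np.all(np.isfinite(w.values)):
                issues.append(("MISSING_VALUES", "window contains NaN or infinite entries", i))
            if w.activity not in vocab:
                issues.append(("UNKNOWN_LABEL", f"activity {w.activity!r} not in vocabulary", i))
            if w.subject not in roster:
                issues.append(("UNKNOWN_SUBJECT", f"subject {w.subject} not in roster", i))
    return ValidationReport(ok=not issues, issues=issues)


def load_external_archive(
    path: str | Path,
    layout: str = "unimib",
    *,
    window_length: int = DEFAULT_N_TIMESTEPS,
    n_axes: int = DEFAULT_N_AXES,
    axis_order: str = "block",
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    data_key: str | None = None,
    labels_key: str | None = None,
) -> Dataset:
    """Best-effort adapter for external archives of flat window records.

    The ``"unimib"`` layout reads a MATLAB ``.mat`` (or NumPy ``.npz``)
    container holding a ``(n_windows, window_length * n_axes)`` data matrix
    and a ``(n_windows, 3)`` label matrix of (activity id, subject id, trial
    id) columns.  Each flat record is reshaped to ``window_length x n_axes``;
    ``axis_order="block"`` treats the record as concatenated per-axis blocks
    of ``window_length`` samples, ``axis_order="interleaved"`` as alternating
    per-timestep axis triples.  The defaults describe the expected layout of
    the public tri-axial fall/ADL archive but are configurable because
    archive internals vary between releases; verify against the archive you
    downloaded.
    """
    if layout != "unimib":
        raise ValueError(f"unknown archive layout {layout!r}; available: 'unimib'")
    if axis_order not in ("block", "interleaved"):
        raise ValueError("axis_order must be 'block' or 'interleaved'")

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"archive not found: {path}")

    if path.suffix == ".npz":
        container = dict(np.load(path, allow_pickle=True))
    else:
        container = {
            k: v for k, v in scipy.io.loadmat(path).items() if not k.startswith("__")
        }

    def _find(key: str | None, suffix: str) -> np.ndarray:
        if key is not None:
            if key not in container:
                raise DatasetFormatError(f"archive has no entry {key!r}; found {sorted(container)}")
            return np.asarray(container[key])
        hits = [k for k in container if k.endswith(suffix)]
        if len(hits) != 1:
            raise DatasetFormatError(
                f"cannot locate a unique '*{suffix}' entry in archive; found {sorted(container)}; "
                f"pass data_key/labels_key explicitly"
            )
        return np.asarray(container[hits[0]])

    data = _find(data_key, "_data")
    labels = _find(labels_key, "_labels")
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    labels = np.atleast_2d(np.asarray(labels))

    flat = window_length * n_axes
    if data.shape[1] != flat:
        raise DatasetFormatError(
            f"records of length {data.shape[1]} do not divide into {n_axes} axes of "
            f"{window_length} samples (need {flat})"
        )
    if labels.shape[0] != data.shape[0]:
        raise DatasetFormatError(
            f"label matrix has {labels.shape[0]} rows but data has {data.shape[0]} records"
        )

    if axis_order == "block":
        cube = data.reshape(-1, n_axes, window_length).transpose(0, 2, 1)
    else:
        cube = data.reshape(-1, window_length, n_axes)

    windows = []
    for i in range(cube.shape[0]):
        act, subj = labels[i, 0], labels[i, 1]
        trial = labels[i, 2] if labels.shape[1] > 2 else 0
        windows.append(
            SignalWindow(
                values=cube[i],
                activity=str(act) if isinstance(act, str) else f"activity_{int(act)}",
                subject=int(subj),
                trial=int(trial),
                sample_rate_hz=sample_rate_hz,
            )
        )
    vocab = sorted({w.activity for w in windows})
    roster = sorted({w.subject for w in windows})
    return Dataset(windows=windows, activity_vocabulary=vocab, subject_roster=roster)
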