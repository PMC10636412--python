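"""Canonical data model and I/O: EEG recordings (EDF/HDF5), event schedules,
behavioral tables, and result frames.

All amplitudes are carried in microvolts internally.  Time is expressed as
0-based sample indices; epochs are half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _edf

ACTION_IDS = (1, 2, 3, 4)
ACTION_DURATION_MS = 10_000

EVENT_COLUMNS = ["onset_sample", "action_id", "iteration", "run", "trial"]


class IOValidationError(ValueError):
    """Raised when a file or table violates the data-model invariants."""


@dataclass
class EEGRecording:
    """Multi-channel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    sample_rate: float
    channel_labels: list[str]
    reference: str = "vertex"  # "vertex" | "average"
    bad_channels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise IOValidationError("data must be a 2-D channels x samples array")
        if len(self.channel_labels) != self.data.shape[0]:
            raise IOValidationError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} data rows"
            )
        dupes = {l for l in self.channel_labels if self.channel_labels.count(l) > 1}
        if dupes:
            raise IOValidationError(f"duplicate channel labels: {sorted(dupes)}")
        if not self.sample_rate > 0:
            raise IOValidationError("sample_rate must be positive")
        if self.reference not in ("vertex", "average"):
            raise IOValidationError(f"unknown reference {self.reference!r}")
        if np.isnan(self.data).any():
            raise IOValidationError("recording contains NaN")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise IOValidationError(f"channel {label!r} not in recording") from None

    def copy_with(self, **kwargs) -> "EEGRecording":
        out = replace(self, **kwargs)
        if "data" not in kwargs:
            out.data = self.data.copy()
        if "bad_channels" not in kwargs:
            out.bad_channels = set(self.bad_channels)
        return out


@dataclass(frozen=True)
class Event:
    onset_sample: int
    action_id: int
    iteration: int
    run: int
    trial: int


@dataclass
class EventSchedule:
    """Validated list of action-onset events."""

    events: list[Event]
    n_samples: int | None = None  # recording length, if known, for bounds checks
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        onsets = [e.onset_sample for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise IOValidationError("event onsets must be strictly increasing")
        keys = [(e.action_id, e.run, e.trial) for e in self.events]
        if len(set(keys)) != len(keys):
            raise IOValidationError("duplicate (action_id, run, trial) events")
        for i, e in enumerate(self.events):
            if e.action_id not in ACTION_IDS:
                raise IOValidationError(f"row {i}: action_id {e.action_id} not in 1..4")
            if e.run not in (1, 2) or e.trial not in (1, 2):
                raise IOValidationError(f"row {i}: run/trial must be 1 or 2")
            if e.iteration not in (1, 2, 3, 4):
                raise IOValidationError(f"row {i}: iteration {e.iteration} not in 1..4")
            if e.onset_sample < 0:
                raise IOValidationError(f"row {i}: negative onset")
        if self.n_samples is not None and self.sample_rate is not None:
            dur = int(round(ACTION_DURATION_MS / 1000.0 * self.sample_rate))
            for i, e in enumerate(self.events):
                if e.onset_sample + dur > self.n_samples:
                    raise IOValidationError(
                        f"row {i}: epoch [{e.onset_sample}, {e.onset_sample + dur}) "
                        f"exceeds recording length {self.n_samples}"
                    )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def by_action(self, action_id: int) -> list[Event]:
        return [e for e in self.events if e.action_id == action_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.events], columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# Recording I/O

_UNIT_SCALE = {"uV": 1.0, "µV": 1.0, "mV": 1000.0}


def write_recording(rec: EEGRecording, path: str | Path, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "edf":
        _edf.write_edf(
            path,
            rec.data,
            rec.sample_rate,
            rec.channel_labels,
            physical_dim="uV",
            recording_id=f"ref={rec.reference}",
        )
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("data", data=rec.data)
            ds.attrs["sample_rate"] = rec.sample_rate
            ds.attrs["channel_labels"] = [l.encode() for l in rec.channel_labels]
            ds.attrs["reference"] = rec.reference
            ds.attrs["unit"] = "uV"
    else:
        raise IOValidationError(f"unknown recording format {fmt!r}")


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read an EDF or HDF5 recording; amplitudes are converted to microvolts."""
    fmt = format or _infer_format(path)
    if fmt == "edf":
        data, rate, labels, dims, rec_id = _edf.read_edf(path)
        scaled = np.empty_like(data)
        for i, dim in enumerate(dims):
            if dim not in _UNIT_SCALE:
                raise IOValidationError(
                    f"channel {labels[i]!r}: unsupported physical dimension {dim!r} "
                    "(expected uV or mV)"
                )
            scaled[i] = data[i] * _UNIT_SCALE[dim]
        reference = "vertex"
        for token in rec_id.split():
            if token.startswith("ref="):
                reference = token[4:]
        return EEGRecording(scaled, rate, labels, reference=reference)
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            ds = f["data"]
            labels = [
                l.decode() if isinstance(l, bytes) else str(l)
                for l in ds.attrs["channel_labels"]
            ]
            ref = ds.attrs.get("reference", "vertex")
            if isinstance(ref, bytes):
                ref = ref.decode()
            return EEGRecording(ds[()], float(ds.attrs["sample_rate"]), labels, reference=ref)
    raise IOValidationError(f"unknown recording format {fmt!r}")


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    raise IOValidationError(f"cannot infer format from suffix {suffix!r}")


# ---------------------------------------------------------------------------
# Event / table I/O


def write_events(sched: EventSchedule, path: str | Path) -> None:
    sched.to_frame().to_csv(path, index=False)


def read_events(
    path: str | Path, n_samples: int | None = None, sample_rate: float | None = None
) -> EventSchedule:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise IOValidationError(f"events file missing columns: {sorted(missing)}")
    events = [
        Event(int(r.onset_sample), int(r.action_id), int(r.iteration), int(r.run), int(r.trial))
        for r in df.itertuples()
    ]
    return EventSchedule(events, n_samples=n_samples, sample_rate=sample_rate)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise IOValidationError(f"{path}: missing columns {sorted(missing)}")
    return df
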