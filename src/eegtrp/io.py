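"""Recordings, event logs, and their file formats.

Recordings are continuous multichannel EEG in microvolts at (nominally)
128 Hz, stored either as EDF (biosignal exchange) or as plain CSV with one
column per electrode and one row per sample — the fixture dialect used in
the tests.  Event logs are CSVs of experiment markers (baseline on/offsets,
drawing presentation, first sketch element, task end) carrying the
projection condition of each CAD task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _edf
from .montage import Montage, default_montage

__all__ = [
    "Recording", "Event", "EventLog",
    "load_recording", "save_recording", "load_events", "save_events",
    "UnknownFormatError", "ChannelMismatchError", "NonNumericSamplesError",
    "EventLogError",
]

NOMINAL_FS = 128.0
CONDITIONS = ("isometric", "orthographic")
MARKERS = ("baseline_start", "baseline_end", "drawing_shown",
           "first_sketch_element", "task_end")


class UnknownFormatError(ValueError):
    """Requested file format is not one of {edf, csv}."""


class ChannelMismatchError(ValueError):
    """File channels do not match the montage."""


class NonNumericSamplesError(ValueError):
    """CSV sample values failed numeric parsing."""


class EventLogError(ValueError):
    """Event log violates ordering/pairing constraints."""


@dataclass
class Recording:
    """Continuous multichannel EEG: samples [channels x time] in µV."""

    samples: np.ndarray
    fs: float
    channel_labels: Tuple[str, ...]
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be [channels x time]")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ChannelMismatchError(
                f"{self.samples.shape[0]} sample rows for "
                f"{len(self.channel_labels)} channel labels")
        if not np.all(np.isfinite(self.samples)):
            raise NonNumericSamplesError("samples contain NaN/Inf")
        if self.fs != NOMINAL_FS:
            warnings.warn(
                f"sampling rate {self.fs} Hz differs from the nominal "
                f"{NOMINAL_FS} Hz", stacklevel=2)
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, samples: np.ndarray) -> "Recording":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class Event:
    time_s: float
    marker: str
    condition: Optional[str] = None
    task_index: Optional[int] = None


@dataclass
class EventLog:
    """Time-sorted experiment markers for one session."""

    events: List[Event]
    baseline_duration_s: float = 20.0
    baseline_tolerance_s: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        times = [e.time_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise EventLogError("events are not sorted by time")
        for e in self.events:
            if e.marker not in MARKERS:
                raise EventLogError(f"unknown marker {e.marker!r}")
            if e.marker in ("drawing_shown", "first_sketch_element", "task_end"):
                if e.condition not in CONDITIONS:
                    raise EventLogError(
                        f"unknown condition {e.condition!r} at t={e.time_s}")
        # every drawing_shown -> first_sketch_element -> task_end, same task
        for task in self.task_indices():
            seq = [e for e in self.events
                   if e.task_index == task and e.marker != "baseline_start"
                   and e.marker != "baseline_end"]
            markers = [e.marker for e in seq]
            if markers != ["drawing_shown", "first_sketch_element", "task_end"]:
                raise EventLogError(
                    f"task {task}: expected drawing_shown/first_sketch_element/"
                    f"task_end, got {markers}")
            conds = {e.condition for e in seq}
            if len(conds) != 1:
                raise EventLogError(f"task {task}: inconsistent condition labels")
        # matched baseline pairs of ~the nominal duration
        starts = [e for e in self.events if e.marker == "baseline_start"]
        ends = [e for e in self.events if e.marker == "baseline_end"]
        if len(starts) != len(ends):
            raise EventLogError("unmatched baseline_start/baseline_end")
        for s, e in zip(starts, ends):
            if e.time_s <= s.time_s:
                raise EventLogError("baseline_end precedes its baseline_start")
            dur = e.time_s - s.time_s
            if abs(dur - self.baseline_duration_s) > self.baseline_tolerance_s:
                raise EventLogError(
                    f"baseline duration {dur:.2f} s outside "
                    f"{self.baseline_duration_s}±{self.baseline_tolerance_s} s")

    def task_indices(self) -> List[int]:
        seen: List[int] = []
        for e in self.events:
            if e.marker == "drawing_shown" and e.task_index not in seen:
                seen.append(e.task_index)
        return seen

    def baselines(self) -> List[Tuple[float, float]]:
        starts = [e.time_s for e in self.events if e.marker == "baseline_start"]
        ends = [e.time_s for e in self.events if e.marker == "baseline_end"]
        return list(zip(starts, ends))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.time_s, e.marker, e.condition or "", e.task_index)
             for e in self.events],
            columns=["time_s", "marker", "condition", "task_index"])


def load_recording(path: str | Path, format: Optional[str] = None,
                   montage: Optional[Montage] = None,
                   subject_id: str = "unknown") -> Recording:
    """Load a recording from EDF or CSV, normalising channel order."""
    path = Path(path)
    montage = montage or default_montage()
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "edf":
        samples, fs, labels = _edf.read_edf(path)
    elif format == "csv":
        try:
            df = pd.read_csv(path).apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise NonNumericSamplesError(str(exc)) from exc
        fs_col = None
        if "fs" in df.columns:  # optional metadata column
            fs_col = float(df["fs"].iloc[0])
            df = df.drop(columns=["fs"])
        labels = list(df.columns)
        samples = df.to_numpy().T
        fs = fs_col if fs_col is not None else NOMINAL_FS
    else:
        raise UnknownFormatError(f"unknown recording format {format!r}")

    missing = [e for e in montage.electrodes if e not in labels]
    extra = [l for l in labels if l not in montage.electrodes]
    if missing or extra:
        raise ChannelMismatchError(
            f"channels do not match montage (missing={missing}, extra={extra})")
    order = [labels.index(e) for e in montage.electrodes]
    samples = np.asarray(samples, dtype=float)[order]
    if not np.all(np.isfinite(samples)):
        raise NonNumericSamplesError("loaded samples contain NaN/Inf")
    return Recording(samples=samples, fs=fs,
                     channel_labels=montage.electrodes, subject_id=subject_id)


def save_recording(recording: Recording, path: str | Path,
                   format: Optional[str] = None) -> None:
    """Write a recording as EDF (16-bit) or CSV (full precision)."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "edf":
        _edf.write_edf(path, recording.samples, recording.fs,
                       recording.channel_labels)
    elif format == "csv":
        df = pd.DataFrame(recording.samples.T, columns=recording.channel_labels)
        df.insert(0, "fs", recording.fs)
        df.to_csv(path, index=False, float_format="%.10g")
    else:
        raise UnknownFormatError(f"unknown recording format {format!r}")


def load_events(path: str | Path, baseline_duration_s: float = 20.0,
                baseline_tolerance_s: float = 1.0) -> EventLog:
    """Load and validate an events CSV (time_s, marker, condition, task_index)."""
    df = pd.read_csv(path)
    required = {"time_s", "marker", "condition", "task_index"}
    if not required.issubset(df.columns):
        raise EventLogError(f"events CSV must have columns {sorted(required)}")
    events = []
    for _, row in df.iterrows():
        cond = row["condition"]
        cond = None if (pd.isna(cond) or cond == "") else str(cond)
        task = row["task_index"]
        task = None if pd.isna(task) else int(task)
        events.append(Event(float(row["time_s"]), str(row["marker"]), cond, task))
    return EventLog(events, baseline_duration_s=baseline_duration_s,
                    baseline_tolerance_s=baseline_tolerance_s)


def save_events(log: EventLog, path: str | Path) -> None:
    log.to_frame().to_csv(path, index=False)
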