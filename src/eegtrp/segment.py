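"""Cutting a session into baseline epochs and the two CAD task segments.

Each CAD task contributes three epochs: the 20 s fixation baseline recorded
immediately before it, segment #1 (drawing presentation up to the first
sketch element — interpreting the technical drawing), and segment #2 (first
sketch element to task end — generating the 3D model).  Segment #1 ends
exactly where segment #2 starts, so the two tile the task span without gap
or overlap.  Boundaries use the half-open sample convention
[round(t_start*fs), round(t_end*fs)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .io import EventLog, Recording

__all__ = ["Epoch", "segment_session", "SegmentationError"]


class SegmentationError(ValueError):
    """Markers outside the recording or a negative-length segment."""


@dataclass
class Epoch:
    """A labelled slice of a recording."""

    samples: np.ndarray              # [channels x time], µV
    fs: float
    subject_id: str
    condition: Optional[str]         # None for baselines not tied to a task yet
    role: str                        # baseline | seg1 | seg2
    task_index: Optional[int]
    t_start_s: float
    t_end_s: float

    def __post_init__(self) -> None:
        if self.t_end_s <= self.t_start_s:
            raise SegmentationError(
                f"{self.role}: non-positive duration "
                f"[{self.t_start_s}, {self.t_end_s}]")

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def _slice(recording: Recording, t0: float, t1: float) -> np.ndarray:
    fs = recording.fs
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    if i0 < 0 or i1 > recording.n_samples:
        raise SegmentationError(
            f"epoch [{t0}, {t1}] s falls outside the {recording.duration_s:.2f} s "
            "recording")
    if i1 <= i0:
        raise SegmentationError(f"negative/zero-length epoch [{t0}, {t1}] s")
    return recording.samples[:, i0:i1]


def segment_session(recording: Recording, events: EventLog) -> List[Epoch]:
    """Cut one session into baseline/seg1/seg2 epochs per CAD task.

    The baseline attached to each task is the one recorded immediately
    before the task's drawing presentation (the denominator epoch of TRP);
    post-task baselines with no following task are segmented with role
    ``baseline`` and ``task_index=None`` so nothing is silently dropped.
    """
    epochs: List[Epoch] = []
    baselines = events.baselines()
    used = [False] * len(baselines)

    for task in events.task_indices():
        ev = {e.marker: e for e in events.events if e.task_index == task}
        shown = ev["drawing_shown"]
        sketch = ev["first_sketch_element"]
        end = ev["task_end"]
        cond = shown.condition
        if not (shown.time_s < sketch.time_s < end.time_s):
            raise SegmentationError(
                f"task {task}: markers not strictly ordered in time")

        # pre-task baseline: latest baseline ending at/before drawing_shown
        pre = None
        for i, (b0, b1) in enumerate(baselines):
            if b1 <= shown.time_s + 1e-9:
                pre = i
        if pre is None:
            raise SegmentationError(f"task {task}: no preceding baseline")
        b0, b1 = baselines[pre]
        used[pre] = True
        epochs.append(Epoch(_slice(recording, b0, b1), recording.fs,
                            recording.subject_id, cond, "baseline", task, b0, b1))
        epochs.append(Epoch(_slice(recording, shown.time_s, sketch.time_s),
                            recording.fs, recording.subject_id, cond, "seg1",
                            task, shown.time_s, sketch.time_s))
        epochs.append(Epoch(_slice(recording, sketch.time_s, end.time_s),
                            recording.fs, recording.subject_id, cond, "seg2",
                            task, sketch.time_s, end.time_s))

    for i, (b0, b1) in enumerate(baselines):
        if not used[i]:
            epochs.append(Epoch(_slice(recording, b0, b1), recording.fs,
                                recording.subject_id, None, "baseline", None,
                                b0, b1))
    return epochs
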