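"""Sliding-window amplitude artifact rejection.

A 1 s window slides over each epoch one sample at a time.  A window is bad
when its mean absolute amplitude (over samples and electrodes) exceeds the
per-participant threshold — capped at the absolute 100 µV limit — or when
any single sample inside it exceeds ±100 µV.  A sample is retained only if
every window covering it is good (conservative union of bad windows).  The
per-participant threshold is the mean plus three standard deviations of the
absolute amplitudes over the whole epoch and all electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .segment import Epoch

__all__ = ["RejectionResult", "subject_threshold", "mark_bad_windows",
           "ABSOLUTE_LIMIT_UV"]

ABSOLUTE_LIMIT_UV = 100.0


@dataclass
class RejectionResult:
    mask: np.ndarray                 # per-sample, True = retained
    threshold_subject_uV: float
    threshold_effective_uV: float
    pct_bad: float

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())


def subject_threshold(epoch: Epoch | np.ndarray) -> float:
    """Per-participant amplitude threshold: mean + 3·SD of |x| over the epoch.

    Computed on absolute values across all samples of all electrodes; raw
    (signed) values are near zero-mean after filtering and would give a
    degenerate threshold.
    """
    x = epoch.samples if isinstance(epoch, Epoch) else np.asarray(epoch)
    if x.size == 0:
        raise ValueError("empty epoch")
    a = np.abs(x)
    return float(a.mean() + 3.0 * a.std(ddof=0))


def mark_bad_windows(epoch: Epoch | np.ndarray, threshold_uV: float,
                     fs: float | None = None,
                     absolute_limit_uV: float = ABSOLUTE_LIMIT_UV,
                     window_s: float = 1.0) -> RejectionResult:
    """Flag samples covered by any bad 1 s window (shift = one sample)."""
    if threshold_uV < 0:
        raise ValueError("threshold must be non-negative")
    if isinstance(epoch, Epoch):
        x, fs = epoch.samples, epoch.fs
    else:
        x = np.atleast_2d(np.asarray(epoch, dtype=float))
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    n = x.shape[1]
    win = int(round(window_s * fs))
    if n < win:
        raise ValueError(f"epoch shorter than one {window_s} s window")

    effective = min(threshold_uV, absolute_limit_uV)
    a = np.abs(x)
    per_sample_mean = a.mean(axis=0)          # mean |x| across electrodes
    per_sample_peak = a.max(axis=0)

    # window means via cumulative sum; window w covers samples [w, w+win)
    c = np.concatenate([[0.0], np.cumsum(per_sample_mean)])
    win_mean = (c[win:] - c[:-win]) / win
    # window peak via a sliding view (win is even at 128 Hz, so the generic
    # centred running-max filters do not line up; the view is exact)
    peak = sliding_window_view(per_sample_peak, win).max(axis=1)

    bad_window = (win_mean > effective) | (peak > absolute_limit_uV)

    # sample t is covered by windows starting in [t-win+1, t] ∩ [0, n-win]
    bad_sample = np.zeros(n, dtype=bool)
    starts = np.flatnonzero(bad_window)
    if starts.size:
        # mark [s, s+win) for every bad start via difference array
        diff = np.zeros(n + 1, dtype=int)
        np.add.at(diff, starts, 1)
        np.add.at(diff, np.minimum(starts + win, n), -1)
        bad_sample = np.cumsum(diff[:-1]) > 0

    mask = ~bad_sample
    pct_bad = 100.0 * bad_sample.mean()
    return RejectionResult(mask=mask, threshold_subject_uV=float(threshold_uV),
                           threshold_effective_uV=float(effective),
                           pct_bad=float(pct_bad))
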