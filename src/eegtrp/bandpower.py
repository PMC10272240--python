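"""Band splitting, power, and task-related power (TRP).

Power is the mean of the squared band-passed samples over the retained
samples of an epoch (time-domain definition; a Welch cross-check utility is
provided).  TRP is the log task power minus the log power of the baseline
recorded immediately before that task, per electrode and band; positive
values mean a task-related power increase.  Log base defaults to 10.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .montage import Montage, default_montage
from .preprocess import design_fir_bandpass, filter_array
from .segment import Epoch
from .simulate import BANDS

__all__ = ["band_filter", "epoch_power", "trp", "welch_band_power",
           "build_trp_table", "EmptyPowerError", "MissingBaselineError"]


class EmptyPowerError(ValueError):
    """Epoch has no retained samples on some electrode."""


class MissingBaselineError(ValueError):
    """A task power row has no pre-task baseline counterpart."""


def band_filter(epoch: Epoch, band: str) -> Epoch:
    """Band-pass an epoch at the analysis band's edges (theta/alpha/beta)."""
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}")
    lo, hi = BANDS[band]
    taps = design_fir_bandpass(lo, hi, epoch.fs)
    if epoch.n_samples < len(taps):
        raise ValueError(
            f"epoch of {epoch.n_samples} samples too short for the {band} "
            f"filter ({len(taps)} taps)")
    return replace(epoch, samples=filter_array(epoch.samples, taps))


def epoch_power(epoch: Epoch, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-electrode mean squared amplitude (µV²) over retained samples."""
    x = epoch.samples
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (x.shape[1],):
            raise ValueError("mask length does not match the epoch")
        if not mask.any():
            raise EmptyPowerError("epoch fully rejected: no retained samples")
        x = x[:, mask]
    return np.mean(x ** 2, axis=1)


def trp(pow_task: np.ndarray | float, pow_baseline: np.ndarray | float,
        base: float = 10.0) -> np.ndarray | float:
    """Task-related power: log(task power) - log(baseline power)."""
    pt = np.asarray(pow_task, dtype=float)
    pb = np.asarray(pow_baseline, dtype=float)
    if np.any(pt <= 0) or np.any(pb <= 0):
        raise ValueError("TRP undefined for non-positive power")
    out = (np.log(pt) - np.log(pb)) / math.log(base)
    return float(out) if out.ndim == 0 else out


def welch_band_power(epoch: Epoch, band: str,
                     nperseg_s: float = 4.0) -> np.ndarray:
    """Band-integrated Welch PSD per electrode — cross-check for epoch_power."""
    lo, hi = BANDS[band]
    nper = min(int(nperseg_s * epoch.fs), epoch.n_samples)
    freqs, psd = _signal.welch(epoch.samples, fs=epoch.fs, nperseg=nper,
                               axis=-1)
    sel = (freqs >= lo) & (freqs <= hi)
    return np.trapezoid(psd[:, sel], freqs[sel], axis=-1)


def build_trp_table(power_records: pd.DataFrame,
                    montage: Optional[Montage] = None,
                    base: float = 10.0) -> pd.DataFrame:
    """Assemble the tidy long-format TRP table from band-power records.

    ``power_records`` needs columns subject, condition, role (baseline/
    seg1/seg2), task_index, band, electrode, pow.  Each task row is paired
    with the baseline of the same (subject, task_index); hemisphere and
    area factors are attached from the montage.  Output columns: subject,
    projection, segment, band, electrode, hemisphere, area, trp.
    """
    montage = montage or default_montage()
    required = {"subject", "condition", "role", "task_index", "band",
                "electrode", "pow"}
    missing = required - set(power_records.columns)
    if missing:
        raise ValueError(f"power records missing columns {sorted(missing)}")

    base_rows = power_records[power_records["role"] == "baseline"]
    base_map = base_rows.set_index(
        ["subject", "task_index", "band", "electrode"])["pow"]
    task_rows = power_records[power_records["role"].isin(["seg1", "seg2"])]

    out = []
    for row in task_rows.itertuples(index=False):
        key = (row.subject, row.task_index, row.band, row.electrode)
        try:
            pb = float(base_map.loc[key])
        except KeyError as exc:
            raise MissingBaselineError(
                f"no baseline power for subject={row.subject} "
                f"task={row.task_index} band={row.band} "
                f"electrode={row.electrode}") from exc
        out.append({
            "subject": row.subject,
            "projection": row.condition,
            "segment": row.role,
            "band": row.band,
            "electrode": row.electrode,
            "hemisphere": montage.hemisphere_of[row.electrode],
            "area": montage.area_of[row.electrode],
            "trp": trp(row.pow, pb, base=base),
        })
    return pd.DataFrame(out)
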