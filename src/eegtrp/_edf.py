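"""Minimal EDF (European Data Format) reader/writer for multichannel EEG.

Implements the plain EDF layout: a 256-byte ASCII header, 256 bytes of
per-signal header fields, then contiguous data records of little-endian
16-bit integers with per-signal physical/digital scaling.  All signals are
written with a common sampling rate and the whole recording is stored as
one data record, which keeps the round trip free of padding.  Quantisation
uses a symmetric physical range so the resolution for typical EEG
(|x| < 3276 µV) stays below 0.1 µV.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["write_edf", "read_edf"]

_DIG_MAX = 32767
_DIG_MIN = -32768


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    samples: np.ndarray,
    fs: float,
    channel_labels: Sequence[str],
    physical_dim: str = "uV",
    patient_id: str = "X",
    recording_id: str = "X",
) -> None:
    """Write a [channels x time] array (physical units) as a 16-bit EDF file."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be a 2-D [channels x time] array")
    n_ch, n_samp = samples.shape
    if n_ch != len(channel_labels):
        raise ValueError("channel_labels length does not match samples")
    if n_samp == 0:
        raise ValueError("cannot write an empty recording")

    # Symmetric per-file physical range -> scaling is sign-preserving and the
    # digital zero maps to physical zero.
    pmax = float(np.max(np.abs(samples)))
    if not np.isfinite(pmax):
        raise ValueError("samples contain NaN/Inf")
    pmax = max(pmax, 1.0)
    scale = _DIG_MAX / pmax
    digital = np.clip(np.rint(samples * scale), _DIG_MIN, _DIG_MAX).astype("<i2")

    record_duration = n_samp / fs
    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(256 * (1 + n_ch)), 8),
        _field("", 44),
        _field("1", 8),                       # one data record
        _field(f"{record_duration:.6g}", 8),
        _field(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_field(lbl, 16) for lbl in channel_labels),
        b"".join(_field("", 80) for _ in channel_labels),
        b"".join(_field(physical_dim, 8) for _ in channel_labels),
        b"".join(_field(f"{-pmax:.6g}"[:8], 8) for _ in channel_labels),
        b"".join(_field(f"{pmax:.6g}"[:8], 8) for _ in channel_labels),
        b"".join(_field(str(_DIG_MIN), 8) for _ in channel_labels),
        b"".join(_field(str(_DIG_MAX), 8) for _ in channel_labels),
        b"".join(_field("", 80) for _ in channel_labels),
        b"".join(_field(str(n_samp), 8) for _ in channel_labels),
        b"".join(_field("", 32) for _ in channel_labels),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # one record: all samples of signal 0, then signal 1, ...
        fh.write(digital.tobytes())


def read_edf(path: str | Path) -> Tuple[np.ndarray, float, List[str]]:
    """Read an EDF file; returns (samples [channels x time], fs, labels)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError("not an EDF file (truncated header)")

    def fld(offset: int, width: int) -> str:
        return raw[offset:offset + width].decode("ascii", errors="replace").strip()

    n_records = int(fld(236, 8))
    record_duration = float(fld(244, 8))
    n_ch = int(fld(252, 4))
    base = 256

    def sig_fields(block: int, width: int) -> List[str]:
        off = base + block
        return [fld(off + i * width, width) for i in range(n_ch)]

    labels = sig_fields(0, 16)
    pmin = np.array([float(v) for v in sig_fields(n_ch * (16 + 80 + 8), 8)])
    pmax = np.array([float(v) for v in sig_fields(n_ch * (16 + 80 + 8 + 8), 8)])
    dmin = np.array([float(v) for v in sig_fields(n_ch * (16 + 80 + 8 + 8 + 8), 8)])
    dmax = np.array([float(v) for v in sig_fields(n_ch * (16 + 80 + 8 + 8 + 8 + 8), 8)])
    spr = np.array([int(v) for v in sig_fields(n_ch * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80), 8)])

    header_bytes = base + n_ch * 256
    data = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    rec_len = int(spr.sum())
    if n_records < 0:  # unknown record count: infer
        n_records = len(data) // rec_len
    data = data[: n_records * rec_len].reshape(n_records, rec_len)

    out = np.empty((n_ch, int(spr[0]) * n_records), dtype=float)
    gains = (pmax - pmin) / (dmax - dmin)
    offsets = pmax - gains * dmax
    starts = np.concatenate([[0], np.cumsum(spr)]).astype(int)
    for c in range(n_ch):
        chunk = data[:, starts[c]:starts[c + 1]].reshape(-1).astype(float)
        out[c] = chunk * gains[c] + offsets[c]
    fs = spr[0] / record_duration * 1.0
    return out, float(fs), labels
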