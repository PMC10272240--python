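"""Synthetic EEG cohorts with controlled band-power structure.

The generator emulates the study design downstream stages expect: per
subject, a session of [baseline1, task1(seg1+seg2), baseline2,
task2(seg1+seg2)] where each task is one projection condition (isometric or
orthographic) and half the cohort performs the conditions in each order.

Channels carry, per frequency band, one spatially coherent oscillation
source (band-limited filtered noise, exactly RMS-normalised within each
epoch so that task/baseline power ratios are controlled to the ground-truth
gain), mixed across the 14 electrodes with per-electrode weights, on top of
independent per-channel background noise composed of a 1/f^chi process and
a white sensor-noise floor.  The beta oscillation is synthesised with
low-beta emphasis (13-20 Hz), which keeps its lag-1 autocorrelation well
above the background's — the property the BSS-CCA cleaning stage relies on
in real EEG.  DC offsets, high-amplitude spikes and broadband EMG bursts
can be injected on demand, each injection recorded in an artifact log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io import Event, EventLog, Recording
from .montage import Montage, default_montage
from .preprocess import design_fir_bandpass, filter_array

__all__ = [
    "BANDS", "SYNTH_EDGES", "CohortSpec", "GroundTruth", "SubjectSession",
    "Cohort", "ArtifactEvent", "synth_band_oscillation", "pink_noise",
    "synth_subject_session", "inject_artifacts", "synth_cohort",
]

#: analysis band edges (Hz) — the bands the pipeline reports
BANDS: Dict[str, Tuple[float, float]] = {
    "theta": (4.0, 7.0), "alpha": (8.0, 12.0), "beta": (13.0, 30.0),
}

#: synthesis edges: where the simulated oscillation actually lives.  Beta is
#: generated as low beta (13-20 Hz), inside the 13-30 Hz analysis band.
SYNTH_EDGES: Dict[str, Tuple[float, float]] = {
    "theta": (4.0, 7.0), "alpha": (8.0, 12.0), "beta": (13.0, 20.0),
}

CONDITIONS = ("isometric", "orthographic")
SEGMENTS = ("seg1", "seg2")


def _normalise_rms(x: np.ndarray, rms: float) -> np.ndarray:
    cur = float(np.sqrt(np.mean(x ** 2)))
    if cur == 0:
        return x
    return x * (rms / cur)


def pink_noise(n_samples: int, fs: float, rms_uV: float, exponent: float,
               rng: np.random.Generator, f_floor: float = 0.5) -> np.ndarray:
    """1/f^exponent noise by spectral shaping; RMS set over the whole series."""
    if rms_uV == 0:
        return np.zeros(n_samples)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], f_floor) ** (-exponent / 2.0)
    shape[0] = 0.0
    spec = shape * (rng.standard_normal(len(freqs))
                    + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n_samples)
    return _normalise_rms(x, rms_uV)


def synth_band_oscillation(band: str, duration_s: float, fs: float,
                           amplitude_uV: float, seed: int,
                           mode: str = "narrowband") -> np.ndarray:
    """One zero-mean band-limited oscillation channel.

    ``narrowband`` mode band-pass-filters white noise at the band's
    synthesis edges; ``sinusoid`` mode emits a pure tone at the band centre
    (for analytic tests).  RMS equals ``amplitude_uV / sqrt(2)`` — the RMS
    of a sinusoid of that peak amplitude.
    """
    if band not in SYNTH_EDGES:
        raise ValueError(f"unknown band {band!r}; expected one of {list(BANDS)}")
    n = int(round(duration_s * fs))
    if amplitude_uV == 0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    lo, hi = SYNTH_EDGES[band]
    target_rms = amplitude_uV / math.sqrt(2.0)
    if mode == "sinusoid":
        f0 = 0.5 * (lo + hi)
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / fs
        return amplitude_uV * np.sin(2 * np.pi * f0 * t + phase)
    if mode != "narrowband":
        raise ValueError(f"unknown oscillation mode {mode!r}")
    taps = design_fir_bandpass(lo, hi, fs)
    if n < len(taps):
        raise ValueError(
            f"duration {duration_s} s too short for the {band} filter "
            f"({len(taps)} taps at {fs} Hz)")
    x = filter_array(rng.standard_normal(n), taps)[0]
    return _normalise_rms(x - x.mean(), target_rms)


@dataclass
class ArtifactEvent:
    kind: str
    channels: Tuple[str, ...]
    onset_s: float
    duration_s: float
    peak_uV: float


@dataclass
class GroundTruth:
    """Simulator ground truth for parameter-recovery tests."""

    #: marginal task/baseline amplitude gain per (band, condition, segment)
    gains: Dict[Tuple[str, str, str], float]
    #: expected log10 TRP per (band, condition, segment, electrode)
    expected_trp: Dict[Tuple[str, str, str, str], float]
    #: baseline oscillation amplitude per (band, electrode), µV
    baseline_amplitudes: Dict[Tuple[str, str], float]
    artifact_log: List[ArtifactEvent] = field(default_factory=list)

    def expected_trp_mean(self, band: str, condition: str,
                          segment: str) -> float:
        vals = [v for (b, c, s, _e), v in self.expected_trp.items()
                if (b, c, s) == (band, condition, segment)]
        return float(np.mean(vals))


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Defaults reproduce the experiment's structure: 18 analysed subjects,
    128 Hz, 20 s baselines, condition order counterbalanced over the cohort,
    and task-segment durations equal to the study's median durations scaled
    down tenfold (seg1 32/71.5 s, seg2 861/904 s for isometric/orthographic).
    """

    n_subjects: int = 18
    fs: float = 128.0
    baseline_s: float = 20.0
    seg1_s: Mapping[str, float] = field(
        default_factory=lambda: {"isometric": 3.2, "orthographic": 7.15})
    seg2_s: Mapping[str, float] = field(
        default_factory=lambda: {"isometric": 86.1, "orthographic": 90.4})
    #: task/baseline amplitude gain per (band, condition, segment); missing
    #: entries default to 1 (no task-related power change)
    gains: Dict[Tuple[str, str, str], float] = field(default_factory=dict)
    #: log10-TRP offsets per factor: keys "projection", "hemisphere", "area",
    #: "projection:hemisphere", "projection:area"; values are floats or
    #: per-band dicts.  Positive levels: orthographic, RH, FA.
    effect_offsets: Dict[str, object] = field(default_factory=dict)
    baseline_amplitude_uV: Mapping[str, float] = field(
        default_factory=lambda: {"theta": 10.0, "alpha": 10.0, "beta": 10.0})
    electrode_weight_spread: float = 0.2
    noise_exponent: float = 1.0
    pink_rms_uV: float = 1.5
    white_rms_uV: float = 1.5
    oscillation_mode: str = "narrowband"
    lead_s: float = 2.0
    tail_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for d in (self.baseline_s, self.lead_s, self.tail_s):
            if d < 0:
                raise ValueError("durations must be non-negative")

    def seg_duration(self, role: str, condition: str) -> float:
        if role == "seg1":
            return float(self.seg1_s[condition])
        if role == "seg2":
            return float(self.seg2_s[condition])
        if role == "baseline":
            return float(self.baseline_s)
        raise ValueError(f"unknown role {role!r}")

    def gain(self, band: str, condition: str, segment: str) -> float:
        return float(self.gains.get((band, condition, segment), 1.0))

    def _offset(self, key: str, band: str) -> float:
        val = self.effect_offsets.get(key, 0.0)
        if isinstance(val, Mapping):
            return float(val.get(band, 0.0))
        return float(val)

    def target_trp(self, band: str, condition: str, segment: str,
                   electrode: str, montage: Montage) -> float:
        """Expected log10 TRP including the factorial effect offsets."""
        trp = 2.0 * math.log10(self.gain(band, condition, segment))
        sp = 1.0 if condition == "orthographic" else -1.0
        sh = 1.0 if montage.hemisphere_of[electrode] == "RH" else -1.0
        sa = 1.0 if montage.area_of[electrode] == "FA" else -1.0
        trp += 0.5 * sp * self._offset("projection", band)
        trp += 0.5 * sh * self._offset("hemisphere", band)
        trp += 0.5 * sa * self._offset("area", band)
        trp += 0.25 * sp * sh * self._offset("projection:hemisphere", band)
        trp += 0.25 * sp * sa * self._offset("projection:area", band)
        return trp


@dataclass
class SubjectSession:
    recording: Recording
    events: EventLog
    ground_truth: GroundTruth
    condition_order: Tuple[str, str]


@dataclass
class Cohort:
    spec: CohortSpec
    sessions: List[SubjectSession]

    @property
    def ground_truth(self) -> GroundTruth:
        # expected TRP is identical across subjects; any session's truth works
        return self.sessions[0].ground_truth


def _session_layout(spec: CohortSpec, order: Sequence[str], fs: float):
    """Sample-exact piece layout: list of (role, condition, task_index, i0, i1)."""
    pieces = []
    i = int(round(spec.lead_s * fs))
    pieces.append(("lead", None, None, 0, i))
    for task_index, cond in enumerate(order, start=1):
        nb = int(round(spec.baseline_s * fs))
        pieces.append(("baseline", cond, task_index, i, i + nb)); i += nb
        n1 = int(round(spec.seg_duration("seg1", cond) * fs))
        pieces.append(("seg1", cond, task_index, i, i + n1)); i += n1
        n2 = int(round(spec.seg_duration("seg2", cond) * fs))
        pieces.append(("seg2", cond, task_index, i, i + n2)); i += n2
    nt = int(round(spec.tail_s * fs))
    pieces.append(("tail", None, None, i, i + nt)); i += nt
    return pieces, i


def synth_subject_session(spec: CohortSpec, subject_id: str, seed: int,
                          condition_order: str = "isometric_first",
                          montage: Optional[Montage] = None) -> SubjectSession:
    """Simulate one subject's session (recording + event log + ground truth)."""
    montage = montage or default_montage()
    rng = np.random.default_rng(seed)
    fs = spec.fs
    order = (("isometric", "orthographic")
             if condition_order == "isometric_first"
             else ("orthographic", "isometric"))
    pieces, n_total = _session_layout(spec, order, fs)

    x = np.zeros((montage.n_channels, n_total))
    baseline_amplitudes: Dict[Tuple[str, str], float] = {}
    expected: Dict[Tuple[str, str, str, str], float] = {}
    gains: Dict[Tuple[str, str, str], float] = {}

    for band in BANDS:
        amp = float(spec.baseline_amplitude_uV.get(band, 0.0))
        spread = spec.electrode_weight_spread
        weights = rng.uniform(1.0 - spread, 1.0 + spread, montage.n_channels)
        for e, w in zip(montage.electrodes, weights):
            baseline_amplitudes[(band, e)] = amp * w
        if amp == 0:
            continue
        src = synth_band_oscillation(
            band, n_total / fs, fs, amplitude_uV=1.0,
            seed=int(rng.integers(2 ** 31)), mode=spec.oscillation_mode)
        target = amp / math.sqrt(2.0)
        for role, cond, _task, i0, i1 in pieces:
            if i1 <= i0:
                continue
            seg = _normalise_rms(src[i0:i1], 1.0)  # exact unit RMS per piece
            if role in SEGMENTS:
                g_e = np.array([
                    10 ** (0.5 * spec.target_trp(band, cond, role, e, montage))
                    for e in montage.electrodes])
            else:
                g_e = np.ones(montage.n_channels)
            x[:, i0:i1] += np.outer(weights * target * g_e, seg)
        for cond in CONDITIONS:
            for segment in SEGMENTS:
                gains[(band, cond, segment)] = spec.gain(band, cond, segment)
                for e in montage.electrodes:
                    expected[(band, cond, segment, e)] = spec.target_trp(
                        band, cond, segment, e, montage)

    for c in range(montage.n_channels):
        x[c] += pink_noise(n_total, fs, spec.pink_rms_uV,
                           spec.noise_exponent, rng)
        if spec.white_rms_uV > 0:
            x[c] += spec.white_rms_uV * rng.standard_normal(n_total)

    events: List[Event] = []
    for role, cond, task, i0, i1 in pieces:
        t0, t1 = i0 / fs, i1 / fs
        if role == "baseline":
            events.append(Event(t0, "baseline_start"))
            events.append(Event(t1, "baseline_end"))
        elif role == "seg1":
            events.append(Event(t0, "drawing_shown", cond, task))
            events.append(Event(t1, "first_sketch_element", cond, task))
        elif role == "seg2":
            events.append(Event(t1, "task_end", cond, task))
    events.sort(key=lambda e: e.time_s)

    recording = Recording(samples=x, fs=fs,
                          channel_labels=montage.electrodes,
                          subject_id=subject_id)
    log = EventLog(events, baseline_duration_s=spec.baseline_s)
    truth = GroundTruth(gains=gains, expected_trp=expected,
                        baseline_amplitudes=baseline_amplitudes)
    return SubjectSession(recording, log, truth, order)


_DEFAULT_ARTIFACT_PARAMS: Dict[str, Dict[str, object]] = {
    "dc_offset": {"offset_uV": 4200.0},
    "spike": {"n": 3, "peak_uV": 150.0, "width_samples": 1},
    "emg_burst": {"n": 1, "duration_s": 1.0, "rms_uV": 30.0,
                  "channels": None, "band": (20.0, 45.0)},
}


def inject_artifacts(recording: Recording, kinds: Sequence[str],
                     params: Optional[Mapping[str, Mapping[str, object]]] = None,
                     seed: int = 0) -> Tuple[Recording, List[ArtifactEvent]]:
    """Add DC offsets, spikes and/or EMG bursts; log every injection exactly.

    ``params`` overrides per-kind defaults (see ``_DEFAULT_ARTIFACT_PARAMS``).
    With no kinds requested the recording is returned unchanged.
    """
    rng = np.random.default_rng(seed)
    x = recording.samples.copy()
    fs = recording.fs
    log: List[ArtifactEvent] = []
    merged = {k: dict(_DEFAULT_ARTIFACT_PARAMS[k]) for k in _DEFAULT_ARTIFACT_PARAMS}
    for k, v in (params or {}).items():
        merged.setdefault(k, {}).update(v)

    for kind in kinds:
        if kind == "dc_offset":
            off = float(merged["dc_offset"]["offset_uV"])
            x += off
            log.append(ArtifactEvent("dc_offset", recording.channel_labels,
                                     0.0, recording.duration_s, off))
        elif kind == "spike":
            p = merged["spike"]
            peak = float(p["peak_uV"])
            if peak <= 0:
                raise ValueError("spike peak must be positive")
            width = int(p["width_samples"])
            for _ in range(int(p["n"])):
                ch = int(rng.integers(recording.n_channels))
                t = int(rng.integers(int(fs), recording.n_samples - int(fs) - width))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                x[ch, t:t + width] += sign * peak
                log.append(ArtifactEvent(
                    "spike", (recording.channel_labels[ch],), t / fs,
                    width / fs, peak))
        elif kind == "emg_burst":
            p = merged["emg_burst"]
            rms = float(p["rms_uV"])
            if rms <= 0:
                raise ValueError("EMG burst RMS must be positive")
            dur = float(p["duration_s"])
            n = int(round(dur * fs))
            lo, hi = p["band"]
            taps = design_fir_bandpass(float(lo), float(hi), fs)
            chans = p["channels"]
            for _ in range(int(p["n"])):
                if chans is None:
                    idx = sorted(rng.choice(recording.n_channels, size=2,
                                            replace=False).tolist())
                else:
                    idx = [recording.channel_labels.index(c) for c in chans]
                t = int(rng.integers(int(fs), recording.n_samples - n - int(fs)))
                # pad so the burst itself is band-limited even when short
                raw = rng.standard_normal(n + 2 * len(taps))
                burst = filter_array(raw, taps)[0][len(taps):len(taps) + n]
                burst = _normalise_rms(burst - burst.mean(), rms)
                for ch in idx:
                    x[ch, t:t + n] += burst
                log.append(ArtifactEvent(
                    "emg_burst",
                    tuple(recording.channel_labels[c] for c in idx),
                    t / fs, dur, float(np.max(np.abs(burst)))))
        else:
            raise ValueError(f"unknown artifact kind {kind!r}")

    return recording.copy_with(x), log


def synth_cohort(spec: CohortSpec) -> Cohort:
    """Simulate the whole cohort, counterbalancing the condition order.

    Even-indexed subjects run isometric first (group 1), odd-indexed run
    orthographic first (group 2); with 18 subjects that is 9 per order.
    All randomness derives from ``spec.seed``.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    sessions = []
    for i, ss in enumerate(seeds):
        order = "isometric_first" if i % 2 == 0 else "orthographic_first"
        subject_id = f"s{i + 1:02d}"
        child_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        sessions.append(synth_subject_session(spec, subject_id, child_seed,
                                              condition_order=order))
    return Cohort(spec=spec, sessions=sessions)
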