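# Methods

This note documents the models, parameter choices and numerical decisions
behind `eegtrp`, and what the synthetic cohorts do and do not establish
about real recordings.

## Signal model of the synthetic cohorts

Each simulated session mimics the structure of a two-task within-subject
experiment: lead-in (2 s), baseline 1 (20 s fixation), task 1 (segment 1 +
segment 2), baseline 2, task 2, tail.  Each task carries one projection
condition; even-indexed subjects run isometric first, odd-indexed
orthographic first, so an 18-subject cohort is counterbalanced 9/9.
Default segment durations are the study-scale medians reduced tenfold for
desk-scale runtime (segment 1: 3.2 s isometric / 7.15 s orthographic;
segment 2: 86.1 s / 90.4 s); every duration is a `CohortSpec` field and the
verification runs use 60 s epochs throughout.

Per band the generator synthesises **one spatially coherent oscillation
source** — band-pass-filtered white noise, exactly RMS-normalised within
each epoch — mixed across the 14 electrodes with per-electrode weights
drawn uniformly from [0.8, 1.2].  Exact per-epoch normalisation makes the
task/baseline power ratio equal the squared ground-truth gain by
construction, so expected TRP is exactly 2·log₁₀(g); the alternative
(free-running source power) only adds estimation noise ∝ 1/(bandwidth ×
duration) without changing the expectation.  Amplitudes follow the
sinusoid convention RMS = amplitude/√2, default 10 µV per band.

Background noise per channel is independent 1/f^χ (χ = 1, RMS 1.5 µV,
spectrum floored below 0.5 Hz) plus a white sensor-noise floor (RMS
1.5 µV).  The white floor reflects the high sensor noise of consumer
headsets and keeps the background's lag-1 autocorrelation (~0.4 after the
4–45 Hz band-pass) well below every oscillation source's, which is the
separation the BSS-CCA stage exploits in real EEG.  For the same reason
the beta source is synthesised with low-beta emphasis (13–20 Hz, inside
the 13–30 Hz analysis band): genuine beta rhythms concentrate below
~25 Hz, and a source spread uniformly over 13–30 Hz would be almost
indistinguishable from broadband noise at lag 1.

Injectable artifacts: a DC offset (default 4200 µV — a conventional figure
for the target device class, used as a default rather than ground truth),
single-sample spikes of specified peak, and 1 s broadband 20–45 Hz EMG
bursts on selected channels.  Every injection is logged exactly.

What the simulator does **not** model: volume-conduction head geometry,
ocular artifacts (the cleaning chain does not target blinks),
non-stationary drifts, electrode pops, or line noise.  Passing tests
therefore demonstrate correctness of the algorithms under a controlled
band-structured signal model, not robustness to every real-world artifact.

## Cleaning stages

**DC removal** — first-order Butterworth high-pass at 0.16 Hz (bilinear
transform), applied causally, as a device-style DC block.  A 4200 µV
offset decays below 1 µV within a minute (time constant ≈ 1 s).

**Broadband FIR** — Hamming-windowed sinc band-pass, 4–45 Hz.  Transition
bandwidth is 2 Hz at the low edge and 25 % of the cutoff (capped at
12.5 Hz) at the high edge; the filter order uses the Hamming rule
N ≈ 3.3/Δf_norm with the narrower transition, rounded to odd length
(4–45 Hz at 128 Hz: 213 taps; theta band: 243 taps).  Filters are applied
once and the (N−1)/2 group delay removed (zero-phase single-pass), with
reflection padding so outputs keep the input length.  Single-pass
application preserves the designed magnitude response; forward–backward
filtering would square it.

**BSS-CCA** — per 2.5 s window (1.2 s shift) the mean-centred channels are
decomposed by the symmetrised canonical-correlation problem against the
one-sample-lagged copy, C₁w = ρC₀w with C₁ = (C(1)+C(1)ᵀ)/2: each source's
lag-1 autocorrelation equals its eigenvalue, sources are uncorrelated with
unit variance, and the k = 4 lowest-autocorrelation sources (EMG-like) are
zeroed before reconstruction through the mixing pseudo-inverse.  C₀ gets a
relative ridge of 1e-12 (raised with a warning if the window is
rank-deficient).  Overlapping windows are blended with a linear crossfade
over the overlap region; a trailing chunk shorter than a window is
processed alone if ≥ 0.5 s, else passed through.  k = 0 reproduces the
input to ~1e-14.

## Rejection

The per-participant threshold is mean + 3·SD of the **absolute** sample
values over the whole epoch and all electrodes; raw signed values are
near zero-mean after filtering and would give a degenerate threshold.  A
1 s window (one-sample shift) is bad when its mean |x| across samples and
electrodes exceeds min(threshold, 100 µV) or any sample exceeds ±100 µV;
a sample is discarded when *any* covering window is bad (conservative
union — the literature this follows removes windows without stating a
sample-level rule).  A single supra-threshold sample therefore removes
exactly the 255-sample union of its 128 covering windows.

## Power and TRP

Power is the time-domain mean of squared band-passed samples over retained
samples only (masked samples are excluded, not zero-filled, which would
bias power downward).  A Welch-PSD band-integration utility cross-checks
the time-domain route (agreement within 10 % on band-limited signals).
TRP averages power over the epoch first and then takes logs
(average-then-log), base 10 by default and configurable; each task pairs
with the baseline recorded immediately before it.  The post-task baseline
is segmented but unused by default.

## Statistics

*Descriptives* — median and MAD; MAD is scaled by 1.4826 by default
(normal-consistency convention of common statistical software), raw MAD
available.

*ART ANOVA* — for each effect (main effects and two-way interactions) the
response is aligned by subtracting the full-factorial cell mean and adding
back the effect's marginal estimate, midranked over all observations, and
tested with a univariate repeated-measures ANOVA: observations are
aggregated to subject × effect-cell means and the effect is tested against
its subject-by-effect interaction stratum (no sphericity correction).
Marginal estimates use unweighted means of cell means, so alignment is
exact even when factorial cells hold unequal replicate counts (frontal
area has 8 electrodes, rear 6).  With a single factor and rank data this F
equals the classical repeated-measures F (verified against an independent
reference implementation).  Partial η² = F·df₁/(F·df₁+df₂).  Null
simulations at the study's geometry (2 × 14 within-subject, n = 18) put
the type-I rate at α = 0.05 within [0.03, 0.07].

*Wilcoxon signed-rank* — zero differences dropped, |d| midranked, V = sum
of positive-difference ranks.  Exact two-sided p (full enumeration
equivalent) for n ≤ 25 without ties, else the normal approximation with
tie and continuity corrections.  Effect size r = |Z|/√n with Z from the
corrected normal approximation; the literal V/√n variant is available
behind a flag but is scale-dependent and not recommended.

*Posthocs* — significant effects decompose into fixed comparison
families: projection within hemisphere/area/electrode, hemisphere within
projection, and the 7 homologous electrode pairs within each projection;
each family is Bonferroni-corrected by its own size.  Pairing is at the
finest shared observation level (subject × electrode where electrodes
match across the contrast, subject × homologous pair across hemispheres);
the frontal-vs-rear contrast pairs per-subject area means because the two
areas hold unequal electrode counts.

## Pipeline determinism and scale

All randomness in a run derives from the single `RunConfig.seed` (cohort
seeds are spawned from it); identical config + seed reproduces every table
bit-for-bit.  The default verification cohort (18 subjects, 60 s epochs)
runs in well under a minute on one CPU; the 500-replicate ANOVA
calibrations take a few seconds.  Stage isolation holds on clean data:
enabling BSS-CCA changes cortex-level band power per epoch by under 2 %
(individual electrode × band cells can wobble slightly more on short
epochs, driven by estimation variance rather than the stage itself).

## Known limitations

- The CCA source count to remove (k = 4) is fixed, not data-adaptive; on
  recordings with more than four simultaneous EMG sources residual
  artifact survives.
- The ART error structure is the univariate within-subject ANOVA;
  sphericity corrections are not applied.
- Exact Wilcoxon p-values switch to the corrected normal approximation in
  the presence of ties regardless of n.
- EDF I/O implements the plain 16-bit EDF layout (one data record, common
  sampling rate); EDF+ annotations and variable-rate signals are out of
  scope.  Round-trip precision is bounded by 16-bit scaling (≤ 0.1 µV for
  |x| ≤ 3276 µV).
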