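# eegtrp

Task-related EEG band-power analysis for two-condition within-subject
experiments on a 14-channel consumer headset (128 Hz, 10–20 placement:
AF3, F7, F3, FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8, AF4).

The motivating setting is design neurocognition: engineers interpret a
technical drawing of a part (isometric, i.e. single-view axonometric, vs
orthographic, i.e. multi-view) and then build a 3D CAD model from it, with
a 20 s fixation baseline before each task.  The question is whether the
projection type changes oscillatory brain activity during the two task
phases — interpreting the drawing (segment 1, up to the first sketch
element) and generating the model (segment 2).  The package implements the
full analysis chain for this class of study and a synthetic-EEG cohort
generator with known ground truth, so every stage is testable without any
recorded data.

## The quantity and the statistics

For electrode *i*, subject *j*, frequency band *b* ∈ {theta 4–7 Hz,
alpha 8–12 Hz, beta 13–30 Hz}, power is the mean of squared band-passed
samples (µV²) over retained samples, and **task-related power** is

&nbsp;&nbsp;&nbsp;&nbsp;TRP*ᵢⱼ* = log₁₀ Pow*ᵢ*(task)*ⱼ* − log₁₀ Pow*ᵢ*(baseline)*ⱼ*

with the baseline recorded immediately before that task.  Positive TRP =
task-related power increase.  Before power is computed the continuous
recording passes through

1. a 0.16 Hz first-order IIR high-pass (amplifier DC offset),
2. a 4–45 Hz Hamming-window FIR band-pass (zero-phase application),
3. BSS-CCA muscle-artifact removal (2.5 s windows, 1.2 s shift, the 4
   least-autocorrelated canonical sources removed per window),
4. event-driven segmentation into baseline / segment-1 / segment-2 epochs,
5. sliding 1 s window rejection: a window is bad when its mean |x| exceeds
   min(M + 3·SD of |x| over the epoch, 100 µV) or any sample exceeds
   ±100 µV; samples covered by any bad window are dropped.

Inference on the tidy TRP table is nonparametric: per segment and band, a
repeated-measures factorial ANOVA on Aligned-Rank-Transformed responses
(factors projection × electrode / hemisphere / cortical area; subject as
the random blocking unit; partial η² = F·df₁/(F·df₁+df₂)), followed by
pairwise Wilcoxon signed-rank posthocs (statistic V, effect size
r = |Z|/√n) with Bonferroni correction per comparison family, and
median/MAD descriptives throughout.

## Worked example

```python
from eegtrp import ArtAnova, CohortSpec, RunConfig, run_pipeline

spec = CohortSpec(                     # 18 subjects, counterbalanced order
    n_subjects=18,
    gains={("alpha", "orthographic", "seg1"): 1.25,
           ("alpha", "orthographic", "seg2"): 1.25})
bundle = run_pipeline(RunConfig(cohort=spec, seed=1))

print(bundle.trp_table.groupby(["band", "projection"])["trp"].mean().round(4))

alpha_seg2 = bundle.trp_table.query("band == 'alpha' and segment == 'seg2'")
print(ArtAnova(alpha_seg2, dv="trp",
               within=["projection", "hemisphere"]).fit().summary())
```

prints

```
band   projection
alpha  isometric      -0.0027
       orthographic    0.1958
beta   isometric      -0.0007
       orthographic    0.0010
theta  isometric      -0.0133
       orthographic    0.0003

Aligned-rank repeated-measures ANOVA
  response: trp   subjects: 18
  within factors: projection, hemisphere

effect                               F       df           p   eta_p^2
---------------------------------------------------------------------
projection                     275.550   1,17      6.14e-12    0.9419
hemisphere                       0.178   1,17         0.679    0.0103
projection:hemisphere            0.556   1,17         0.466    0.0317
```

The simulated alpha amplitude gain of 1.25 in the orthographic condition
corresponds to a true TRP of 2·log₁₀(1.25) ≈ 0.1938 (power scales with
amplitude squared); the pipeline recovers 0.1958 across the cohort while
the null cells stay near zero, and the ART ANOVA flags the projection main
effect and nothing else.

A CLI mirrors the stages (`eegtrp simulate | preprocess | segment |
reject | trp | stats | run-all`), reading YAML configs and writing
CSV/JSON report bundles; recordings travel as EDF or plain CSV.

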