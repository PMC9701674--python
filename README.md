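# iapsync

Quantifying **intrapersonal synchrony (IaPS)** — the temporal coordination of
communication signals produced by one person — for deictic gaze and pointing.
In a controlled interaction task, a participant announces the side of a target
to a partner with a gaze shift from the partner's face to the target, followed
by a pointing gesture. The delay between the two signal onsets,

```
delay = t(gesture onset) − t(communicative gaze-shift onset)   [ms]
```

and its within-subject variability (SD of delays per subject × block × target
side) index how tightly nonverbal signals are bound in time. The package is
aimed at researchers studying nonverbal timing — for example comparing
autistic and non-autistic adults, where temporal baselines of this kind have
been proposed as an objective behavioral marker.

The participant-level data such studies rest on are typically not shareable,
so the package includes a first-class synthetic cohort generator with full
ground truth; every stage of the analysis is validated against it.

## What it does

* **Synthetic cohorts** (`iapsync.synthetic`) — two groups (autistic / ASD and
  typically-developed / TD comparison), by default 24 subjects per group with
  4 blocks × 30 trials. Subject mean delay and within-subject SD come from a
  bivariate lognormal (delays are positive and right-skewed; subjects with
  larger means have larger SDs, coupling +0.6). The TD group's mean is 206 ms
  (between-subject SD 59 ms); the ASD group is shifted by +55 ms. Gaze is
  synthesized at 1000 Hz as fixation–saccade–fixation streams with
  raised-cosine saccade velocity pulses, and each trial carries a label for
  the exclusion rule it violates (if any), plus rendered finger-cap gesture
  videos with programmed kinematics.
* **Event parsing** (`iapsync.gazeparse`) — degree conversion, a 30°/s
  velocity-threshold saccade parser with blink handling, and region-of-interest
  (RoI) labeling: the partner's face ("social"), the two stimulus bars, and
  everything else ("random").
* **Communicative gaze-shift selection** (`iapsync.selection`) — shifts from
  the social RoI to the target via three pathways (direct; face-refixation,
  second saccade selected; random-refixation, first saccade selected), with
  six exclusion rules applied in precedence order (first trial of block; gaze
  off the face at stimulus onset; no communicative shift; blink within 100 ms
  before onset; saccade latency < 75 ms; gesture before gaze).
* **Delay metrics** (`iapsync.delays`) — per-trial delays, subject means,
  per-cell SDs, 3×IQR extreme-value fences per group, and free-task
  channel-use coding (gaze / verbal / gesture combination flags).
* **Trajectory extraction** (`iapsync.trajectory`) — fingertip tracking from
  video by color thresholding and shrink-to-point, movement segmentation, and
  gesture amplitude (mm) and mean velocity (mm/ms).
* **Inference** (`iapsync.stats`) — maximum-likelihood LMMs (statsmodels) and
  a Gauss–Hermite random-intercept logistic GLMM, compared through
  likelihood-ratio tests `χ² = 2(ℓ₁ − ℓ₀)`; group-comparison dispatch
  (Shapiro–Wilk → Mann–Whitney r; Bartlett → Welch t; else Student t with
  Cohen's d); Pearson correlations with Fisher-z CIs; Benjamini–Hochberg
  adjustment.
* **Pipeline + CLI** (`iapsync.pipeline`, `iapsync` command) — simulate →
  parse → select → measure → model, emitting a CSV report bundle.

## Worked example

```python
from iapsync import CohortConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="demo_out", seed=11,
                     cohort=CohortConfig(n_per_group=8))
results = run_pipeline(cfg)
print(results["models"][["measure", "chi2", "df", "p_lrt", "beta_group"]])
```

prints (seed 11):

```
random-slopes LMM for delay_ms failed to converge; refitting with random intercepts only
              measure      chi2  df     p_lrt  beta_group
0  gaze_gesture_delay  3.237612   1  0.071965   68.324678
1        sd_of_delays  1.095788   1  0.295192   20.238799
```

The first row compares nested delay LMMs with and without the group factor.
The logged line shows the documented convergence fallback: with only 8
subjects per group the random-slopes structure cannot be supported, so the
model refits with random intercepts (the refit is flagged in the output
table as well). The treatment-coded coefficient estimates the ASD group's
delays as 68 ms longer than the comparison group's — the generator's
programmed 55 ms shift recovered within this small cohort's sampling error —
with the group term marginal at this n (χ²(1) = 3.24, p = .072; at the full
24-per-group scale the test is well powered, see the acceptance studies
below). The second row runs the same comparison for the within-subject SD of
delays. The same numbers, along with selection tallies, descriptive tables
and channel frequencies, are written to `demo_out/`.

Equivalent CLI: `iapsync all --seed 11 --out demo_out`.

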