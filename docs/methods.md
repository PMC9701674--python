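# Methods

This note documents the models, conventions, and design choices behind
`iapsync`: what the synthetic cohorts emulate, how gaze and gesture signals
are parsed and selected, and how the group inference is set up. It is the
companion to the README's overview; nothing here reports an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The measurement model

A trial produces two signal onsets: a communicative gaze shift (a saccade
leaving the partner's face region and landing on the target stimulus) and a
pointing gesture (operationalized as space-bar release, giving millisecond
precision). Intrapersonal synchrony is indexed per trial by the delay
`gesture onset − gaze-shift onset` in integer ms, and per subject by
(a) the mean delay and (b) the SD of delays per subject × block × target
side. All times are integer milliseconds on the 1000 Hz tracker grid;
stimulus onset defines trial time zero semantics (streams themselves start
at trial onset, with stimulus onset at 1000 ms).

## Synthetic cohorts

The generator emulates the study design the analysis assumes: two groups of
`n_per_group` subjects (default 24), 4 blocks × 30 trials, target side
counterbalanced within block.

**Subject level.** Each subject draws a (mean delay, within-subject SD) pair
from a bivariate lognormal. Marginal targets: comparison (TD) group mean
206 ms with 59 ms between-subject SD; ASD group mean 206 + 55 ms; within-
subject SDs 81 ms (TD) and 95 ms (ASD) with 45 ms dispersion; correlation
+0.6 on the log scale. The lognormal was chosen because delays are positive
and right-skewed, and it realizes the observed pattern that subjects with
larger mean delays also have more variable delays. A single
`td_between_subject_sd` applies to both groups; the lognormal scaling gives
the shifted group a mildly larger raw SD, smaller than the ratio a real
cohort showed — an acknowledged simplification of the config surface.

**Trial level.** Delay = subject mean + Gaussian noise with the subject's
SD, redrawn to stay ≥ 1 ms (a negative delay would be a rule-6 violation,
which is generated deliberately instead; the truncation bias is ≪ 1 ms at
the default parameters). Saccade latency is uniform on [120, 300] ms — the
literature this package operationalizes reports no stimulus-locked latency
distribution, so this range is a documented placeholder covering typical
externally triggered latencies. Pathways are drawn as 80% direct, 10%
face-refixation, 10% random-refixation (placeholder frequencies; the real
pathway mix is not public).

**Gaze streams.** Piecewise events: a fixation inside the social RoI, the
pathway's saccades (raised-cosine velocity pulses; duration ≈ 21 ms +
2.2 ms/deg of amplitude, a main-sequence convention), intermediate and final
fixations, plus additive Gaussian position noise (default 0.5 px, far too
small to trip the 30°/s criterion but enough to de-idealize centroids).
Ground-truth shift onsets are defined *operationally*: the first sample at
which the noise-free programmed trace, run through the same differentiation
and smoothing pipeline as the parser, reaches 30°/s. This keeps truth
aligned with the parser's definition; on noise-free streams the parser
recovers boundaries exactly, and with default noise the onset can jitter by
±1 ms on a small fraction of trials (labels are unaffected; the delay-
exactness test therefore runs noise-free).

**Exclusion-rule emulation.** First trials of each block are always labeled
`first_trial`. Other trials violate one of the five remaining rules with
probability `exclusion_rate` each (default 3%, giving ≈ 18% total exclusions
with first trials — the order of magnitude real cohorts show). Each case is
constructed to violate exactly its rule and no higher-precedence rule:
off-face fixation at onset; no target-bound saccade; a blink ending 10–90 ms
before stimulus onset; latency drawn from [30, 70] ms; gesture 20–80 ms
before the shift.

**Determinism.** Every draw comes from a `numpy` generator keyed by
`(seed, stream-id, subject, block, trial)`, so outputs are identical across
runs and independent of iteration order, and the stream-free fast path
(`simulate_delay_table`) produces byte-identical trial truth to the full
stream pass.

**What the generator does not emulate.** Real saccade kinematics (glissades,
curvature), microsaccades, drift, calibration error, head motion, tracker
dropout other than scripted blinks, anticipatory strategies, or fatigue and
learning trends across blocks (block enters the models but the generator
places no block effect). Passing tests therefore validate the *pipeline* —
parsing, selection, aggregation, inference — under the stated statistical
structure, not robustness to every artifact of real recordings.

## Event parsing

Angular position per axis is `atan2(offset from screen center in mm,
viewing distance)`; the default geometry is a 1920 × 1200 px, 518.4 × 324 mm
panel at 940 mm. Velocity is a 5-point central difference smoothed with a
3 ms boxcar; samples at or above 30°/s for ≥ 4 ms form saccades. The 30°/s
threshold is the one published number for the reference parser; the
acceleration criterion and minimum durations of that proprietary parser are
not public, so the difference stencil, smoothing width and 4 ms gate are
this package's documented substitutes. Blinks are contiguous invalid-pupil
runs; velocity artifacts within 20 ms of a blink edge are absorbed into the
blink (standard practice). Remaining samples are fixations; events tile the
trial. RoI containment is inclusive on min edges, exclusive on max edges.

## Selection

Candidates are scanned over post-onset saccade chains anchored in a
social-RoI fixation (fixations labeled by centroid), capped at one
intermediate fixation: direct (candidate = the saccade), face-refixation
(candidate = second saccade), random-refixation (candidate = first saccade).
A fixation landing on the *non-target* stimulus bar is not a valid
intermediate — it ends in a defined RoI, not an undefined one. Where one
saccade could be read both as a refixation chain's second leg and as a
direct shift, the chain that starts earlier wins (candidates are
deduplicated by candidate saccade).

The six exclusion rules apply in their listed order, which the package
treats as precedence (exactly one code per trial, the lowest-numbered
violated rule): (1) first trial of block; (2) the *sample at the stimulus
onset timestamp* not inside the social RoI — the sample, not the enclosing
fixation, for robustness to parser boundary jitter; (3) no candidate;
(4) a blink ending within the 100 ms pre-onset window or spanning onset;
(5) first-pathway-saccade latency < 75 ms (the externally-triggered
criterion concerns the initial orienting movement, so for refixation chains
the *first* saccade's latency is tested); (6) gesture onset before the
candidate's onset. A missing gesture onset when rule 6 must be evaluated is
flagged with a distinct `indeterminate_gesture` code. Rules 5–6 are
evaluated on the earliest candidate. If a blink spans stimulus onset, the
onset sample is invalid and rule 2 fires before rule 4 ever would — a
deliberate consequence of the precedence order.

## Delay metrics and channel coding

Subject means average all included delays; SD cells use the n−1 sample SD
and drop single-observation cells. Extreme values use per-group
3 × IQR fences with linear-interpolation quartiles (no convention is forced
by the method; this is the numpy default and is documented as the package's
choice). Channel coding sets gaze = 1 exactly when the selection algorithm
selected a shift; the six combination flags are mutually exclusive
(gaze-and-gesture implies verbal = 0) so that together with the three
modality-count flags nothing is double-counted; first-block trials are
dropped to match their upstream exclusion.

## Trajectory analysis

Per frame: median filter (3 × 3), per-channel threshold conjunction for the
cap color (red = left index, blue = right index; dominant hand is a config
key), largest connected component ≥ 10 px, centroid ("shrink to point").
Trajectories are Gaussian-smoothed (bandwidth 1 frame), and movements are
maximal runs of frame-to-frame speed ≥ 2 px/frame lasting ≥ 3 frames, each
extended down its flanks to a floor of 1.4% of the run's peak speed. The
floor is the boundary-detection compromise for smooth (minimum-jerk-like)
strokes: the smoothing leak just *outside* a stroke is ≈ 1% of peak speed
while the first real displacement is ≥ 1.8%, so 1.4% lands between them for
strokes of roughly 18–28 frames; much longer, slower strokes would need a
wider bandwidth budget. Amplitude is the start-to-end displacement of the
stroke in mm — the ballistic-pointing reading of "amplitude", matching a mm
effect-size scale; path length is exposed separately. Mean velocity is path
length / duration (frame count at 30 fps).

## Inference

The group question is answered by likelihood-ratio tests between nested
maximum-likelihood mixed models: delays (long format, one row per trial)
with fixed block + side, random intercepts per subject and random slopes
for block and side, against the same model plus group; SD of delays
(aggregated, extreme values excluded) with random intercepts only — the
slopes structure is not supportable after aggregation; binary channel-use
variables in random-intercept logistic GLMMs. If a random-slopes LMM fails
to converge, the documented fallback refits both models of the comparison
with random intercepts only, visibly (a logged warning and a `fallback`
flag).

Gaussian LMMs delegate to statsmodels `MixedLM` with `reml=False` (the
contract here is the model structure, nesting logic, LRT arithmetic and
fallback — not a bespoke estimator); the test suite cross-checks
log-likelihoods and coefficients against R `lme4::lmer`. No installed
Python package fits binomial GLMMs by ML with a usable log-likelihood, so
the package implements a random-intercept logistic GLMM via Gauss–Hermite
quadrature (25 nodes) maximized with BFGS, cross-checked against
`lme4::glmer` (nAGQ = 25). Complete separation (a binary predictor level
with a constant outcome) is detected and flagged; the coefficient's Wald
inference is then unreliable and marked so, while the LRT remains the
recommended test.

Coefficient p-values and CIs are Wald normal approximations. The
Satterthwaite small-sample correction used by some R tooling is not
available in the Python stack and was not re-implemented: with thousands of
trials per model the correction is negligible, and all headline tests run
through the LRT, which it would not touch.

Two-sample comparisons dispatch on the data's own diagnostics at α = 0.05:
Shapiro–Wilk non-normality in either group → Mann–Whitney with
r = |Z|/√N (normal approximation with tie correction, no continuity
correction); otherwise Bartlett heterogeneity → Welch t with
Welch–Satterthwaite df; otherwise Student t. Cohen's d uses the pooled SD
(for equal n, √((s₁² + s₂²)/2)). The same statistics can be recomputed from
printed summary statistics (M, SD, n). Pearson CIs use the Fisher z
transform. Multiple-comparison adjustment defaults to Benjamini–Hochberg —
chosen because sets of identical adjusted p-values, as reported in this
literature, are the signature of a step-up FDR procedure; Bonferroni and
Holm are available.

## Problem sizes in the reproducibility studies

`scripts/acceptance.py` and the acceptance tests use: one 48-subject cohort
with full 1000 Hz streams (5,760 trials) for selector ground-truth
agreement; 50 paper-scale cohorts for group-coefficient recovery (fitted
with random-intercept models — the generator is the random-intercept model,
having no block/side variance; the full slopes structure is exercised on
single cohorts); 200 reduced cohorts (24 per group, 2 blocks × 10 trials)
for null LRT calibration; 20 rendered gestures across an amplitude ×
duration grid for kinematics recovery; and 30 identical-group rendering
replicates (6 subjects per group × 3 gestures) for the trajectory type-I
rate. These sizes keep the full run in the minutes range on one CPU while
leaving Monte-Carlo error well inside each check's tolerance.

## Known limitations

* The generator's saccade latency distribution, pathway mix and exclusion
  rates are plausible placeholders, not estimates.
* Group inference on synthetic data inherits the generator's idealizations
  (no block trends, no heavy-tailed trial noise).
* The movement-boundary floor is tuned for 0.6–1 s pointing strokes at
  30 fps; very slow movements blur into the smoothing leak.
* The binomial GLMM supports random intercepts only (matching the models it
  exists for); crossed or nested random effects are out of scope.
* `read_asc_events` covers a simplified monocular event export, not the full
  ASC grammar.
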