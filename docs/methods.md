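# Methods

This note documents the models, numerical choices and limitations of the
`gazefatigue` pipeline: what the synthetic generator emulates, how each
processing stage is defined, and what the validation suite does and does
not demonstrate about real recordings.

## The analysis problem

During dwell-time eye-typing, a user fixates keys on an on-screen keyboard
to select them while an eye tracker records gaze, pupil diameter and eye
position. The pipeline summarises each typing trial into 14 features in
three groups — typing performance (speed in words per minute, corrected
and uncorrected error rates, read-text-events ratio, attended-but-not-
selected rate), eye-based measures (tonic "baseline-related" pupil
diameter, blink frequency/duration/interval, blink-burst ratio, saccade
amplitude/duration/peak velocity) and posture (eye height relative to the
start of the day) — and regresses self-reported mental fatigue (1–7
Likert, in practice 6 usable levels) on them. Chance level is defined by a
Monte-Carlo predictor that draws labels from their observed distribution.

## Synthetic experiment generator

The generator exists so that every downstream stage can be validated
against a known ground truth; it is a first-class, tested module, not a
test fixture.

**Design.** 18 participants x 4 days x 2 sessions x 5 trials (720 trials)
by default; easy/difficult sentence sessions with order balanced over
participants and days; a 5 s inter-trial break precedes every trial;
90 Hz sampling (a Tobii 4C-class consumer device; configurable, minimum
30 Hz). Roughly 10/18 participants are tagged English, the rest Danish.
Sentence difficulty is a tag, not a readability computation.

**Latent fatigue and labels.** Within a day, latent fatigue after trial t
is `latent0 + Σ_k (slope_time + slope_effort · effort_k)` with
`latent0 = 0.5`, `slope_time = 0.10` per trial and `slope_effort = 0.07`
per unit of that trial's perceived effort. Perceived effort is drawn
around 3.0 (easy) / 4.7 (difficult) with SD 0.8 and rounded onto 1–7.
Fatigue is reported three times a day (day start, after session 1, after
session 2); the report is the latent state plus N(0, 0.35) report noise
pushed through fixed cutpoints (0.5, 1.5, 2.5, 3.5, 4.5, 5.8) onto 1–7.
Fixed cutpoints (not rank quantiles) keep the label distribution skewed,
with the top level rare — matching how such reports behave in practice.
The three reports attach to trials 1, 5 and 10 as the representative
trials of the day.

**Gaze kinematics.** The scene alternates fixations (mean 0.70 s, SD
0.20 s, floor 0.35 s — eye-typing dwell times are long) and saccades
(amplitude mean 5°, SD 1.5°, truncated to 2.5–10°) inside a ±14° x ±9°
screen box. Saccade velocity follows the main sequence
`V = η(1 − e^(−A/c))` with η = 480°/s, c = 6°. At 90 Hz a saccade spans
only 1–5 samples, so the velocity profile within a saccade is modelled as
constant (the pulse shape is unresolvable at this rate); the realised
per-saccade mean velocity is kept inside 140–395°/s so that saccade
samples and fixation samples remain separable by a 100°/s split even at
the run boundaries of the central-difference stencil. Gaze noise is
0.25° per eye per sample.

**Blinks and track loss.** Blinks are missing-data runs generated
directly on the sample grid — an integer number k of samples with
duration k/fs strictly inside (0.075, 0.500) s — at a base rate of
0.25 Hz. Track losses (0.6–1.2 s) occur at 0.01 Hz. Both are placed
inside sufficiently long fixations with a 14-sample guard on each side,
so the visible fixation fragments survive the 0.100 s duration filter;
the ground-truth ledger records the fragments (what is actually visible
on screen), the gap, and at most one gap per fixation.

**Fatigue couplings.** Latent fatigue drives three signals: blink rate
(+0.06 Hz per latent unit), eye height (−0.60 cm per latent unit) and
tonic pupil diameter (−0.08 units per latent unit from a 3.6/3.5 mm
left/right base). Pupil traces share a slow AR(1) wander (stationary SD
0.08, a = 0.995) plus independent per-eye noise (SD 0.02), which makes
the left/right correlation high (≈ 0.95) as the quality check expects.
These couplings have the signs reported for fatigue in the pupillometry
and oculomotor literature; their magnitudes are package choices.

**Typing process.** Characters are selected with a 0.6 s dwell and a
lognormal-ish inter-key gap; 5% of selections are wrong characters, 70%
of which are corrected with a backspace; attend-without-select events
(15% per key, ~0.3 s) and read-text events (20% per word, ~1 s) are
interspersed. Replaying select/backspace events reconstructs the final
string exactly — the replay is the ground-truth oracle for every
performance feature.

**Ground-truth conventions.** True feature values are computed by an
independent straightforward pass over the noiseless event ledger, not by
the pipeline. Two measurement-aware choices: ground-truth saccade peak
velocity is the maximum of the noiseless velocity profile evaluated
through the same central-difference stencil on the sample grid (the
feature measures sampled velocity, so the oracle predicts the measurable
quantity; the analytic main-sequence peak is also stored), and
ground-truth blink durations are exactly k/fs.

**Fast path.** `simulate_feature_dataset` draws the 14-feature table
directly from the same generative couplings without synthesising signals,
so full-size (720-trial) modelling experiments stay cheap. The three
fatigue-coupled features carry trial-level noise (blink frequency SD
0.08 Hz, eye height SD 0.15 cm, baseline pupil SD 0.03); the remaining
eleven features are realistic-scale noise with no fatigue content.

## Preprocessing

* **Invalid samples**: runs of ≥ 2 samples identical in every signal
  field are treated as tracker output stuck on its last measurement and
  blanked. The rule presumes sensor noise makes exact repeats impossible;
  on idealised noise-free synthetic streams every fixation sample repeats,
  so validation runs on such streams switch the rule off
  (`preprocess_trial(..., drop_repeats=False)`).
* **Blink classification**: every maximal missing run is exactly one of
  short gap (< 0.075 s), blink (0.075–0.500 s, closed interval — the
  boundary durations count as blinks) or track loss (> 0.500 s). Run
  duration is k samples / fs; a 1 ns tolerance absorbs float error at the
  boundaries.
* **Interpolation**: blink and short-gap spans are linearly interpolated
  per channel from the nearest valid anchors; spans touching a stream
  edge have no anchor on one side and stay missing (they behave as track
  loss downstream). Track losses are never interpolated.
* **Pupil cleaning**: pupil samples inside blink spans widened by 0.200 s
  on each side are removed and re-interpolated (overlapping margins are
  merged first), then a Hampel filter (window 5 centred, threshold 3
  scale units) replaces outliers with the window median. The scale
  estimate defaults to the standard Hampel 1.4826 x MAD; a `scale="sd"`
  switch gives the literal window standard deviation instead.
* **Binocular fusion**: each eye is weighted by the inverse of its pupil
  standard deviation over the trailing 25 samples including the current
  one (ε floor 10⁻⁶); the first samples fall back to whatever trailing
  window exists (minimum 2) and then to the plain two-eye mean; a sample
  with one eye missing uses the other.
* **Quality control**: Pearson r between left and right cleaned
  (pre-fusion) pupil over all of a session's trials; sessions with
  r < 0.75 are dropped. QC runs on cleaned series because the removal
  targets sessions whose *signal* disagrees between the eyes, not ones
  with many (already-handled) blinks.

## Event detection

Angular velocity is the central-difference speed of the two-eye mean gaze
(missing wherever a neighbour is missing, so velocity never bridges a
gap). A two-state Gaussian HMM on log(velocity + 10⁻³) is initialised
from a 100°/s threshold split (means/variances per side, sticky
transition matrix), refined by Baum–Welch (≤ 100 iterations, tolerance
10⁻⁴) over the contiguous valid segments, and decoded by Viterbi; the
state with the larger emission mean is the saccade state. Degenerate
situations — an empty side of the split, a zero-spread low state (noise-
free input collapses fixation velocities to a point mass), or a failed
fit — fall back to plain threshold labelling with a warning. Samples
inside blinks and track losses are forced to noise regardless of any
interpolated values beneath them.

Maximal same-label runs become events (span = first sample to one past
the last). Fixations shorter than 0.100 s and saccades smaller than 0.5°
are relabelled noise. Saccade amplitude is measured between the gaze
positions *bracketing* the run (the movement's start and landing
positions): with 1–5 samples per saccade, the run's own endpoint samples
are mid-flight and would understate the amplitude by (k−1)/k. Successive
fixations with no intervening saccade, a gap ≤ 0.075 s and centroids
< 0.5° apart merge into one fixation with a duration-weighted centroid;
merging re-checks after every merge until stable (a merged fixation can
merge again). Blink bursts are maximal chains of ≥ 2 blinks whose
consecutive onsets lie within 2 s (onset-to-onset chaining; a
first-to-last window variant is available via the `span` argument).

## Features

Performance features use the typing-log span (first to last event) as
trial time; eye features use the post-break gaze span. Uncorrected error
rate averages character- and word-level Levenshtein distances (computed
with `edlib`; words are mapped to code points for the word-level
alignment). The corrected error rate counts backspaces per
character-producing selection, including selections later deleted. ANSR
counts an attend event only when the attended key is not selected before
the attendance ends. Baseline pupil is the mean fused pupil over the
*latest* contiguous 0.300 s of non-interpolated break samples, searching
earlier windows when the break's tail is contaminated; a break with no
clean window yields a missing value and the trial is flagged.
"Non-interpolated" means free of blink/gap interpolation — Hampel-replaced
outliers are corrected measurements and still count as clean time (a
5-sample Hampel flags scattered samples often enough that excluding them
would spuriously void many breaks). Eye height
is the trial's mean vertical eye position minus the day reference (mean
over the opening 0.5 s of the day's first trial). Saccade amplitude is
aggregated as the per-saccade mean (a `agg="sum"` switch gives the summed
path reading). The blink-burst ratio is bursts divided by blink frequency,
as defined — its units (events per Hz) are unusual but intentional.

The exclusion cascade runs in a fixed order and logs every removal:
(1) trials of QC-failed sessions, (2) trials missing any feature,
(3) for the model table: keep trials 1/5/10, drop rows without a fatigue
label, drop fatigue levels with fewer than 5 pooled rows, drop
participants left with fewer than 6 rows. Counts reconcile:
kept + excluded = generated.

## Modelling

`FatigueRegressor` wraps a `Pipeline(Normalizer → estimator)` in a
scikit-learn `GridSearchCV` over 5x5 `RepeatedKFold`, scored by negative
MAE. Normalisation scales each sample vector to unit Euclidean length
(zero rows stay zero and are flagged). Default grids: random forest
{trees 100/300, depth ∞/5/10, min leaf 1/5}; PLS {1–8 components};
bagged SVR {C 0.1/1/10, ε 0.01/0.1, 10 estimators}; AdaBoost trees
{50/200 estimators, learning rate 0.1/1}. Explained variance is
`1 − Var(y − ŷ)/Var(y)` on out-of-fold predictions (reported as a
percentage; constant labels yield 0 with a warning). Fatigue labels are
treated as numeric targets on the pruned 6-level scale.

The Monte-Carlo baseline draws `n_sim = 10 000` replicate prediction
vectors i.i.d. from the label distribution and scores each against the
observed labels (a `score_against="simulated"` switch scores against an
independent draw instead); the mean and its standard error are reported.
For i.i.d. uniform{1..6} labels the expectation is E|X−Y| = 35/18 ≈ 1.944.
Note the baseline is deliberately a *random* predictor: a no-signal
regressor converging to the label median attains the (smaller) mean
absolute deviation, so beating the baseline is a weaker claim than
beating the best constant predictor — both floors are exercised in the
tests.

Recursive feature elimination drops one feature per step (by impurity
importance for tree models, permutation importance otherwise), scores
each subset by repeated-CV MAE, and returns the subset minimising it
together with the full curve. The holdout split is 80/20 stratified by
fatigue level. Leave-one-subject-out refits the (grid-searched) model on
all other participants per fold and reports per-subject MAEs with
min/mean/max.

## Statistics

Pearson correlations report Fisher-z 95% intervals
(tanh(atanh r ± 1.96/√(n−3))) and two-sided t-test p-values. The paired
fatigue-level contrasts use the Wilcoxon signed-rank test with
V = sum of positive-difference ranks; zero differences are dropped; the
exact two-sided p for n ≤ 25 comes from a subset-sum dynamic program over
tie-averaged ranks (exact even with tied magnitudes, which off-the-shelf
exact routines refuse), and n > 25 uses the normal approximation with
tie-corrected variance Σr²/4 and continuity correction.

Mixed models are fitted by statsmodels `MixedLM`: maximum-likelihood fits
drive the likelihood-ratio χ² tests between nested models (LRTs are only
valid under ML), while the reported coefficients and standard errors come
from a REML refit of the selected structure — the lmerTest convention, as
ML variance components are biased low with few groups and shrink the SEs.
Random intercepts per participant always, plus a random slope for
perceived effort when a likelihood-ratio test at 0.05 favours it and the
fit converges; failed optimisations retry with alternative optimisers and
finally fall back to the intercept-only structure, flagged. Semi-partial
R² per fixed effect is the drop in Nakagawa–Schielzeth marginal R²
(Var(Xβ) / (Var(Xβ) + Var(random) + Var(residual))) when the term is
removed. Bonferroni correction multiplies each p by the number of fixed
effects tested for that feature. Likert outcomes are treated numerically
(no ordinal link), matching the analysis tradition this pipeline follows.

## Validation scale and runtime choices

The test suite validates event recovery on ~1 200 noiseless events and
~10 default-noise trials, oracle equivalence on 1 000 random instances
per primitive, RFE recovery over 50 seeded 200-row datasets, and
mixed-model recovery over 50 seeded study-scale (18-participant) datasets;
the
acceptance script processes the raw-signal path on 18 trials and the
modelling path on the full 216-row model table. These sizes make a
single-CPU run complete in minutes while keeping every estimate's
sampling error far from the asserted margins.

## Limitations

* The generator's noise model is simple (i.i.d. gaze noise, AR(1) pupil
  wander); real recordings show calibration drift, saccadic suppression
  artefacts, partial-lid samples around blinks and nonstationary noise.
  Passing recovery tests therefore demonstrates correctness of the
  *rules*, not robustness to every real-world artefact.
* Saccade velocity profiles are flat within a saccade; at 90 Hz this is
  immaterial, but the simulator should not be used to study velocity
  waveform shape.
* The latent-fatigue model is linear and within-day; it does not model
  between-day carry-over, circadian effects, motivation or caffeine.
* The synthetic fatigue signal is stronger than in real participants, so
  absolute MAEs and explained variances on synthetic data are optimistic;
  only relative comparisons (model vs baseline, with vs without a
  feature) transfer.
* Smooth pursuit, microsaccades and glissades are out of scope, as are
  pixel-space coordinates (the pipeline works in degrees throughout; a
  screen-geometry config handles conversion at the I/O boundary only).
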