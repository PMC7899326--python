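# gazefatigue

Mental fatigue creeps up during sustained, cognitively demanding work, and
for people who communicate through camera-based eye-typing it directly
limits how long and how well they can interact. `gazefatigue` is a Python
pipeline for estimating self-reported mental fatigue on a Likert scale
from the signals an eye-typing session already produces: binocular gaze
and pupil streams from a consumer eye tracker, and the typing event log of
an on-screen keyboard.

The package covers the full analysis chain:

1. **Synthetic experiments with ground truth** (`gazefatigue.simulate`) —
   a generative model of a multi-day eye-typing study (18 participants x
   4 days x 2 sessions x 5 trials by default, easy/difficult sentence
   sessions, 5 s inter-trial breaks). Gaze is an alternating
   fixation/saccade scene whose saccade velocities follow the main-sequence
   law V = η(1 − e^(−A/c)); blinks appear as missing-data runs of
   0.075–0.500 s; a latent fatigue state raises blink rate, lowers the eyes
   and shrinks tonic pupil diameter, and is discretised into 1–7 Likert
   self-reports.
2. **Preprocessing** (`gazefatigue.preprocessing`) — invalid-sample
   removal, blink detection by missing-run duration (< 0.075 s short gap,
   0.075–0.500 s blink, > 0.500 s track loss), linear interpolation,
   pupil cleaning with ±0.200 s blink margins and a Hampel filter
   (window 5, 3 scale units), inverse-variance binocular pupil fusion, and
   session-level quality control (left/right pupil Pearson r ≥ 0.75).
3. **Event detection** (`gazefatigue.events`) — a two-state Gaussian HMM
   on log angular velocity labels fixations and saccades (Baum–Welch
   refinement, Viterbi decoding); fixations < 0.100 s and saccades < 0.5°
   become noise; nearby similar fixations merge; blink bursts are chains
   of ≥ 2 blinks within 2 s.
4. **Feature extraction** (`gazefatigue.features`) — the 14 per-trial
   features: typing speed (WPM), corrected/uncorrected error rate, read-text
   events ratio (RTE), attended-but-not-selected rate (ANSR),
   baseline-related pupil diameter, blink frequency/duration/interval,
   blink-burst ratio, saccade amplitude/duration/peak velocity, and eye
   height; plus the exclusion cascade that assembles the analysis tables.
5. **Modelling** (`gazefatigue.modeling`) — `FatigueRegressor`, a
   scikit-learn style estimator (random forest, PLS, bagged SVR or AdaBoost
   trees) grid-searched under 5x5 repeated CV scored by MAE after unit-norm
   row scaling, with a Monte-Carlo chance baseline, recursive feature
   elimination, stratified 80/20 holdout and leave-one-subject-out
   cross-validation.
6. **Statistics** (`gazefatigue.stats`) — Pearson correlations with
   Fisher-z CIs, exact (tie-safe) Wilcoxon signed-rank tests, and linear
   mixed models with likelihood-ratio χ², Nakagawa–Schielzeth semi-partial
   R² and Bonferroni correction.

## Worked example

```python
import numpy as np
from gazefatigue import build_experiment_design, simulate_feature_dataset, CVSpec
from gazefatigue.features import assemble_feature_table
from gazefatigue.core import FEATURE_COLUMNS
from gazefatigue.modeling import (
    crossval_grid_search, empirical_label_distribution, monte_carlo_baseline_mae,
)

design = build_experiment_design(18, 4, seed=1)        # 720 trial slots
table = simulate_feature_dataset(design, seed=1)
stats_table, model_table, _ = assemble_feature_table(table)
print(len(stats_table), len(model_table))               # 720 216

y = model_table["fatigue_level"].to_numpy()
X = model_table[FEATURE_COLUMNS].to_numpy()
baseline, se = monte_carlo_baseline_mae(
    empirical_label_distribution(y), y, n_sim=10_000, seed=1
)
reg = crossval_grid_search(X, y, model="rfr", cv=CVSpec(seed=1))
print(f"baseline MAE {baseline:.3f}  RFR CV MAE {reg.cv_mae_:.3f}  "
      f"explained variance {reg.explained_variance_:.1f}%")
```

Output:

```
720 216
baseline MAE 1.765  RFR CV MAE 0.432  explained variance 87.7%
```

The Monte-Carlo baseline (1.765) is the MAE of a predictor that draws
fatigue levels at random from their observed distribution; the
random-forest regressor reaches 0.432 by exploiting the three features the
generative model couples to latent fatigue (blink frequency, eye height,
baseline pupil), and explains ~88% of label variance on this clean
synthetic dataset (real recordings are far noisier — see
`docs/methods.md`).

A thin CLI wraps the same functions:

```bash
gazefatigue simulate --participants 2 --days 1 --seed 1 --out scratch/raw
gazefatigue preprocess --in scratch/raw --out scratch/clean
gazefatigue features --in scratch/raw --out scratch/feat
gazefatigue train --table model_table.csv --model rfr --rfe --seed 1
```

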