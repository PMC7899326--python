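"""Synthetic eye-typing experiments with ground truth.

Generates the three raw materials of the analysis — binocular gaze streams,
typing logs and Likert self-reports — from an explicit generative model, and
records a ground-truth ledger (events, blinks, true feature values, latent
fatigue) so that every downstream stage can be validated without real
recordings.

Generative model, in brief
--------------------------
* A latent fatigue state grows over a day's ten trials, driven by a
  per-trial increment plus the accumulated perceived effort
  (:class:`LabelModel`); fixed cutpoints discretise latent state (plus
  report noise) onto the 1-7 Likert scale.
* Gaze is an alternating fixation/saccade scene.  Saccade mean velocity
  follows the main-sequence law ``V = eta * (1 - exp(-A / c))``; at a 90 Hz
  class sampling rate a saccade spans only a handful of samples, so a
  constant-velocity profile is used (the pulse shape is unresolvable at
  this rate).
* Blinks are missing-data runs generated on the sample grid (duration =
  samples / fs) strictly inside 0.075-0.500 s, placed inside sufficiently
  long fixations; track losses (> 0.500 s) are generated the same way at a
  low rate.
* The latent fatigue state drives three eye features: blink rate rises,
  eye height sinks and tonic pupil diameter shrinks as fatigue grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .core import (
    BlinkEvent,
    GAZE_COLUMNS,
    FEATURE_COLUMNS,
    OculomotorEvent,
    TypingLog,
    empty_gaze_frame,
)
from .design import DIFFICULT, EASY, ExperimentDesign, TrialSlot

# ---------------------------------------------------------------------------
# parameter blocks

#: Fragment guard around an inserted gap, in samples: keeps the visible
#: fixation fragments on both sides long enough (>= 0.1 s after losing one
#: velocity sample at the gap edge) to survive event filtering.
_GAP_GUARD = 14


@dataclass(frozen=True)
class OculomotorParams:
    """Kinematic and signal parameters of the gaze generator.

    Durations in s, amplitudes in degrees, rates in Hz, pupil in device
    units (mm), eye position in cm.  ``*_fatigue_slope`` parameters couple
    the latent fatigue state (roughly 0-5 over a day) to the signals.
    """

    fixation_duration_mean: float = 0.70
    fixation_duration_sd: float = 0.20
    fixation_duration_min: float = 0.35
    saccade_amplitude_mean: float = 5.0
    saccade_amplitude_sd: float = 1.5
    saccade_amplitude_min: float = 2.5
    saccade_amplitude_max: float = 10.0
    main_sequence_eta: float = 480.0  # deg/s
    main_sequence_c: float = 6.0  # deg
    blink_rate: float = 0.25  # Hz at latent fatigue 0
    blink_rate_fatigue_slope: float = 0.06  # Hz per latent unit
    blink_duration_mean: float = 0.150
    blink_duration_sd: float = 0.040
    blink_duration_min: float = 0.090
    blink_duration_max: float = 0.250
    trackloss_rate: float = 0.01  # Hz
    trackloss_duration_range: tuple[float, float] = (0.6, 1.2)
    pupil_base: tuple[float, float] = (3.60, 3.50)  # left, right
    pupil_fatigue_slope: float = -0.08  # per latent unit
    pupil_wander_sd: float = 0.08  # shared slow drift, stationary sd
    pupil_noise_sd: float = 0.02  # per-eye independent
    gaze_noise_sd: float = 0.25  # deg, per eye
    eye_position_base: tuple[float, float, float] = (0.0, 35.0, 60.0)
    eye_height_fatigue_slope: float = -0.60  # cm per latent unit
    eye_position_noise_sd: float = 0.15
    screen_half_extent: tuple[float, float] = (14.0, 9.0)  # deg

    @classmethod
    def noiseless(cls, **overrides) -> "OculomotorParams":
        """All stochastic signal components switched off (kinematics kept)."""
        base = dict(
            gaze_noise_sd=0.0,
            pupil_noise_sd=0.0,
            pupil_wander_sd=0.0,
            eye_position_noise_sd=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class TypingSkill:
    """Rates of the typing-event process."""

    dwell: float = 0.60  # s, selection dwell time
    inter_key_gap_mean: float = 0.35
    inter_key_gap_sd: float = 0.12
    error_rate: float = 0.05  # probability a selection is a wrong character
    correction_rate: float = 0.7  # probability a wrong character is corrected
    attend_rate: float = 0.15  # probability of an attend-not-select per key
    attend_duration_mean: float = 0.30
    read_rate: float = 0.20  # probability of a read event after each word
    read_duration_mean: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "dwell",
            "inter_key_gap_mean",
            "error_rate",
            "correction_rate",
            "attend_rate",
            "attend_duration_mean",
            "read_rate",
            "read_duration_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class LabelModel:
    """Generative model of the Likert self-reports.

    Latent fatigue after trial t of a day is
    ``latent0 + sum_k (slope_time + slope_effort * effort_k)`` and the
    reported level is the latent state (plus report noise) pushed through
    fixed, strictly increasing cutpoints onto 1-7.  Fixed cutpoints (rather
    than rank quantiles) let the label distribution stay skewed, with the
    top level rare.
    """

    effort_by_difficulty: dict = field(
        default_factory=lambda: {EASY: 3.0, DIFFICULT: 4.7}
    )
    effort_sd: float = 0.8
    latent_start: float = 0.5
    fatigue_slope_time: float = 0.10  # latent increment per trial
    fatigue_slope_effort: float = 0.07  # weight of that trial's effort
    noise_sd: float = 0.35  # report noise on the latent scale
    likert_cutpoints: tuple[float, ...] = (0.5, 1.5, 2.5, 3.5, 4.5, 5.8)

    def __post_init__(self) -> None:
        cp = np.asarray(self.likert_cutpoints, dtype=float)
        if cp.ndim != 1 or len(cp) != 6 or np.any(np.diff(cp) <= 0):
            raise ValueError("likert_cutpoints must be 6 strictly increasing values")

    def to_likert(self, latent: float | np.ndarray) -> np.ndarray:
        """Map latent values to integer Likert levels 1-7."""
        return np.searchsorted(self.likert_cutpoints, np.atleast_1d(latent)) + 1


@dataclass
class GroundTruth:
    """Per-trial generative ledger: what was actually put into the stream."""

    events: list[OculomotorEvent]
    blinks: list[BlinkEvent]
    losses: list[tuple[float, float]]
    feature_row: dict
    latent: float
    labels: np.ndarray | None = None  # per-sample {0 fix, 1 sac, 2 noise}


# ---------------------------------------------------------------------------
# sentences (difficulty is a tag; these only feed the typing-event process)

EASY_SENTENCES = [
    "the sun is out today",
    "we had tea after lunch",
    "she likes to read books",
    "the dog ran in the park",
    "he will come home soon",
    "it rained all day long",
    "they play ball outside",
    "my friend lives near me",
    "we saw a bird in a tree",
    "the cake was very good",
]

DIFFICULT_SENTENCES = [
    "the committee postponed the negotiation despite considerable pressure",
    "quantitative reasoning underpins contemporary statistical methodology",
    "the architectural restoration required meticulous documentation",
    "unprecedented circumstances necessitated immediate reorganisation",
    "the parliamentary representative questioned the proposed legislation",
    "technological infrastructure facilitates international collaboration",
    "the experimental apparatus demonstrated remarkable reproducibility",
    "administrative responsibilities accumulated throughout the semester",
    "the philosophical implications remained fundamentally controversial",
    "environmental sustainability demands comprehensive transformation",
]


def pick_sentence(difficulty: str, rng: np.random.Generator) -> str:
    pool = EASY_SENTENCES if difficulty == EASY else DIFFICULT_SENTENCES
    return pool[int(rng.integers(len(pool)))]


# ---------------------------------------------------------------------------
# subjective labels


def generate_subjective_labels(
    design: ExperimentDesign, label_model: LabelModel, seed: int
) -> pd.DataFrame:
    """Per-trial effort (1-7) and per-day fatigue reports (1-7).

    Returns one row per trial with the latent fatigue state entering the
    trial and, on trials 1, first-session-end and day-end, the fatigue
    level reported at day start / after session 1 / after session 2.
    """
    rng = np.random.default_rng(seed)
    lm = label_model
    rows = []
    for pid in design.participants:
        for day in range(1, design.days_per_participant + 1):
            latent = lm.latent_start
            day_slots = [
                s
                for s in design.iter_trials()
                if s.participant == pid and s.day == day
            ]
            n_sess1 = design.trials_per_session
            reports = {}
            reports["initial"] = int(
                lm.to_likert(latent + rng.normal(0, lm.noise_sd))[0]
            )
            for slot in day_slots:
                effort_latent = lm.effort_by_difficulty[
                    slot.difficulty
                ] + rng.normal(0, lm.effort_sd)
                effort = int(np.clip(round(effort_latent), 1, 7))
                rows.append(
                    {
                        "participant": pid,
                        "day": day,
                        "session": slot.session,
                        "trial": slot.trial_of_day,
                        "difficulty": slot.difficulty,
                        "language": slot.language,
                        "latent": latent,
                        "perceived_effort": effort,
                    }
                )
                latent += lm.fatigue_slope_time + lm.fatigue_slope_effort * effort
                if slot.trial_of_day == n_sess1:
                    reports["intermediate"] = int(
                        lm.to_likert(latent + rng.normal(0, lm.noise_sd))[0]
                    )
                if slot.trial_of_day == design.trials_per_day:
                    reports["terminal"] = int(
                        lm.to_likert(latent + rng.normal(0, lm.noise_sd))[0]
                    )
            for r in rows[-design.trials_per_day :]:
                r["fatigue_initial"] = reports["initial"]
                r["fatigue_intermediate"] = reports["intermediate"]
                r["fatigue_terminal"] = reports["terminal"]
    df = pd.DataFrame(rows)
    # fatigue label attached to the representative trials 1 / 5 / 10
    fl = np.full(len(df), np.nan)
    fl[df["trial"] == 1] = df.loc[df["trial"] == 1, "fatigue_initial"]
    fl[df["trial"] == design.trials_per_session] = df.loc[
        df["trial"] == design.trials_per_session, "fatigue_intermediate"
    ]
    fl[df["trial"] == design.trials_per_day] = df.loc[
        df["trial"] == design.trials_per_day, "fatigue_terminal"
    ]
    df["fatigue_level"] = fl
    return df


# ---------------------------------------------------------------------------
# typing log


def simulate_typing_log(
    sentence: str,
    skill: TypingSkill = TypingSkill(),
    seed: int = 0,
    t_start: float = 0.0,
) -> TypingLog:
    """Simulate an eye-typing event log for one sentence.

    Events are strictly time-ordered; replaying select/backspace events
    reconstructs the final typed string; every backspace follows at least
    one surviving selection.
    """
    if not sentence:
        raise ValueError("sentence must be non-empty")
    rng = np.random.default_rng(seed)
    letters = "abcdefghijklmnopqrstuvwxyz"
    t = float(t_start)
    events: list[dict] = []
    typed = 0  # characters currently on screen

    def emit(kind: str, key: str, aoi: str, dur: float) -> None:
        nonlocal t
        events.append({"t_s": round(t, 4), "kind": kind, "key": key, "aoi": aoi, "dur_s": round(dur, 4)})
        t += dur + max(0.05, rng.normal(skill.inter_key_gap_mean, skill.inter_key_gap_sd))

    for i, ch in enumerate(sentence):
        if rng.random() < skill.attend_rate:
            wrong = letters[int(rng.integers(26))]
            emit("attend", wrong, "keyboard", max(0.05, rng.exponential(skill.attend_duration_mean)))
        make_error = rng.random() < skill.error_rate and ch != " "
        if make_error:
            bad = letters[int(rng.integers(26))]
            emit("select", bad, "keyboard", skill.dwell)
            typed += 1
            if rng.random() < skill.correction_rate and typed > 0:
                emit("backspace", "<-", "keyboard", skill.dwell)
                typed -= 1
                emit("select", ch, "keyboard", skill.dwell)
                typed += 1
            # uncorrected error: wrong character stays, intended one skipped
        else:
            emit("select", ch, "keyboard", skill.dwell)
            typed += 1
        if ch == " " and rng.random() < skill.read_rate:
            emit("read", "", "typed_text", max(0.2, rng.exponential(skill.read_duration_mean)))
    return TypingLog(target_sentence=sentence, events=pd.DataFrame(events))


def typing_feature_truth(log: TypingLog) -> dict:
    """Straightforward replay pass computing the true performance features.

    Independent oracle for the feature-extraction module: a single linear
    scan of the event list, no shared code with the pipeline.
    """
    import edlib

    typed: list[str] = []
    n_select = 0
    n_backspace = 0
    read_time = 0.0
    attend_rows = []
    for _, ev in log.events.iterrows():
        k = ev["kind"]
        if k == "select":
            typed.append(str(ev["key"]))
            n_select += 1
        elif k == "backspace":
            typed.pop()
            n_backspace += 1
        elif k == "read":
            read_time += float(ev["dur_s"])
        elif k == "attend":
            attend_rows.append(ev)
    final = "".join(typed)
    span = log.span
    # attend time on keys never selected during the attendance window
    attend_time = 0.0
    sel = log.events[log.events["kind"] == "select"]
    for ev in attend_rows:
        t0, t1 = float(ev["t_s"]), float(ev["t_s"]) + float(ev["dur_s"])
        hit = sel[(sel["key"] == ev["key"]) & (sel["t_s"] >= t0) & (sel["t_s"] <= t1)]
        if hit.empty:
            attend_time += float(ev["dur_s"])
    target = log.target_sentence
    char_err = edlib.align(final, target, task="distance")["editDistance"]
    vocab: dict[str, str] = {}

    def encode(words: list[str]) -> str:
        out = []
        for w in words:
            if w not in vocab:
                vocab[w] = chr(len(vocab) + 1)
            out.append(vocab[w])
        return "".join(out)

    word_err = edlib.align(
        encode(final.split(" ")), encode(target.split(" ")), task="distance"
    )["editDistance"]
    n_chars_final = len(final)
    n_words_final = max(len(final.split(" ")), 1)
    return {
        "final_string": final,
        "span": span,
        "typing_speed": (n_chars_final / 5.0) / (span / 60.0) if span > 0 else 0.0,
        "corrected_error_rate": 100.0 * n_backspace / n_select if n_select else np.nan,
        "uncorrected_error_rate": 50.0 * (char_err / max(n_chars_final, 1) + word_err / n_words_final),
        "rte": read_time / span if span > 0 else 0.0,
        "ansr": attend_time / n_select if n_select else np.nan,
        "n_selections": n_select,
        "n_backspaces": n_backspace,
    }


# ---------------------------------------------------------------------------
# gaze stream


def _trunc_normal(rng, mean, sd, lo, hi=None) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x >= lo and (hi is None or x <= hi):
            return float(x)
    return float(lo if hi is None else min(max(mean, lo), hi))


def _plan_scene(
    n: int, fs: float, params: OculomotorParams, rng: np.random.Generator
) -> list[dict]:
    """Plan alternating fixation/saccade events covering exactly n samples.

    Returns dicts with kind, i0 (first sample), k (samples) and, for
    saccades, the start/end points; for fixations, the centroid.  The plan
    begins and ends with a fixation.
    """
    hx, hy = params.screen_half_extent
    pos = np.array([rng.uniform(-hx, hx), rng.uniform(-hy, hy)])
    plan: list[dict] = []
    i = 0
    while True:
        kf = max(
            int(round(_trunc_normal(
                rng,
                params.fixation_duration_mean,
                params.fixation_duration_sd,
                params.fixation_duration_min,
            ) * fs)),
            int(params.fixation_duration_min * fs),
        )
        plan.append({"kind": "fixation", "i0": i, "k": kf, "centroid": pos.copy()})
        i += kf
        if i >= n - 2:
            break
        amp = _trunc_normal(
            rng,
            params.saccade_amplitude_mean,
            params.saccade_amplitude_sd,
            params.saccade_amplitude_min,
            params.saccade_amplitude_max,
        )
        target = None
        for _ in range(20):
            ang = rng.uniform(0, 2 * math.pi)
            cand = pos + amp * np.array([math.cos(ang), math.sin(ang)])
            if abs(cand[0]) <= hx and abs(cand[1]) <= hy:
                target = cand
                break
        if target is None:  # aim toward centre
            u = -pos / max(np.linalg.norm(pos), 1e-9)
            target = pos + amp * u
        v = params.main_sequence_eta * (1.0 - math.exp(-amp / params.main_sequence_c))
        # samples spanned by the saccade: as close to the main-sequence
        # duration A/V as the grid allows, while keeping the realised mean
        # velocity A/(ks*dt) inside (140, 395) deg/s so fixation and saccade
        # samples stay separable at a 90 Hz-class sampling rate
        k_min = max(int(math.ceil(amp / 395.0 * fs)), 1)
        k_max = max(int(math.floor(amp / 140.0 * fs)), k_min)
        ks = int(np.clip(round(amp / v * fs), k_min, k_max))
        plan.append({
            "kind": "saccade", "i0": i, "k": ks,
            "p0": pos.copy(), "p1": target.copy(), "amplitude": amp,
        })
        i += ks
        pos = target
        if i >= n - 2:
            break
    # close the timeline with a fixation of at least the minimum duration
    # reaching exactly sample n-1 (drop trailing events that leave no room)
    min_k = int(round(params.fixation_duration_min * fs))
    while plan and (
        plan[-1]["kind"] == "saccade" or n - plan[-1]["i0"] < min_k
    ):
        plan.pop()
    if not plan:
        plan = [{"kind": "fixation", "i0": 0, "k": n, "centroid": pos.copy()}]
    else:
        plan[-1]["k"] = n - plan[-1]["i0"]
    return [e for e in plan if e["k"] > 0]


def _place_gaps(
    plan: list[dict],
    n: int,
    fs: float,
    rng: np.random.Generator,
    rate: float,
    k_lo: int,
    k_hi: int,
    occupied: list[tuple[int, int]],
    duration_sampler=None,
) -> list[tuple[int, int]]:
    """Place missing-data runs inside long-enough fixations.

    Each run needs ``_GAP_GUARD`` clean fixation samples on both sides; at
    most one run per fixation.  Runs that find no host are dropped (the
    ledger records only inserted runs).
    """
    n_runs = rng.poisson(rate * n / fs)
    out: list[tuple[int, int]] = []
    for _ in range(n_runs):
        k = int(duration_sampler(rng)) if duration_sampler else int(rng.integers(k_lo, k_hi + 1))
        hosts = [
            e for e in plan
            if e["kind"] == "fixation"
            and e["k"] >= k + 2 * _GAP_GUARD
            and not any(
                e["i0"] < b + kb and b < e["i0"] + e["k"] for b, kb in occupied + out
            )
        ]
        if not hosts:
            continue
        host = hosts[int(rng.integers(len(hosts)))]
        off = int(rng.integers(_GAP_GUARD, host["k"] - k - _GAP_GUARD + 1))
        out.append((host["i0"] + off, k))
    return sorted(out)


def _ar1(rng, n: int, stationary_sd: float, a: float = 0.995) -> np.ndarray:
    """Smooth stationary AR(1) drift with given stationary sd."""
    from scipy.signal import lfilter

    if stationary_sd == 0:
        return np.zeros(n)
    innov_sd = stationary_sd * math.sqrt(1 - a * a)
    eps = rng.normal(0, innov_sd, n)
    x0 = rng.normal(0, stationary_sd)
    x, _ = lfilter([1.0], [1.0, -a], eps, zi=[a * x0])
    return x


def simulate_trial_gaze(
    design: ExperimentDesign,
    params: OculomotorParams,
    seed: int,
    latent: float = 0.0,
    trial_duration: float = 30.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one trial's gaze stream: 5 s break followed by the trial.

    Returns the raw stream (break + trial, time from stream start) and the
    ground-truth ledger.  Ground-truth events are what is visible on the
    sample grid: a fixation hosting a blink or track loss is recorded as
    its two visible fragments around the gap.
    """
    if design.sampling_rate < 30:
        raise ValueError("sampling rate must be >= 30 Hz")
    if design.inter_trial_break <= 0.300:
        raise ValueError("inter-trial break must exceed 0.300 s")
    rng = np.random.default_rng(seed)
    fs = design.sampling_rate
    dt = 1.0 / fs
    n_break = int(round(design.inter_trial_break * fs))
    n = n_break + int(round(trial_duration * fs))

    plan = _plan_scene(n, fs, params, rng)

    # --- gaps: blinks (grid lengths strictly inside 0.075-0.500 s) + losses
    blink_rate = max(params.blink_rate + params.blink_rate_fatigue_slope * latent, 0.0)
    k_min = int(math.floor(0.075 * fs)) + 1  # shortest run classified as blink
    k_b_lo = max(int(round(params.blink_duration_min * fs)), k_min)
    k_b_hi = int(round(params.blink_duration_max * fs))

    def blink_len(r):
        d = _trunc_normal(
            r, params.blink_duration_mean, params.blink_duration_sd,
            params.blink_duration_min, params.blink_duration_max,
        )
        return int(np.clip(round(d * fs), k_b_lo, k_b_hi))

    blinks_idx = _place_gaps(plan, n, fs, rng, blink_rate, k_b_lo, k_b_hi, [], blink_len)
    lo_s, hi_s = params.trackloss_duration_range
    loss_lo, loss_hi = int(math.ceil(lo_s * fs)), int(round(hi_s * fs))
    losses_idx = _place_gaps(
        plan, n, fs, rng, params.trackloss_rate, loss_lo, loss_hi, blinks_idx
    )

    # --- noiseless scene positions
    scene = np.empty((n, 2))
    labels = np.zeros(n, dtype=np.int8)  # 0 fixation, 1 saccade, 2 noise
    for e in plan:
        i0, k = e["i0"], e["k"]
        if e["kind"] == "fixation":
            scene[i0 : i0 + k] = e["centroid"]
        else:
            step = (e["p1"] - e["p0"]) / k
            m = np.arange(k)[:, None]
            scene[i0 : i0 + k] = e["p0"] + step * (m + 0.5)
            labels[i0 : i0 + k] = 1

    # --- signals
    t = np.arange(n) * dt
    df = empty_gaze_frame(n)
    df["t_s"] = t
    gnoise = params.gaze_noise_sd
    for pre, off in (("l", 0), ("r", 1)):
        df[f"{pre}x_deg"] = scene[:, 0] + rng.normal(0, gnoise, n) if gnoise else scene[:, 0]
        df[f"{pre}y_deg"] = scene[:, 1] + rng.normal(0, gnoise, n) if gnoise else scene[:, 1]
    wander = _ar1(rng, n, params.pupil_wander_sd)
    for i, pre in enumerate(("l", "r")):
        base = params.pupil_base[i] + params.pupil_fatigue_slope * latent
        noise = rng.normal(0, params.pupil_noise_sd, n) if params.pupil_noise_sd else 0.0
        df[f"pupil_{pre}"] = base + wander + noise
    ex, ey, ez = params.eye_position_base
    ey_trial = ey + params.eye_height_fatigue_slope * latent
    pnoise = params.eye_position_noise_sd
    df["eye_x_cm"] = ex + (rng.normal(0, pnoise, n) if pnoise else 0.0)
    df["eye_y_cm"] = ey_trial + (_ar1(rng, n, pnoise) if pnoise else 0.0)
    df["eye_z_cm"] = ez + (rng.normal(0, pnoise, n) if pnoise else 0.0)
    df["valid"] = 1

    # --- knock out gaps
    from .core import SIGNAL_COLUMNS

    for i0, k in blinks_idx + losses_idx:
        df.loc[i0 : i0 + k - 1, SIGNAL_COLUMNS] = np.nan
        df.loc[i0 : i0 + k - 1, "valid"] = 0
        labels[i0 : i0 + k] = 2

    # --- ground-truth ledger -------------------------------------------------
    # noiseless central-difference velocity (the measurable quantity)
    v = np.full(n, np.nan)
    d = np.linalg.norm(scene[2:] - scene[:-2], axis=1)
    v[1:-1] = d / (2 * dt)

    gaps = sorted(blinks_idx + losses_idx)
    events: list[OculomotorEvent] = []
    for e in plan:
        i0, k = e["i0"], e["k"]
        if e["kind"] == "saccade":
            events.append(
                OculomotorEvent(
                    kind="saccade",
                    start=i0 * dt,
                    end=(i0 + k) * dt,
                    amplitude=float(e["amplitude"]),
                    peak_velocity=float(np.nanmax(v[i0 : i0 + k])),
                )
            )
        else:
            # split around any hosted gap
            frags = [(i0, i0 + k)]
            for g0, gk in gaps:
                if i0 <= g0 and g0 + gk <= i0 + k:
                    frags = [(i0, g0), (g0 + gk, i0 + k)]
            for a, b in frags:
                if b > a:
                    events.append(
                        OculomotorEvent(
                            kind="fixation",
                            start=a * dt,
                            end=b * dt,
                            centroid=(float(e["centroid"][0]), float(e["centroid"][1])),
                        )
                    )
    events.sort(key=lambda ev: ev.start)
    blink_events = [BlinkEvent(start=i0 * dt, end=(i0 + k) * dt) for i0, k in blinks_idx]
    loss_spans = [(i0 * dt, (i0 + k) * dt) for i0, k in losses_idx]

    truth_features = _eye_feature_truth(
        events, blink_events, design, params, latent, n_break * dt, n * dt
    )
    truth = GroundTruth(
        events=events,
        blinks=blink_events,
        losses=loss_spans,
        feature_row=truth_features,
        latent=latent,
        labels=labels,
    )
    df.attrs["fs"] = fs
    df.attrs["break_end"] = n_break * dt
    return df, truth


def _eye_feature_truth(
    events: list[OculomotorEvent],
    blinks: list[BlinkEvent],
    design: ExperimentDesign,
    params: OculomotorParams,
    latent: float,
    break_end: float,
    stream_end: float,
) -> dict:
    """Straightforward pass over the noiseless event ledger -> eye features.

    Trial time is the post-break span; only blinks/saccades with onset in
    the trial portion count, mirroring the feature definitions.
    """
    trial_time = stream_end - break_end
    tb = [b for b in blinks if b.start >= break_end]
    sac = [e for e in events if e.kind == "saccade" and e.start >= break_end]
    onsets = np.array([b.start for b in tb])
    # blink bursts: onsets chaining within 2 s, groups of >= 2
    n_bursts = 0
    i = 0
    while i < len(onsets):
        j = i
        while j + 1 < len(onsets) and onsets[j + 1] - onsets[j] <= 2.0:
            j += 1
        if j > i:
            n_bursts += 1
        i = j + 1
    freq = len(tb) / trial_time
    row = {
        "baseline_pupil": float(np.mean(params.pupil_base))
        + params.pupil_fatigue_slope * latent,
        "blink_frequency": freq,
        "blink_duration": float(np.mean([b.duration for b in tb])) if tb else np.nan,
        "blink_interval": float(np.mean(np.diff(onsets))) if len(onsets) >= 2 else np.nan,
        "blink_burst_ratio": (n_bursts / freq) if freq > 0 else np.nan,
        "saccade_amplitude": float(np.mean([e.amplitude for e in sac])) if sac else np.nan,
        "saccade_duration": float(np.mean([e.duration for e in sac])) if sac else np.nan,
        "saccade_peak_velocity": float(np.mean([e.peak_velocity for e in sac])) if sac else np.nan,
        "eye_height_abs": params.eye_position_base[1]
        + params.eye_height_fatigue_slope * latent,
    }
    return row


# ---------------------------------------------------------------------------
# whole-trial and whole-experiment orchestration


@dataclass
class TrialData:
    slot: TrialSlot
    stream: pd.DataFrame
    log: TypingLog
    truth: GroundTruth


def simulate_trial(
    design: ExperimentDesign,
    slot: TrialSlot,
    label_row: pd.Series,
    seed: int,
    params: OculomotorParams = OculomotorParams(),
    skill: TypingSkill = TypingSkill(),
) -> TrialData:
    """Simulate one full trial: typing log plus matching gaze stream."""
    rng = np.random.default_rng(seed)
    sentence = pick_sentence(slot.difficulty, rng)
    log = simulate_typing_log(sentence, skill, int(rng.integers(2**31)))
    log.ids = {
        "participant": slot.participant,
        "day": slot.day,
        "session": slot.session,
        "trial": slot.trial_of_day,
    }
    latent = float(label_row["latent"])
    stream, truth = simulate_trial_gaze(
        design,
        params,
        int(rng.integers(2**31)),
        latent=latent,
        trial_duration=math.ceil(log.span) + 1.0,
    )
    perf = typing_feature_truth(log)
    truth.feature_row.update(
        {k: perf[k] for k in (
            "typing_speed", "corrected_error_rate", "uncorrected_error_rate",
            "rte", "ansr",
        )}
    )
    return TrialData(slot=slot, stream=stream, log=log, truth=truth)


def simulate_experiment(
    design: ExperimentDesign,
    seed: int,
    params: OculomotorParams = OculomotorParams(),
    skill: TypingSkill = TypingSkill(),
    label_model: LabelModel = LabelModel(),
    max_trials: int | None = None,
) -> Iterator[tuple[TrialData, pd.Series]]:
    """Yield (trial data, label row) for every trial slot of the design."""
    labels = generate_subjective_labels(design, label_model, seed)
    rng = np.random.default_rng(seed + 1)
    count = 0
    for slot in design.iter_trials():
        row = labels[
            (labels["participant"] == slot.participant)
            & (labels["day"] == slot.day)
            & (labels["trial"] == slot.trial_of_day)
        ].iloc[0]
        yield simulate_trial(design, slot, row, int(rng.integers(2**31)), params, skill), row
        count += 1
        if max_trials is not None and count >= max_trials:
            return


# ---------------------------------------------------------------------------
# fast path: feature-level dataset with the same generative couplings


@dataclass(frozen=True)
class FeatureNoise:
    """Trial-to-trial measurement noise of the feature-level generator."""

    blink_frequency: float = 0.08
    eye_height: float = 0.15
    baseline_pupil: float = 0.03


def simulate_feature_dataset(
    design: ExperimentDesign,
    seed: int,
    label_model: LabelModel = LabelModel(),
    params: OculomotorParams = OculomotorParams(),
    noise: FeatureNoise = FeatureNoise(),
) -> pd.DataFrame:
    """Per-trial feature table drawn directly from the generative law.

    Uses the same latent-fatigue couplings as the raw-signal generator
    (blink frequency rises, eye height sinks, tonic pupil shrinks with
    latent fatigue) but skips signal synthesis, so full-size experiments
    are cheap.  The remaining features are realistic-scale noise carrying
    no fatigue signal.
    """
    labels = generate_subjective_labels(design, label_model, seed)
    rng = np.random.default_rng(seed + 2)
    n = len(labels)
    lat = labels["latent"].to_numpy()
    day_ref_latent = labels.groupby(["participant", "day"])["latent"].transform("first").to_numpy()
    out = labels[
        ["participant", "day", "session", "trial", "difficulty", "language",
         "perceived_effort", "fatigue_level"]
    ].copy()
    out["blink_frequency"] = np.maximum(
        params.blink_rate + params.blink_rate_fatigue_slope * lat
        + rng.normal(0, noise.blink_frequency, n),
        0.0,
    )
    out["eye_height"] = (
        params.eye_height_fatigue_slope * (lat - day_ref_latent)
        + rng.normal(0, noise.eye_height, n)
    )
    out["baseline_pupil"] = (
        float(np.mean(params.pupil_base)) + params.pupil_fatigue_slope * lat
        + rng.normal(0, noise.baseline_pupil, n)
    )
    out["typing_speed"] = rng.normal(6.0, 1.0, n)
    out["corrected_error_rate"] = np.abs(rng.normal(8.0, 3.0, n))
    out["uncorrected_error_rate"] = np.abs(rng.normal(5.0, 2.0, n))
    out["rte"] = np.clip(rng.normal(0.10, 0.03, n), 0, None)
    out["ansr"] = np.clip(rng.normal(0.20, 0.05, n), 0, None)
    out["blink_duration"] = np.clip(rng.normal(0.15, 0.02, n), 0.075, 0.5)
    out["blink_interval"] = np.abs(rng.normal(4.0, 1.0, n))
    out["blink_burst_ratio"] = np.abs(rng.normal(10.0, 4.0, n))
    out["saccade_amplitude"] = np.clip(rng.normal(5.0, 0.8, n), 0.5, None)
    out["saccade_duration"] = np.clip(rng.normal(0.035, 0.005, n), 0.01, None)
    out["saccade_peak_velocity"] = np.abs(rng.normal(280.0, 30.0, n))
    out["latent"] = lat
    return out[
        ["participant", "day", "session", "trial", "difficulty", "language"]
        + FEATURE_COLUMNS
        + ["perceived_effort", "fatigue_level", "latent"]
    ]


#: Features the default feature-level generator couples to latent fatigue.
INFORMATIVE_FEATURES = ["blink_frequency", "eye_height", "baseline_pupil"]
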