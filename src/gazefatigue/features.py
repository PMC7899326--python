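"""Per-trial feature computation (the 14-feature set) and table assembly.

Performance features come from the typing log, eye-based features from the
cleaned gaze stream and its detected events.  Trial time is the
first-to-last typing-log event for performance features and the post-break
gaze span for eye features.  Assembly applies the exclusion cascade (noisy
sessions, missing data, representative-trial selection, sparse fatigue
levels, under-sampled participants) and logs every exclusion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import edlib

from .core import (
    BlinkBurst,
    BlinkEvent,
    FEATURE_COLUMNS,
    ID_COLUMNS,
    OculomotorEvent,
    QCResult,
    TypingLog,
    stream_fs,
)

BASELINE_WINDOW_S = 0.300


# ---------------------------------------------------------------------------
# performance features


def compute_typing_speed(log: TypingLog, trial_time: float) -> float:
    """Words per minute; one word = five characters including spaces."""
    if trial_time <= 0:
        raise ValueError("trial_time must be positive")
    n_chars = len(log.replay())
    return (n_chars / 5.0) / (trial_time / 60.0)


def _word_distance(a: str, b: str) -> int:
    """Word-level edit distance via a word-to-codepoint mapping."""
    vocab: dict[str, str] = {}

    def enc(s: str) -> str:
        out = []
        for w in s.split(" "):
            if w not in vocab:
                vocab[w] = chr(len(vocab) + 1)
            out.append(vocab[w])
        return "".join(out)

    ea, eb = enc(a), enc(b)
    return edlib.align(ea, eb, task="distance")["editDistance"]


def compute_error_rates(log: TypingLog) -> tuple[float, float]:
    """(corrected %, uncorrected %).

    Corrected: backspaces per character-producing selection.  Uncorrected:
    equally weighted character- and word-level edit distance between the
    final string and the target, as percentages of final-string length.
    """
    kinds = log.events["kind"]
    n_backspace = int((kinds == "backspace").sum())
    n_select = int((kinds == "select").sum())
    final = log.replay()
    target = log.target_sentence
    corrected = 100.0 * n_backspace / n_select if n_select else (0.0 if not n_backspace else np.nan)
    if not final and target:
        return corrected, 100.0
    char_err = edlib.align(final, target, task="distance")["editDistance"]
    word_err = _word_distance(final, target)
    n_chars = max(len(final), 1)
    n_words = max(len(final.split(" ")), 1)
    uncorrected = 50.0 * (char_err / n_chars + word_err / n_words)
    return corrected, uncorrected


def compute_rte(log: TypingLog, typing_time: float) -> float:
    """Fraction of the trial spent gazing at the already-typed text."""
    if typing_time <= 0:
        raise ValueError("typing_time must be positive")
    reads = log.events[log.events["kind"] == "read"]
    return float(reads["dur_s"].sum()) / typing_time


def compute_ansr(log: TypingLog) -> float:
    """Attended-but-not-selected time per selected key.

    An attend event contributes its duration only if the attended key is
    not selected before the attendance ends.  NaN when the trial has no
    selections (flagged upstream).
    """
    ev = log.events
    n_select = int((ev["kind"] == "select").sum())
    if n_select == 0:
        return np.nan
    sel = ev[ev["kind"] == "select"]
    total = 0.0
    for _, a in ev[ev["kind"] == "attend"].iterrows():
        t0 = float(a["t_s"])
        t1 = t0 + float(a["dur_s"])
        hit = sel[(sel["key"] == a["key"]) & (sel["t_s"] >= t0) & (sel["t_s"] <= t1)]
        if hit.empty:
            total += float(a["dur_s"])
    return total / n_select


# ---------------------------------------------------------------------------
# eye-based features


def compute_pupil_baseline(
    break_pupil: np.ndarray,
    interp_flags: np.ndarray,
    fs: float,
    window_s: float = BASELINE_WINDOW_S,
) -> float:
    """Tonic pupil over the latest clean window of the inter-trial break.

    Scans backwards for the latest contiguous ``window_s`` run of
    non-interpolated, non-missing fused pupil samples; NaN (trial flagged)
    when no clean window exists.
    """
    y = np.asarray(break_pupil, dtype=float)
    bad = np.asarray(interp_flags, dtype=bool) | ~np.isfinite(y)
    k = int(round(window_s * fs))
    if k < 1 or len(y) < k:
        return np.nan
    run = 0
    best_end = -1
    for i in range(len(y)):
        run = 0 if bad[i] else run + 1
        if run >= k:
            best_end = i
    if best_end < 0:
        return np.nan
    return float(np.mean(y[best_end - k + 1 : best_end + 1]))


def compute_blink_features(
    blinks: list[BlinkEvent],
    bursts: list[BlinkBurst],
    trial_time: float,
) -> tuple[float, float, float, float]:
    """(frequency Hz, mean duration s, mean onset interval s, burst ratio)."""
    if trial_time <= 0:
        raise ValueError("trial_time must be positive")
    n = len(blinks)
    freq = n / trial_time
    if n == 0:
        return 0.0, np.nan, np.nan, np.nan
    dur = float(np.mean([b.duration for b in blinks]))
    onsets = np.sort([b.start for b in blinks])
    interval = float(np.mean(np.diff(onsets))) if n >= 2 else np.nan
    burst_ratio = len(bursts) / freq
    return freq, dur, interval, burst_ratio


def compute_saccade_features(
    events: list[OculomotorEvent], agg: str = "mean"
) -> tuple[float, float, float]:
    """(amplitude deg, duration s, peak velocity deg/s), averaged per trial.

    ``agg`` switches the amplitude aggregation between the per-saccade mean
    (default, consistent with the sibling features) and the summed path.
    """
    sacs = [e for e in events if e.kind == "saccade"]
    if not sacs:
        return np.nan, np.nan, np.nan
    amps = np.array([e.amplitude for e in sacs], dtype=float)
    amp = float(amps.sum() if agg == "sum" else amps.mean())
    dur = float(np.mean([e.duration for e in sacs]))
    pv = float(np.mean([e.peak_velocity for e in sacs]))
    return amp, dur, pv


def compute_eye_height(stream: pd.DataFrame, day_start_reference: float) -> float:
    """Mean vertical eye position of the trial minus the day reference (cm)."""
    y = stream["eye_y_cm"].to_numpy(dtype=float)
    if not np.isfinite(y).any():
        return np.nan
    return float(np.nanmean(y)) - day_start_reference


def day_reference_eye_height(first_stream: pd.DataFrame, window_s: float = 0.5) -> float:
    """Day reference: mean eye height over the opening samples of the day's
    first trial stream."""
    fs = stream_fs(first_stream)
    k = max(int(round(window_s * fs)), 1)
    y = first_stream["eye_y_cm"].to_numpy(dtype=float)[:k]
    return float(np.nanmean(y))


# ---------------------------------------------------------------------------
# whole-trial orchestration


def extract_trial_features(
    pre,  # PreprocessedTrial
    events: list[OculomotorEvent],
    log: TypingLog,
    day_reference: float,
    break_end: float | None = None,
) -> dict:
    """All 14 features for one preprocessed trial."""
    from .events import detect_blink_bursts

    stream = pre.stream
    fs = stream_fs(stream)
    if break_end is None:
        break_end = float(stream.attrs.get("break_end", 0.0))
    t = stream["t_s"].to_numpy()
    trial_mask = t >= break_end
    trial_time_eye = float(t[-1] + 1.0 / fs - break_end)
    span = log.span

    trial_blinks = [b for b in pre.blinks if b.start >= break_end]
    bursts = detect_blink_bursts(trial_blinks)
    freq, bdur, bint, bratio = compute_blink_features(
        trial_blinks, bursts, trial_time_eye
    )
    trial_events = [e for e in events if e.start >= break_end]
    samp, sdur, spv = compute_saccade_features(trial_events)
    corrected, uncorrected = compute_error_rates(log)

    break_sel = ~trial_mask
    baseline = compute_pupil_baseline(
        pre.fused_pupil[break_sel], pre.pupil_interp[break_sel], fs
    )
    return {
        "typing_speed": compute_typing_speed(log, span),
        "corrected_error_rate": corrected,
        "uncorrected_error_rate": uncorrected,
        "rte": compute_rte(log, span),
        "ansr": compute_ansr(log),
        "baseline_pupil": baseline,
        "blink_frequency": freq,
        "blink_duration": bdur,
        "blink_interval": bint,
        "blink_burst_ratio": bratio,
        "saccade_amplitude": samp,
        "saccade_duration": sdur,
        "saccade_peak_velocity": spv,
        "eye_height": compute_eye_height(stream[trial_mask], day_reference),
    }


# ---------------------------------------------------------------------------
# table assembly


def assemble_feature_table(
    trials: pd.DataFrame,
    qc_results: list[QCResult] | None = None,
    representative_trials: tuple[int, ...] = (1, 5, 10),
    min_level_count: int = 5,
    min_participant_trials: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Apply the exclusion cascade; return (stats_table, model_table, log).

    ``trials`` carries one row per trial with id columns, the 14 features,
    ``perceived_effort`` and (for representative trials) ``fatigue_level``.
    Cascade order: (1) drop trials of QC-failed sessions, (2) drop trials
    with any missing feature, (3) model table = representative trials with
    a fatigue label, minus sparse fatigue levels (< ``min_level_count``
    rows pooled) and under-sampled participants.
    """
    log: list[dict] = []
    df = trials.copy()

    failed = {
        q.session_id for q in (qc_results or []) if not q.passed
    }
    if failed:
        key = list(zip(df["participant"], df["day"], df["session"]))
        drop = np.array([k in failed for k in key])
        for _, row in df[drop].iterrows():
            log.append({
                "participant": row["participant"], "day": int(row["day"]),
                "trial": int(row["trial"]), "reason": "qc_failed_session",
            })
        df = df[~drop]

    missing = df[FEATURE_COLUMNS].isna().any(axis=1)
    for _, row in df[missing].iterrows():
        log.append({
            "participant": row["participant"], "day": int(row["day"]),
            "trial": int(row["trial"]), "reason": "missing_feature",
        })
    stats_table = df[~missing].reset_index(drop=True)

    model = stats_table[stats_table["trial"].isin(representative_trials)].copy()
    no_label = model["fatigue_level"].isna()
    for _, row in model[no_label].iterrows():
        log.append({
            "participant": row["participant"], "day": int(row["day"]),
            "trial": int(row["trial"]), "reason": "missing_fatigue_label",
        })
    model = model[~no_label]

    counts = model["fatigue_level"].value_counts()
    sparse = set(counts[counts < min_level_count].index)
    if sparse:
        drop = model["fatigue_level"].isin(sparse)
        for _, row in model[drop].iterrows():
            log.append({
                "participant": row["participant"], "day": int(row["day"]),
                "trial": int(row["trial"]),
                "reason": f"sparse_fatigue_level_{int(row['fatigue_level'])}",
            })
        model = model[~drop]

    pcounts = model["participant"].value_counts()
    thin = set(pcounts[pcounts < min_participant_trials].index)
    if thin:
        drop = model["participant"].isin(thin)
        for _, row in model[drop].iterrows():
            log.append({
                "participant": row["participant"], "day": int(row["day"]),
                "trial": int(row["trial"]), "reason": "participant_too_few_trials",
            })
        model = model[~drop]

    if stats_table.empty:
        raise ValueError("exclusion cascade removed every trial")
    return stats_table, model.reset_index(drop=True), log
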