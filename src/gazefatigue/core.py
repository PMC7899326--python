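"""Shared domain types for eye-typing gaze analysis.

Gaze streams are plain :class:`pandas.DataFrame` objects with the column
layout in :data:`GAZE_COLUMNS`; missing samples carry NaN in every signal
field and ``valid == 0``.  Time is seconds from stream start, gaze is in
degrees of visual angle, pupil in device units (mm for a Tobii-class
tracker), eye position in cm.  The sampling rate travels in
``df.attrs["fs"]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column order of the on-disk gaze CSV dialect.
GAZE_COLUMNS = [
    "t_s",
    "lx_deg",
    "ly_deg",
    "rx_deg",
    "ry_deg",
    "pupil_l",
    "pupil_r",
    "eye_x_cm",
    "eye_y_cm",
    "eye_z_cm",
    "valid",
]

#: Signal fields that are blanked when a sample is missing.
SIGNAL_COLUMNS = GAZE_COLUMNS[1:-1]

#: The 14 per-trial features, in presentation order.
FEATURE_COLUMNS = [
    "typing_speed",
    "corrected_error_rate",
    "uncorrected_error_rate",
    "rte",
    "ansr",
    "baseline_pupil",
    "blink_frequency",
    "blink_duration",
    "blink_interval",
    "blink_burst_ratio",
    "saccade_amplitude",
    "saccade_duration",
    "saccade_peak_velocity",
    "eye_height",
]

ID_COLUMNS = ["participant", "day", "session", "trial", "difficulty", "language"]


@dataclass(frozen=True)
class BlinkEvent:
    """A spontaneous blink: a missing-data run of 0.075-0.500 s."""

    start: float
    end: float
    interpolated: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class OculomotorEvent:
    """A labelled oculomotor interval (fixation, saccade or noise)."""

    kind: str  # "fixation" | "saccade" | "noise"
    start: float
    end: float
    centroid: tuple[float, float] | None = None  # fixations, degrees
    amplitude: float | None = None  # saccades, degrees
    peak_velocity: float | None = None  # saccades, deg/s

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class BlinkBurst:
    """Two or more blinks whose onsets chain within 2 s."""

    start: float
    end: float
    n_blinks: int


@dataclass(frozen=True)
class QCResult:
    """Session-level binocular quality check (left/right pupil Pearson r)."""

    session_id: tuple
    pearson_r: float
    passed: bool
    n_pairs: int = 0
    reason: str = ""


@dataclass
class TypingLog:
    """Ordered eye-typing events for one trial plus the target sentence.

    ``events`` columns: ``t_s`` (event onset), ``kind`` in
    {select, backspace, attend, read}, ``key`` (character or AOI key id),
    ``aoi`` (area of interest tag), ``dur_s`` (event duration; dwell time
    for selections, gaze-on time for attend/read events).
    """

    target_sentence: str
    events: pd.DataFrame
    ids: dict = field(default_factory=dict)

    def replay(self) -> str:
        """Reconstruct the final typed string from select/backspace events."""
        out: list[str] = []
        for _, ev in self.events.iterrows():
            if ev["kind"] == "select":
                out.append(str(ev["key"]))
            elif ev["kind"] == "backspace":
                if not out:
                    raise ValueError("backspace with no prior selection")
                out.pop()
        return "".join(out)

    @property
    def span(self) -> float:
        """Trial time: first-to-last event (end of last event included)."""
        if self.events.empty:
            return 0.0
        t0 = float(self.events["t_s"].iloc[0])
        last = self.events.iloc[-1]
        return float(last["t_s"] + last["dur_s"]) - t0


def empty_gaze_frame(n: int) -> pd.DataFrame:
    """Allocate a gaze frame of *n* all-missing samples."""
    df = pd.DataFrame(
        {c: np.full(n, np.nan) for c in GAZE_COLUMNS}
    )
    df["valid"] = 0
    return df


def missing_mask(stream: pd.DataFrame) -> np.ndarray:
    """Boolean mask of missing samples (invalid or all signal fields NaN)."""
    sig_nan = stream[SIGNAL_COLUMNS].isna().all(axis=1).to_numpy()
    invalid = (stream["valid"].fillna(0) == 0).to_numpy()
    return sig_nan | invalid


def stream_fs(stream: pd.DataFrame) -> float:
    """Sampling rate: from ``attrs`` if present, else median dt."""
    fs = stream.attrs.get("fs")
    if fs:
        return float(fs)
    dt = np.median(np.diff(stream["t_s"].to_numpy()))
    return 1.0 / float(dt)
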