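"""On-disk dialects: gaze CSV, typing-log JSON lines, event/interval tables.

Gaze CSV columns: ``t_s,lx_deg,ly_deg,rx_deg,ry_deg,pupil_l,pupil_r,
eye_x_cm,eye_y_cm,eye_z_cm,valid`` — missing samples leave the signal
fields empty with ``valid=0``.  Typing logs are JSON lines: a header
object carrying the target sentence and trial ids, then one event per
line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GAZE_COLUMNS, OculomotorEvent, TypingLog


def write_gaze_csv(stream: pd.DataFrame, path: str | Path) -> None:
    out = stream[GAZE_COLUMNS].copy()
    out["valid"] = out["valid"].fillna(0).astype(int)
    out.to_csv(path, index=False, na_rep="", float_format="%.6g")


def read_gaze_csv(path: str | Path, fs: float | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze CSV missing columns: {missing}")
    df = df[GAZE_COLUMNS]
    df["valid"] = df["valid"].fillna(0).astype(int)
    if fs:
        df.attrs["fs"] = fs
    else:
        dt = np.median(np.diff(df["t_s"].to_numpy()))
        df.attrs["fs"] = 1.0 / float(dt)
    return df


def write_typing_log(log: TypingLog, path: str | Path) -> None:
    with open(path, "w") as fh:
        header = {"target_sentence": log.target_sentence, **log.ids}
        fh.write(json.dumps(header) + "\n")
        for _, ev in log.events.iterrows():
            fh.write(
                json.dumps(
                    {
                        "t_s": float(ev["t_s"]),
                        "kind": ev["kind"],
                        "key": ev["key"],
                        "aoi": ev["aoi"],
                        "dur_s": float(ev["dur_s"]),
                    }
                )
                + "\n"
            )


def read_typing_log(path: str | Path) -> TypingLog:
    with open(path) as fh:
        lines = [json.loads(l) for l in fh if l.strip()]
    if not lines:
        raise ValueError("empty typing log")
    header, events = lines[0], lines[1:]
    sentence = header.pop("target_sentence")
    return TypingLog(
        target_sentence=sentence, events=pd.DataFrame(events), ids=header
    )


def write_events_tsv(
    events: list[OculomotorEvent], trial_id: str, path: str | Path, append: bool = False
) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "trial_id": trial_id,
                "kind": e.kind,
                "start_s": e.start,
                "end_s": e.end,
                "duration_s": e.duration,
                "centroid_x": e.centroid[0] if e.centroid else "",
                "centroid_y": e.centroid[1] if e.centroid else "",
                "amplitude_deg": e.amplitude if e.amplitude is not None else "",
                "peak_velocity_dps": e.peak_velocity if e.peak_velocity is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(
        path, sep="\t", index=False, mode="a" if append else "w",
        header=not append,
    )


def write_blink_intervals(
    blinks, losses, trial_id: str, path: str | Path, append: bool = False
) -> None:
    """BED-like interval table: trial_id, start_s, end_s, kind."""
    rows = [
        {"trial_id": trial_id, "start_s": b.start, "end_s": b.end, "kind": "blink"}
        for b in blinks
    ] + [
        {"trial_id": trial_id, "start_s": s, "end_s": e, "kind": "loss"}
        for s, e in losses
    ]
    pd.DataFrame(rows).to_csv(
        path, sep="\t", index=False, mode="a" if append else "w",
        header=not append,
    )
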