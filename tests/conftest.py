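"""Shared fixtures: small experiment designs and synthetic gaze frames."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gazefatigue.core import GAZE_COLUMNS, SIGNAL_COLUMNS
from gazefatigue.design import build_experiment_design


@pytest.fixture
def small_design():
    return build_experiment_design(2, 1, seed=7)


@pytest.fixture
def full_design():
    return build_experiment_design(18, 4, seed=7)


def make_stream(
    n: int,
    fs: float = 90.0,
    missing: list[tuple[int, int]] | None = None,
    pupil=3.5,
    gaze=0.0,
) -> pd.DataFrame:
    """Minimal valid gaze frame with optional missing runs (start, length)."""
    t = np.arange(n) / fs
    df = pd.DataFrame({c: np.zeros(n) for c in GAZE_COLUMNS})
    df["t_s"] = t
    # slight per-sample jitter keeps rows unique (real sensors never repeat)
    rng = np.random.default_rng(12345)
    for c in ("lx_deg", "ly_deg", "rx_deg", "ry_deg"):
        df[c] = gaze + rng.normal(0, 1e-6, n)
    for c in ("pupil_l", "pupil_r"):
        df[c] = pupil + rng.normal(0, 1e-6, n)
    df["eye_x_cm"] = 0.0
    df["eye_y_cm"] = 35.0 + rng.normal(0, 1e-6, n)
    df["eye_z_cm"] = 60.0
    df["valid"] = 1
    for start, length in missing or []:
        df.loc[start : start + length - 1, SIGNAL_COLUMNS] = np.nan
        df.loc[start : start + length - 1, "valid"] = 0
    df.attrs["fs"] = fs
    return df


@pytest.fixture
def stream_factory():
    return make_stream
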