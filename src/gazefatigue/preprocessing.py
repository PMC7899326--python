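"""Raw gaze-stream cleaning.

Order of operations for one trial stream:

1. :func:`mark_invalid_samples` — device samples that repeat every data
   field exactly are treated as tracker failures and blanked.
2. :func:`detect_blinks` — every maximal missing run is classified by
   duration: < 0.075 s short gap, 0.075-0.500 s blink (closed interval),
   > 0.500 s track loss.
3. :func:`interpolate_gaps` — blink and short-gap spans are linearly
   interpolated per channel; track losses stay missing.
4. :func:`clean_pupil` — pupil samples within blink span +/- 0.200 s are
   re-interpolated, then Hampel-filtered (window 5, 3 scale units).
5. :func:`fuse_binocular_pupil` — inverse-trailing-sd weighted average of
   the two eyes (25-sample window including the current sample).
6. :func:`session_quality_check` — Pearson r of left vs right pupil over
   the session; sessions below 0.75 are dropped from analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BlinkEvent,
    QCResult,
    SIGNAL_COLUMNS,
    missing_mask,
    stream_fs,
)

BLINK_MIN_S = 0.075
BLINK_MAX_S = 0.500
PUPIL_MARGIN_S = 0.200
QC_THRESHOLD = 0.75
WEIGHT_EPS = 1e-6  # floor for inverse-sd fusion weights, pupil units


# ---------------------------------------------------------------------------


def mark_invalid_samples(stream: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Blank samples whose data fields all repeat the neighbouring sample.

    A tracker that loses the eyes may keep emitting the last measurement;
    any run of >= 2 samples identical in every signal field is therefore
    treated as invalid.  Returns the cleaned copy and the removal count.
    """
    if stream.empty:
        raise ValueError("empty stream")
    out = stream.copy()
    sig = out[SIGNAL_COLUMNS].to_numpy()
    same_as_prev = np.zeros(len(out), dtype=bool)
    if len(out) > 1:
        with np.errstate(invalid="ignore"):
            same_as_prev[1:] = np.all(sig[1:] == sig[:-1], axis=1)
    in_run = same_as_prev.copy()
    in_run[:-1] |= same_as_prev[1:]  # first sample of each run too
    # only non-missing samples count as removals
    already = missing_mask(out)
    kill = in_run & ~already
    out.loc[kill, SIGNAL_COLUMNS] = np.nan
    out.loc[kill, "valid"] = 0
    out.attrs = dict(stream.attrs)
    return out, int(kill.sum())


def detect_blinks(
    stream: pd.DataFrame,
) -> tuple[list[BlinkEvent], list[tuple[float, float]], list[tuple[float, float]]]:
    """Classify every maximal missing run by duration.

    Returns ``(blinks, short_gaps, losses)`` where a run of *k* samples at
    rate fs has duration k/fs; durations of exactly 0.075 or 0.500 s count
    as blinks (closed interval).  Span times are [first sample, one past
    last sample).
    """
    t = stream["t_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    fs = stream_fs(stream)
    dt = 1.0 / fs
    miss = missing_mask(stream)
    blinks: list[BlinkEvent] = []
    short: list[tuple[float, float]] = []
    losses: list[tuple[float, float]] = []
    i = 0
    n = len(miss)
    while i < n:
        if not miss[i]:
            i += 1
            continue
        j = i
        while j < n and miss[j]:
            j += 1
        dur = (j - i) * dt
        span = (t[i], t[j - 1] + dt)
        # boundary durations (exactly 0.075 / 0.500 s) count as blinks;
        # the 1e-9 guard absorbs float error in k * (1/fs)
        if dur < BLINK_MIN_S - 1e-9:
            short.append(span)
        elif dur <= BLINK_MAX_S + 1e-9:
            blinks.append(BlinkEvent(start=span[0], end=span[1]))
        else:
            losses.append(span)
        i = j
    return blinks, short, losses


def _interp_span(
    t: np.ndarray, y: np.ndarray, mask: np.ndarray, i0: int, i1: int
) -> bool:
    """Linearly interpolate y over samples [i0, i1) from the nearest valid
    anchors outside the span.  Returns False for edge spans (no anchor)."""
    lo = i0 - 1
    while lo >= 0 and not np.isfinite(y[lo]):
        lo -= 1
    hi = i1
    while hi < len(y) and not np.isfinite(y[hi]):
        hi += 1
    if lo < 0 or hi >= len(y):
        return False
    y[i0:i1] = np.interp(t[i0:i1], [t[lo], t[hi]], [y[lo], y[hi]])
    mask[i0:i1] = True
    return True


def interpolate_gaps(
    stream: pd.DataFrame,
    blinks: list[BlinkEvent],
    short_gaps: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Fill blink and short-gap spans by per-channel linear interpolation.

    Adds a boolean ``interp`` column marking filled samples; spans touching
    the stream edges are left unfilled (no anchor on one side).  Track-loss
    spans are untouched.
    """
    out = stream.copy()
    t = out["t_s"].to_numpy()
    tmax = t[-1] + 1.0 / stream_fs(stream)
    interp = out.get("interp")
    mask = (
        interp.to_numpy().astype(bool)
        if interp is not None
        else np.zeros(len(out), dtype=bool)
    )
    spans = [(b.start, b.end) for b in blinks] + list(short_gaps or [])
    cols = {c: out[c].to_numpy(dtype=float) for c in SIGNAL_COLUMNS}
    filled_any = np.zeros(len(out), dtype=bool)
    for s0, s1 in spans:
        if s0 < t[0] - 1e-9 or s1 > tmax + 1e-9:
            raise ValueError("gap event outside stream bounds")
        i0 = int(np.searchsorted(t, s0 - 1e-9))
        i1 = int(np.searchsorted(t, s1 - 1e-9))
        ok = True
        for c in SIGNAL_COLUMNS:
            ok = _interp_span(t, cols[c], mask, i0, i1) and ok
        if ok:
            filled_any[i0:i1] = True
    for c in SIGNAL_COLUMNS:
        out[c] = cols[c]
    out.loc[filled_any, "valid"] = 1
    out["interp"] = mask
    out.attrs = dict(stream.attrs)
    return out


# ---------------------------------------------------------------------------


def hampel_filter(
    series: np.ndarray | pd.Series,
    window: int = 5,
    n_sigmas: float = 3.0,
    scale: str = "mad",
) -> tuple[np.ndarray, np.ndarray]:
    """Centred rolling-median outlier rejection.

    A sample deviating from the median of the ``window`` samples centred on
    it by more than ``n_sigmas`` scale units is replaced by that median.
    ``scale="mad"`` uses the standard Hampel estimate 1.4826 x MAD;
    ``scale="sd"`` uses the window standard deviation.  NaNs are ignored
    within windows and never treated as outliers.

    Returns ``(filtered, outlier_indices)``.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    x = np.asarray(series, dtype=float)
    if len(x) < window:
        warnings.warn("series shorter than window; returned unchanged")
        return x.copy(), np.array([], dtype=int)
    if scale not in ("mad", "sd"):
        raise ValueError("scale must be 'mad' or 'sd'")
    half = window // 2
    n = len(x)
    med = np.full(n, np.nan)
    sig = np.full(n, np.nan)
    sw = np.lib.stride_tricks.sliding_window_view(x, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        enough = np.isfinite(sw).sum(axis=1) >= half + 1
        m = np.nanmedian(np.where(enough[:, None], sw, np.nan), axis=1)
        med[half : n - half] = m
        if scale == "mad":
            sig[half : n - half] = 1.4826 * np.nanmedian(
                np.abs(sw - m[:, None]), axis=1
            )
        else:
            sig[half : n - half] = np.nanstd(
                np.where(enough[:, None], sw, np.nan), axis=1
            )
        # truncated windows at the edges (still centred on the sample)
        for i in list(range(half)) + list(range(n - half, n)):
            w = x[max(0, i - half) : i + half + 1]
            if np.isfinite(w).sum() < half + 1:
                continue
            med[i] = np.nanmedian(w)
            if scale == "mad":
                sig[i] = 1.4826 * np.nanmedian(np.abs(w - med[i]))
            else:
                sig[i] = np.nanstd(w)
    with np.errstate(invalid="ignore"):
        bad = np.abs(x - med) > n_sigmas * sig
    bad &= np.isfinite(x)
    out = x.copy()
    out[bad] = med[bad]
    return out, np.flatnonzero(bad)


def _merge_intervals(spans: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not spans:
        return []
    spans = sorted(spans)
    out = [list(spans[0])]
    for s0, s1 in spans[1:]:
        if s0 <= out[-1][1]:
            out[-1][1] = max(out[-1][1], s1)
        else:
            out.append([s0, s1])
    return [tuple(s) for s in out]


def clean_pupil(
    stream: pd.DataFrame,
    blinks: list[BlinkEvent],
    margin: float = PUPIL_MARGIN_S,
    hampel_window: int = 5,
    hampel_nsig: float = 3.0,
    hampel_scale: str = "mad",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-eye pupil cleaning: blink margins re-interpolated, then Hampel.

    Pupil samples within any blink span widened by ``margin`` on each side
    are removed and linearly interpolated (overlapping margins are merged
    first, so nothing is double-counted).  Returns the stream with cleaned
    ``pupil_l``/``pupil_r`` and a boolean mask of interpolated pupil
    samples (used by the baseline-pupil window search).  Hampel-replaced
    outliers are corrected measurements, not interpolated time, so they do
    not enter the mask.
    """
    out = stream.copy()
    t = out["t_s"].to_numpy()
    spans = _merge_intervals([(b.start - margin, b.end + margin) for b in blinks])
    interp_mask = np.zeros(len(out), dtype=bool)
    if "interp" in out.columns:
        interp_mask |= out["interp"].to_numpy().astype(bool)
    for col in ("pupil_l", "pupil_r"):
        y = out[col].to_numpy(dtype=float)
        for s0, s1 in spans:
            i0 = int(np.searchsorted(t, s0 - 1e-9))
            i1 = int(np.searchsorted(t, s1 - 1e-9))
            if i1 > i0:
                y[i0:i1] = np.nan
                _interp_span(t, y, interp_mask, i0, i1)
        y, _ = hampel_filter(y, hampel_window, hampel_nsig, hampel_scale)
        out[col] = y
    out.attrs = dict(stream.attrs)
    return out, interp_mask


def fuse_binocular_pupil(
    left: np.ndarray | pd.Series,
    right: np.ndarray | pd.Series,
    window: int = 25,
) -> np.ndarray:
    """Combine the eyes by inverse-trailing-sd weighting.

    At each sample the weight of eye *e* is ``1 / max(sd_e, eps)`` with the
    sd taken over the trailing ``window`` samples up to and including the
    current one.  Early samples use whatever trailing samples exist (at
    least 2); before that, the plain mean of the two eyes.  A sample where
    one eye is missing falls back to the other; both missing gives NaN.
    """
    l = np.asarray(left, dtype=float)
    r = np.asarray(right, dtype=float)
    if l.shape != r.shape:
        raise ValueError("left and right series must be aligned")
    sl = pd.Series(l).rolling(window, min_periods=2).std().to_numpy()
    sr = pd.Series(r).rolling(window, min_periods=2).std().to_numpy()
    wl = 1.0 / np.maximum(sl, WEIGHT_EPS)
    wr = 1.0 / np.maximum(sr, WEIGHT_EPS)
    with np.errstate(invalid="ignore", divide="ignore"):
        fused = (wl * l + wr * r) / (wl + wr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        simple = np.nanmean(np.vstack([l, r]), axis=0)
    # fall back to the simple mean where weights are unavailable, and to the
    # single available eye where the other is missing
    fused = np.where(np.isfinite(fused), fused, simple)
    return fused


def session_quality_check(
    session_streams: list[pd.DataFrame],
    session_id: tuple = (),
    threshold: float = QC_THRESHOLD,
    min_pairs: int = 3,
) -> QCResult:
    """Pearson r of left vs right pupil over a whole session's trials."""
    ls, rs = [], []
    for s in session_streams:
        ls.append(s["pupil_l"].to_numpy(dtype=float))
        rs.append(s["pupil_r"].to_numpy(dtype=float))
    l = np.concatenate(ls) if ls else np.array([])
    r = np.concatenate(rs) if rs else np.array([])
    ok = np.isfinite(l) & np.isfinite(r)
    if ok.sum() < min_pairs:
        return QCResult(session_id, np.nan, False, int(ok.sum()), "insufficient pairs")
    if np.std(l[ok]) == 0 or np.std(r[ok]) == 0:
        return QCResult(session_id, np.nan, False, int(ok.sum()), "zero variance")
    rho = float(np.corrcoef(l[ok], r[ok])[0, 1])
    return QCResult(session_id, rho, bool(rho >= threshold), int(ok.sum()))


# ---------------------------------------------------------------------------


@dataclass
class PreprocessedTrial:
    """Everything downstream stages need from one cleaned trial stream."""

    stream: pd.DataFrame
    blinks: list[BlinkEvent]
    short_gaps: list[tuple[float, float]]
    losses: list[tuple[float, float]]
    pupil_interp: np.ndarray
    fused_pupil: np.ndarray
    n_invalid: int


def preprocess_trial(stream: pd.DataFrame, drop_repeats: bool = True) -> PreprocessedTrial:
    """Run the full single-trial cleaning chain in the canonical order.

    ``drop_repeats`` controls the repeated-sample invalidation rule.  The
    rule presumes sensor noise makes exact repeats impossible in real
    recordings; on idealised noise-free synthetic streams every fixation
    sample repeats exactly, so validation runs on such streams switch it
    off.
    """
    if drop_repeats:
        marked, n_invalid = mark_invalid_samples(stream)
    else:
        marked, n_invalid = stream.copy(), 0
        marked.attrs = dict(stream.attrs)
    blinks, short, losses = detect_blinks(marked)
    filled = interpolate_gaps(marked, blinks, short)
    cleaned, pupil_interp = clean_pupil(filled, blinks)
    fused = fuse_binocular_pupil(cleaned["pupil_l"], cleaned["pupil_r"])
    return PreprocessedTrial(
        stream=cleaned,
        blinks=blinks,
        short_gaps=short,
        losses=losses,
        pupil_interp=pupil_interp,
        fused_pupil=fused,
        n_invalid=n_invalid,
    )
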