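"""Oculomotor event detection: velocity, HMM labelling, segmentation.

Samples are labelled fixation/saccade by a two-state Gaussian HMM on
log angular velocity (the log stabilises the heavy right tail of the
velocity distribution).  Parameters are initialised from a 100 deg/s
threshold split, refined by Baum-Welch and decoded by Viterbi; the state
with the larger emission mean is the saccade state.  Samples inside
blinks and track losses are labelled noise.  Segmented events are then
filtered (fixations < 0.100 s and saccades < 0.5 deg become noise) and
nearby similar fixations are merged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .core import BlinkBurst, BlinkEvent, OculomotorEvent, stream_fs

FIX, SAC, NOISE = 0, 1, 2

MIN_FIXATION_S = 0.100
MIN_SACCADE_DEG = 0.5
MERGE_GAP_S = 0.075
MERGE_DIST_DEG = 0.5
BURST_SPAN_S = 2.0
INIT_THRESHOLD_DPS = 100.0
_LOG_EPS = 1e-3  # deg/s floor before taking logs


def binocular_gaze(stream: pd.DataFrame) -> np.ndarray:
    """(n, 2) gaze in degrees: mean of the available eyes per sample."""
    lx = stream["lx_deg"].to_numpy(dtype=float)
    ly = stream["ly_deg"].to_numpy(dtype=float)
    rx = stream["rx_deg"].to_numpy(dtype=float)
    ry = stream["ry_deg"].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        x = np.nanmean(np.vstack([lx, rx]), axis=0)
        y = np.nanmean(np.vstack([ly, ry]), axis=0)
    return np.column_stack([x, y])


def angular_velocity(stream: pd.DataFrame) -> np.ndarray:
    """Central-difference angular speed in deg/s.

    NaN wherever either neighbouring gaze sample is missing (velocity never
    bridges a track-loss span) and at the stream edges.
    """
    if len(stream) < 3:
        return np.array([])
    g = binocular_gaze(stream)
    dt = 1.0 / stream_fs(stream)
    v = np.full(len(g), np.nan)
    d = np.linalg.norm(g[2:] - g[:-2], axis=1)
    v[1:-1] = d / (2 * dt)
    return v


def _threshold_labels(v: np.ndarray, threshold: float) -> np.ndarray:
    lab = np.full(len(v), NOISE, dtype=np.int8)
    ok = np.isfinite(v)
    lab[ok & (v < threshold)] = FIX
    lab[ok & (v >= threshold)] = SAC
    return lab


def hmm_label(
    velocity: np.ndarray,
    noise_spans: list[tuple[float, float]] | None = None,
    t: np.ndarray | None = None,
    threshold: float = INIT_THRESHOLD_DPS,
    n_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
) -> np.ndarray:
    """Per-sample state in {FIX, SAC, NOISE} from the velocity series.

    ``noise_spans`` (with the matching time vector ``t``) force NOISE over
    blink/track-loss intervals regardless of any interpolated values
    beneath them.  Degenerate fits (a state left empty by the threshold
    initialisation, or a failed Baum-Welch) fall back to plain threshold
    labelling with a warning.
    """
    v = np.asarray(velocity, dtype=float)
    if np.isfinite(v).sum() < 50:
        raise ValueError("need >= 50 non-missing velocity samples")
    labels = _threshold_labels(v, threshold)

    ok = np.isfinite(v)
    x = np.log(np.maximum(v[ok], 0.0) + _LOG_EPS)
    lo = x[v[ok] < threshold]
    hi = x[v[ok] >= threshold]
    # a state whose emission spread collapses (noise-free fixations give a
    # point mass at log(eps)) makes Baum-Welch/Viterbi degenerate: the
    # density spike swallows everything else, so fall back to thresholding
    lo_mad = float(np.median(np.abs(lo - np.median(lo)))) if len(lo) else 0.0
    use_hmm = len(lo) >= 2 and len(hi) >= 2 and lo_mad > 1e-6
    if use_hmm:
        model = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            n_iter=n_iter,
            tol=tol,
            init_params="",
            params="stmc",
            min_covar=1e-3,
            random_state=seed,
        )
        model.startprob_ = np.array([0.95, 0.05])
        model.transmat_ = np.array([[0.98, 0.02], [0.30, 0.70]])
        model.means_ = np.array([[lo.mean()], [hi.mean()]])
        model.covars_ = np.maximum(
            np.array([[lo.var()], [hi.var()]]), 1e-3
        )
        # contiguous valid segments as separate sequences
        idx = np.flatnonzero(ok)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        seg_bounds = np.split(idx, breaks + 1)
        X = x.reshape(-1, 1)
        lengths = [len(s) for s in seg_bounds]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X, lengths)
                states = model.predict(X, lengths)
            sac_state = int(np.argmax(model.means_.ravel()))
            if model.means_[0, 0] == model.means_[1, 0]:
                raise ValueError("identical emission means")
            lab = np.where(states == sac_state, SAC, FIX).astype(np.int8)
            labels = np.full(len(v), NOISE, dtype=np.int8)
            labels[ok] = lab
        except Exception:
            warnings.warn("degenerate HMM fit; falling back to threshold labelling")
            labels = _threshold_labels(v, threshold)

    if noise_spans:
        if t is None:
            raise ValueError("noise_spans requires the time vector t")
        for s0, s1 in noise_spans:
            labels[(t >= s0 - 1e-9) & (t < s1 - 1e-9)] = NOISE
    return labels


def segment_and_filter_events(
    labels: np.ndarray,
    stream: pd.DataFrame,
    velocity: np.ndarray | None = None,
    min_fixation: float = MIN_FIXATION_S,
    min_saccade_amp: float = MIN_SACCADE_DEG,
) -> list[OculomotorEvent]:
    """Maximal same-label runs -> events; sub-threshold events -> noise.

    Fixation centroid is the mean binocular gaze over the run; saccade
    amplitude is the straight-line angular distance between the run's
    endpoint samples; peak velocity the run maximum.  Events span
    [first sample, one past last sample).
    """
    if len(labels) != len(stream):
        raise ValueError("labels must align with the stream")
    t = stream["t_s"].to_numpy()
    dt = 1.0 / stream_fs(stream)
    g = binocular_gaze(stream)
    if velocity is None:
        velocity = angular_velocity(stream)
    events: list[OculomotorEvent] = []
    i, n = 0, len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        kind_code = labels[i]
        start, end = t[i], t[j - 1] + dt
        if kind_code == FIX:
            c = np.nanmean(g[i:j], axis=0)
            ev = OculomotorEvent(
                "fixation", start, end, centroid=(float(c[0]), float(c[1]))
            )
            if ev.duration < min_fixation:
                ev = OculomotorEvent("noise", start, end)
        elif kind_code == SAC:
            # movement endpoints: the gaze positions bracketing the run
            # (the run samples themselves are mid-flight; with only a few
            # samples per saccade they would understate the amplitude)
            i_pre = i - 1 if i > 0 and np.all(np.isfinite(g[i - 1])) else i
            i_post = j if j < n and np.all(np.isfinite(g[j])) else j - 1
            amp = float(np.linalg.norm(g[i_post] - g[i_pre]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                pv = float(np.nanmax(velocity[i:j]))
            ev = OculomotorEvent("saccade", start, end, amplitude=amp, peak_velocity=pv)
            if amp < min_saccade_amp:
                ev = OculomotorEvent("noise", start, end)
        else:
            ev = OculomotorEvent("noise", start, end)
        events.append(ev)
        i = j
    return events


def merge_fixations(
    events: list[OculomotorEvent],
    max_gap: float = MERGE_GAP_S,
    max_dist: float = MERGE_DIST_DEG,
) -> list[OculomotorEvent]:
    """Merge successive similar fixations, iteratively re-checking.

    Two fixations merge when no saccade lies between them, their gap is
    <= ``max_gap`` s and their centroids are < ``max_dist`` deg apart.  The
    merged fixation spans both (absorbing any noise between) with a
    duration-weighted centroid; merging repeats until stable.
    """
    evs = sorted(events, key=lambda e: e.start)
    changed = True
    while changed:
        changed = False
        out: list[OculomotorEvent] = []
        i = 0
        while i < len(evs):
            e = evs[i]
            if e.kind != "fixation":
                out.append(e)
                i += 1
                continue
            # find the next fixation; give up if a saccade intervenes
            j = i + 1
            blocked = False
            while j < len(evs) and evs[j].kind != "fixation":
                if evs[j].kind == "saccade":
                    blocked = True
                    break
                j += 1
            if blocked or j >= len(evs):
                out.append(e)
                i += 1
                continue
            nxt = evs[j]
            gap = nxt.start - e.end
            dist = float(
                np.hypot(
                    e.centroid[0] - nxt.centroid[0], e.centroid[1] - nxt.centroid[1]
                )
            )
            if gap <= max_gap + 1e-12 and dist < max_dist:
                w1, w2 = e.duration, nxt.duration
                cx = (e.centroid[0] * w1 + nxt.centroid[0] * w2) / (w1 + w2)
                cy = (e.centroid[1] * w1 + nxt.centroid[1] * w2) / (w1 + w2)
                merged = OculomotorEvent(
                    "fixation", e.start, nxt.end, centroid=(cx, cy)
                )
                evs = out + [merged] + evs[j + 1 :]
                changed = True
                break
            out.append(e)
            i += 1
        if not changed:
            evs = out
    return evs


def detect_blink_bursts(
    blinks: list[BlinkEvent], span: float = BURST_SPAN_S, mode: str = "chain"
) -> list[BlinkBurst]:
    """Maximal groups of >= 2 blinks within a ``span`` of 2 s.

    ``mode="chain"`` (default): each consecutive onset lies within ``span``
    of the previous one.  ``mode="window"``: the stricter reading where a
    whole group's onsets fit inside one ``span``-long window (greedy
    left-to-right maximal windows).
    """
    bs = sorted(blinks, key=lambda b: b.start)
    bursts: list[BlinkBurst] = []
    i = 0
    while i < len(bs):
        j = i
        if mode == "chain":
            while j + 1 < len(bs) and bs[j + 1].start - bs[j].start <= span:
                j += 1
        elif mode == "window":
            while j + 1 < len(bs) and bs[j + 1].start - bs[i].start <= span:
                j += 1
        else:
            raise ValueError("mode must be 'chain' or 'window'")
        if j > i:
            bursts.append(
                BlinkBurst(start=bs[i].start, end=bs[j].end, n_blinks=j - i + 1)
            )
        i = j + 1
    return bursts


def detect_trial_events(
    stream: pd.DataFrame,
    blinks: list[BlinkEvent],
    losses: list[tuple[float, float]],
    seed: int = 0,
) -> list[OculomotorEvent]:
    """Velocity -> HMM labels -> segmentation -> filtering -> merging."""
    v = angular_velocity(stream)
    spans = [(b.start, b.end) for b in blinks] + list(losses)
    labels = hmm_label(v, noise_spans=spans, t=stream["t_s"].to_numpy(), seed=seed)
    events = segment_and_filter_events(labels, stream, v)
    return merge_fixations(events)
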