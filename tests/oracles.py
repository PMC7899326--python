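"""Independent brute-force oracles used to cross-check pipeline operations.

Deliberately naive implementations (double loops, exhaustive enumeration)
kept free of any code shared with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def hampel_brute(x: np.ndarray, window: int = 5, n_sigmas: float = 3.0) -> np.ndarray:
    """Naive double-loop Hampel filter (MAD scale)."""
    x = np.asarray(x, dtype=float)
    out = x.copy()
    half = window // 2
    n = len(x)
    if n < window:
        return out
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        w = x[lo:hi]
        w = w[np.isfinite(w)]
        if len(w) < half + 1 or not np.isfinite(x[i]):
            continue
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        if abs(x[i] - med) > n_sigmas * 1.4826 * mad:
            out[i] = med
    return out


def classify_runs_brute(miss: np.ndarray, fs: float) -> list[tuple[int, int, str]]:
    """Scan a missing mask; classify each maximal run by duration.

    Returns (start index, length, kind) with kind in
    {short, blink, loss}.
    """
    out = []
    n = len(miss)
    i = 0
    while i < n:
        if not miss[i]:
            i += 1
            continue
        j = i
        while j < n and miss[j]:
            j += 1
        dur = (j - i) / fs
        if dur < 0.075 - 1e-9:
            kind = "short"
        elif dur <= 0.500 + 1e-9:
            kind = "blink"
        else:
            kind = "loss"
        out.append((i, j - i, kind))
        i = j
    return out


def wilcoxon_exact_brute(deltas: np.ndarray) -> tuple[float, float]:
    """Exhaustive 2^n enumeration of sign patterns; (V, two-sided p)."""
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    vs = signs @ ranks
    cdf = float((vs <= v + 1e-9).mean())
    sf = float((vs >= v - 1e-9).mean())
    return v, min(1.0, 2.0 * min(cdf, sf))


def merge_fixations_brute(
    fixes: list[tuple[float, float, float, float]],
    max_gap: float = 0.075,
    max_dist: float = 0.5,
) -> list[tuple[float, float, float, float]]:
    """Naive repeated-scan merger of (start, end, cx, cy) fixation tuples.

    Re-starts the scan from scratch after every merge until stable.
    """
    evs = sorted([list(f) for f in fixes])
    while True:
        merged = False
        for i in range(len(evs) - 1):
            a, b = evs[i], evs[i + 1]
            gap = b[0] - a[1]
            dist = np.hypot(a[2] - b[2], a[3] - b[3])
            if gap <= max_gap + 1e-12 and dist < max_dist:
                wa, wb = a[1] - a[0], b[1] - b[0]
                cx = (a[2] * wa + b[2] * wb) / (wa + wb)
                cy = (a[3] * wa + b[3] * wb) / (wa + wb)
                evs[i : i + 2] = [[a[0], b[1], cx, cy]]
                merged = True
                break
        if not merged:
            return [tuple(e) for e in evs]
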