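"""Independent brute-force oracles used to cross-check the detectors.

Pure-python reimplementations from first principles: every local maximum is
enumerated and the threshold/prominence/separation/width rules are applied
literally, with no shared code with the package internals.
"""

from __future__ import annotations

import numpy as np


def local_maxima(y: np.ndarray) -> list[int]:
    """Strict local maxima; plateaus report their midpoint (rounded down)."""
    out = []
    i = 1
    n = len(y)
    while i < n - 1:
        if y[i - 1] < y[i]:
            j = i
            while j < n - 1 and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def prominence(y: np.ndarray, p: int) -> float:
    n = len(y)
    left_min = y[p]
    i = p - 1
    while i >= 0 and y[i] <= y[p]:
        left_min = min(left_min, y[i])
        i -= 1
    right_min = y[p]
    j = p + 1
    while j < n and y[j] <= y[p]:
        right_min = min(right_min, y[j])
        j += 1
    return y[p] - max(left_min, right_min)


def width_above_level(t: np.ndarray, y: np.ndarray, p: int, level: float) -> float:
    n = len(y)
    i = p
    while i > 0 and y[i - 1] > level:
        i -= 1
    left = t[0] if i == 0 else t[i - 1] + (level - y[i - 1]) / (y[i] - y[i - 1]) * (t[i] - t[i - 1])
    j = p
    while j < n - 1 and y[j + 1] > level:
        j += 1
    right = t[-1] if j == n - 1 else t[j] + (y[j] - level) / (y[j] - y[j + 1]) * (t[j + 1] - t[j])
    return right - left


def oracle_detect_peaks(
    t: np.ndarray,
    y: np.ndarray,
    baseline_sd: float,
    k_sd: float = 3.0,
    min_separation_s: float = 2.0,
    min_width_s: float | None = None,
) -> list[int]:
    """Sample indices of detected event peaks, by exhaustive enumeration."""
    dt = t[1] - t[0]
    if min_width_s is None:
        min_width_s = 2.0 * dt
    thr = 1.0 + k_sd * baseline_sd
    cands = [
        p
        for p in local_maxima(y)
        if y[p] >= thr and prominence(y, p) >= k_sd * baseline_sd
    ]
    # tallest first, ties to the earlier peak
    order = sorted(cands, key=lambda p: (-y[p], p))
    kept: list[int] = []
    for p in order:
        if all(abs(t[p] - t[q]) >= min_separation_s for q in kept):
            kept.append(p)
    kept = [p for p in kept if width_above_level(t, y, p, thr) >= min_width_s]
    return sorted(kept)


def oracle_threshold_crossings(x: np.ndarray, threshold: float) -> int:
    """Number of contiguous excursions of x below -threshold (inward events)."""
    below = x < -threshold
    count = 0
    prev = False
    for b in below:
        if b and not prev:
            count += 1
        prev = b
    return count


def oracle_exp_rise_grid(
    t: np.ndarray, y: np.ndarray, tau_lo: float = 5.0, tau_hi: float = 200.0
) -> tuple[float, float, float]:
    """Brute-force SSE grid over tau, with (baseline, amplitude) solved
    linearly at each tau; two refinement passes reach ~0.05% resolution."""
    best = None
    lo, hi = tau_lo, tau_hi
    for _ in range(3):
        taus = np.linspace(lo, hi, 201)
        for tau in taus:
            basis = 1.0 - np.exp(-t / tau)
            design = np.column_stack([np.ones_like(t), basis])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            sse = float(np.sum((design @ coef - y) ** 2))
            if best is None or sse < best[0]:
                best = (sse, tau, coef)
        step = taus[1] - taus[0]
        lo = max(tau_lo, best[1] - 2 * step)
        hi = min(tau_hi, best[1] + 2 * step)
    _, tau, (b, a) = best
    return float(tau), float(a), float(b)
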