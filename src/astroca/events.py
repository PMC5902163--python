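"""Spontaneous calcium-event detection and per-cell/per-field summaries.

Events are elevations of F/F0 that exceed the quiescent baseline by at least
``k_sd`` (default 3) baseline standard deviations, located as local maxima
with matching prominence. Each event carries its onset (last upward
threshold crossing before the peak), peak time, peak F/F0 amplitude and
full width at half maximum. Cells with at least ``oscillating_min_events``
events in a recording count as oscillating; fields summarize the fraction
of oscillating cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ValidationError
from .preprocess import NormalizedTrace

__all__ = [
    "CalciumEvent",
    "CellSummary",
    "FieldSummary",
    "DetectionParams",
    "estimate_baseline_sd",
    "detect_events",
    "event_fwhm",
    "summarize_cells",
    "summarize_fields",
]


@dataclass(frozen=True)
class CalciumEvent:
    """One detected calcium transient on a single ROI."""

    roi_id: str
    onset_s: float
    peak_time_s: float
    amplitude: float  # peak F/F0, baseline = 1
    fwhm_s: float  # NaN when the half-level crossing is truncated
    compartment: str | None = None
    cell_id: int | None = None


@dataclass(frozen=True)
class CellSummary:
    roi_id: str
    compartment: str | None
    cell_id: int | None
    n_events: int
    duration_min: float
    frequency_per_min: float
    mean_amplitude: float  # NaN when no events
    is_oscillating: bool


@dataclass(frozen=True)
class FieldSummary:
    field_id: str
    n_cells: int
    fraction_oscillating: float


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the 3-SD event detector.

    min_separation_s mirrors the generator's resolvability rule (half the
    indicator decay constant: ~2 s for Fluo-4, ~3 s for GCaMP6s); peaks
    closer than this keep only the larger. min_width_s of None means two
    frame intervals.
    """

    k_sd: float = 3.0
    min_separation_s: float = 2.0
    min_width_s: float | None = None
    oscillating_min_events: int = 2


def estimate_baseline_sd(
    trace: NormalizedTrace,
    method: str = "robust",
    mask_k: float = 2.0,
    max_iter: int = 5,
) -> float:
    """Standard deviation of the event-free baseline noise.

    method="robust" (default): MAD of the second differences of the trace,
    scaled to an SD (Var of the second difference of white noise is
    6 sigma^2). Slow indicator transients are nearly linear over adjacent
    frames and cancel, so the estimate stays anchored to the noise floor
    even when events and their shoulders occupy half the recording.

    method="iterative_mask": SD of the whole trace, masking samples above
    median + ``mask_k`` x scale and recomputing on the rest until
    convergence (<= ``max_iter`` rounds); adequate when events are sparse,
    biased upward on highly active traces.
    """
    y = trace.f_over_f0
    if y.size < 30:
        raise ValidationError("need >= 30 samples to estimate a baseline SD")

    if method == "robust":
        d2 = np.diff(y, n=2)
        return float(1.4826 * np.median(np.abs(d2)) / np.sqrt(6.0))
    if method != "iterative_mask":
        raise ValidationError(f"unknown method {method!r}")

    def scale(v: np.ndarray) -> float:
        mad = 1.4826 * float(np.median(np.abs(v - np.median(v))))
        return mad if mad > 0 else float(np.std(v))

    mask = np.ones(y.size, dtype=bool)
    s = scale(y)
    for _ in range(max_iter):
        med = float(np.median(y[mask]))
        new_mask = y <= med + mask_k * s
        if new_mask.sum() < 10:
            raise ValidationError("fewer than 10 baseline samples; no identifiable baseline")
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
        s = scale(y[mask])
    return float(np.std(y[mask]))


def _greedy_separation(
    peaks: np.ndarray, heights: np.ndarray, time_s: np.ndarray, min_separation_s: float
) -> np.ndarray:
    """Keep the larger of any two peaks closer than min_separation_s.

    Peaks are visited tallest first; equal heights break toward the earlier
    peak so output is deterministic.
    """
    order = np.lexsort((peaks, -heights))
    kept: list[int] = []
    for idx in order:
        p = peaks[idx]
        if all(abs(time_s[p] - time_s[q]) >= min_separation_s for q in kept):
            kept.append(p)
    return np.sort(np.asarray(kept, dtype=int))


def detect_events(
    trace: NormalizedTrace,
    params: DetectionParams = DetectionParams(),
    baseline_sd: float | None = None,
) -> list[CalciumEvent]:
    """Detect calcium elevations at a 3x baseline-SD threshold.

    Candidate peaks are local maxima whose value is >= 1 + k_sd*SD and
    whose prominence is >= k_sd*SD; peaks closer than min_separation_s keep
    only the larger; events whose contiguous excursion above the threshold
    (linearly interpolated crossings) is narrower than min_width_s are
    discarded — isolated noise spikes cannot stay above the threshold for
    two frames, genuine indicator transients do. Onset is the last upward
    crossing of the threshold before the peak (linearly interpolated).
    """
    y = trace.f_over_f0
    t = trace.time_s
    dt = trace.frame_interval_s
    if baseline_sd is None:
        baseline_sd = estimate_baseline_sd(trace)
    if baseline_sd == 0.0:
        if np.ptp(y) == 0.0:
            return []
        raise ValidationError("baseline SD is zero for a non-constant trace")
    thr_prom = params.k_sd * baseline_sd
    thr_height = 1.0 + params.k_sd * baseline_sd
    min_width_s = params.min_width_s if params.min_width_s is not None else 2.0 * dt

    peaks, props = signal.find_peaks(y, height=thr_height, prominence=thr_prom)
    if peaks.size == 0:
        return []
    kept = _greedy_separation(peaks, y[peaks], t, params.min_separation_s)
    kept = np.asarray(
        [p for p in kept if _width_above(t, y, p, thr_height) >= min_width_s], dtype=int
    )

    events = []
    prev_peak: int | None = None
    for p in kept:
        onset = _onset_time(t, y, p, thr_height)
        # reference the peak to the local pre-onset level so an event riding
        # the decaying tail of its predecessor reports its own amplitude
        if prev_peak is not None and np.all(y[prev_peak : p + 1] > thr_height):
            # same supra-threshold excursion: reference the dip in between
            local_level = float(np.min(y[prev_peak:p]))
        else:
            pre = y[(t >= onset - 4 * dt) & (t < onset)]
            local_level = float(np.median(pre)) if pre.size else 1.0
        prev_peak = p
        ev = CalciumEvent(
            roi_id=trace.roi_id,
            onset_s=onset,
            peak_time_s=float(t[p]),
            amplitude=float(y[p]) - (local_level - 1.0),
            fwhm_s=_fwhm_at_peak(t, y, p),
            compartment=trace.compartment,
            cell_id=trace.cell_id,
        )
        events.append(ev)
    return events


def _width_above(t: np.ndarray, y: np.ndarray, peak: int, level: float) -> float:
    """Duration of the contiguous excursion of y above `level` around `peak`."""
    n = len(y)
    i = peak
    while i > 0 and y[i - 1] > level:
        i -= 1
    if i == 0:
        left = float(t[0])
    else:
        frac = (level - y[i - 1]) / (y[i] - y[i - 1])
        left = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    j = peak
    while j < n - 1 and y[j + 1] > level:
        j += 1
    if j == n - 1:
        right = float(t[-1])
    else:
        frac = (y[j] - level) / (y[j] - y[j + 1])
        right = float(t[j] + frac * (t[j + 1] - t[j]))
    return right - left


def _onset_time(t: np.ndarray, y: np.ndarray, peak: int, level: float) -> float:
    """Last upward crossing of `level` before `peak`, interpolated."""
    i = peak
    while i > 0 and y[i - 1] >= level:
        i -= 1
    if i == 0:
        return float(t[0])
    # crossing between i-1 and i
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _half_crossings(t: np.ndarray, y: np.ndarray, peak: int, half: float):
    left = np.nan
    i = peak
    while i > 0:
        if y[i - 1] < half <= y[i]:
            frac = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = t[i - 1] + frac * (t[i] - t[i - 1])
            break
        i -= 1
    right = np.nan
    j = peak
    n = len(y)
    while j < n - 1:
        if y[j + 1] < half <= y[j]:
            frac = (y[j] - half) / (y[j] - y[j + 1])
            right = t[j] + frac * (t[j + 1] - t[j])
            break
        j += 1
    return left, right


def _fwhm_at_peak(t: np.ndarray, y: np.ndarray, peak: int) -> float:
    amplitude = y[peak]
    half = 1.0 + (amplitude - 1.0) / 2.0
    left, right = _half_crossings(t, y, peak, half)
    if np.isnan(left) or np.isnan(right):
        return float("nan")  # truncated at a border: FWHM missing, not an error
    return float(right - left)


def event_fwhm(trace: NormalizedTrace, event: CalciumEvent) -> float:
    """Full width at half maximum of one event, in seconds.

    The half level is 1 + (amplitude - 1)/2; the width runs from the last
    upward crossing before the peak to the first downward crossing after
    it, linearly interpolated between samples. Returns NaN when either
    crossing falls outside the trace (event truncated at a border).
    """
    peak = int(np.argmin(np.abs(trace.time_s - event.peak_time_s)))
    return _fwhm_at_peak(trace.time_s, trace.f_over_f0, peak)


def summarize_cells(
    events: list[CalciumEvent],
    traces: list[NormalizedTrace],
    oscillating_min_events: int = 2,
) -> list[CellSummary]:
    """Per-ROI frequency/amplitude summary with the oscillating flag."""
    by_roi: dict[str, list[CalciumEvent]] = {}
    for ev in events:
        by_roi.setdefault(ev.roi_id, []).append(ev)
    summaries = []
    for tr in traces:
        duration_min = tr.duration_s / 60.0
        if duration_min <= 0:
            raise ValidationError(f"zero-duration trace for ROI {tr.roi_id}")
        evs = by_roi.get(tr.roi_id, [])
        n = len(evs)
        amps = [e.amplitude for e in evs]
        summaries.append(
            CellSummary(
                roi_id=tr.roi_id,
                compartment=tr.compartment,
                cell_id=tr.cell_id,
                n_events=n,
                duration_min=duration_min,
                frequency_per_min=n / duration_min,
                mean_amplitude=float(np.mean(amps)) if amps else float("nan"),
                is_oscillating=n >= oscillating_min_events,
            )
        )
    return summaries


def summarize_fields(
    cells: list[CellSummary],
    field_map: dict[str, str] | None = None,
    soma_only: bool = True,
) -> list[FieldSummary]:
    """Fraction of oscillating cells per field.

    ``field_map`` maps roi_id -> field_id; a single field is assumed when
    omitted. Soma and process compartments are summarized separately in the
    per-cell table; by default only somatic ROIs (or ROIs with no
    compartment tag) enter the oscillating fraction, matching how fields of
    view are scored.
    """
    groups: dict[str, list[CellSummary]] = {}
    for c in cells:
        if soma_only and c.compartment not in (None, "soma"):
            continue
        fid = field_map.get(c.roi_id, "field_0") if field_map else "field_0"
        groups.setdefault(fid, []).append(c)
    out = []
    for fid in sorted(groups):
        cs = groups[fid]
        frac = sum(c.is_oscillating for c in cs) / len(cs)
        out.append(FieldSummary(field_id=fid, n_cells=len(cs), fraction_oscillating=frac))
    return out
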