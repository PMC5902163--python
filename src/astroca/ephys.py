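"""Detection of slow inward currents and epileptiform discharges.

Works on whole-cell voltage-clamp current recordings (inward currents are
negative). Slow inward currents (SICs) — NMDA-receptor-mediated events
attributed to astrocytic glutamate release — are separated from fast
synaptic currents by a minimum 10-90% rise time. Epileptiform activity
(GABA_A-blockade-induced) is summarized by four metrics: latency from drug
application to the first discharge, discharge rate, mean event duration
(time above half-peak) and mean peak amplitude.

Both operators are documented stand-ins for interactive template detection
in acquisition software; all thresholds are explicit parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .errors import ValidationError

__all__ = [
    "CurrentTrace",
    "SICEvent",
    "EpileptiformEvent",
    "EpileptiformSummary",
    "SICParams",
    "EpileptiformParams",
    "detect_sics",
    "sic_rate_per_20min",
    "detect_epileptiform",
]


@dataclass
class CurrentTrace:
    """A uniformly sampled voltage-clamp current recording (pA, inward negative)."""

    time_s: np.ndarray
    current_pa: np.ndarray
    sampling_hz: float
    holding_mv: float = -70.0
    drug_onset_s: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_pa = np.asarray(self.current_pa, dtype=float)
        if self.time_s.shape != self.current_pa.shape:
            raise ValidationError("time and current lengths differ")
        if not np.all(np.isfinite(self.current_pa)):
            raise ValidationError("current contains non-finite values")

    @property
    def duration_s(self) -> float:
        return len(self.current_pa) / self.sampling_hz


@dataclass(frozen=True)
class SICEvent:
    onset_s: float
    peak_time_s: float
    peak_amplitude_pa: float  # signed; inward events are negative
    rise_time_10_90_ms: float
    decay_tau_ms: float


@dataclass(frozen=True)
class EpileptiformEvent:
    onset_s: float
    duration_ms: float
    amplitude_pa: float  # peak magnitude of the discharge burst
    n_discharges: int


@dataclass
class EpileptiformSummary:
    latency_min: float  # NaN when no discharges occurred
    frequency_hz: float
    mean_duration_ms: float
    mean_amplitude_pa: float
    events: list[EpileptiformEvent] = field(default_factory=list)


@dataclass(frozen=True)
class SICParams:
    amp_threshold_pa: float = 20.0
    slow_rise_min_ms: float = 10.0  # excludes fast synaptic currents
    min_width_ms: float = 100.0
    baseline_window_s: float = 2.0
    analysis_hz: float = 200.0  # SICs are slow; detection runs decimated


@dataclass(frozen=True)
class EpileptiformParams:
    amp_threshold_pa: float = 100.0
    merge_gap_ms: float = 400.0  # bridges sub-threshold dips between rhythmic discharges
    min_event_ms: float = 100.0
    peak_min_distance_ms: float = 80.0
    peak_prominence_frac: float = 0.15
    analysis_hz: float = 500.0


def _decimate(x: np.ndarray, fs: float, target_hz: float) -> tuple[np.ndarray, float]:
    """Boxcar-average decimation to approximately target_hz."""
    factor = max(1, int(round(fs / target_hz)))
    n = (len(x) // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1), fs / factor


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    window = max(3, window | 1)
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()
    )


def detect_sics(trace: CurrentTrace, params: SICParams = SICParams()) -> list[SICEvent]:
    """Detect slow inward currents in a voltage-clamp recording.

    The recording is boxcar-decimated, a rolling-median baseline is
    subtracted, and negative deflections qualify when they exceed
    ``amp_threshold_pa``, last at least ``min_width_ms`` at half amplitude,
    and rise (10-90%) no faster than ``slow_rise_min_ms``. Each event's
    decay time constant comes from a single-exponential fit of the falling
    phase.
    """
    x, fs = _decimate(trace.current_pa, trace.sampling_hz, params.analysis_hz)
    t = np.arange(len(x)) / fs
    n30 = int(min(30.0, trace.duration_s) * fs)
    head = x[:n30]
    robust_sd = 1.4826 * float(np.median(np.abs(head - np.median(head))))
    if robust_sd >= params.amp_threshold_pa:
        raise ValidationError(
            "baseline unstable: robust SD over the first 30 s exceeds the amplitude threshold"
        )
    baseline = _rolling_median(x, int(params.baseline_window_s * fs))
    r = -(x - baseline)  # positive = inward deflection magnitude

    min_dist = max(1, int(0.5 * fs))
    peaks, _ = signal.find_peaks(r, height=params.amp_threshold_pa, distance=min_dist)
    events: list[SICEvent] = []
    for p in peaks:
        amp = r[p]
        onset_i = _walk_down(r, p, 0.1 * amp, direction=-1)
        end_i = _walk_down(r, p, 0.1 * amp, direction=+1)
        width_ms = _level_width(t, r, p, 0.5 * amp) * 1000.0
        if width_ms < params.min_width_ms:
            continue
        t10 = _cross_time(t, r, onset_i, p, 0.1 * amp)
        t90 = _cross_time(t, r, onset_i, p, 0.9 * amp)
        rise_ms = (t90 - t10) * 1000.0
        if rise_ms < params.slow_rise_min_ms:
            continue
        tau_ms = _fit_decay_tau(t, r, p, end_i)
        events.append(
            SICEvent(
                onset_s=float(t[onset_i]),
                peak_time_s=float(t[p]),
                peak_amplitude_pa=float(-amp),
                rise_time_10_90_ms=float(rise_ms),
                decay_tau_ms=float(tau_ms),
            )
        )
    return events


def sic_rate_per_20min(events: list[SICEvent], duration_s: float) -> float:
    """SIC frequency expressed per 20 minutes of recording."""
    if duration_s <= 0:
        raise ValidationError("duration must be positive")
    return len(events) / duration_s * 1200.0


def _walk_down(r: np.ndarray, peak: int, level: float, direction: int) -> int:
    i = peak
    stop = 0 if direction < 0 else len(r) - 1
    while i != stop and r[i + direction] > level:
        i += direction
    return i + direction if i != stop else stop


def _cross_time(t, r, lo: int, peak: int, level: float) -> float:
    """Interpolated time where r last rises through `level` before peak."""
    i = peak
    while i > lo and r[i - 1] >= level:
        i -= 1
    if i == lo or r[i] == r[i - 1]:
        return float(t[max(i - 1, 0)])
    frac = (level - r[i - 1]) / (r[i] - r[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _level_width(t, r, peak: int, level: float) -> float:
    left = _cross_time(t, r, 0, peak, level)
    j = peak
    n = len(r)
    while j < n - 1 and r[j + 1] >= level:
        j += 1
    if j == n - 1 or r[j] == r[j + 1]:
        right = float(t[j])
    else:
        frac = (r[j] - level) / (r[j] - r[j + 1])
        right = float(t[j] + frac * (t[j + 1] - t[j]))
    return right - left


def _fit_decay_tau(t, r, peak: int, end_i: int) -> float:
    seg = slice(peak, max(end_i, peak + 4))
    ts = t[seg] - t[peak]
    ys = r[seg]
    if len(ts) < 4:
        return float("nan")
    # 1/e crossing as a robust initial guess
    below = np.flatnonzero(ys <= ys[0] / np.e)
    tau0 = ts[below[0]] if len(below) else ts[-1] / 2
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            ts,
            ys,
            p0=(ys[0], max(tau0, ts[1])),
            maxfev=2000,
        )
        return float(popt[1] * 1000.0)
    except RuntimeError:
        return float("nan")


def detect_epileptiform(
    trace: CurrentTrace, params: EpileptiformParams = EpileptiformParams()
) -> EpileptiformSummary:
    """Detect epileptiform discharge bursts and compute the four metrics.

    Deflections after drug onset exceeding ``amp_threshold_pa`` are merged
    across gaps shorter than ``merge_gap_ms`` into events. Per event:
    duration is the span between the outermost crossings of half the event
    peak, amplitude is the peak magnitude, and discharge peaks inside the
    event are counted. Latency is the time from drug application to the
    first event; frequency is the discharge rate while epileptiform
    activity is ongoing, estimated from inter-peak intervals (number of
    intervals over the first-to-last peak span, summed across events).
    With no discharges the summary has NaN latency and zero frequency.
    """
    if trace.drug_onset_s is None:
        raise ValidationError("drug_onset_s must be set for epileptiform detection")
    x, fs = _decimate(trace.current_pa, trace.sampling_hz, params.analysis_hz)
    t = np.arange(len(x)) / fs
    pre = x[t < trace.drug_onset_s]
    baseline = float(np.median(pre)) if len(pre) else float(np.median(x))
    r = -(x - baseline)
    r[t < trace.drug_onset_s] = 0.0

    above = r >= params.amp_threshold_pa
    segments = _merge_segments(above, int(params.merge_gap_ms / 1000.0 * fs))
    events: list[EpileptiformEvent] = []
    _spans: list[tuple[int, float]] = []  # (intervals, first-to-last peak span) per event
    for i0, i1 in segments:
        if (i1 - i0) / fs * 1000.0 < params.min_event_ms:
            continue
        seg = r[i0:i1]
        amp = float(seg.max())
        half_idx = np.flatnonzero(seg >= 0.5 * amp)
        duration_s = (half_idx[-1] - half_idx[0]) / fs
        dist = max(1, int(params.peak_min_distance_ms / 1000.0 * fs))
        pk, _ = signal.find_peaks(
            seg, prominence=params.peak_prominence_frac * amp, distance=dist
        )
        events.append(
            EpileptiformEvent(
                onset_s=float(t[i0]),
                duration_ms=duration_s * 1000.0,
                amplitude_pa=amp,
                n_discharges=max(len(pk), 1),
            )
        )
        if len(pk) >= 2:
            _spans.append((len(pk) - 1, (pk[-1] - pk[0]) / fs))
    if not events:
        return EpileptiformSummary(
            latency_min=float("nan"),
            frequency_hz=0.0,
            mean_duration_ms=float("nan"),
            mean_amplitude_pa=float("nan"),
        )
    if _spans:
        # rate from inter-peak intervals: unbiased regardless of how the
        # event window sits relative to the discharge phase
        frequency = sum(k for k, _ in _spans) / sum(s for _, s in _spans)
    else:
        total_dur = sum(e.duration_ms for e in events) / 1000.0
        frequency = sum(e.n_discharges for e in events) / total_dur if total_dur > 0 else 0.0
    return EpileptiformSummary(
        latency_min=(events[0].onset_s - trace.drug_onset_s) / 60.0,
        frequency_hz=frequency,
        mean_duration_ms=float(np.mean([e.duration_ms for e in events])),
        mean_amplitude_pa=float(np.mean([e.amplitude_pa for e in events])),
        events=events,
    )


def _merge_segments(above: np.ndarray, gap_samples: int) -> list[tuple[int, int]]:
    """Contiguous True runs, merged across gaps shorter than gap_samples."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > gap_samples)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1
    return list(zip(starts.tolist(), ends.tolist()))
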