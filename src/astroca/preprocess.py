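"""Trace normalization and baseline conditioning.

Fluorescence traces are expressed as the ratio F/F0 of instantaneous
fluorescence to a baseline estimate F0, so that the quiescent level sits
near 1 and dF/F0 = F/F0 - 1. Slowly drifting baselines are flattened with a
rolling-ball (1-D greyscale morphological opening) correction, and noisy
low-frame-rate recordings can be zero-phase low-pass filtered before event
detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

from .errors import ValidationError

__all__ = [
    "NormalizedTrace",
    "normalize_f0",
    "rolling_ball_correct",
    "lowpass",
    "drift_slope",
    "auto_baseline_correct",
]


@dataclass
class NormalizedTrace:
    """A per-ROI F/F0 time series with provenance.

    Attributes
    ----------
    time_s : sample times in seconds (uniform spacing assumed)
    f_over_f0 : the F/F0 ratio series, baseline ~ 1
    f0 : scalar baseline fluorescence estimate in raw units
    baseline_model : "static_percentile" or "rolling_ball"
    roi_id, compartment, cell_id : provenance of the ROI
    """

    time_s: np.ndarray
    f_over_f0: np.ndarray
    f0: float = 1.0
    baseline_model: str = "static_percentile"
    roi_id: str = "roi_0"
    compartment: str | None = None
    cell_id: int | None = None
    baseline: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f_over_f0 = np.asarray(self.f_over_f0, dtype=float)
        if self.time_s.shape != self.f_over_f0.shape:
            raise ValidationError("time_s and f_over_f0 must have equal length")
        if self.time_s.ndim != 1:
            raise ValidationError("traces must be one-dimensional")
        if np.ndim(self.f0) == 0 and not self.f0 > 0:
            raise ValidationError("f0 must be positive")

    @property
    def df_over_f0(self) -> np.ndarray:
        return self.f_over_f0 - 1.0

    @property
    def frame_interval_s(self) -> float:
        if len(self.time_s) < 2:
            raise ValidationError("need at least 2 samples to define a frame interval")
        return float(self.time_s[1] - self.time_s[0])

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) + self.frame_interval_s


def normalize_f0(
    raw: np.ndarray,
    time_s: np.ndarray,
    method: str = "static_percentile",
    percentile: float = 20.0,
    **provenance,
) -> NormalizedTrace:
    """Convert a raw fluorescence trace to F/F0.

    F0 is the given percentile of the raw trace (default 20th), a robust
    choice when transients occupy a minority of samples. Scale-invariant:
    normalize_f0(a * raw) == normalize_f0(raw) for any a > 0.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValidationError("empty trace")
    if not np.all(np.isfinite(raw)):
        raise ValidationError("raw trace contains non-finite values")
    if np.any(raw <= 0):
        raise ValidationError(
            "raw fluorescence must be strictly positive (indicator fluorescence cannot be <= 0)"
        )
    if method != "static_percentile":
        raise ValidationError(f"unknown F0 method: {method!r}")
    f0 = float(np.percentile(raw, percentile))
    return NormalizedTrace(
        time_s=np.asarray(time_s, dtype=float),
        f_over_f0=raw / f0,
        f0=f0,
        baseline_model="static_percentile",
        **provenance,
    )


def _padded_opening(y: np.ndarray, size: int) -> np.ndarray:
    """Greyscale opening with linear edge extrapolation.

    Padding each end with the locally fitted linear continuation keeps a pure
    ramp invariant under opening all the way to the boundary; plain
    edge-replication flattens the last half-window and leaves a kink.
    """
    n = len(y)
    fit_n = min(max(size, 3), n)
    x = np.arange(fit_n)
    left_coef = np.polyfit(x, y[:fit_n], 1)
    right_coef = np.polyfit(x, y[-fit_n:], 1)
    pad_x = np.arange(1, size + 1)
    left_pad = np.polyval(left_coef, -pad_x[::-1])
    right_pad = np.polyval(right_coef, fit_n - 1 + pad_x)
    ext = np.concatenate([left_pad, y, right_pad])
    opened = ndimage.grey_opening(ext, size=size, mode="nearest")
    return opened[size : size + n]


def rolling_ball_correct(
    trace: NormalizedTrace,
    ball_radius_s: float = 60.0,
    decay_tau_s: float | None = None,
) -> NormalizedTrace:
    """Subtract a rolling-ball baseline from a normalized trace.

    The baseline is the 1-D greyscale opening of the series with a flat
    structuring window ``ball_radius_s`` long; the corrected trace is
    ``trace - baseline + median(baseline)`` so the overall level is kept.
    The window must be much longer than a transient (>= 5x the indicator
    decay time constant when known), otherwise genuine events are eaten
    into the baseline.
    """
    dt = trace.frame_interval_s
    size = int(round(ball_radius_s / dt))
    if size < 3:
        raise ValidationError(
            f"rolling-ball radius {ball_radius_s} s is shorter than 3 samples at dt={dt} s"
        )
    if decay_tau_s is not None and ball_radius_s < 5 * decay_tau_s:
        import warnings

        warnings.warn(
            "rolling-ball radius < 5x decay tau; transients may be absorbed into the baseline",
            stacklevel=2,
        )
    y = trace.f_over_f0
    baseline = _padded_opening(y, size)
    # anti-extensivity of opening guarantees baseline <= y everywhere
    corrected = y - baseline + float(np.median(baseline))
    return replace(
        trace, f_over_f0=corrected, baseline_model="rolling_ball", baseline=baseline
    )


def lowpass(trace: NormalizedTrace, cutoff_hz: float, order: int = 4) -> NormalizedTrace:
    """Zero-phase Butterworth low-pass filter with unit DC gain.

    Applied forward and backward (``sosfiltfilt``) so event onsets are not
    shifted in time; used for noisy low-frame-rate in vivo recordings
    (cut-off 0.5 Hz at 1.83 fps in the standard preset).
    """
    dt = trace.frame_interval_s
    nyquist = 0.5 / dt
    if cutoff_hz <= 0 or cutoff_hz >= nyquist:
        raise ValidationError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist:.3f} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=1.0 / dt, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.f_over_f0)
    return replace(trace, f_over_f0=filtered)


def drift_slope(trace: NormalizedTrace) -> float:
    """Least-squares linear slope of the trace in F/F0 per second."""
    coef = np.polyfit(trace.time_s, trace.f_over_f0, 1)
    return float(coef[0])


def auto_baseline_correct(
    trace: NormalizedTrace,
    ball_radius_s: float = 60.0,
    drift_threshold: float = 0.1,
    decay_tau_s: float | None = None,
) -> NormalizedTrace:
    """Apply rolling-ball correction only when the trace drifts.

    The trigger is |linear slope| x duration > ``drift_threshold`` (in F/F0
    units over the recording), an automated stand-in for the by-eye call of
    which traces need baseline correction.
    """
    total_drift = abs(drift_slope(trace)) * trace.duration_s
    if total_drift > drift_threshold:
        return rolling_ball_correct(trace, ball_radius_s, decay_tau_s=decay_tau_s)
    return trace
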