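"""Pharmacologically evoked response quantification.

Covers four protocols: agonist-evoked transients (ATP, glutamate), the slow
cytosolic rise after SERCA inhibition with thapsigargin (quantified by a
single-exponential rise fit whose time constant reflects the passive ER
leak), store-operated calcium entry measured as the peak on extracellular
Ca2+ re-addition after store depletion, and the antagonist-sensitive
membrane current density (pA/pF) isolated as a pre/post drug difference at
a fixed holding potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import FitRejectedError, ValidationError
from .events import estimate_baseline_sd
from .preprocess import NormalizedTrace

__all__ = [
    "ExpRiseFit",
    "EvokedResponse",
    "CurrentDensityResult",
    "evoked_peak",
    "fit_exp_rise",
    "soce_amplitude",
    "ml204_sensitive_density",
    "normalize_to_group_mean",
]


@dataclass(frozen=True)
class ExpRiseFit:
    """Single-exponential rise fit y(t) = B + A*(1 - exp(-(t-onset)/tau))."""

    tau_s: float
    amplitude: float
    baseline: float
    r_squared: float
    window: tuple[float, float]


@dataclass(frozen=True)
class EvokedResponse:
    peak_amplitude: float  # max F/F0 in the response window
    time_to_peak_s: float  # from the stimulus
    kind: str  # atp | glutamate | tg_release | soce
    responded: bool = True  # False when the peak stays under 1 + 3*SD


@dataclass(frozen=True)
class CurrentDensityResult:
    density_pa_per_pf: float
    capacitance_pf: float
    window_s: tuple[float, float]


def _smoothed(y: np.ndarray, dt: float, smooth_s: float) -> np.ndarray:
    """Short moving average; bounds the upward bias of a max statistic on noise."""
    w = max(1, int(round(smooth_s / dt)))
    if w <= 1:
        return y
    kernel = np.ones(w) / w
    pad = w // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="same")[pad : pad + len(y)]


def evoked_peak(
    trace: NormalizedTrace,
    stim_time_s: float,
    window_s: float,
    kind: str = "atp",
    smooth_s: float = 1.0,
) -> EvokedResponse:
    """Peak F/F0 in [stim, stim + window] and its latency from the stimulus.

    The trace is lightly smoothed (default 1 s moving average) before the
    maximum is taken. A peak below 1 + 3x the pre-stimulus baseline SD is
    flagged as no-response (``responded=False``).
    """
    t = trace.time_s
    dt = trace.frame_interval_s
    sel = (t >= stim_time_s) & (t <= stim_time_s + window_s)
    if not np.any(sel):
        raise ValidationError("response window contains no samples")
    ys = _smoothed(trace.f_over_f0, dt, smooth_s)
    win = ys[sel]
    i = int(np.argmax(win))
    peak = float(win[i])
    time_to_peak = float(t[sel][i] - stim_time_s)
    pre = trace.f_over_f0[t < stim_time_s]
    if pre.size >= 30:
        sd = estimate_baseline_sd(
            NormalizedTrace(time_s=t[t < stim_time_s], f_over_f0=pre)
        )
    else:
        sd = float(np.std(pre)) if pre.size else 0.0
    responded = peak >= 1.0 + 3.0 * sd if sd > 0 else peak > 1.0
    return EvokedResponse(
        peak_amplitude=peak, time_to_peak_s=time_to_peak, kind=kind, responded=responded
    )


def soce_amplitude(
    trace: NormalizedTrace,
    readdition_time_s: float,
    window_s: float,
    smooth_s: float = 2.5,
    **kw,
) -> EvokedResponse:
    """Store-operated Ca2+ entry: peak on extracellular Ca2+ re-addition.

    The influx transient is slower and flatter-topped than agonist-evoked
    responses, so a wider smoothing window is safe (negligible peak loss)
    and needed to keep the max statistic unbiased.
    """
    return evoked_peak(trace, readdition_time_s, window_s, kind="soce", smooth_s=smooth_s, **kw)


_TAU_STARTS = (10.0, 30.0, 60.0, 120.0)


def fit_exp_rise(
    trace: NormalizedTrace,
    onset_s: float = 0.0,
    fit_window_s: float | None = None,
    r2_min: float = 0.5,
) -> ExpRiseFit:
    """Least-squares single-exponential rise fit on [onset, onset+window].

    Initialization is multi-start over tau in {10, 30, 60, 120} s keeping
    the lowest residual. The window must contain a rising trend (the mean
    of its last decile must exceed the mean of its first decile); fits
    with R^2 below ``r2_min`` are rejected.
    """
    t = trace.time_s
    y = trace.f_over_f0
    t_end = onset_s + fit_window_s if fit_window_s is not None else t[-1]
    sel = (t >= onset_s) & (t <= t_end)
    ts = t[sel] - onset_s
    ys = y[sel]
    if len(ts) < 10:
        raise ValidationError("fit window contains fewer than 10 samples")
    dec = max(1, len(ys) // 10)
    if np.mean(ys[-dec:]) <= np.mean(ys[:dec]):
        raise FitRejectedError("no rising trend in the fit window")

    def model(tt, b, a, tau):
        return b + a * (1.0 - np.exp(-tt / tau))

    a0 = float(ys[-dec:].mean() - ys[:dec].mean())
    b0 = float(ys[:dec].mean())
    best = None
    for tau0 in _TAU_STARTS:
        try:
            popt, _ = optimize.curve_fit(
                model,
                ts,
                ys,
                p0=(b0, a0, tau0),
                bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((model(ts, *popt) - ys) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitRejectedError("exponential rise fit failed to converge")
    sse, (b, a, tau) = best
    sst = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    if r2 < r2_min:
        raise FitRejectedError(f"fit rejected: R^2 = {r2:.3f} < {r2_min}")
    return ExpRiseFit(
        tau_s=float(tau),
        amplitude=float(a),
        baseline=float(b),
        r_squared=r2,
        window=(float(onset_s), float(t_end)),
    )


def ml204_sensitive_density(
    current_pre_pa: np.ndarray,
    current_post_pa: np.ndarray,
    capacitance_pf: float,
    window: slice | None = None,
    window_s: tuple[float, float] = (0.0, 0.0),
) -> CurrentDensityResult:
    """Antagonist-sensitive current density at the holding potential, pA/pF.

    density = (mean(pre) - mean(post)) / capacitance over the averaging
    window; the sign is preserved (inward currents are negative). The
    pre/post traces must share the holding potential and duration.
    Antisymmetric under swapping pre and post.
    """
    pre = np.asarray(current_pre_pa, dtype=float)
    post = np.asarray(current_post_pa, dtype=float)
    if pre.shape != post.shape:
        raise ValidationError("pre and post recordings must have the same duration")
    if capacitance_pf <= 0:
        raise ValidationError("membrane capacitance must be positive")
    if window is not None:
        pre, post = pre[window], post[window]
    density = (float(pre.mean()) - float(post.mean())) / capacitance_pf
    return CurrentDensityResult(
        density_pa_per_pf=density, capacitance_pf=capacitance_pf, window_s=window_s
    )


def normalize_to_group_mean(values: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Express responses as percent of the control-group mean (control = 100%)."""
    control_mean = float(np.mean(control))
    if control_mean == 0:
        raise ValidationError("control group mean is zero")
    return 100.0 * np.asarray(values, dtype=float) / control_mean
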