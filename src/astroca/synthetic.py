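"""Synthetic fluorescence traces, movies and voltage-clamp recordings.

Every generator returns the simulated data together with its ground truth
(event times, true peaks, true time constants, label images), so the whole
analysis chain can be validated by parameter recovery. The population
presets encode the group statistics of astrocytes from wild-type and
MeCP2-deficient preparations (human iPSC-derived, mouse primary, acute
slice, and in vivo): oscillating-cell fractions, spontaneous event rates
and mean peak amplitudes, plus evoked-response, ER-release, SOCE, SIC and
epileptiform parameters.

Calcium transients use a difference-of-exponentials kernel (fast rise,
slow exponential decay) normalized to unit peak on the sampling grid, so
a recorded true peak equals the sampled trace maximum exactly. Event
placement is a Poisson process with a non-paralyzable dead time of half
the decay constant (two transients closer than that are unresolvable and
are merged into one ground-truth event); the candidate rate is compensated
so the surviving event rate equals the nominal rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .errors import PlacementError, ValidationError
from .ephys import CurrentTrace
from .preprocess import NormalizedTrace
from .segmentation import Movie, ROISet

__all__ = [
    "TraceSpec",
    "PopulationPreset",
    "EphysSpec",
    "GroundTruth",
    "MovieGroundTruth",
    "make_trace",
    "make_population",
    "make_movie",
    "make_exp_rise",
    "make_evoked_trace",
    "make_ephys_trace",
    "derive_seed",
    "get_preset",
    "POPULATION_PRESETS",
    "EPHYS_PRESETS",
    "EVOKED_PRESETS",
    "TG_RISE_TAU_S",
]


# ---------------------------------------------------------------------------
# specs and ground truth


@dataclass(frozen=True)
class TraceSpec:
    """Generative parameters of one spontaneous-activity F/F0 trace."""

    duration_s: float = 600.0
    frame_interval_s: float = 0.5
    event_rate_per_min: float = 0.0
    peak_f_over_f0: float = 1.66
    peak_cv: float = 0.3
    rise_tau_s: float = 1.0
    decay_tau_s: float = 4.0
    noise_sd: float = 0.05
    drift_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.duration_s > 0, "duration_s must be > 0"),
            (self.frame_interval_s > 0, "frame_interval_s must be > 0"),
            (self.event_rate_per_min >= 0, "event_rate_per_min must be >= 0"),
            (self.peak_f_over_f0 > 1, "peak_f_over_f0 must be > 1 (baseline is 1)"),
            (self.rise_tau_s > 0, "rise_tau_s must be > 0"),
            (
                self.decay_tau_s > self.rise_tau_s,
                "decay_tau_s must exceed rise_tau_s",
            ),
            (self.noise_sd >= 0, "noise_sd must be >= 0"),
            (self.peak_cv >= 0, "peak_cv must be >= 0"),
            (self.drift_amplitude >= 0, "drift_amplitude must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(msg)


@dataclass(frozen=True)
class PopulationPreset:
    """A mixed population: a fraction of oscillating cells, the rest silent."""

    name: str
    fraction_oscillating: float
    oscillating_spec: TraceSpec
    silent_spec: TraceSpec

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_oscillating <= 1.0:
            raise ValidationError("fraction_oscillating must lie in [0, 1]")


@dataclass(frozen=True)
class EphysSpec:
    """Generative parameters of a synthetic voltage-clamp recording."""

    kind: str = "sic"  # "sic" or "epileptiform"
    duration_s: float = 1200.0
    sampling_hz: float = 5000.0
    sic_rate_per_20min: float = 3.88
    sic_rise_ms: float = 20.0
    sic_decay_ms: float = 300.0
    drug_onset_s: float = 60.0
    latency_min: float = 4.5
    discharge_rate_hz: float = 5.6
    event_duration_ms: float = 755.0
    event_amplitude_pa: float = 364.0
    active_duration_s: float = 480.0
    inter_burst_gap_s: float = 1.5
    modulation_depth: float = 0.3
    noise_sd_pa: float = 5.0
    holding_current_pa: float = 0.0
    clip_pa: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("sic", "epileptiform"):
            raise ValidationError(f"kind must be 'sic' or 'epileptiform', got {self.kind!r}")
        if self.sampling_hz < 1000:
            raise ValidationError("sampling_hz must be >= 1000")
        for name in (
            "duration_s",
            "sic_rate_per_20min",
            "sic_rise_ms",
            "sic_decay_ms",
            "latency_min",
            "discharge_rate_hz",
            "event_duration_ms",
            "event_amplitude_pa",
            "noise_sd_pa",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """True event times/peaks (and tau for kinetics traces) of one trace."""

    event_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_peaks: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_tau_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.event_times_s = np.asarray(self.event_times_s, dtype=float)
        self.true_peaks = np.asarray(self.true_peaks, dtype=float)
        if len(self.event_times_s) != len(self.true_peaks):
            raise ValidationError("event_times_s and true_peaks lengths differ")
        if np.any(np.diff(self.event_times_s) < 0):
            raise ValidationError("event_times_s must be sorted ascending")


@dataclass
class MovieGroundTruth:
    """Per-pixel labels and per-compartment generative traces for a movie."""

    label_image: np.ndarray
    compartments: dict[int, str]
    cell_ids: dict[int, int]
    traces: dict[int, NormalizedTrace]
    event_truth: dict[int, GroundTruth]


# ---------------------------------------------------------------------------
# presets (group statistics of the study populations)

_IN_VITRO = dict(frame_interval_s=0.5, rise_tau_s=1.0, decay_tau_s=4.0)  # Fluo-4
_GCAMP = dict(rise_tau_s=1.5, decay_tau_s=6.0)  # GCaMP6s


def _preset(name, frac, rate, amp, **kw) -> PopulationPreset:
    osc = TraceSpec(event_rate_per_min=rate, peak_f_over_f0=amp, **kw)
    silent = replace(osc, event_rate_per_min=0.0)
    return PopulationPreset(name, frac, osc, silent)


POPULATION_PRESETS: dict[str, PopulationPreset] = {
    p.name: p
    for p in [
        _preset("human_WT_soma", 0.18, 0.41, 1.660, **_IN_VITRO),
        _preset("human_MT_soma", 0.30, 0.74, 1.808, **_IN_VITRO),
        _preset("human_WT_process", 0.18, 0.41, 1.467, **_IN_VITRO),
        _preset("human_MT_process", 0.30, 0.74, 1.722, **_IN_VITRO),
        _preset("mouse_WT", 0.47, 1.64, 1.787, frame_interval_s=1.0, **_GCAMP),
        _preset("mouse_MT", 0.67, 2.01, 1.822, frame_interval_s=1.0, **_GCAMP),
        _preset("insitu_WT", 0.47, 0.47, 2.010, **_IN_VITRO),
        _preset("insitu_MT", 0.67, 0.59, 2.151, **_IN_VITRO),
        _preset("invivo_WT", 1.0, 1.44, 3.463, frame_interval_s=1 / 1.83, **_GCAMP),
        _preset("invivo_MT", 1.0, 2.15, 3.045, frame_interval_s=1 / 1.83, **_GCAMP),
    ]
}

# evoked-response peaks (F/F0) and kernel shapes per protocol/population
EVOKED_PRESETS: dict[str, dict] = {
    "atp_human_WT": dict(kind="atp", peak=4.04, rise_tau_s=2.0, decay_tau_s=20.0),
    "atp_human_MT": dict(kind="atp", peak=4.60, rise_tau_s=2.0, decay_tau_s=20.0),
    "atp_mouse_WT": dict(kind="atp", peak=6.54, rise_tau_s=2.0, decay_tau_s=20.0),
    "atp_mouse_MT": dict(kind="atp", peak=7.25, rise_tau_s=2.0, decay_tau_s=20.0),
    "glutamate_WT": dict(kind="glutamate", peak=2.22, rise_tau_s=2.0, decay_tau_s=20.0),
    "glutamate_MT": dict(kind="glutamate", peak=2.75, rise_tau_s=2.0, decay_tau_s=20.0),
    "soce_WT": dict(kind="soce", peak=2.41, rise_tau_s=8.0, decay_tau_s=60.0),
    "soce_MT": dict(kind="soce", peak=2.93, rise_tau_s=8.0, decay_tau_s=60.0),
}

# single-exponential ER-release (thapsigargin) rise time constants, seconds
TG_RISE_TAU_S = {"WT": 59.0, "MT": 54.0}

EPHYS_PRESETS: dict[str, EphysSpec] = {
    "sic_WT": EphysSpec(kind="sic", sic_rate_per_20min=1.50, event_amplitude_pa=50.0),
    "sic_MT": EphysSpec(kind="sic", sic_rate_per_20min=3.88, event_amplitude_pa=50.0),
    "epileptiform_WT": EphysSpec(
        kind="epileptiform",
        latency_min=6.5,
        discharge_rate_hz=3.5,
        event_duration_ms=621.0,
        event_amplitude_pa=279.0,
    ),
    "epileptiform_MT": EphysSpec(
        kind="epileptiform",
        latency_min=4.5,
        discharge_rate_hz=5.6,
        event_duration_ms=755.0,
        event_amplitude_pa=364.0,
    ),
}


def get_preset(name: str) -> PopulationPreset:
    try:
        return POPULATION_PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {', '.join(sorted(POPULATION_PRESETS))}"
        ) from None


def derive_seed(master_seed: int, *path: int) -> int:
    """Counter-based child seed, independent of generation order (< 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# calcium traces


def _doe_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials transient, unit continuous-time peak."""
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay_tau) - np.exp(-np.maximum(t, 0) / rise_tau), 0.0)
    tpk = rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    peak = math.exp(-tpk / decay_tau) - math.exp(-tpk / rise_tau)
    return k / peak


def _dead_time_rate(rate_hz: float, dead_s: float) -> float:
    """Candidate rate whose dead-time-thinned output rate equals rate_hz."""
    if rate_hz * dead_s >= 0.5:
        raise ValidationError(
            "event rate too high for the resolvability dead time (rate * decay/2 >= 0.5)"
        )
    return rate_hz / (1.0 - rate_hz * dead_s)


def _thin_dead_time(times: np.ndarray, dead_s: float) -> np.ndarray:
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= dead_s:
            kept.append(t)
            last = t
    return np.asarray(kept)


def make_trace(
    spec: TraceSpec,
    events: list[tuple[float, float]] | None = None,
    f0_scale: float = 1.0,
) -> tuple[NormalizedTrace, GroundTruth]:
    """Simulate one spontaneous-activity trace in F/F0 units (baseline 1).

    ``events`` forces explicit (onset_s, peak_f_over_f0) pairs instead of
    Poisson placement. ``f0_scale`` multiplies the whole trace to emulate raw
    fluorescence counts (the returned f0 equals this scale).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s / spec.frame_interval_s))
    t = np.arange(n) * spec.frame_interval_s

    phase = rng.uniform(0, 2 * np.pi)
    drift = (spec.drift_amplitude / 2.0) * np.sin(2 * np.pi * t / spec.duration_s + phase)

    if events is None:
        dead = spec.decay_tau_s / 2.0
        lam = spec.event_rate_per_min / 60.0
        if lam > 0:
            lam_adj = _dead_time_rate(lam, dead)
            count = rng.poisson(lam_adj * spec.duration_s)
            raw_times = np.sort(rng.uniform(0, spec.duration_s, count))
            onsets = _thin_dead_time(raw_times, dead)
        else:
            onsets = np.empty(0)
        if spec.peak_cv > 0 and len(onsets):
            m = spec.peak_f_over_f0 - 1.0
            s = spec.peak_cv * spec.peak_f_over_f0
            sigma2 = math.log(1.0 + (s / m) ** 2)
            mu = math.log(m) - sigma2 / 2.0
            excess = rng.lognormal(mu, math.sqrt(sigma2), len(onsets))
        else:
            excess = np.full(len(onsets), spec.peak_f_over_f0 - 1.0)
    else:
        pairs = sorted(events)
        onsets = np.asarray([p[0] for p in pairs], dtype=float)
        excess = np.asarray([p[1] - 1.0 for p in pairs], dtype=float)

    y = 1.0 + drift
    for onset, a in zip(onsets, excess):
        k = _doe_kernel(t - onset, spec.rise_tau_s, spec.decay_tau_s)
        kmax = k.max()
        if kmax > 0:
            y = y + a * k / kmax  # unit peak on this sampling grid
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, n)

    trace = NormalizedTrace(
        time_s=t,
        f_over_f0=f0_scale * y if f0_scale != 1.0 else y,
        f0=f0_scale,
        roi_id="roi_0",
    )
    gt = GroundTruth(event_times_s=onsets, true_peaks=1.0 + excess)
    return trace, gt


def make_population(
    preset: PopulationPreset | str,
    n_cells: int,
    seed: int,
    duration_s: float | None = None,
) -> tuple[list[NormalizedTrace], list[GroundTruth]]:
    """Simulate a field of cells: round(n * fraction) oscillating, rest silent.

    Per-cell seeds derive deterministically from the master seed and the cell
    index, so output is independent of generation order and bit-identical
    across calls.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    n_osc = int(round(n_cells * preset.fraction_oscillating))
    order = np.random.default_rng(derive_seed(seed, 0)).permutation(n_cells)
    oscillating = set(order[:n_osc].tolist())
    traces, truths = [], []
    for i in range(n_cells):
        spec = preset.oscillating_spec if i in oscillating else preset.silent_spec
        spec = replace(spec, seed=derive_seed(seed, 1, i))
        if duration_s is not None:
            spec = replace(spec, duration_s=duration_s)
        tr, gt = make_trace(spec)
        tr.roi_id = f"roi_{i}"
        tr.compartment = "soma"
        tr.cell_id = i
        gt.meta["oscillating"] = i in oscillating
        traces.append(tr)
        truths.append(gt)
    return traces, truths


# ---------------------------------------------------------------------------
# movies


def _render_cell(rng, center, shape):
    """Pixel masks for one cell: an elliptical soma plus 1-3 detached thin processes."""
    from skimage.draw import ellipse as draw_ellipse
    from skimage.draw import polygon as draw_polygon

    h, w = shape
    cy, cx = center
    a = rng.uniform(7.0, 9.0)  # semi-axes in px
    b = rng.uniform(5.0, 6.5)
    theta = rng.uniform(0, np.pi)
    soma_rr, soma_cc = draw_ellipse(cy, cx, a, b, shape=shape, rotation=theta)
    masks = [("soma", soma_rr, soma_cc)]
    gap = 3.0  # detachment keeps compartments as separate components
    for _ in range(rng.integers(1, 4)):
        ang = rng.uniform(0, 2 * np.pi)
        r0 = max(a, b) + gap
        length = rng.uniform(15.0, 28.0)
        width = 2.0
        d = np.array([np.cos(ang), np.sin(ang)])
        p = np.array([-np.sin(ang), np.cos(ang)]) * (width / 2.0)
        start = np.array([cy, cx]) + r0 * d
        end = start + length * d
        corners = np.array([start + p, start - p, end - p, end + p])
        rr, cc = draw_polygon(corners[:, 0], corners[:, 1], shape=shape)
        if rr.size >= 20:
            masks.append(("process", rr, cc))
    return masks


def make_movie(
    preset: PopulationPreset | str,
    n_cells: int,
    height: int = 128,
    width: int = 128,
    seed: int = 0,
    duration_s: float = 120.0,
    f0_cell: float = 100.0,
    f0_background: float = 10.0,
    pixel_noise_sd: float = 0.0,
    process_rate_scale: float = 1.0,
) -> tuple[Movie, MovieGroundTruth]:
    """Render a fluorescence movie of a synthetic cell population.

    Cells are placed on a jittered grid; overcrowded frames raise
    PlacementError. Pixels of a compartment carry ``f0_cell`` times that
    compartment's generative F/F0 trace (background pixels sit at
    ``f0_background``), plus optional per-pixel Gaussian noise.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    pitch = 52  # soma + processes footprint with margin
    rows, cols = height // pitch, width // pitch
    if rows * cols < n_cells:
        raise PlacementError(
            f"cannot place {n_cells} cells in a {height}x{width} frame without overlap "
            f"(capacity {rows * cols})"
        )
    rng = np.random.default_rng(derive_seed(seed, 2))
    slots = rng.permutation(rows * cols)[:n_cells]

    spec0 = preset.oscillating_spec
    dt = spec0.frame_interval_s
    n_frames = int(round(duration_s / dt))
    n_osc = int(round(n_cells * preset.fraction_oscillating))
    osc_order = np.random.default_rng(derive_seed(seed, 0)).permutation(n_cells)
    oscillating = set(osc_order[:n_osc].tolist())

    label_image = np.zeros((height, width), dtype=np.int32)
    data = np.full((n_frames, height, width), f0_background, dtype=np.float32)
    compartments: dict[int, str] = {}
    cell_ids: dict[int, int] = {}
    gtraces: dict[int, NormalizedTrace] = {}
    truths: dict[int, GroundTruth] = {}

    label = 0
    for i in range(n_cells):
        r, c = divmod(int(slots[i]), cols)
        cy = r * pitch + pitch / 2 + rng.uniform(-3, 3)
        cx = c * pitch + pitch / 2 + rng.uniform(-3, 3)
        base_spec = preset.oscillating_spec if i in oscillating else preset.silent_spec
        masks = _render_cell(rng, (cy, cx), (height, width))
        for j, (comp, rr, cc) in enumerate(masks):
            spec = replace(base_spec, duration_s=duration_s, seed=derive_seed(seed, 1, i, j))
            if comp == "process":
                spec = replace(
                    spec, event_rate_per_min=spec.event_rate_per_min * process_rate_scale
                )
            tr, gt = make_trace(spec)
            label += 1
            label_image[rr, cc] = label
            data[:, rr, cc] = f0_cell * tr.f_over_f0[:, None].astype(np.float32)
            compartments[label] = comp
            cell_ids[label] = i
            tr.roi_id = f"gt_{label}"
            tr.compartment = comp
            tr.cell_id = i
            gtraces[label] = tr
            truths[label] = gt
    if pixel_noise_sd > 0:
        data = data + rng.normal(0.0, pixel_noise_sd, data.shape).astype(np.float32)
        np.clip(data, 0.0, None, out=data)

    movie = Movie(data=data, frame_interval_s=dt)
    gt = MovieGroundTruth(
        label_image=label_image,
        compartments=compartments,
        cell_ids=cell_ids,
        traces=gtraces,
        event_truth=truths,
    )
    return movie, gt


# ---------------------------------------------------------------------------
# kinetics traces


def make_exp_rise(
    tau_s: float,
    amplitude: float = 1.0,
    baseline: float = 1.0,
    noise_sd: float = 0.0,
    duration_s: float = 300.0,
    frame_interval_s: float = 0.5,
    seed: int = 0,
) -> tuple[NormalizedTrace, GroundTruth]:
    """Single-exponential rise y(t) = baseline + amplitude*(1 - exp(-t/tau)) + noise.

    Emulates the slow cytosolic rise unmasked by SERCA-pump inhibition
    (thapsigargin), whose time constant reflects the passive ER leak rate.
    """
    if tau_s <= 0:
        raise ValidationError("tau_s must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / frame_interval_s))
    t = np.arange(n) * frame_interval_s
    y = baseline + amplitude * (1.0 - np.exp(-t / tau_s))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    trace = NormalizedTrace(time_s=t, f_over_f0=y)
    return trace, GroundTruth(true_tau_s=tau_s, meta={"amplitude": amplitude, "baseline": baseline})


def make_evoked_trace(
    peak: float,
    stim_time_s: float = 60.0,
    duration_s: float = 240.0,
    frame_interval_s: float = 0.5,
    rise_tau_s: float = 2.0,
    decay_tau_s: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[NormalizedTrace, GroundTruth]:
    """One agonist-evoked (or Ca-readdition) transient with true peak F/F0 ``peak``."""
    if peak <= 1.0:
        raise ValidationError("evoked peak must exceed the baseline of 1")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / frame_interval_s))
    t = np.arange(n) * frame_interval_s
    k = _doe_kernel(t - stim_time_s, rise_tau_s, decay_tau_s)
    kmax = k.max()
    y = 1.0 + (peak - 1.0) * (k / kmax if kmax > 0 else k)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, n)
    trace = NormalizedTrace(time_s=t, f_over_f0=y)
    gt = GroundTruth(
        event_times_s=[stim_time_s], true_peaks=[peak], meta={"stim_time_s": stim_time_s}
    )
    return trace, gt


# ---------------------------------------------------------------------------
# voltage-clamp recordings


@lru_cache(maxsize=32)
def _burst_width_for_duration(
    duration_s: float, f_hz: float, depth: float, fs: float
) -> float:
    """Envelope width whose above-half-peak span equals ``duration_s``.

    A burst is a half-sine envelope carrying rhythmic modulation at the
    discharge rate; the mapping from envelope width to measured duration
    (outermost crossings of half the burst maximum) has no closed form, so
    it is inverted numerically, averaging over the modulation phase.
    """
    phases = np.linspace(0, 2 * np.pi, 9)[:-1]

    def measured(width: float) -> float:
        t = np.arange(0.0, width, 1.0 / fs)
        env = np.sin(np.pi * t / width)
        durs = []
        for ph in phases:
            w = env * ((1 - depth) + depth * np.cos(2 * np.pi * f_hz * (t - width / 2) + ph))
            above = np.flatnonzero(w >= 0.5 * w.max())
            durs.append(t[above[-1]] - t[above[0]])
        return float(np.mean(durs))

    lo, hi = duration_s, 6.0 * duration_s + 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if measured(mid) < duration_s:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _burst_waveform(rng, width: float, f_hz: float, depth: float, fs: float) -> np.ndarray:
    t = np.arange(0.0, width, 1.0 / fs)
    env = np.sin(np.pi * t / width)
    ph = rng.uniform(0, 2 * np.pi)
    w = env * ((1 - depth) + depth * np.cos(2 * np.pi * f_hz * (t - width / 2) + ph))
    return w / w.max()


def make_ephys_trace(spec: EphysSpec) -> tuple[CurrentTrace, GroundTruth]:
    """Simulate a whole-cell voltage-clamp current recording.

    kind="sic": Poisson-timed slow inward currents (difference-of-exponentials
    with tens-of-ms rise and hundreds-of-ms decay), negative-going from the
    holding current, with a 2 s resolvability dead time.

    kind="epileptiform": quiescence until drug_onset_s + latency, then
    recurring discharge bursts. Each burst is an amplitude-modulated envelope
    whose above-half-peak duration equals event_duration_ms and whose
    internal discharge peaks recur at discharge_rate_hz.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_hz
    n = int(round(spec.duration_s * fs))
    current = np.full(n, spec.holding_current_pa, dtype=np.float64)

    if spec.kind == "sic":
        dead = 2.0
        lam = spec.sic_rate_per_20min / 1200.0
        if lam > 0:
            lam_adj = _dead_time_rate(lam, dead)
            count = rng.poisson(lam_adj * spec.duration_s)
            raw = np.sort(rng.uniform(0, spec.duration_s, count))
            onsets = _thin_dead_time(raw, dead)
        else:
            onsets = np.empty(0)
        rise, decay = spec.sic_rise_ms / 1000.0, spec.sic_decay_ms / 1000.0
        span = int(round((rise + 8 * decay) * fs))
        tk = np.arange(span) / fs
        kernel = _doe_kernel(tk, rise, decay)
        kernel /= kernel.max()
        for onset in onsets:
            i0 = int(round(onset * fs))
            i1 = min(i0 + span, n)
            current[i0:i1] -= spec.event_amplitude_pa * kernel[: i1 - i0]
        gt = GroundTruth(
            event_times_s=onsets,
            true_peaks=np.full(len(onsets), -spec.event_amplitude_pa),
            meta={"rate_per_20min": spec.sic_rate_per_20min},
        )
    else:  # epileptiform
        onset0 = spec.drug_onset_s + spec.latency_min * 60.0
        width = _burst_width_for_duration(
            spec.event_duration_ms / 1000.0, spec.discharge_rate_hz, spec.modulation_depth, fs
        )
        period = width + spec.inter_burst_gap_s
        stop = min(onset0 + spec.active_duration_s, spec.duration_s)
        onsets = []
        t0 = onset0
        while t0 + width <= stop:
            onsets.append(t0)
            t0 += period
        onsets = np.asarray(onsets)
        for onset in onsets:
            w = _burst_waveform(rng, width, spec.discharge_rate_hz, spec.modulation_depth, fs)
            i0 = int(round(onset * fs))
            i1 = min(i0 + len(w), n)
            current[i0:i1] -= spec.event_amplitude_pa * w[: i1 - i0]
        gt = GroundTruth(
            event_times_s=onsets,
            true_peaks=np.full(len(onsets), -spec.event_amplitude_pa),
            meta={
                "latency_min": spec.latency_min,
                "discharge_rate_hz": spec.discharge_rate_hz,
                "event_duration_ms": spec.event_duration_ms,
                "event_amplitude_pa": spec.event_amplitude_pa,
            },
        )

    if spec.noise_sd_pa > 0:
        current += rng.standard_normal(n, dtype=np.float32) * spec.noise_sd_pa
    if spec.clip_pa is not None:
        np.clip(current, -abs(spec.clip_pa), abs(spec.clip_pa), out=current)

    trace = CurrentTrace(
        time_s=np.arange(n) / fs,
        current_pa=current,
        sampling_hz=fs,
        holding_mv=-30.0 if spec.kind == "sic" else -70.0,
        drug_onset_s=spec.drug_onset_s if spec.kind == "epileptiform" else None,
    )
    return trace, gt
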