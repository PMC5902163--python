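# Methods

This note documents the models, estimators and numerical choices behind
`astroca`, in the spirit of a package methods appendix. It states no
empirical result that the test suite and `scripts/acceptance.py` do not
themselves compute.

## Trace model and normalization

A fluorescence trace is modelled as

    F(t) = F₀ · [ 1 + d(t) + Σᵢ aᵢ k(t − tᵢ) ] + ε(t)

with baseline fluorescence F₀, a slow drift d(t), transient amplitudes aᵢ
(peak ΔF/F₀), a fast-rise/slow-decay kernel k, and white Gaussian noise ε.
`normalize_f0` estimates F₀ as the 20th percentile of the raw trace — a
robust choice as long as transients occupy a minority of samples — and is
exactly scale-invariant. Raw fluorescence must be strictly positive;
non-positive values indicate a broken extraction, not data.

## Transient kernel

Transients use a difference of exponentials,
k(t) ∝ e^(−t/τ_d) − e^(−t/τ_r), which captures the fast-rise /
exponential-decay morphology of astrocyte somatic transients without
committing to an indicator biophysics model. Defaults are τ_r = 1 s,
τ_d = 4 s for Fluo-4 and τ_r = 1.5 s, τ_d = 6 s for GCaMP6s —
indicator-plausible values, adjustable per spec. Each event's kernel is
normalized to unit peak **on the trace's sampling grid**, so a recorded
ground-truth peak equals the sampled maximum exactly rather than the
continuous-time peak the grid never hits.

## Event placement and the resolvability dead time

Events are placed by a homogeneous Poisson process with a non-paralyzable
dead time of τ_d/2: two transients closer than half the decay constant are
not separable by any threshold detector, so the generator merges them into
a single ground-truth event. Because plain thinning would depress the
realized rate by ~λ·τ_d/2 (≈10% at 2 events/min), the candidate rate is
compensated to λ′ = λ / (1 − λ·τ_d/2), making the surviving ground-truth
rate equal the nominal rate (the dead-time-counter identity
R = λ′/(1 + λ′·d)). The generator refuses rates with λ·d ≥ 0.5, where the
compensation becomes unstable.

## Amplitude distribution

Preset amplitudes are means of the peak F/F₀ ratio (human in vitro 1.660
WT / 1.808 MT; mouse primary 1.787 / 1.822; in situ 2.010 / 2.151; in vivo
3.463 / 3.045) with a coefficient of variation of 0.3 on the ratio. The
excess over baseline, a = peak − 1, is drawn lognormal with mean
(peak − 1) and SD 0.3·peak: the lognormal keeps every peak above baseline
and keeps the population mean exact, whereas a truncated normal on the
ratio would inflate the mean by ~5% at this CV.

## Baseline noise estimation

The event detector thresholds at 3× the SD of the event-free baseline. The
default estimator is the MAD of the trace's second differences divided by
√6 (the second difference of white noise has variance 6σ²). Indicator
transients are nearly linear across adjacent frames, so they cancel in the
second difference and the estimate stays anchored to the noise floor even
when events and their shoulders cover half the recording — the regime of
the high-rate presets, where a naive masked-SD scheme inflates by 2× and
silently halves detector sensitivity. An iterative masking estimator
(`method="iterative_mask"`: mask samples above median + 2×scale, recompute,
repeat ≤ 5 rounds) is retained for sparse traces.

## Event detection

Candidate peaks are local maxima with value ≥ 1 + k·SD **and** prominence
≥ k·SD (k = 3 by default). Peaks closer than `min_separation_s` keep only
the larger (ties to the earlier peak, so output is deterministic); the
default separation is τ_d/2 — the same resolvability rule the generator
uses — i.e. 2 s for Fluo-4 and 3 s for GCaMP6s. An event must stay above
the detection threshold for at least two frame intervals (interpolated
crossings): isolated noise spikes cannot, genuine indicator transients do.
This width-at-threshold rule is what keeps the false-positive rate on
noise-only traces below 0.05 events/min; a width rule evaluated at half
prominence passes about half of all super-threshold noise maxima and
cannot meet that bound.

Event amplitude is the peak F/F₀ referenced to the local pre-onset level
(median of the ~2 s before the onset crossing; within a shared
supra-threshold excursion, the dip between peaks). For isolated events the
reference is 1 and the amplitude is simply the peak value; for an event
riding its predecessor's decay the reference removes the inherited tail,
which otherwise inflates mean amplitudes by ~10% at 2 events/min. FWHM is
measured at 1 + (amplitude − 1)/2 with linear interpolation; events
truncated at a recording border get NaN FWHM and are excluded from means,
not errors.

A cell is *oscillating* with ≥ 2 detected events per recording (one
crossing is not an oscillation); the threshold is configurable.

## Rolling-ball baseline correction

The baseline is the 1-D greyscale opening of the trace with a flat window
(default 60 s; at least 5× the indicator decay constant, warned
otherwise). Opening is anti-extensive, so the baseline never exceeds the
trace. The series is padded at both ends with its locally fitted linear
continuation before opening: with edge-replication padding a pure ramp
acquires a half-window kink at the boundary, while linear-extrapolation
padding leaves ramps exactly invariant, so the corrected ramp is flat to
numerical precision. The corrected trace is
`trace − baseline + median(baseline)`, preserving the overall level.
Whether correction is applied is automated: |linear slope| × duration >
0.1 F/F₀ triggers it (the original analyses made this call by eye).
In vitro traces are not low-pass filtered; the 0.5 Hz zero-phase
Butterworth filter is an in vivo preset (1.83 fps, Nyquist 0.915 Hz).

## Segmentation stand-in

The reference segmentation is deliberately simple and fully specified:
per-pixel temporal-median detrending → per-pixel SD over time → Gaussian
smoothing (σ = 0.5 px) → threshold at mean + 2·SD of the map → binary
closing and 1 px dilation (recovering edges the threshold erodes) →
connected components ≥ 20 px. It is invariant to affine intensity changes
of the movie. It finds *active* regions; a cell with no events in the
window is invisible to it by construction. Somata are components with
area ≥ 100 px and eccentricity ≤ 0.95 at the synthetic pixel scale;
everything else is a process, assigned to the nearest soma within 45 px.
The movie generator renders processes detached from their soma by a 3 px
gap so connected components keep the compartments separate — a geometric
stand-in for the manual morphology-based split used on real data.

## Evoked responses and kinetics

`evoked_peak` reads the maximum of the response window after a light
moving average (1 s default). The smoothing bounds the upward bias of a
max statistic over noisy samples; with noise SD 0.05 it keeps the bias
well under the 2% recovery tolerance while costing < 0.2% of a noiseless
peak. The SOCE variant uses a 2.5 s window because the influx transient is
slower and flatter-topped (more samples compete for the max; the wider
average is still negligible against the peak curvature). A response whose
peak stays below 1 + 3×(pre-stimulus SD) is flagged `responded=False`
rather than reported as a tiny peak.

`fit_exp_rise` fits y(t) = B + A·(1 − e^(−(t−t₀)/τ)) by least squares with
multi-start initialization (τ₀ ∈ {10, 30, 60, 120} s, lowest SSE kept),
requires a rising trend in the window (last-decile mean > first-decile
mean) and rejects fits with R² < 0.5. Noiseless recovery is exact to
< 0.1% over τ ∈ [20, 120] s; on noisy inputs the fits agree with a
brute-force SSE grid (τ scanned, A and B solved linearly) to within 1%.

ML204-sensitive current density is (mean pre − mean post)/C_m in pA/pF at
the holding potential, sign preserved (inward negative), antisymmetric
under swapping pre and post.

## Voltage-clamp event detection

**SICs.** The recording is boxcar-decimated to ~200 Hz (SIC kinetics are
tens to hundreds of ms; this also whitens fast noise), a 2 s rolling-median
baseline is subtracted, and negative deflections qualify at ≥ 20 pA with a
10–90% rise time ≥ 10 ms (excluding fast synaptic currents) and width
≥ 100 ms. Decay constants come from a per-event single-exponential fit
seeded at the 1/e crossing. The baseline-stability precheck uses a robust
(MAD) scale so that legitimate large events do not masquerade as drift.

**Epileptiform activity.** The four published metrics are only mutually
consistent if "events" are bursts and "frequency" is the discharge rate
inside them: a 755 ms event cannot repeat at 5.6 Hz. The generator
therefore emits bursts — a half-sine envelope carrying rhythmic modulation
at the discharge rate — whose envelope width is numerically calibrated
(bisection, phase-averaged) so the span above half the burst peak equals
the preset duration. The detector thresholds at 100 pA after drug onset,
merges segments across gaps < 400 ms (rhythmic discharges at 3–6 Hz dip
below threshold for up to one cycle, ~330 ms, so a 50 ms merge gap would
fragment every burst), and reports per event the above-half-peak duration
and peak amplitude. Latency is first-event onset minus drug onset. The
discharge rate is estimated from inter-peak intervals (number of intervals
over the first-to-last-peak span, summed across events): a plain
count-over-duration estimate is biased high because the event window edges
anchor at discharge peaks. Detection is robust to amplitude clipping
(truncated action-potential escapes), which the generator can emulate.

## Synthetic presets: what they do and do not emulate

Presets encode the published group parameters: oscillating fractions
(0.18/0.30 human, 0.47/0.67 mouse), soma rates (0.41/0.74, 1.64/2.01,
0.47/0.59 in situ, 1.44/2.15 in vivo events/min), amplitudes (Table above),
evoked peaks (ATP 4.04/4.60 human, 6.54/7.25 mouse; glutamate 2.22/2.75),
TG τ 59/54 s, SOCE 2.41/2.93, SIC 1.50/3.88 per 20 min, and epileptiform
6.5/4.5 min, 3.5/5.6 Hz, 621/755 ms, 279/364 pA. Frame intervals follow
the acquisition protocols (1 s GCaMP6s in vitro, 1/1.83 s in vivo), except
the human in vitro presets which default to 0.5 s: at the acquisition's
2 s/frame a 4 s-decay transient spans ~2 samples and a two-frame width
rule would reject genuine events, so the finer grid is used for synthetic
validation. The in vivo oscillating fraction is not published; the preset
uses 1.0 (all quantified in vivo ROIs were active). Default trace noise is
SD 0.05 F/F₀ and drift is off (drift is a capability exercised by the
baseline-correction tests, not a claimed property of the source data).
Indicator kinetics and noise levels are configuration defaults, not
claims. The generator does not model photobleaching, motion artifacts,
indicator saturation, or any mechanistic ER/SOCE biophysics — passing
recovery tests shows the estimators are unbiased under the stated noise
model, not that they are robust to artifacts the model omits.

Seeding uses counter-based derivation (`numpy SeedSequence` over
[master, index…]), so per-cell streams are independent of generation order
and every output is bit-reproducible from one master seed.

## Problem sizes

The always-run test suite uses scaled problem sizes chosen to keep each
statistical assertion at ≥ 3σ margins: 300-seed count-consistency checks,
60–120 traces per recovery rate, 200-trace evoked/SOCE means, 60 SIC and
6–30 epileptiform recordings (at 1 kHz sampling where kinetics allow).
The acceptance script runs the full published-scale versions (400/280
traces, 500 evoked, 200 fits per τ, 200 SIC recordings at 5 kHz, 100
epileptiform recordings).

## Known limitations

- Activity-based segmentation cannot find silent cells; oscillating
  fractions from movies are conditional on a recording window long enough
  for active cells to fire (P(no event) = e^(−rate·T)).
- At 1 frame/s with a 6 s decay (mouse GCaMP preset), events 3–6 s apart
  partly merge; detected frequency underestimates the generative rate by
  up to ~10% at 2 events/min. This is a resolution limit, not an estimator
  bias; the finer-sampled presets recover the same rates within a few
  percent.
- Detected amplitudes carry a small positive bias (~1–3%) from the max
  statistic on noise and from sub-threshold events being excluded; both
  are inherent to threshold detection and are quantified by the recovery
  tests.
- The Mann–Whitney test switches from the exact null to the tie-corrected
  normal approximation above n = 20 per group.
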