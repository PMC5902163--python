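# astroca

Quantification of astrocyte calcium activity and its electrophysiological
readouts, built for studies of disordered calcium homeostasis (e.g. in
MeCP2-deficient astrocytes), with a ground-truth synthetic data generator
so every stage can be validated by parameter recovery.

## What it measures

Astrocytes signal through cytosolic Ca²⁺ transients. Fluorescence from a
calcium indicator (Fluo-4, GCaMP6s, Rhod-2) is reported as the ratio
F/F₀ = F_t / F₀, where F₀ is a low percentile of the trace, so the
quiescent level sits near 1 and ΔF/F₀ = F/F₀ − 1. On these traces the
package computes the quantities such studies report:

- **Spontaneous events** — elevations exceeding the baseline by 3× its
  standard deviation, located as local maxima with matching prominence.
  Per event: onset, peak time, peak F/F₀ amplitude, FWHM. Per cell:
  frequency (events/min), mean amplitude, oscillating flag (≥ 2 events).
  Per field: fraction of oscillating cells. Somatic and process ROIs are
  summarized separately.
- **Drift handling** — rolling-ball baseline correction (1-D greyscale
  opening) for slowly drifting traces; zero-phase Butterworth low-pass
  (0.5 Hz preset) for noisy in vivo recordings at 1.83 fps.
- **Segmentation** — activity-based ROIs from a movie (temporal-SD map →
  smoothing → mean + k·SD threshold → connected components), classified
  into somata (large, round) and processes (small, elongated) and grouped
  into cells.
- **Evoked kinetics** — agonist-evoked peak amplitudes (ATP, glutamate);
  the slow cytosolic rise after SERCA inhibition by thapsigargin, fitted
  with y(t) = B + A·(1 − e^(−t/τ)) to estimate the ER leak time constant
  τ; store-operated Ca²⁺ entry (SOCE) as the peak on Ca²⁺ re-addition;
  and antagonist-sensitive (ML204) current density in pA/pF.
- **Neuronal currents** — slow inward currents (SICs; NMDA-receptor events
  driven by astrocytic glutamate) separated from fast synaptic currents by
  their 10–90% rise time, and bicuculline-induced epileptiform bursts
  quantified by latency, discharge rate, duration and amplitude.
- **Group statistics** — Student's t, exact Mann–Whitney U (n ≤ 20), and
  one-way ANOVA with Holm–Šidák post-hoc tests; means ± SEM.

Because raw recordings from such studies are rarely deposited, the
`astroca.synthetic` module generates traces, movies and voltage-clamp
recordings with known ground truth whose population statistics mirror the
published group values (e.g. 30% vs 18% oscillating cells, 0.74 vs 0.41
events/min, evoked peak 4.60, τ = 54 s vs 59 s, 3.88 SICs/20 min,
epileptiform 4.5 min / 5.6 Hz / 755 ms / 364 pA). These presets are the
basis of the test suite and the acceptance script.

## Worked example

Simulate wild-type and mutant fields of 100 cells, detect events, and
compare the per-cell frequencies of the oscillating cells:

```python
import numpy as np
from astroca.synthetic import make_population
from astroca.events import detect_events, summarize_cells, summarize_fields, DetectionParams
from astroca.stats import compare

params = DetectionParams(min_separation_s=2.0)
groups = {}
for preset in ("human_WT_soma", "human_MT_soma"):
    traces, _ = make_population(preset, n_cells=100, seed=42)
    events = [e for tr in traces for e in detect_events(tr, params)]
    cells = summarize_cells(events, traces)
    field = summarize_fields(cells)[0]
    osc = [c.frequency_per_min for c in cells if c.is_oscillating]
    groups[preset] = osc
    print(f"{preset}: {field.fraction_oscillating:.0%} oscillating, "
          f"frequency {np.mean(osc):.2f} +/- "
          f"{np.std(osc, ddof=1)/np.sqrt(len(osc)):.2f} /min "
          f"(n = {len(osc)} oscillating cells)")

res = compare(groups, test="mann_whitney", metric="frequency_per_min")
print(f"Mann-Whitney U = {res.statistic:.0f}, p = {res.p_value:.2e}")
```

Output:

```
human_WT_soma: 18% oscillating, frequency 0.44 +/- 0.04 /min (n = 18 oscillating cells)
human_MT_soma: 30% oscillating, frequency 0.79 +/- 0.05 /min (n = 30 oscillating cells)
Mann-Whitney U = 74, p = 2.71e-05
```

The detected fractions match the generative 18% / 30%, the recovered
frequencies sit within sampling error of the generative 0.41 and 0.74
events/min, and the genotype difference is highly significant at this
sample size — the same picture the real experiments give.

## Command line

Every stage is a subcommand of `astroca`: `simulate`, `segment`,
`preprocess`, `detect`, `kinetics`, `ephys`, `report`, and `all` (the full
simulate → detect → report pipeline from a YAML config, writing a manifest
with the config hash and seed for byte-for-byte reproducibility).

```bash
astroca simulate --preset human_MT_soma --n-cells 50 --seed 1 --out run/
astroca detect --traces run/traces.csv --out run/
astroca all --seed 1 --out full_run/
```

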