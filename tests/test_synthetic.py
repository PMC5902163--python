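"""Generator contracts: determinism, count/amplitude consistency, kernels."""

from dataclasses import replace

import numpy as np
import pytest

from astroca.errors import PlacementError, ValidationError
from astroca.synthetic import (
    EphysSpec,
    TraceSpec,
    derive_seed,
    get_preset,
    make_ephys_trace,
    make_exp_rise,
    make_movie,
    make_population,
    make_trace,
)


class TestMakeTrace:
    def test_silent_noiseless_cell_is_flat_unity(self):
        spec = TraceSpec(event_rate_per_min=0.0, noise_sd=0.0, drift_amplitude=0.0)
        trace, gt = make_trace(spec)
        assert np.allclose(trace.f_over_f0, 1.0)
        assert len(gt.event_times_s) == 0

    def test_forced_event_peak_equals_requested_amplitude(self):
        """The transient kernel is unit-peak on the sampling grid."""
        spec = TraceSpec(event_rate_per_min=0.0, noise_sd=0.0)
        trace, _ = make_trace(spec, events=[(100.0, 2.0)])
        assert trace.f_over_f0.max() == pytest.approx(2.0, abs=1e-12)
        peak_t = trace.time_s[np.argmax(trace.f_over_f0)]
        assert 100.0 < peak_t < 104.0  # fast rise, peak shortly after onset

    def test_event_count_matches_nominal_rate(self, master_seed):
        """Mean true count over many seeds within 3 SE of rate x duration."""
        rate = 0.74
        counts = [
            len(make_trace(TraceSpec(event_rate_per_min=rate, seed=derive_seed(master_seed, i)))[1].event_times_s)
            for i in range(300)
        ]
        expected = rate * 10.0
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se + 1e-9

    def test_true_peak_mean_matches_preset_amplitude(self, master_seed):
        spec = get_preset("human_WT_soma").oscillating_spec
        peaks = np.concatenate(
            [
                make_trace(replace(spec, seed=derive_seed(master_seed, 1, i)))[1].true_peaks
                for i in range(400)
            ]
        )
        se = peaks.std() / np.sqrt(len(peaks))
        assert abs(peaks.mean() - spec.peak_f_over_f0) < 3 * se

    def test_events_respect_resolvability_dead_time(self, master_seed):
        spec = TraceSpec(event_rate_per_min=2.15, seed=master_seed)
        _, gt = make_trace(spec)
        gaps = np.diff(gt.event_times_s)
        assert np.all(gaps >= spec.decay_tau_s / 2.0)

    def test_determinism(self, invitro_spec):
        spec = replace(invitro_spec, event_rate_per_min=1.0)
        t1, g1 = make_trace(spec)
        t2, g2 = make_trace(spec)
        assert np.array_equal(t1.f_over_f0, t2.f_over_f0)
        assert np.array_equal(g1.event_times_s, g2.event_times_s)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("duration_s", -1.0),
            ("frame_interval_s", 0.0),
            ("event_rate_per_min", -0.1),
            ("peak_f_over_f0", 0.9),
            ("noise_sd", -0.01),
        ],
    )
    def test_invalid_spec_names_the_field(self, field, value):
        with pytest.raises(ValidationError, match=field):
            TraceSpec(**{field: value})

    def test_decay_must_exceed_rise(self):
        with pytest.raises(ValidationError, match="decay_tau_s"):
            TraceSpec(rise_tau_s=5.0, decay_tau_s=4.0)


class TestMakePopulation:
    def test_oscillating_fraction_is_exact(self, master_seed):
        traces, truths = make_population("human_MT_soma", 100, seed=master_seed)
        n_osc = sum(gt.meta["oscillating"] for gt in truths)
        assert n_osc == 30
        assert len(traces) == 100

    def test_zero_fraction_gives_empty_ground_truths(self, master_seed):
        preset = get_preset("human_WT_soma")
        silent = replace(preset, fraction_oscillating=0.0)
        _, truths = make_population(silent, 20, seed=master_seed)
        assert all(len(gt.event_times_s) == 0 for gt in truths)

    def test_bit_identical_across_calls(self, master_seed):
        a, _ = make_population("mouse_WT", 10, seed=master_seed)
        b, _ = make_population("mouse_WT", 10, seed=master_seed)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.f_over_f0, tb.f_over_f0)

    def test_unknown_preset_error_lists_available(self):
        with pytest.raises(ValidationError, match="human_MT_soma"):
            make_population("no_such_preset", 5, seed=0)


class TestMakeMovie:
    def test_soma_event_does_not_leak_into_process_pixels(self, all_oscillating_preset):
        movie, gt = make_movie(
            all_oscillating_preset, 1, seed=11, duration_s=120.0, process_rate_scale=0.0
        )
        soma = [lb for lb, c in gt.compartments.items() if c == "soma"][0]
        procs = [lb for lb, c in gt.compartments.items() if c == "process"]
        soma_max = movie.data[:, gt.label_image == soma].max()
        assert soma_max > 100.0 * 1.2  # an event raised soma pixels above F0
        for lb in procs:
            assert movie.data[:, gt.label_image == lb].max() < 100.0 * 1.2

    def test_label_image_contains_all_cells(self, all_oscillating_preset):
        _, gt = make_movie(all_oscillating_preset, 10, height=160, width=280, seed=3)
        assert len(set(gt.cell_ids.values())) == 10

    def test_soma_mean_reproduces_generative_trace(self, all_oscillating_preset):
        movie, gt = make_movie(all_oscillating_preset, 2, seed=5, duration_s=120.0)
        for lb, tr in gt.traces.items():
            pix = movie.data[:, gt.label_image == lb].mean(axis=1)
            r = np.corrcoef(pix, tr.f_over_f0)[0, 1]
            assert r > 0.99

    def test_overcrowded_frame_raises(self, all_oscillating_preset):
        with pytest.raises(PlacementError):
            make_movie(all_oscillating_preset, 50, height=64, width=64, seed=0)


class TestMakeExpRise:
    def test_one_tau_point_on_noiseless_curve(self):
        tau = 54.0
        trace, gt = make_exp_rise(tau, amplitude=1.0, baseline=1.0, duration_s=300.0)
        i = np.argmin(np.abs(trace.time_s - tau))
        assert trace.f_over_f0[i] - 1.0 == pytest.approx(1.0 - np.exp(-1.0), abs=1e-2)
        assert gt.true_tau_s == tau

    def test_zero_amplitude_is_constant(self):
        trace, _ = make_exp_rise(59.0, amplitude=0.0, baseline=2.0)
        assert np.allclose(trace.f_over_f0, 2.0)

    def test_asymptote(self):
        tau, amp, dur = 59.0, 1.0, 600.0
        trace, _ = make_exp_rise(tau, amplitude=amp, baseline=1.0, duration_s=dur)
        # last sample sits at dur - dt
        gap = amp * np.exp(-(dur - 0.5) / tau)
        assert trace.f_over_f0[-1] == pytest.approx(2.0, abs=gap + 1e-12)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValidationError):
            make_exp_rise(0.0)


class TestMakeEphysTrace:
    def test_sic_count_matches_rate(self, master_seed):
        spec = EphysSpec(
            kind="sic", sic_rate_per_20min=3.88, duration_s=1200.0, sampling_hz=1000.0
        )
        counts = [
            len(make_ephys_trace(replace(spec, seed=derive_seed(master_seed, i)))[1].event_times_s)
            for i in range(200)
        ]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 3.88) < 3 * se + 1e-9

    def test_epileptiform_respects_latency(self):
        spec = EphysSpec(
            kind="epileptiform", latency_min=4.5, drug_onset_s=60.0,
            duration_s=600.0, sampling_hz=1000.0, seed=4,
        )
        _, gt = make_ephys_trace(spec)
        assert gt.event_times_s[0] >= 60.0 + 270.0

    def test_noise_only_is_flat_at_holding(self):
        spec = EphysSpec(
            kind="sic", sic_rate_per_20min=0.0, duration_s=60.0,
            sampling_hz=1000.0, holding_current_pa=-40.0, noise_sd_pa=5.0, seed=1,
        )
        trace, gt = make_ephys_trace(spec)
        assert len(gt.event_times_s) == 0
        assert trace.current_pa.mean() == pytest.approx(-40.0, abs=1.0)
        assert trace.current_pa.std() == pytest.approx(5.0, rel=0.1)

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValidationError, match="kind"):
            EphysSpec(kind="ramp")

    def test_clipping_applies(self):
        spec = EphysSpec(kind="epileptiform", duration_s=400.0, sampling_hz=1000.0,
                         latency_min=1.0, clip_pa=200.0, seed=2)
        trace, _ = make_ephys_trace(spec)
        assert trace.current_pa.min() >= -200.0
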