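"""Measurement operators against analytic and generator ground truth."""

import numpy as np
import pytest

from puffquant import kinetics as K
from puffquant import quantify, synth
from puffquant.trace import CURRENT_CLAMP, VOLTAGE_CLAMP, Trace
from tests.conftest import PUFF_ONSET

RATE = 50_000.0


def flat_trace(value=-65.0, duration=1.0, rate=RATE, mode=CURRENT_CLAMP):
    return Trace(np.full(int(duration * rate), value), rate, mode)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        assert quantify.detect_spikes(flat_trace(), threshold=-20.0).count == 0

    def test_refractory_merges_close_crossings(self):
        v = np.full(1000, -65.0)
        v[100:105] = 0.0  # first crossing
        v[130:135] = 0.0  # 0.6 ms later at 50 kHz
        tr = Trace(v, RATE, CURRENT_CLAMP)
        assert quantify.detect_spikes(tr, -20.0, refractory_ms=1.0).count == 1
        assert quantify.detect_spikes(tr, -20.0, refractory_ms=0.3).count == 2

    def test_voltage_clamp_rejected(self):
        with pytest.raises(ValueError, match="current-clamp"):
            quantify.detect_spikes(flat_trace(mode=VOLTAGE_CLAMP))

    def test_counts_match_generator_ground_truth(self, cc_noisy):
        det = quantify.detect_spikes(cc_noisy.trace, threshold=-10.0)
        assert det.count == cc_noisy.spike_times.size
        # detected times within one AP duration of the true times
        assert np.max(np.abs(det.spike_times - cc_noisy.spike_times)) < 0.002


class TestMedianFilter:
    def test_window_is_forced_odd(self):
        tr = flat_trace(duration=0.5)
        out = quantify.median_filter_envelope(tr, window_ms=80.0)
        assert out.meta["median_window_samples"] == 3999  # 4000 at 50 kHz, forced odd

    def test_constant_trace_unchanged(self):
        tr = flat_trace(value=-61.5, duration=0.3)
        out = quantify.median_filter_envelope(tr)
        assert np.array_equal(out.samples, tr.samples)
        assert out.n_samples == tr.n_samples

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter than the trace"):
            quantify.median_filter_envelope(flat_trace(duration=0.05), window_ms=80.0)

    def test_removes_spliced_spikes(self, cc_default):
        """Filtered spiking trace tracks the true noiseless envelope."""
        filt = quantify.median_filter_envelope(cc_default.trace)
        env = cc_default.envelope.samples
        peak = np.max(env - env[0])
        err = np.max(np.abs(filt.samples - env))
        assert err < 0.05 * peak

    def test_area_preserved_after_spike_removal(self, cc_default):
        filt = quantify.median_filter_envelope(cc_default.trace)
        base = quantify.estimate_baseline(filt, PUFF_ONSET)
        a_filt = quantify.response_area(filt, base, PUFF_ONSET, 2.0)
        env = cc_default.envelope
        a_env = quantify.response_area(env, env.samples[0], PUFF_ONSET, 2.0)
        assert a_filt == pytest.approx(a_env, rel=0.05)


class TestBaseline:
    def test_constant_trace(self):
        assert quantify.estimate_baseline(flat_trace(-65.0), onset=0.5) == -65.0

    def test_noise_standard_error_bound(self):
        # mean of 5000 samples of sd 0.3 noise: |error| < 3 SE in most seeds
        hits = 0
        for seed in range(20):
            noise = np.random.default_rng(seed).normal(0.0, 0.3, 25_000)
            tr = Trace(-65.0 + noise, RATE, CURRENT_CLAMP)
            b = quantify.estimate_baseline(tr, onset=0.4, window_s=0.1)
            if abs(b + 65.0) < 3.0 * 0.3 / np.sqrt(5000):
                hits += 1
        assert hits >= 19

    def test_linear_drift_gives_midpoint_value(self):
        t = np.arange(int(0.5 * RATE)) / RATE
        tr = Trace(-65.0 + 1.0 * t, RATE, CURRENT_CLAMP)  # 1 mV/s drift
        b = quantify.estimate_baseline(tr, onset=0.4, window_s=0.1, gap_s=0.0)
        assert b == pytest.approx(-65.0 + 1.0 * 0.35, abs=1e-4)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            quantify.estimate_baseline(flat_trace(duration=0.05), onset=0.04)


class TestAreaAndPeak:
    def test_zero_trace_zero_area(self):
        tr = flat_trace(0.0, mode=VOLTAGE_CLAMP)
        assert quantify.response_area(tr, 0.0, 0.1, 0.5) == 0.0
        assert quantify.peak_amplitude(tr, 0.0, 0.1, 0.5) == 0.0

    def test_rectangular_deflection(self):
        v = np.zeros(int(0.5 * RATE))
        i0, i1 = int(0.1 * RATE), int(0.2 * RATE)
        v[i0:i1] = 10.0
        tr = Trace(v, RATE, CURRENT_CLAMP)
        area = quantify.response_area(tr, 0.0, 0.05, 0.4)
        assert area == pytest.approx(1000.0, rel=1e-3)  # 10 mV x 100 ms

    def test_template_area_matches_component_weighted_integral(self, template_trace):
        """Charge conservation: numeric area vs closed-form truncated integral."""
        window = 2.0
        area = quantify.response_area(template_trace, 0.0, PUFF_ONSET, window)
        t_ms = window * 1000.0
        expected = 0.0
        for c in K.default_components():
            tmpl = c.template
            norm = K.deexp_norm(tmpl.tau_rise, tmpl.tau_decay)
            expected += (
                tmpl.amplitude
                / norm
                * (
                    tmpl.tau_decay * (1.0 - np.exp(-t_ms / tmpl.tau_decay))
                    - tmpl.tau_rise * (1.0 - np.exp(-t_ms / tmpl.tau_rise))
                )
            )
        assert area == pytest.approx(expected, rel=1e-3)

    def test_peak_time_matches_closed_form(self):
        tau_r, tau_d = 20.0, 300.0
        t_ms = np.arange(0.0, 2000.0, 1000.0 / RATE)
        tr = Trace(-100.0 * K.deexp_waveform(t_ms, tau_r, tau_d), RATE, VOLTAGE_CLAMP)
        sl = slice(0, tr.n_samples)
        ipk = np.argmax(np.abs(tr.samples))
        assert ipk / RATE * 1000.0 == pytest.approx(
            K.deexp_peak_time(tau_r, tau_d), abs=1000.0 / RATE
        )
        assert quantify.peak_amplitude(tr, 0.0, 0.0, 1.9) == pytest.approx(-100.0)

    def test_window_past_trace_end_rejected(self):
        with pytest.raises(ValueError, match="past the end"):
            quantify.response_area(flat_trace(duration=0.5), -65.0, 0.3, 1.0)


class TestRiseTime:
    def test_pure_exponential_rise(self):
        tau = 50.0  # ms
        t_ms = np.arange(0.0, 1000.0, 1000.0 / RATE)
        tr = Trace(10.0 * (1.0 - np.exp(-t_ms / tau)), RATE, CURRENT_CLAMP)
        rise = quantify.rise_time_10_90(tr, 0.0, 0.0, 0.9)
        assert rise == pytest.approx(tau * np.log(9.0), rel=2e-3)

    def test_instantaneous_step_is_subsample(self):
        v = np.zeros(5000)
        v[2500:] = 10.0
        tr = Trace(v, RATE, CURRENT_CLAMP)
        rise = quantify.rise_time_10_90(tr, 0.0, 0.0, 0.09)
        assert rise <= 1000.0 / RATE

    def test_peak_below_noise_floor_rejected(self):
        tr = flat_trace(0.001, duration=0.2, mode=VOLTAGE_CLAMP)
        with pytest.raises(ValueError, match="noise floor"):
            quantify.rise_time_10_90(tr, 0.0, 0.0, 0.15, noise_sd=0.5)


class TestDecayFit:
    def test_pure_exponential_recovered_exactly(self):
        tau = 100.0
        t_ms = np.arange(0.0, 1500.0, 1000.0 / RATE)
        tr = Trace(-200.0 * np.exp(-t_ms / tau), RATE, VOLTAGE_CLAMP)
        fit = quantify.fit_exponential_decay(tr, 0.0, 0.0, 1.4)
        assert fit.success
        assert fit.tau_ms == pytest.approx(tau, rel=1e-6)
        assert fit.amplitude == pytest.approx(-200.0, rel=1e-6)

    def test_noisy_recovery_monte_carlo(self):
        """tau = 400 ms + 5 pA noise: recovered within 5% in >= 19/20 seeds."""
        tau = 400.0
        t_ms = np.arange(0.0, 2000.0, 1000.0 / RATE)
        clean = -300.0 * np.exp(-t_ms / tau)
        ok = 0
        for seed in range(20):
            noise = np.random.default_rng(seed).normal(0.0, 5.0, clean.size)
            tr = Trace(clean + noise, RATE, VOLTAGE_CLAMP)
            fit = quantify.fit_exponential_decay(tr, 0.0, 0.0, 1.9, from_time=0.0)
            if abs(fit.tau_ms - tau) / tau < 0.05:
                ok += 1
        assert ok >= 19

    def test_too_few_samples_rejected(self):
        tr = Trace(np.linspace(1, 0, 50), 1000.0, VOLTAGE_CLAMP)
        with pytest.raises(ValueError, match="at least"):
            quantify.fit_exponential_decay(tr, 0.0, 0.0, 0.04)


class TestLinearity:
    @pytest.mark.parametrize("scale", [0.5, 2.0, -3.0])
    def test_scaling_trace_scales_area_and_peak_only(self, template_trace, scale):
        scaled = template_trace.with_samples(template_trace.samples * scale)
        a0 = quantify.response_area(template_trace, 0.0, PUFF_ONSET, 2.0)
        p0 = quantify.peak_amplitude(template_trace, 0.0, PUFF_ONSET, 2.0)
        r0 = quantify.rise_time_10_90(template_trace, 0.0, PUFF_ONSET, 2.0)
        assert quantify.response_area(scaled, 0.0, PUFF_ONSET, 2.0) == pytest.approx(
            scale * a0, rel=1e-9
        )
        assert quantify.peak_amplitude(scaled, 0.0, PUFF_ONSET, 2.0) == pytest.approx(
            scale * p0, rel=1e-9
        )
        assert quantify.rise_time_10_90(scaled, 0.0, PUFF_ONSET, 2.0) == pytest.approx(
            r0, rel=1e-9
        )
        tau0 = quantify.fit_exponential_decay(template_trace, 0.0, PUFF_ONSET, 2.0).tau_ms
        tau1 = quantify.fit_exponential_decay(scaled, 0.0, PUFF_ONSET, 2.0).tau_ms
        assert tau1 == pytest.approx(tau0, rel=1e-6)


class TestAverageCondition:
    def _measurement(self, cell="c1", cond="control", spikes=0, area=0.0, idx=1):
        return quantify.PuffResponseMeasurement(
            cell_id=cell,
            condition=cond,
            puff_index=idx,
            spike_count=spikes,
            area=area,
            area_sign=1,
            peak=0.0,
            rise_10_90=float("nan"),
            decay_tau=float("nan"),
            baseline=-65.0,
        )

    def test_identical_measurements_average_to_themselves(self):
        ms = [self._measurement(spikes=12, area=500.0, idx=i) for i in range(1, 6)]
        s = quantify.average_condition(ms)
        assert s.mean_spike_count == 12 and s.mean_area == 500.0 and s.n_puffs == 5

    def test_arithmetic_means(self):
        counts = [30, 35, 40, 38, 40]
        areas = [1.0, 2.0, 3.0, 4.0, 5.0]
        ms = [
            self._measurement(spikes=c, area=a, idx=i + 1)
            for i, (c, a) in enumerate(zip(counts, areas))
        ]
        s = quantify.average_condition(ms)
        assert s.mean_spike_count == pytest.approx(36.6)
        assert s.mean_area == pytest.approx(3.0)

    def test_mixed_cells_rejected(self):
        ms = [self._measurement(cell="c1"), self._measurement(cell="c2")]
        with pytest.raises(ValueError, match="mix"):
            quantify.average_condition(ms)
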