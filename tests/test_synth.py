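"""Generator contracts: scenarios, spiking ground truth, trains, populations."""

import numpy as np
import pytest

from puffquant import kinetics as K
from puffquant import quantify, synth
from puffquant.trace import PuffProtocol
from tests.conftest import PUFF_ONSET


class TestTemplateCurrent:
    def test_zero_amplitude_gives_flat_trace(self):
        comps = tuple(
            synth.ReceptorComponent(
                name=c.name,
                charge_fraction=c.charge_fraction,
                template=K.KineticTemplate(0.0, c.template.tau_rise, c.template.tau_decay),
            )
            for c in K.default_components()
        )
        tr = synth.make_template_current(components=comps)
        assert np.all(tr.samples == 0.0)

    def test_default_peak(self, template_trace):
        assert template_trace.samples.min() == pytest.approx(-329.0, rel=1e-9)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="1 kHz"):
            synth.make_template_current(rate=500.0)

    def test_duplicate_puff_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            PuffProtocol(puff_times=np.array([0.2, 0.2]))


class TestVoltageClampScenarios:
    def test_control_noiseless_equals_template(self, template_trace):
        vc = synth.synthesize_vc_recording(scenario="control", noise_sd=0.0, seed=1)
        assert np.array_equal(vc.samples, template_trace.samples)

    def test_sr16584_leaves_pure_fast_component(self):
        vc = synth.synthesize_vc_recording(scenario="SR16584", noise_sd=0.0)
        a7 = K.default_components()[1]
        expected = synth.make_template_current(components=(a7,))
        assert np.allclose(vc.samples, expected.samples, atol=1e-12)
        # residual is much smaller and faster than control
        assert abs(vc.samples.min()) < 0.5 * 329.0

    def test_unknown_scenario_rejected(self):
        with pytest.raises(KeyError, match="unknown scenario"):
            synth.synthesize_vc_recording(scenario="nonsense")

    def test_same_seed_bit_identical(self):
        a = synth.synthesize_vc_recording(seed=42)
        b = synth.synthesize_vc_recording(seed=42)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(
            a.samples, synth.synthesize_vc_recording(seed=43).samples
        )

    def test_block_monotonicity(self):
        """More block never increases the noiseless response magnitude."""
        areas = []
        for frac in (0.0, 0.3, 0.7, 1.0):
            sc = synth.PharmacologyScenario("x", {"alpha3beta4": frac})
            vc = synth.synthesize_vc_recording(scenario=sc, noise_sd=0.0)
            areas.append(abs(np.trapezoid(vc.samples, dx=vc.dt)))
        assert np.all(np.diff(areas) < 0)


class TestCurrentClamp:
    def test_zero_amplitude_rests_quietly(self):
        comps = tuple(
            synth.ReceptorComponent(
                name=c.name,
                charge_fraction=c.charge_fraction,
                template=K.KineticTemplate(0.0, c.template.tau_rise, c.template.tau_decay),
            )
            for c in K.default_components()
        )
        rec = synth.synthesize_cc_recording(components=comps, noise_sd=0.0)
        assert rec.spike_times.size == 0
        assert np.allclose(rec.trace.samples, -65.0, atol=1e-9)

    def test_default_response_fires_tens_of_spikes(self, cc_default):
        assert 15 <= cc_default.spike_times.size <= 80
        # depolarisation outlasts the stimulus by hundreds of ms
        env = cc_default.envelope.samples
        above = np.flatnonzero(env > -60.0)
        assert (above[-1] - above[0]) / cc_default.trace.rate > 0.8

    def test_ground_truth_equals_pacing_threshold_crossings(self, cc_default):
        """Oracle equivalence: spikes are exactly the internal state's crossings."""
        state = cc_default.pacing_state
        theta = -40.0
        crossings = np.flatnonzero((state[:-1] < theta) & (state[1:] >= theta)) + 1
        np.testing.assert_array_equal(
            crossings / cc_default.trace.rate, cc_default.spike_times
        )

    def test_mec_abolishes_spiking(self):
        rec = synth.synthesize_cc_recording(scenario="Mec", noise_sd=0.0)
        assert rec.spike_times.size == 0
        depol = rec.envelope.samples.max() + 65.0
        assert 0.0 < depol < 25.0  # small residual depolarisation

    def test_undersampled_rate_rejected(self):
        with pytest.raises(ValueError, match="undersamples"):
            synth.synthesize_cc_recording(rate=200.0)

    def test_same_seed_bit_identical(self):
        a = synth.synthesize_cc_recording(seed=5)
        b = synth.synthesize_cc_recording(seed=5)
        assert np.array_equal(a.trace.samples, b.trace.samples)
        assert np.array_equal(a.spike_times, b.spike_times)


class TestTrains:
    def test_single_puff_train_equals_single_puff(self):
        prof = synth.SummationProfile(d=2.0, r=0.5, concentration=30.0, frequency=10.0)
        train = PuffProtocol.train(1, 10.0, onset=PUFF_ONSET, concentration=30.0)
        rec_t = synth.simulate_train_response(train=train, profile=prof, noise_sd=0.0)
        single = synth.synthesize_cc_recording(
            protocol=train, noise_sd=0.0, duration=rec_t.trace.duration
        )
        np.testing.assert_allclose(rec_t.trace.samples, single.trace.samples)

    def test_d_equal_one_sums_linearly(self):
        """d = 1: every puff adds the same envelope area (10 puffs -> 10x)."""
        prof = synth.SummationProfile(d=1.0, r=0.5, concentration=30.0, frequency=10.0)

        def env_area(n):
            train = PuffProtocol.train(n, 10.0, onset=PUFF_ONSET, concentration=30.0)
            rec = synth.simulate_train_response(
                train=train, profile=prof, noise_sd=0.0, rate=25_000.0, tail_s=3.5
            )
            env = rec.envelope.samples
            return np.trapezoid(env - env[0], dx=rec.envelope.dt)

        assert env_area(10) / env_area(1) == pytest.approx(10.0, rel=0.02)

    def test_missing_profile_key_rejected(self):
        train = PuffProtocol.train(3, 7.0, concentration=55.0)
        with pytest.raises(KeyError, match="no summation profile"):
            synth.simulate_train_response(train=train)

    def test_puff_scales_follow_increment_law(self):
        prof = synth.SummationProfile(d=0.4, r=0.3, concentration=30.0, frequency=30.0)
        scales = prof.puff_scales(5)
        k = np.arange(1, 6)
        np.testing.assert_allclose(scales, 0.4 + 0.6 * 0.3 ** (k - 1))
        assert scales[0] == pytest.approx(1.0)  # first increment is the reference


class TestPopulation:
    def test_responder_expectation(self):
        neurons = synth.sample_population(n=126 * 20, seed=0)
        frac = np.mean([n.responder for n in neurons])
        # binomial SE at this n is ~0.006
        assert frac == pytest.approx(116.0 / 126.0, abs=0.02)

    def test_zero_sd_gives_identical_mean_neurons(self):
        pop = synth.PopulationParams(
            peak_pa_sd=0.0, tau_scale_sd=0.0, alpha7_fraction_sd=0.0,
            resting_sd=0.0, responder_probability=1.0,
        )
        neurons = synth.sample_population(pop, n=5, seed=3)
        ref = K.default_components()
        for n in neurons:
            assert n.components[0].template.amplitude == pytest.approx(
                ref[0].template.amplitude
            )
            assert n.membrane.resting_potential == -65.0

    def test_fixed_seed_reproducible(self):
        a = synth.sample_population(n=10, seed=11)
        b = synth.sample_population(n=10, seed=11)
        for x, y in zip(a, b):
            assert x == y

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            synth.PopulationParams(peak_pa_sd=-1.0)


class TestProfileCalibration:
    def test_unit_slope_recovers_linear_summation(self):
        profs = synth.calibrate_summation_profiles(
            {(30.0, 10.0): {"slope": 1.0}}, method="analytic"
        )
        p = profs[(30.0, 10.0)]
        assert p.d == pytest.approx(1.0, abs=1e-8)
        assert p.r == 0.5  # convention for the unidentified parameter

    def test_supralinear_target_needs_facilitation(self):
        profs = synth.calibrate_summation_profiles(
            {(100.0, 10.0): {"slope": 4.0}}, method="analytic"
        )
        assert profs[(100.0, 10.0)].d > 1.0

    def test_joint_slope_ratio_matches_grid_search_oracle(self):
        """Independent coarse grid search confirms the least-squares solution."""
        slope_t, ratio_t = 0.38, 3.8
        try:
            profs = synth.calibrate_summation_profiles(
                {(30.0, 30.0): {"slope": slope_t, "ratio": ratio_t}},
                method="analytic",
            )
        except synth.CalibrationError as err:
            profs = err.best
        p = profs[(30.0, 30.0)]
        assert p.d < 1.0  # depression

        def objective(d, r):
            s = synth.profile_slope(d, r)
            rho = synth.profile_normalized_area(d, r, 10)
            return (s / slope_t - 1.0) ** 2 + (rho / ratio_t - 1.0) ** 2

        best = min(
            objective(d, r)
            for d in np.linspace(0.05, 1.0, 60)
            for r in np.linspace(0.02, 0.95, 60)
        )
        assert objective(p.d, p.r) <= best + 1e-6

    def test_infeasible_targets_reported_not_clipped(self):
        with pytest.raises(synth.CalibrationError, match="infeasible"):
            synth.calibrate_summation_profiles(
                {(30.0, 30.0): {"slope": 0.38, "ratio": 3.8}}, method="analytic"
            )
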