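"""Generators: binomial-quantal samples, IPSP waveforms, dendrite stand-in."""

import math

import numpy as np
import pytest

from ngfc.errors import CalibrationError, ConfigurationError, GeometryError
from ngfc.summation import measure_kinetics
from ngfc.synthetic_data import (
    FAST_IPSP,
    IpspKinetics,
    QuantalModel,
    simulate_quantal,
    synth_ca_trials,
    synth_dendrite,
    synth_ipsp,
)


class TestSimulateQuantal:
    def test_deterministic_limit_all_sites_release(self):
        m = QuantalModel(n_sites=10, q=4.0, p_by_condition={"c": 1.0},
                         quantal_cv=0.0, noise_sd=0.0)
        amps = simulate_quantal(m, "c", 50, seed=0)
        assert np.allclose(amps, 40.0)

    def test_zero_release_probability_is_pure_noise(self):
        m = QuantalModel(n_sites=10, q=4.0, p_by_condition={"c": 0.0},
                         quantal_cv=0.0, noise_sd=2.0)
        amps = simulate_quantal(m, "c", 5000, seed=1)
        assert abs(amps.mean()) < 3 * 2.0 / math.sqrt(5000)

    def test_moments_match_binomial_quantal_model(self):
        m = QuantalModel(n_sites=11, q=3.9, p_by_condition={"c": 0.6},
                         quantal_cv=0.25, noise_sd=1.0)
        n = 10_000
        amps = simulate_quantal(m, "c", n, seed=2)
        se_mean = math.sqrt(m.variance("c") / n)
        assert abs(amps.mean() - m.mean("c")) < 3 * se_mean
        # variance agrees within 3 SE of the sample variance
        se_var = m.variance("c") * math.sqrt(2.0 / n)
        assert abs(amps.var() - m.variance("c")) < 3 * se_var

    def test_unknown_condition_rejected(self):
        m = QuantalModel(n_sites=2, q=1.0, p_by_condition={"c": 0.5})
        with pytest.raises(ConfigurationError):
            simulate_quantal(m, "nope", 5, seed=0)

    def test_seed_determinism(self):
        m = QuantalModel(n_sites=5, q=2.0, p_by_condition={"c": 0.5})
        a = simulate_quantal(m, "c", 100, seed=7)
        b = simulate_quantal(m, "c", 100, seed=7)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("bad", [
        dict(n_sites=0, q=1.0, p_by_condition={"c": 0.5}),
        dict(n_sites=3, q=-1.0, p_by_condition={"c": 0.5}),
        dict(n_sites=3, q=1.0, p_by_condition={"c": 1.5}),
    ])
    def test_invalid_models_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            QuantalModel(**bad)


class TestSynthIpsp:
    def test_zero_amplitude_gives_flat_trace(self):
        kin = IpspKinetics(amplitude=0.0, rise_time_10_90=5.0, half_width=20.0)
        tr = synth_ipsp(kin)
        assert np.all(tr.values == 0.0)

    def test_requested_peak_amplitude_matches(self):
        tr = synth_ipsp(FAST_IPSP)
        kin = measure_kinetics(tr, peak_window=60.0)
        assert kin.peak == pytest.approx(-2.19, rel=0.01)

    def test_kinetics_round_trip_within_five_percent(self):
        tr = synth_ipsp(FAST_IPSP, dt=0.05)
        kin = measure_kinetics(tr, peak_window=60.0)
        assert kin.rise_10_90 == pytest.approx(4.66, abs=0.23)
        assert kin.half_width == pytest.approx(19.29, rel=0.05)

    def test_slow_ipsp_kinetics_round_trip(self):
        kin_req = IpspKinetics(amplitude=-0.94, rise_time_10_90=86.95,
                               half_width=252.27, onset_latency=49.42)
        tr = synth_ipsp(kin_req, dt=1.0)
        kin = measure_kinetics(tr, peak_window=500.0)
        assert kin.rise_10_90 == pytest.approx(86.95, rel=0.05)
        assert kin.half_width == pytest.approx(252.27, rel=0.05)

    def test_unreachable_kinetics_signal_calibration_failure(self):
        bad = IpspKinetics(amplitude=-1.0, rise_time_10_90=30.0, half_width=20.0)
        with pytest.raises(CalibrationError):
            synth_ipsp(bad)

    def test_seed_determinism_with_noise(self):
        a = synth_ipsp(FAST_IPSP, seed=3, noise_sd=0.05)
        b = synth_ipsp(FAST_IPSP, seed=3, noise_sd=0.05)
        assert np.array_equal(a.values, b.values)


class TestSynthCaTrials:
    def test_trials_share_time_base(self):
        ts = synth_ca_trials(n_trials=5, seed=0)
        assert ts.n_trials == 5
        for tr in ts.trials[1:]:
            assert ts.trials[0].same_timebase(tr)

    def test_nonresponsive_set_has_no_transient(self):
        ts = synth_ca_trials(n_trials=10, responsive=False, noise_sd=0.0,
                             response_amplitude=0.0, seed=0)
        assert all(np.all(tr.values == 0) for tr in ts.trials)

    def test_invalid_trial_count_rejected(self):
        with pytest.raises(ConfigurationError):
            synth_ca_trials(n_trials=0, seed=0)


class TestSynthDendrite:
    def test_no_spines_all_faces_shaft(self):
        g = synth_dendrite(n_spines=0, seed=0)
        assert set(g.face_labels) == {"shaft"}
        assert g.n_spines == 0

    def test_cylinder_area_matches_closed_form(self):
        g = synth_dendrite(length=10.0, radius=0.5, n_spines=0, seed=0)
        expected = 2 * math.pi * 0.5 * 10.0 + 2 * math.pi * 0.5**2
        assert g.area() == pytest.approx(expected, rel=0.02)

    def test_spine_count_matches_request(self):
        g = synth_dendrite(n_spines=10, seed=1)
        assert g.n_spines == 10
        assert set(g.face_labels) == {"shaft", "spine"}

    def test_mesh_is_watertight(self):
        g = synth_dendrite(n_spines=4, seed=2)
        assert g.mesh.is_watertight

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(GeometryError):
            synth_dendrite(length=0.0)
        with pytest.raises(GeometryError):
            synth_dendrite(radius=-1.0)
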