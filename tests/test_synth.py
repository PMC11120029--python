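"""Synthetic-data generators: determinism, instrument model, noise realism."""

import numpy as np
import pytest

from clampkin.cleavage import CleavageParams, predict_readouts
from clampkin.melting import read_melting_csv, write_melting_csv
from clampkin.schemes import one_step_binding_scheme, two_step_binding_scheme
from clampkin.synth import (
    InstrumentModel,
    ResponseModel,
    read_traceset_csv,
    simulate_cleavage_timecourse,
    simulate_melting_curve,
    simulate_titration,
    simulate_trace_set,
    vant_hoff_duplex_fraction,
    write_traceset_csv,
)

FLAT_BASELINES = {
    260: ((0.8, 0.0), (1.0, 0.0)),
    270: ((0.7, 0.0), (0.9, 0.0)),
    330: ((0.02, 0.0), (0.02, 0.0)),
}


class TestTraceSets:
    def test_default_sampling_starts_at_dead_time(self):
        assert InstrumentModel().times().min() == pytest.approx(0.0014)

    def test_seed_determinism(self, clamp_response):
        scheme = two_step_binding_scheme(2e7, 100.0, 5.0, 20.0)
        a = simulate_trace_set(scheme, clamp_response, InstrumentModel(seed=7, n_samples=50))
        b = simulate_trace_set(scheme, clamp_response, InstrumentModel(seed=7, n_samples=50))
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.signal, tb.signal)

    def test_zero_response_is_flat_background(self):
        scheme = one_step_binding_scheme(1e6, 10.0)
        resp = ResponseModel(0.3, {})
        ts = simulate_trace_set(scheme, resp, InstrumentModel(noise_sd=0.0, n_samples=40))
        for tr in ts.traces:
            np.testing.assert_array_equal(tr.signal, np.full(40, 0.3))

    def test_pseudo_first_order_trace_is_single_exponential(self):
        scheme = one_step_binding_scheme(1e6, 10.0)
        resp = ResponseModel(0.0, {"ES": 1e6})
        instr = InstrumentModel(noise_sd=0.0, n_samples=300)
        ts = simulate_trace_set(scheme, resp, instr, design=((2e-6, 4e-8),))
        tr = ts.traces[0]
        kobs = 1e6 * 2e-6 + 10.0
        model = tr.signal[-1] * (1 - np.exp(-kobs * tr.times)) / (1 - np.exp(-kobs * tr.times[-1]))
        ss_res = np.sum((tr.signal - model) ** 2)
        ss_tot = np.sum((tr.signal - tr.signal.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.9999

    def test_nonpositive_design_rejected(self, clamp_response):
        scheme = one_step_binding_scheme(1e6, 10.0)
        with pytest.raises(ValueError):
            simulate_trace_set(scheme, clamp_response, InstrumentModel(), ((0.0, 1e-6),))

    def test_noise_sd_realised_within_ten_percent(self):
        scheme = one_step_binding_scheme(0.0, 0.0)
        resp = ResponseModel(1.0, {})
        instr = InstrumentModel(noise_sd=0.01, seed=3, n_samples=1500)
        ts = simulate_trace_set(scheme, resp, instr, design=((1e-6, 1e-6),))
        resid = ts.traces[0].signal - 1.0
        assert np.std(resid) == pytest.approx(0.01 * 1.0, rel=0.1)

    def test_csv_round_trip(self, tmp_path, clamp_response):
        scheme = two_step_binding_scheme(2e7, 100.0, 5.0, 20.0)
        ts = simulate_trace_set(scheme, clamp_response,
                                InstrumentModel(seed=1, n_samples=30))
        path = tmp_path / "traces.csv"
        write_traceset_csv(ts, path)
        back = read_traceset_csv(path)
        assert len(back.traces) == len(ts.traces)
        np.testing.assert_allclose(back.traces[2].signal, ts.traces[2].signal)
        assert back.instrument.dead_time == ts.instrument.dead_time
        assert back.truth["rate_constants"] == dict(scheme.rate_constants)


class TestMeltingCurves:
    def test_midpoint_absorbance_with_flat_baselines(self):
        curve = simulate_melting_curve(48.0, baselines=FLAT_BASELINES, noise_sd=0.0)
        i = np.where(curve.temperatures == 48.0)[0][0]
        assert curve.absorbance[260][i] == pytest.approx(0.9, abs=1e-6)

    def test_theta_monotone_and_saturating(self):
        T = np.arange(5, 95.5, 0.5)
        theta = vant_hoff_duplex_fraction(T, 48.0, -350e3, 2e-6)
        assert np.all(np.diff(theta) < 0)
        assert theta[0] > 0.999

    def test_theta_is_half_at_tm(self):
        assert vant_hoff_duplex_fraction(48.0, 48.0, -350e3, 2e-6) == pytest.approx(0.5, abs=1e-12)

    def test_reference_channel_has_no_transition(self):
        curve = simulate_melting_curve(48.0, noise_sd=0.0)
        a330 = curve.absorbance[330]
        # pure linear baseline: second differences vanish
        assert np.max(np.abs(np.diff(a330, 2))) < 1e-12

    def test_positive_dh_rejected(self):
        with pytest.raises(ValueError):
            simulate_melting_curve(48.0, dH=+350e3)

    def test_seed_determinism_and_csv_round_trip(self, tmp_path):
        a = simulate_melting_curve(40.0, noise_sd=0.002, seed=5)
        b = simulate_melting_curve(40.0, noise_sd=0.002, seed=5)
        np.testing.assert_array_equal(a.absorbance[260], b.absorbance[260])
        path = tmp_path / "melt.csv"
        write_melting_csv(a, path)
        back = read_melting_csv(path)
        np.testing.assert_allclose(back.absorbance[270], a.absorbance[270])


class TestTitration:
    def test_zero_added_gives_unit_signal(self):
        df = simulate_titration(1e-5, [0.0, 1e-5], 1e-7, 0.22, noise_sd=0.0)
        assert df["relative_fluorescence"].iloc[0] == pytest.approx(1.0)

    def test_tight_binding_equimolar_quench(self):
        df = simulate_titration(1e-5, [1e-5], 1e-15, 0.22, noise_sd=0.0)
        assert df["relative_fluorescence"].iloc[0] == pytest.approx(1 - 0.22, abs=1e-5)

    def test_excess_partner_plateaus(self):
        added = np.array([2e-5, 5e-5, 1e-4])
        df = simulate_titration(1e-5, added, 1e-7, 0.22, noise_sd=0.0)
        sig = df["relative_fluorescence"].to_numpy()
        assert np.max(np.abs(np.diff(sig))) < 0.005

    def test_g_partner_control_is_flat(self):
        df = simulate_titration(1e-5, np.linspace(0, 3e-5, 7), 1e-7, 0.22,
                                noise_sd=0.0, partner_is_oxoG=False)
        np.testing.assert_array_equal(df["relative_fluorescence"], np.ones(7))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_titration(1e-5, [-1e-6], 1e-7, 0.22)


class TestCleavageTimecourses:
    def test_zero_glycosylase_rate_gives_null_readouts(self):
        times = np.linspace(60, 7200, 8)
        for alkali in (True, False):
            tc = simulate_cleavage_timecourse(0.0, 0.0, 0.55, times, alkali, noise_sd=0.0)
            np.testing.assert_array_equal(tc.readout, np.zeros(8))

    def test_long_time_plateau_is_active_fraction(self):
        tc = simulate_cleavage_timecourse(1e-2, 1e-2, 0.55, [1e5, 2e5], True, noise_sd=0.0)
        np.testing.assert_allclose(tc.readout, 0.55, rtol=1e-6)

    def test_alkali_readout_dominates_untreated(self):
        times = np.linspace(30, 7200, 20)
        alk = simulate_cleavage_timecourse(2e-3, 2.5e-4, 0.55, times, True, noise_sd=0.0)
        unt = simulate_cleavage_timecourse(2e-3, 2.5e-4, 0.55, times, False, noise_sd=0.0)
        assert np.all(alk.readout >= unt.readout)

    def test_seed_determinism(self):
        times = np.linspace(60, 7200, 10)
        a = simulate_cleavage_timecourse(2e-3, 2.5e-4, 0.55, times, True, 0.02, seed=9)
        b = simulate_cleavage_timecourse(2e-3, 2.5e-4, 0.55, times, True, 0.02, seed=9)
        np.testing.assert_array_equal(a.readout, b.readout)
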