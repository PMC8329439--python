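"""Subthreshold measurements: RMP, R_in, sag, summation, impedance."""

import numpy as np
import pytest

from dgphys import sim
from dgphys.errors import MeasurementError
from dgphys.subthresh import (
    ImpedanceProfile,
    TimeSeriesTrace,
    impedance_metrics,
    impedance_profile,
    inductive_phase,
    input_resistance,
    measure_rmp,
    percentage_sag,
    summation_ratio,
    voltage_dependence,
)

from conftest import rc_step_response


def flat_trace(v=-75.0, total=400.0, dt=0.05, t_on=300.0):
    n = int(round(total / dt))
    return TimeSeriesTrace(dt=dt, voltage=np.full(n, v), t_on=t_on, t_off=total)


class TestRMP:
    def test_constant_baseline(self):
        assert measure_rmp(flat_trace(-75.0)) == -75.0

    def test_noisy_baseline_equals_arithmetic_mean(self):
        rng = np.random.default_rng(0)
        tr = flat_trace(-75.0)
        tr.voltage += rng.normal(0.0, 0.5, tr.n)
        i0, i1 = tr.index(tr.t_on - 100.0), tr.index(tr.t_on)
        assert measure_rmp(tr) == pytest.approx(np.mean(tr.voltage[i0:i1]), abs=1e-12)

    def test_short_baseline_rejected(self):
        with pytest.raises(MeasurementError):
            measure_rmp(flat_trace(t_on=50.0))


class TestInputResistance:
    def test_ohmic_cell_recovers_slope(self):
        resp = [(a, rc_step_response(150.0, 25.0, a)) for a in np.arange(-25.0, 26.0, 5.0)]
        assert input_resistance(resp) == pytest.approx(150.0, rel=1e-3)

    def test_matches_closed_form_least_squares(self):
        rng = np.random.default_rng(1)
        amps = np.arange(-25.0, 26.0, 5.0)
        resp = []
        for a in amps:
            tr = rc_step_response(150.0, 25.0, a)
            tr.voltage += rng.normal(0.0, 0.3, tr.n)
            resp.append((a, tr))
        # independent oracle: normal equations on the same deflections
        defl = []
        for a, tr in resp:
            base = np.mean(tr.voltage[tr.index(100.0) : tr.index(200.0)])
            ss = np.mean(tr.voltage[tr.index(800.0) : tr.index(900.0)])
            defl.append(ss - base)
        defl = np.asarray(defl)
        x = np.c_[amps, np.ones_like(amps)]
        slope = np.linalg.solve(x.T @ x, x.T @ defl)[0]
        assert input_resistance(resp) == pytest.approx(slope * 1000.0, rel=1e-9)

    def test_single_amplitude_rejected(self):
        resp = [(10.0, rc_step_response(150.0, 25.0, 10.0))] * 3
        with pytest.raises(ValueError):
            input_resistance(resp)

    def test_spiking_trace_rejected(self):
        tr = rc_step_response(150.0, 25.0, 25.0)
        tr.voltage[tr.index(400.0)] = 10.0  # spike contaminant
        with pytest.raises(MeasurementError):
            input_resistance([(25.0, tr), (-25.0, rc_step_response(150.0, 25.0, -25.0))])


class TestSag:
    def build_sag_trace(self, v_peak=-10.0, v_ss=-8.0, baseline=-75.0):
        dt, total, t_on, t_off = 0.05, 1100.0, 200.0, 900.0
        n = int(round(total / dt))
        t = np.arange(n) * dt
        v = np.full(n, baseline)
        on = (t >= t_on) & (t < t_off)
        # drop to the peak deflection, then settle at the steady state
        v[on & (t < t_on + 100.0)] = baseline + v_peak
        v[on & (t >= t_on + 100.0)] = baseline + v_ss
        return TimeSeriesTrace(dt=dt, voltage=v, t_on=t_on, t_off=t_off)

    def test_formula_on_constructed_deflections(self):
        tr = self.build_sag_trace(-10.0, -8.0)
        assert percentage_sag(tr) == pytest.approx(100.0 * (1 - (-8.0) / (-10.0)), rel=0.01)

    def test_passive_response_has_zero_sag(self):
        tr = rc_step_response(150.0, 25.0, -100.0)
        assert percentage_sag(tr) == pytest.approx(0.0, abs=0.5)

    def test_simulated_hcn_sag_matches_dense_grid_extrema(self, default_model):
        tr = sim.simulate(default_model, sim.sag_pulse_stimulus())
        # independent oracle: direct extremum scan of deflections
        base = np.mean(tr.voltage[tr.index(100.0) : tr.index(200.0)])
        seg = tr.voltage[tr.index(tr.t_on) : tr.index(tr.t_off)] - base
        v_peak = np.min(seg)
        v_ss = np.mean(tr.voltage[tr.index(tr.t_off - 100.0) : tr.index(tr.t_off)]) - base
        expected = 100.0 * (1 - v_ss / v_peak)
        assert percentage_sag(tr) == pytest.approx(expected, rel=1e-9)
        assert percentage_sag(tr) > 0

    def test_invariant_to_baseline_shift(self):
        tr = self.build_sag_trace()
        shifted = TimeSeriesTrace(
            dt=tr.dt, voltage=tr.voltage + 7.0, t_on=tr.t_on, t_off=tr.t_off
        )
        assert percentage_sag(shifted) == pytest.approx(percentage_sag(tr), rel=1e-9)

    def test_depolarizing_pulse_rejected(self):
        tr = rc_step_response(150.0, 25.0, 100.0)
        with pytest.raises(ValueError):
            percentage_sag(tr)


class TestSummation:
    def test_identical_nonoverlapping_epsps(self):
        dt, total, t_on = 0.05, 700.0, 200.0
        t = np.arange(int(round(total / dt))) * dt
        v = np.full(t.size, -75.0)
        for j in range(5):
            rel = t - (t_on + j * 50.0)
            v += np.where(rel > 0, 4.0 * (rel / 3.0) * np.exp(1 - rel / 3.0), 0.0)
        tr = TimeSeriesTrace(dt=dt, voltage=v, t_on=t_on, t_off=total)
        assert summation_ratio(tr) == pytest.approx(1.0, rel=1e-3)

    def test_passive_membrane_matches_convolution_oracle(self):
        # RC cell tau=30 ms driven by the alpha train; oracle = discrete
        # convolution of the current with the RC impulse response
        tau, r = 30.0, 150.0
        st = sim.alpha_train_stimulus(peak_pa=30.0)
        t = st.time
        kernel = np.exp(-t / tau) * (st.dt / tau) * (r / 1000.0)  # mV per pA
        v = -75.0 + np.convolve(st.samples, kernel)[: t.size]
        tr = TimeSeriesTrace(dt=st.dt, voltage=v, t_on=st.t_on, t_off=st.duration)
        base = -75.0
        amps = []
        for j in range(5):
            i0 = tr.index(st.t_on + j * 50.0)
            i1 = tr.index(st.t_on + (j + 1) * 50.0) if j < 4 else tr.n
            amps.append(np.max(tr.voltage[i0:i1]) - base)
        assert summation_ratio(tr) == pytest.approx(amps[-1] / amps[0], rel=1e-9)
        assert summation_ratio(tr) > 1.0  # tau=30 ms summates at 20 Hz

    def test_simulated_granule_cell_summates(self, default_record):
        assert default_record.s_alpha > 1.0

    def test_spike_contamination_rejected(self):
        tr = rc_step_response(150.0, 25.0, 10.0)
        tr.voltage[tr.index(300.0)] = 20.0
        with pytest.raises(MeasurementError):
            summation_ratio(tr)


class TestImpedance:
    def test_pure_resistor_identity(self):
        st = sim.chirp_stimulus(amplitude=30.0)
        v = -70.0 + st.samples * 100.0 / 1000.0  # V = R*I, R = 100 MOhm
        tr = TimeSeriesTrace(dt=st.dt, voltage=v, t_on=st.t_on, t_off=st.t_off)
        prof = impedance_profile(tr, st)
        np.testing.assert_allclose(prof.z_mag, 100.0, rtol=1e-6)
        np.testing.assert_allclose(prof.z_phase, 0.0, atol=1e-6)

    def test_rc_profile_matches_analytic_transfer_function(self):
        m = sim.default_model(
            g_leak=10.0, g_hcn=0.0, g_kir=0.0, g_nap=0.0, g_nat=0.0, g_kdr=0.0,
            c_m=100.0, e_leak=-70.0,
        )  # R = 100 MOhm, tau = 10 ms
        st = sim.chirp_stimulus(amplitude=30.0)
        tr = sim.simulate(m, st, v_init=-70.0)
        prof = impedance_profile(tr, st)
        w = 2 * np.pi * prof.freq * 10.0 / 1000.0
        np.testing.assert_allclose(prof.z_mag, 100.0 / np.sqrt(1 + w**2), rtol=0.03)

    def test_length_mismatch_rejected(self):
        st = sim.chirp_stimulus(amplitude=30.0)
        tr = TimeSeriesTrace(
            dt=st.dt, voltage=np.zeros(st.n - 5), t_on=st.t_on, t_off=st.t_off
        )
        with pytest.raises(ValueError):
            impedance_profile(tr, st)


class TestImpedanceMetrics:
    def test_constructed_bandpass_profile(self):
        freq = np.linspace(0.5, 15.0, 200)
        bump = np.exp(-0.5 * ((freq - 4.0) / 1.5) ** 2)
        # affine transform pinning z(0.5) = 100 and z(4 Hz) = 150 exactly
        z = 100.0 + 50.0 * (bump - bump[0]) / (np.exp(-0.5 * ((4.0 - 4.0) / 1.5) ** 2) - bump[0])
        prof = ImpedanceProfile(freq=freq, z_mag=z, z_phase=np.zeros_like(z))
        z_max, f_r, q = impedance_metrics(prof)
        assert f_r == pytest.approx(4.0, abs=0.1)
        assert q == pytest.approx(1.5, rel=1e-3)
        assert z_max == pytest.approx(z.max())

    def test_monotonically_decreasing_profile_is_low_pass(self):
        freq = np.linspace(0.5, 15.0, 200)
        z = 100.0 / np.sqrt(1 + (2 * np.pi * freq * 0.01) ** 2)
        prof = ImpedanceProfile(freq=freq, z_mag=z, z_phase=np.zeros_like(z))
        z_max, f_r, q = impedance_metrics(prof)
        assert f_r == freq[0]
        assert q == pytest.approx(1.0, abs=1e-9)

    def test_band_must_include_half_hertz(self):
        prof = ImpedanceProfile(
            freq=np.linspace(1.0, 15.0, 50),
            z_mag=np.ones(50),
            z_phase=np.zeros(50),
            band=(1.0, 15.0),
        )
        with pytest.raises(ValueError):
            impedance_metrics(prof)


class TestInductivePhase:
    def test_all_negative_phase_gives_zero(self):
        freq = np.linspace(0.5, 15.0, 100)
        prof = ImpedanceProfile(freq=freq, z_mag=np.ones(100), z_phase=-0.3 * np.ones(100))
        assert inductive_phase(prof) == 0.0

    def test_rectangular_inductive_region(self):
        freq = np.linspace(0.0, 5.0, 5001)
        phase = np.where((freq >= 1.0) & (freq <= 3.0), 0.1, -0.1)
        prof = ImpedanceProfile(freq=freq, z_mag=np.ones(freq.size), z_phase=phase, band=(0.0, 5.0))
        assert inductive_phase(prof) == pytest.approx(0.2, rel=1e-2)


class TestVoltageDependence:
    def test_passive_cell_is_voltage_independent(self):
        m = sim.default_model(
            g_leak=1000.0 / 150.0, g_hcn=0.0, g_kir=0.0, g_nap=0.0, g_nat=0.0,
            g_kdr=0.0, c_m=200.0, e_leak=-75.0,
        )
        r_map, z_map = voltage_dependence(m, (-85.0, -75.0, -65.0))
        rins = list(r_map.values())
        assert max(rins) / min(rins) == pytest.approx(1.0, abs=0.01)
        # single-pulse estimator agrees with the known resistance
        assert rins[0] == pytest.approx(150.0, rel=0.01)

    def test_hcn_block_effect_is_larger_when_hyperpolarized(self, default_model):
        blocked = sim.apply_blockade(default_model, sim.BlockadeSpec("HCN", 1.0))
        r_before, _ = voltage_dependence(default_model, (-85.0, -65.0))
        r_after, _ = voltage_dependence(blocked, (-85.0, -65.0))
        gain_hyper = r_after[-85.0] / r_before[-85.0]
        gain_depol = r_after[-65.0] / r_before[-65.0]
        assert gain_hyper > gain_depol > 1.0


class TestPaddingInvariance:
    def test_measurements_ignore_post_stimulus_padding(self):
        tr = rc_step_response(150.0, 25.0, -100.0)
        padded = TimeSeriesTrace(
            dt=tr.dt,
            voltage=np.concatenate([tr.voltage, np.full(4000, tr.voltage[-1])]),
            t_on=tr.t_on,
            t_off=tr.t_off,
        )
        assert percentage_sag(padded) == pytest.approx(percentage_sag(tr), rel=1e-12)
        assert measure_rmp(padded) == measure_rmp(tr)
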