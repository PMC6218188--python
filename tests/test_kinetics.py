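"""Kinetics analyses: LTI sinusoid prediction, temporal-shift estimation,
integration time, zero crossings and membrane-τ fitting."""

import numpy as np
import pytest

import rodpath as rp
from rodpath import kinetics
from rodpath.errors import FitError
from rodpath.traces import StimulusSpec, Trace


def _kernel(values, dt=1e-3):
    return Trace(t0=0.0, dt=dt, values=np.asarray(values, float), units="pA")


def _conv_oracle(kernel: Trace, f: float, n_periods=12):
    """Independent time-domain oracle: convolve the kernel with a long
    sinusoid and fit amplitude/phase on the steady-state tail."""
    dt = kernel.dt
    T = 1.0 / f
    t = np.arange(0.0, n_periods * T + kernel.dt * len(kernel.values), dt)
    drive = np.sin(2 * np.pi * f * t)
    y = np.convolve(drive, kernel.values)[: len(t)] * dt
    # steady state: an exact integer number of trailing periods, projected
    # on the quadrature pair (leakage-free for integer periods)
    P = int(round(T / dt))
    tt, yy = t[-4 * P:], y[-4 * P:]
    c = 2 / len(tt) * np.sum(yy * np.cos(2 * np.pi * f * tt))
    s = 2 / len(tt) * np.sum(yy * np.sin(2 * np.pi * f * tt))
    return np.hypot(c, s), np.arctan2(c, s)


class TestPredictSinusoidResponse:
    def test_delta_kernel_identity(self):
        dt = 1e-3
        v = np.zeros(1200)
        v[0] = 1.0 / dt
        for f in (1.0, 4.0, 15.0):
            amp, phase, _ = rp.predict_sinusoid_response(_kernel(v), f)
            assert amp == pytest.approx(1.0, rel=1e-9)
            assert phase == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("tau,f", [(0.02, 4.0), (0.05, 2.0), (0.01, 10.0)])
    def test_exponential_kernel_phase_closed_form(self, tau, f):
        dt = 1e-5
        t = np.arange(0.0, 1.0, dt)
        k = np.exp(-t / tau) / tau
        amp, phase, _ = rp.predict_sinusoid_response(_kernel(k, dt), f)
        assert phase == pytest.approx(-np.arctan(2 * np.pi * f * tau), abs=1e-3)
        assert amp == pytest.approx(1 / np.hypot(1, 2 * np.pi * f * tau), rel=1e-3)

    def test_time_shift_theorem(self):
        dt = 1e-3
        t = np.arange(0.0, 1.5, dt)
        k = np.exp(-t / 0.03) / 0.03
        shifted = np.concatenate([np.zeros(50), k[:-50]])  # 50 ms delay
        f = 4.0
        _, p0, _ = rp.predict_sinusoid_response(_kernel(k), f)
        _, p1, _ = rp.predict_sinusoid_response(_kernel(shifted), f)
        dphi = (p1 - p0 + np.pi) % (2 * np.pi) - np.pi
        assert dphi == pytest.approx(-2 * np.pi * f * 0.050, abs=1e-6)

    def test_agrees_with_convolution_oracle(self):
        """LTI equivalence: DFT-based and time-domain routes agree to 1e-6."""
        dt = 1e-3
        t = np.arange(0.0, 1.75, dt)
        k = t**3 * np.exp(-t / 0.02)
        k /= np.max(k)
        kernel = _kernel(k)
        for f in (2.0, 4.0, 8.0):
            amp, phase, _ = rp.predict_sinusoid_response(kernel, f)
            amp_o, phase_o = _conv_oracle(kernel, f)
            assert abs(amp - amp_o) / amp_o < 1e-6
            dphi = (phase - phase_o + np.pi) % (2 * np.pi) - np.pi
            assert abs(dphi) < 1e-6

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            rp.predict_sinusoid_response(_kernel(np.ones(2000)), 600.0)

    def test_kernel_shorter_than_period_rejected(self):
        with pytest.raises(ValueError):
            rp.predict_sinusoid_response(_kernel(np.ones(100)), 4.0)


class TestTemporalShift:
    def _sins(self, d_ms, f=4.0, dur=2.0, dt=1e-3, noise=0.0, rng=None):
        t = np.arange(0.0, dur, dt)
        b = np.sin(2 * np.pi * f * t)
        a = np.sin(2 * np.pi * f * (t - d_ms / 1000.0))
        if rng is not None and noise > 0:
            a = a + rng.normal(0, noise, len(t))
            b = b + rng.normal(0, noise, len(t))
        return Trace(0, dt, a, "pA"), Trace(0, dt, b, "pA")

    def test_identical_traces_zero_shift(self):
        a, _ = self._sins(0.0)
        assert rp.temporal_shift(a, a, frequency=4.0) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_25ms_shift(self):
        a, b = self._sins(25.0)
        assert rp.temporal_shift(a, b, frequency=4.0) == pytest.approx(25.0, abs=0.05)

    def test_antisymmetric(self):
        a, b = self._sins(40.0)
        s_ab = rp.temporal_shift(a, b, frequency=4.0)
        s_ba = rp.temporal_shift(b, a, frequency=4.0)
        assert s_ab == pytest.approx(-s_ba, abs=1e-6)

    def test_amplitude_scaling_invariance(self):
        a, b = self._sins(25.0)
        a5 = Trace(a.t0, a.dt, 5.0 * a.values, a.units)
        assert rp.temporal_shift(a5, b, frequency=4.0) == \
            pytest.approx(rp.temporal_shift(a, b, frequency=4.0), abs=1e-9)

    def test_noisy_mean_within_1ms(self):
        rng = np.random.default_rng(4)
        shifts = []
        for _ in range(50):
            a, b = self._sins(25.0, noise=0.1, rng=rng)  # SNR 10
            shifts.append(rp.temporal_shift(a, b, frequency=4.0))
        assert abs(np.mean(shifts) - 25.0) < 1.0

    def test_all_zero_trace_rejected(self):
        z = Trace(0, 1e-3, np.zeros(1000), "pA")
        a, _ = self._sins(0.0)
        with pytest.raises(ValueError):
            rp.temporal_shift(z, a)

    def test_periodic_wrap_smallest_magnitude(self):
        a, b = self._sins(230.0)  # 4 Hz: period 250 ms, so reported as -20 ms
        assert rp.temporal_shift(a, b, frequency=4.0) == pytest.approx(-20.0, abs=0.1)

    def test_phase_estimator_cross_check(self, sinusoid_store):
        trs = {tr.stimulus.background: tr.window(1.0, 3.0)
               for tr in sinusoid_store if tr.stimulus.background in (0.2, 100.0)}
        xc = rp.temporal_shift(trs[0.2], trs[100.0], frequency=4.0)
        ph = kinetics.phase_shift(trs[0.2], trs[100.0], 4.0)
        assert abs(xc - ph) < 2.0


class TestShiftCurve:
    def test_full_cascade_total_shift_about_100ms(self, sinusoid_store):
        curve = rp.shift_curve(sinusoid_store, "On_parasol_exc", 4.0)
        assert curve.shifts_ms[0] == 0.0
        assert np.all(np.diff(curve.shifts_ms) > 0)
        assert curve.total_shift_ms == pytest.approx(100.0, abs=5.0)

    def test_photocurrent_stage_is_40pct_of_full(self):
        from rodpath.reproduce import run_shift_pair
        full, photo = run_shift_pair()
        assert 100 * photo / full == pytest.approx(40.0, abs=5.0)

    def test_stage_shifts_add_up(self):
        """Group delays of cascaded stages are additive: the voltage-stage
        shift plus the phototransduction shift matches the full-cascade
        shift within 5 ms."""
        from rodpath.reproduce import _flash_kernel_trace, run_shift_pair
        d = {}
        for stage in ("photocurrent", "voltage"):
            lo = kinetics.phase_delay_ms(_flash_kernel_trace(0.2, "primate", stage), 4.0)
            hi = kinetics.phase_delay_ms(_flash_kernel_trace(100.0, "primate", stage), 4.0)
            d[stage] = lo - hi
        full, photo = run_shift_pair()
        assert d["photocurrent"] == pytest.approx(photo, abs=0.5)
        assert d["voltage"] == pytest.approx(full, abs=5.0)  # voltage = photo + membrane

    def test_single_background_rejected(self):
        proto = {"master_seed": 0, "cell_types": ["On_parasol_exc"],
                 "backgrounds": [1.0], "noise_frac": 0.0, "cell_variability": False,
                 "stimulus": {"kind": "sinusoid", "frequency_hz": 4.0,
                              "pre_ms": 500, "stim_ms": 2000, "tail_ms": 0}}
        store = rp.generate_dataset(proto)
        with pytest.raises(ValueError):
            rp.shift_curve(store, "On_parasol_exc", 4.0)


class TestIntegrationTime:
    def test_rectangular_pulse(self):
        dt = 1e-4
        v = np.zeros(5000)
        v[:2000] = 3.0  # 200 ms rectangle, no zero crossing
        assert rp.integration_time(Trace(0, dt, v, "pA")) == pytest.approx(200.0, rel=1e-3)

    def test_half_sine_analytic_value(self):
        dt = 1e-5
        D = 0.3
        t = np.arange(0.0, D, dt)
        v = np.sin(np.pi * t / D)
        assert rp.integration_time(Trace(0, dt, v, "pA")) == \
            pytest.approx(2 * D / np.pi * 1000, rel=1e-3)

    def test_amplitude_scale_invariance(self):
        dt = 1e-4
        t = np.arange(0.0, 1.0, dt)
        v = t * np.exp(-t / 0.05)
        it1 = rp.integration_time(Trace(0, dt, v, "pA"))
        it2 = rp.integration_time(Trace(0, dt, 7.3 * v, "pA"))
        assert it1 == pytest.approx(it2, rel=1e-12)

    def test_time_dilation_equivariance(self):
        dt = 1e-4
        t = np.arange(0.0, 2.0, dt)
        alpha = 2.5
        v1 = t * np.exp(-t / 0.05)
        v2 = (t / alpha) * np.exp(-t / (alpha * 0.05))
        it1 = rp.integration_time(Trace(0, dt, v1, "pA"))
        it2 = rp.integration_time(Trace(0, dt, v2, "pA"))
        assert it2 / it1 == pytest.approx(alpha, rel=1e-3)

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(ValueError):
            rp.integration_time(Trace(0, 1e-3, -np.ones(100), "pA"))

    def test_identical_kernels_unit_ratio(self):
        proto = {"master_seed": 0, "cell_types": ["On_parasol_exc"],
                 "backgrounds": [5.0], "noise_frac": 0.0, "cell_variability": False,
                 "stimulus": {"kind": "flash", "pre_ms": 200, "stim_ms": 1500,
                              "tail_ms": 0}}
        store = rp.generate_dataset(proto)
        assert rp.integration_time_ratio(store, "On_parasol_exc", 5.0, 5.0) == \
            pytest.approx(1.0, rel=1e-12)

    def test_synthetic_low_high_ratio_about_3(self):
        from rodpath.reproduce import run_integration_ratio
        assert run_integration_ratio() == pytest.approx(3.0, rel=0.02)


class TestZeroCrossing:
    def test_sine_crosses_at_half_period(self):
        dt = 1e-4
        T = 0.4
        t = np.arange(0.0, T, dt)
        v = np.sin(2 * np.pi * t / T)
        assert rp.zero_crossing_time(Trace(0, dt, v, "pA")) == \
            pytest.approx(T / 2 * 1000, abs=0.2)

    def test_monophasic_decay_has_no_crossing(self):
        dt = 1e-3
        t = np.arange(0.0, 1.0, dt)
        assert rp.zero_crossing_time(Trace(0, dt, np.exp(-t / 0.1), "pA")) is None

    def test_bandpass_crossing_moves_earlier_with_faster_tau(self):
        dt = 1e-4
        t = np.arange(0.0, 1.0, dt)
        def crossing(tau):
            v = np.exp(-t / tau) - 0.5 * np.exp(-t / (2 * tau))
            return rp.zero_crossing_time(Trace(0, dt, v, "pA"))
        # analytic crossing: t = 2·tau·ln 2
        assert crossing(0.05) == pytest.approx(2 * 0.05 * np.log(2) * 1000, rel=1e-2)
        assert crossing(0.025) == pytest.approx(crossing(0.05) / 2, rel=1e-2)


class TestFitMembraneTau:
    def test_pure_exponential(self):
        dt = 1e-4
        t = np.arange(0.0, 0.3, dt)
        v = 4.0 * np.exp(-t / 0.020)
        assert rp.fit_membrane_tau(Trace(0, dt, v, "mV")) == pytest.approx(20.0, rel=1e-4)

    def test_noisy_recovery_within_10pct(self):
        rng = np.random.default_rng(9)
        dt = 1e-4
        t = np.arange(0.0, 0.3, dt)
        v = 4.0 * np.exp(-t / 0.020) + 0.05 * 4.0 * rng.standard_normal(len(t))
        assert rp.fit_membrane_tau(Trace(0, dt, v, "mV")) == pytest.approx(20.0, rel=0.10)

    def test_voltage_dependence_recovered_from_simulation(self, primate):
        dt = 1e-4
        x = np.zeros(15000)
        x[:10] = 5.0
        tau44 = rp.fit_membrane_tau(rp.membrane_filter(Trace(0, dt, x, "pA"), -44.0, primate))
        tau53 = rp.fit_membrane_tau(rp.membrane_filter(Trace(0, dt, x, "pA"), -53.0, primate))
        assert tau44 / tau53 == pytest.approx(2.0, rel=0.02)

    def test_non_decaying_tail_rejected(self):
        # pre-pulse baseline at zero, then a ramp that never relaxes
        v = np.concatenate([np.zeros(100), np.linspace(0, 1, 500)])
        with pytest.raises(FitError):
            rp.fit_membrane_tau(Trace(-0.1, 1e-3, v, "mV"))
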