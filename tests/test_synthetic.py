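"""Generative model: steady-state anchors, gain law, voltage and membrane
behaviour, routing weights, pharmacology, spikes and dataset generation."""

import dataclasses

import numpy as np
import pytest

import rodpath as rp
from rodpath import synthetic
from rodpath.errors import ConfigError
from rodpath.traces import StimulusSpec, Trace

from conftest import flash_trace, response_amp


class TestSteadySuppression:
    def test_anchors(self, primate, mouse):
        assert rp.steady_suppression(0.0, primate) == 0.0
        assert rp.steady_suppression(40.0, primate) == pytest.approx(0.5)
        assert rp.steady_suppression(250.0, primate) == pytest.approx(0.90, abs=1e-9)
        assert rp.steady_suppression(1000.0, mouse) == pytest.approx(0.90, abs=1e-9)

    def test_strictly_increasing_and_bounded(self, primate):
        bgs = np.logspace(-2, 4, 60)
        s = np.array([rp.steady_suppression(b, primate) for b in bgs])
        assert np.all(np.diff(s) > 0)
        assert np.all((s >= 0) & (s <= 1))


class TestRodGain:
    def test_dark_gain_is_one(self, primate):
        assert rp.rod_gain(0.0, primate) == 1.0

    def test_weber_range_loglog_slope(self, primate):
        bgs = np.logspace(np.log10(3), 2, 20)
        g = np.array([rp.rod_gain(b, primate) for b in bgs])
        slope = np.polyfit(np.log10(bgs), np.log10(g), 1)[0]
        assert -1.3 <= slope <= -0.8

    def test_saturation_gain_drop(self, primate):
        ratio = rp.rod_gain(100.0, primate) / rp.rod_gain(1000.0, primate)
        assert 80.0 <= ratio <= 160.0

    def test_strictly_decreasing(self, primate):
        bgs = np.logspace(-2, 3.5, 60)
        g = np.array([rp.rod_gain(b, primate) for b in bgs])
        assert np.all(np.diff(g) < 0)


class TestSteadyVoltage:
    def test_dark_resting_potential(self, primate):
        assert rp.steady_voltage(0.0, primate) == pytest.approx(-44.0)

    def test_step_hyperpolarization(self, primate):
        dv = rp.steady_voltage(1.0, primate) - rp.steady_voltage(60.0, primate)
        assert dv == pytest.approx(9.0, abs=1e-9)

    def test_monotone_nonincreasing(self, primate):
        bgs = np.logspace(-2, 4, 50)
        v = np.array([rp.steady_voltage(b, primate) for b in bgs])
        assert np.all(np.diff(v) <= 0)
        assert v.min() >= primate.V_dark_mV - primate.dV_max_mV


class TestMembrane:
    def test_tau_halves_over_physiological_hyperpolarization(self, primate):
        assert rp.tau_of_voltage(-44.0, primate) / rp.tau_of_voltage(-53.0, primate) \
            == pytest.approx(2.0)

    def test_tau_clamped_outside_linear_range(self, primate):
        assert rp.tau_of_voltage(-80.0, primate) == rp.tau_of_voltage(-56.0, primate)

    def test_impulse_response_integrates_to_dc_gain(self, primate):
        dt = 1e-4
        x = np.zeros(20000)
        x[0] = 1.0 / dt  # unit-area impulse
        tr = Trace(0.0, dt, x, "pA")
        out = rp.membrane_filter(tr, -44.0, primate)
        area = np.sum(out.values - (-44.0)) * dt
        assert area == pytest.approx(primate.input_resistance_gohm, rel=1e-6)

    @pytest.mark.parametrize("V", [-44.0, -48.5, -53.0])
    def test_pulse_tau_recovery_within_5pct(self, primate, V):
        dt = 1e-4
        x = np.zeros(15000)
        x[: int(0.001 / dt)] = 5.0  # 1 ms current pulse
        out = rp.membrane_filter(Trace(0.0, dt, x, "pA"), V, primate)
        tau_ms = rp.fit_membrane_tau(out)
        assert tau_ms == pytest.approx(rp.tau_of_voltage(V, primate) * 1000, rel=0.05)


class TestRodCurrent:
    def test_small_signal_gain_recovery(self, primate):
        stim = StimulusSpec(kind="flash", background=0.0, strength_rstar=1e-4,
                            pre_s=0.1, stim_s=1.0, tail_s=0.0, dt_s=1e-3)
        tr = rp.simulate_rod_current(stim, primate)
        gain = response_amp(tr) / stim.flash_strength
        assert gain == pytest.approx(primate.sens_dark_pA_per_rstar, rel=1e-9)

    def test_steady_circulating_current_at_250(self, primate):
        stim = StimulusSpec(kind="step", background=250.0, pre_s=0.2, stim_s=3.0,
                            tail_s=0.0, dt_s=5e-3)
        tr = rp.simulate_rod_current(stim, primate)
        assert tr.values[-1] == pytest.approx(
            primate.dark_current_pA * 0.1, rel=1e-3)  # 2 pA of a 20 pA dark current

    def test_same_seed_same_trace(self, primate):
        stim = StimulusSpec(kind="flash", background=10.0, contrast=6.0,
                            pre_s=0.1, stim_s=0.5, tail_s=0.0, dt_s=1e-3)
        a = rp.simulate_rod_current(stim, primate, noise_sd=0.5, seed=11)
        b = rp.simulate_rod_current(stim, primate, noise_sd=0.5, seed=11)
        assert np.array_equal(a.values, b.values)


class TestPathwayWeights:
    def test_secondary_half_max_backgrounds(self, primate, mouse):
        _, sec300, _ = rp.pathway_weights(300.0, "primate")
        assert sec300 == pytest.approx(0.5 * primate.secondary_weight, rel=1e-9)
        _, sec5, _ = rp.pathway_weights(5.0, "mouse")
        assert sec5 == pytest.approx(0.5 * mouse.secondary_weight, rel=1e-9)

    def test_nbqx_removes_most_of_response_at_30(self):
        p, s, t = rp.pathway_weights(30.0, "primate", "control")
        p2, s2, t2 = rp.pathway_weights(30.0, "primate", "NBQX")
        assert p2 == 0.0
        reduction = 1.0 - (p2 + s2 + t2) / (p + s + t)
        assert reduction >= 0.80

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            rp.pathway_weights(1.0, "gerbil")

    def test_tertiary_zero_in_primate_nonzero_in_mouse(self):
        assert rp.pathway_weights(10.0, "primate")[2] == 0.0
        assert rp.pathway_weights(10.0, "mouse")[2] > 0.0


class TestSimulateCell:
    def test_h1_rod_signal_much_weaker_than_parasol(self):
        """Rod:cone response ratio in H1 is >= 7x smaller than in On parasols."""
        def ratio(cell):
            rod = response_amp(flash_trace(cell, 10.0, led="rod_preferring"))
            cone = response_amp(flash_trace(cell, 10.0, led="cone_preferring"))
            return rod / cone
        assert ratio("H1") <= ratio("On_parasol_exc") / 7.0

    def test_mouse_off_alpha_ly_apb_block(self):
        ctrl = response_amp(flash_trace("Off_alpha_exc", 0.5, species="mouse"))
        ly = response_amp(flash_trace("Off_alpha_exc", 0.5, species="mouse",
                                      condition="LY_APB"))
        assert 1.0 - ly / ctrl == pytest.approx(0.90, abs=0.03)

    def test_nbqx_never_increases_aii_response(self):
        for bg in (0.5, 3.0, 30.0, 300.0, 2000.0):
            c = response_amp(flash_trace("AII", bg))
            n = response_amp(flash_trace("AII", bg, condition="NBQX"))
            assert c >= n

    def test_incompatible_condition_cell_rejected(self):
        stim = StimulusSpec(kind="flash", background=1.0, contrast=6.0)
        with pytest.raises(ValueError):
            rp.simulate_cell("rod_current", stim, "primate", "NBQX")
        with pytest.raises(ValueError):
            rp.simulate_cell("H1", stim, "primate", "LY_APB")
        with pytest.raises(ValueError):
            rp.simulate_cell("Off_alpha_exc", stim, "primate")

    def test_determinism_with_noise(self):
        stim = StimulusSpec(kind="flash", background=10.0, contrast=6.0,
                            pre_s=0.1, stim_s=0.5, tail_s=0.0)
        a = rp.simulate_cell("AII", stim, "primate", seed=5, noise_frac=0.1)
        b = rp.simulate_cell("AII", stim, "primate", seed=5, noise_frac=0.1)
        assert np.array_equal(a.values, b.values)


class TestSpikes:
    def test_zero_rate_gives_no_spikes(self):
        rate = Trace(0.0, 1e-3, np.zeros(500), "spikes_s")
        psth, trains = rp.spikes_from_rate(rate, 10, 0, return_trains=True)
        assert np.all(psth.values == 0)
        assert all(len(tr) == 0 for tr in trains)

    def test_psth_expectation_matches_rate(self):
        rate = Trace(0.0, 5e-3, np.full(200, 100.0), "spikes_s")
        psth = rp.spikes_from_rate(rate, 200, 1)
        se = np.sqrt(100.0 / (5e-3 * 200))
        assert abs(psth.values.mean() - 100.0) < 3 * se / np.sqrt(200)

    def test_same_seed_identical(self):
        rate = Trace(0.0, 1e-3, np.linspace(0, 80, 400), "spikes_s")
        a = rp.spikes_from_rate(rate, 20, 3)
        b = rp.spikes_from_rate(rate, 20, 3)
        assert np.array_equal(a.values, b.values)

    def test_negative_rate_rejected(self):
        rate = Trace(0.0, 1e-3, np.array([1.0, -0.5, 2.0]), "spikes_s")
        with pytest.raises(ValueError):
            rp.spikes_from_rate(rate, 5, 0)


class TestGenerateDataset:
    def test_factorial_cardinality(self):
        proto = {"master_seed": 1, "cell_types": ["AII"], "backgrounds": [1.0, 10.0],
                 "n_cells": 2, "stimulus": {"kind": "flash", "stim_ms": 300,
                                            "pre_ms": 100, "tail_ms": 0}}
        assert len(rp.generate_dataset(proto)) == 4

    def test_same_master_seed_identical_store(self, tmp_path):
        proto = {"master_seed": 9, "cell_types": ["rod_current"],
                 "backgrounds": [1.0, 10.0], "n_cells": 2, "noise_frac": 0.1,
                 "stimulus": {"kind": "flash", "stim_ms": 300, "pre_ms": 100,
                              "tail_ms": 0, "dt_ms": 2}}
        s1, s2 = rp.generate_dataset(proto), rp.generate_dataset(proto)
        assert s1 == s2
        p1, p2 = tmp_path / "a.h5", tmp_path / "b.h5"
        s1.to_hdf5(p1)
        s2.to_hdf5(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_protocol_empty_store(self):
        assert len(rp.generate_dataset({})) == 0

    def test_unknown_key_named_in_error(self):
        with pytest.raises(ConfigError, match="backgroundz"):
            rp.generate_dataset({"master_seed": 1, "backgroundz": [1]})

    def test_missing_master_seed_rejected(self):
        with pytest.raises(ConfigError, match="master_seed"):
            rp.generate_dataset({"cell_types": ["AII"]})

    def test_malformed_yaml_reports_line(self):
        bad = "master_seed: 1\ncell_types: [unclosed\n"
        with pytest.raises(ConfigError, match="line"):
            rp.generate_dataset(bad)


class TestCellVariability:
    def test_sampled_params_are_positive_and_centered(self, primate):
        rng = np.random.default_rng(0)
        draws = [synthetic.sample_cell_params(primate, rng) for _ in range(200)]
        dv = np.array([d.dV_max_mV for d in draws])
        assert np.all(dv > 0)
        assert abs(dv.mean() / primate.dV_max_mV - 1.0) < 0.05
        cv = dv.std() / dv.mean()
        assert cv == pytest.approx(primate.cell_cv, rel=0.25)
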