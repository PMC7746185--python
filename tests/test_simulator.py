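"""The synthetic walker: determinism, mechanics, ground-truth consistency."""

import numpy as np
import pytest

import fpcontrol as fpc
from fpcontrol.simulate import SimTruth, propagate_pendulum

G = 9.81


def _fit_ts(cfg):
    trial, truth = fpc.simulate_trial(cfg)
    ev = fpc.detect_events_force(trial.fz, rate=trial.rate_force,
                                 body_weight_n=trial.body_mass * G)
    recs = fpc.extract_step_records(trial, ev, n_strides=cfg.n_strides,
                                    include_emg=False)
    return fpc.fit_fp_model(recs, min_steps=3), truth


class TestDeterminism:
    def test_identical_seed_bit_identical(self):
        cfg = fpc.make_config("normal", "steady", seed=5, n_strides=12)
        t1, tr1 = fpc.simulate_trial(cfg)
        t2, tr2 = fpc.simulate_trial(cfg)
        np.testing.assert_array_equal(t1.com_ml, t2.com_ml)
        np.testing.assert_array_equal(t1.fz["L"], t2.fz["L"])
        np.testing.assert_array_equal(t1.emg["gm_L"], t2.emg["gm_L"])
        np.testing.assert_array_equal(tr1.fp_lateral["R"], tr2.fp_lateral["R"])

    def test_different_seed_different_placements(self):
        a = fpc.simulate_trial(fpc.make_config(seed=1, n_strides=12,
                                               include_emg=False))[1]
        b = fpc.simulate_trial(fpc.make_config(seed=2, n_strides=12,
                                               include_emg=False))[1]
        assert not np.allclose(a.fp_lateral["R"], b.fp_lateral["R"])


class TestPendulumCore:
    def test_frozen_cop_matches_closed_form(self):
        """Stance with frozen CoP follows x0*cosh + (v0/omega)*sinh exactly."""
        leg = 0.9
        omega = np.sqrt(G / leg)
        x0, v0 = 0.02, 0.05
        t = np.linspace(0.0, 0.5, 101)
        x, v = propagate_pendulum(x0, v0, omega, 0.0, 0.0, t)
        expect = x0 * np.cosh(omega * t) + (v0 / omega) * np.sinh(omega * t)
        assert np.max(np.abs(x - expect)) < 1e-6
        expect_v = x0 * omega * np.sinh(omega * t) + v0 * np.cosh(omega * t)
        assert np.max(np.abs(v - expect_v)) < 1e-6

    def test_divergence_error_names_gains(self):
        cfg = fpc.make_config("normal", "steady", seed=0, n_strides=20,
                              k_pos=0.05, k_vel=0.01, aux_stiffness=0.0,
                              aux_damping=0.0, include_emg=False)
        with pytest.raises(fpc.SimulationUnstableError, match="k_pos=0.05"):
            fpc.simulate_trial(cfg)


class TestSupport:
    def test_belt_forces_sum_to_total_load(self, trial60):
        _, trial, _ = trial60
        total = trial.total_fz
        assert np.all(total >= 0)
        # away from the boundaries the walker always carries its weight
        core = slice(200, -200)
        assert total[core].min() > 0.5 * trial.body_mass * G

    def test_combined_cop_between_feet(self, trial60):
        _, trial, _ = trial60
        lo = np.minimum(trial.cop_ml["L"], trial.cop_ml["R"])
        hi = np.maximum(trial.cop_ml["L"], trial.cop_ml["R"])
        ok = (trial.combined_cop_ml >= lo - 1e-9) & \
             (trial.combined_cop_ml <= hi + 1e-9)
        assert ok.all()

    def test_ankle_constrained_cop_stays_on_ridge(self):
        """Single-support CoP never leaves the 5 mm ridge half-width."""
        cfg = fpc.make_config("normal", "ankle_constrained", seed=3,
                              n_strides=30, include_emg=False)
        assert cfg.cop_half_width == 0.005
        trial, truth = fpc.simulate_trial(cfg)
        bw = trial.body_mass * G
        for leg in "LR":
            # single support: this belt carries (almost) the whole load
            ss = trial.fz[leg] > 0.99 * bw
            cop = trial.cop_ml[leg][ss]
            t_ss = trial.force_time[ss]
            # stance foot position at each single-support sample
            hs = truth.heel_strike_times[leg]
            pl = truth.placements[leg]
            idx = np.searchsorted(hs, t_ss, side="right") - 1
            valid = idx >= 0
            dev = np.abs(cop[valid] - pl[idx[valid]])
            assert dev.max() <= 0.005 + 1e-12


class TestStrideFrequency:
    def test_trivial_one_hertz(self):
        truth = SimTruth(
            true_k_pos=0, true_k_vel=0, effective_k_pos=0, effective_k_vel=0,
            nominal_step_width=0.1,
            heel_strike_times={"R": np.arange(11.0), "L": np.arange(11.0) + 0.5},
            toe_off_times={}, placements={}, fp_lateral={},
            com_series=np.zeros(2))
        assert fpc.realized_stride_frequency(truth) == pytest.approx(1.0)

    def test_configured_frequency_honoured(self):
        cfg = fpc.make_config("normal", "steady", seed=0, n_strides=20,
                              stride_frequency=0.9, fp_noise_sd=0.0,
                              include_emg=False)
        _, truth = fpc.simulate_trial(cfg)
        for leg in "LR":
            assert fpc.realized_stride_frequency(truth, leg) == \
                pytest.approx(0.9, abs=1e-6)

    def test_single_heel_strike_is_an_error(self):
        truth = SimTruth(
            true_k_pos=0, true_k_vel=0, effective_k_pos=0, effective_k_vel=0,
            nominal_step_width=0.1, heel_strike_times={"R": np.array([1.0])},
            toe_off_times={}, placements={}, fp_lateral={},
            com_series=np.zeros(2))
        with pytest.raises(ValueError, match="at least 2"):
            fpc.realized_stride_frequency(truth)

    def test_event_counts_match_stride_count(self, trial60):
        cfg, _, truth = trial60
        n = cfg.n_strides
        for leg in "LR":
            assert abs(len(truth.heel_strike_times[leg]) - n) <= \
                cfg.warmup_strides + 2
            hs = truth.heel_strike_times[leg]
            to = truth.toe_off_times[leg]
            assert np.all(np.diff(hs) > 0) and np.all(np.diff(to) > 0)


class TestNoiseEffects:
    def test_more_placement_noise_lowers_degree_of_control(self):
        """Mean terminal-swing R^2 strictly decreases with fp noise."""
        levels = (0.004, 0.010, 0.022)
        means = []
        for sd in levels:
            r2 = [
                _fit_ts(fpc.make_config("normal", "steady", seed=s,
                                        n_strides=40, fp_noise_sd=sd,
                                        include_emg=False))[0].r2_ts
                for s in range(20)]
            means.append(np.mean(r2))
        assert means[0] > means[1] > means[2]

    def test_target_stepping_narrows_step_width(self):
        """fp_constrained yields lower step-width variability than steady."""
        for seed in (3, 4):
            sds = {}
            for cond in ("steady", "fp_constrained"):
                cfg = fpc.make_config("normal", cond, seed=seed, n_strides=60,
                                      include_emg=False)
                trial, _ = fpc.simulate_trial(cfg)
                ev = fpc.detect_events_force(trial.fz, rate=trial.rate_force,
                                             body_weight_n=trial.body_mass * G)
                recs = fpc.extract_step_records(trial, ev,
                                                n_strides=cfg.n_strides,
                                                include_emg=False)
                sds[cond] = fpc.condition_metrics(recs)["step_width_variability"]
            assert sds["fp_constrained"] < sds["steady"]
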