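"""CoM estimation and per-step outcome extraction."""

import numpy as np
import pytest

import fpcontrol as fpc
from fpcontrol.kinematics import AnthropometricTable, Segment

G = 9.81


def toy_table(masses, frac=0.5):
    """Intercept-only regressions giving exactly the requested masses."""
    entries = {(name, "M"): (m, 0.0, 0.0, frac) for name, m in masses.items()}
    return AnthropometricTable(entries)


class TestComputeCom:
    def test_equal_masses_average_positions(self):
        segs = [Segment("a", np.full(5, -0.1), np.full(5, -0.1), 0.4, 0.3),
                Segment("b", np.full(5, 0.1), np.full(5, 0.1), 0.4, 0.3)]
        com = fpc.compute_com(segs, toy_table({"a": 2.0, "b": 2.0}))
        np.testing.assert_allclose(com, 0.0, atol=1e-12)

    def test_single_segment_is_its_own_com(self):
        seg = Segment("a", np.array([0.0]), np.array([1.0]), 1.0, 0.3)
        com = fpc.compute_com([seg], toy_table({"a": 3.0}, frac=0.41))
        np.testing.assert_allclose(com, 0.41)

    def test_integer_mass_weighted_mean(self):
        """Masses 2,3,5 kg at 0, 0.1, 0.2 m give (0.3+1.0)/10 = 0.13 m."""
        segs = [Segment(n, np.full(3, x), np.full(3, x), 0.4, 0.3)
                for n, x in (("a", 0.0), ("b", 0.1), ("c", 0.2))]
        com = fpc.compute_com(segs, toy_table({"a": 2.0, "b": 3.0, "c": 5.0}))
        np.testing.assert_allclose(com, 0.13)

    def test_missing_segment_entry_raises(self):
        seg = Segment("pelvis", np.zeros(2), np.zeros(2), 0.3, 0.9)
        with pytest.raises(KeyError, match="pelvis"):
            fpc.compute_com([seg], toy_table({"thigh": 5.0}))

    def test_nonpositive_mass_names_segment(self):
        seg = Segment("shank", np.zeros(2), np.zeros(2), 0.4, 0.3)
        with pytest.raises(ValueError, match="shank"):
            fpc.compute_com([seg], toy_table({"shank": -1.0}))

    def test_mass_conservation_over_segment_union(self):
        rng = np.random.default_rng(0)
        xs = rng.normal(size=(6, 4))
        names = [f"s{i}" for i in range(6)]
        masses = {n: float(m) for n, m in
                  zip(names, rng.uniform(1, 10, size=6))}
        segs = [Segment(n, xs[i], xs[i], 0.4, 0.3)
                for i, n in enumerate(names)]
        table = toy_table(masses)
        whole = fpc.compute_com(segs, table)
        com_a = fpc.compute_com(segs[:3], table)
        com_b = fpc.compute_com(segs[3:], table)
        m_a = sum(masses[n] for n in names[:3])
        m_b = sum(masses[n] for n in names[3:])
        np.testing.assert_allclose(
            whole, (m_a * com_a + m_b * com_b) / (m_a + m_b), atol=1e-12)

    def test_default_table_predicts_positive_masses(self):
        table = AnthropometricTable.default()
        for (seg, gender) in table.entries:
            assert table.mass(seg, gender, 0.4, 0.35) > 0
            assert 0 <= table.com_fraction(seg, gender) <= 1


class TestComVelocity:
    def test_constant_series_zero_velocity(self):
        np.testing.assert_allclose(
            fpc.com_velocity(np.full(10, 0.3), dt=0.02), 0.0)

    def test_linear_series_unit_velocity(self):
        x = 0.02 * np.arange(50)
        np.testing.assert_allclose(fpc.com_velocity(x, dt=0.02), 1.0)

    def test_sine_matches_analytic_derivative_to_first_order(self):
        A, f, dt = 0.03, 1.1, 0.02
        t = np.arange(0, 4, dt)
        v = fpc.com_velocity(A * np.sin(2 * np.pi * f * t), dt=dt)
        expect = A * 2 * np.pi * f * np.cos(2 * np.pi * f * (t + dt / 2))
        # forward difference is exact at the midpoint up to O(dt^2)
        bound = A * (2 * np.pi * f) ** 3 * dt ** 2
        assert np.max(np.abs(v[:-1] - expect[:-1])) < bound

    def test_non_uniform_timestamps_rejected(self):
        t = np.array([0.0, 0.02, 0.05, 0.06])
        with pytest.raises(ValueError, match="uniform"):
            fpc.com_velocity(np.ones(4), times=t)


class TestStepRecords:
    def test_fp_matches_generator_placements(self):
        cfg = fpc.make_config("normal", "steady", seed=11, n_strides=40,
                              include_emg=False)
        trial, truth = fpc.simulate_trial(cfg)
        ev = fpc.detect_events_force(trial.fz, rate=trial.rate_force,
                                     body_weight_n=trial.body_mass * G)
        recs = fpc.extract_step_records(trial, ev, n_strides=cfg.n_strides,
                                        include_emg=False)
        for r in recs:
            true_fp = truth.fp_lateral[r.leg]
            # the step's heel strike identifies the placement
            hs = truth.heel_strike_times[r.leg]
            i = int(np.argmin(np.abs(hs - r.t_heel_strike)))
            assert abs(r.fp - true_fp[i]) < 1e-6

    def test_noise_free_gait_walks_at_nominal_width(self):
        cfg = fpc.make_config("normal", "steady", seed=0, n_strides=30,
                              fp_noise_sd=0.0, cop_noise_sd=0.0,
                              include_emg=False)
        trial, _ = fpc.simulate_trial(cfg)
        ev = fpc.detect_events_force(trial.fz, rate=trial.rate_force,
                                     body_weight_n=trial.body_mass * G)
        recs = fpc.extract_step_records(trial, ev, n_strides=cfg.n_strides,
                                        include_emg=False)
        fp = np.array([r.fp for r in recs])
        assert fp.std() < 1e-3
        assert abs(fp.mean() - cfg.nominal_step_width) < 2e-3

    def test_mirrored_trial_gives_identical_records(self, trial60, events60,
                                                    records60):
        _, trial, _ = trial60
        mirrored = fpc.TrialTimeSeries(
            force_time=trial.force_time,
            fz={"L": trial.fz["R"], "R": trial.fz["L"]},
            cop_ml={"L": -trial.cop_ml["R"], "R": -trial.cop_ml["L"]},
            cop_ap={"L": trial.cop_ap["R"], "R": trial.cop_ap["L"]},
            combined_cop_ml=-trial.combined_cop_ml,
            combined_cop_ap=trial.combined_cop_ap,
            kin_time=trial.kin_time, com_ml=-trial.com_ml,
            foot_ml={"L": -trial.foot_ml["R"], "R": -trial.foot_ml["L"]},
            emg_time=None, emg=None, body_mass=trial.body_mass)
        ev_m = fpc.detect_events_force(mirrored.fz, rate=200.0,
                                       body_weight_n=trial.body_mass * G)
        recs_m = fpc.extract_step_records(mirrored, ev_m, n_strides=60,
                                          include_emg=False)
        assert len(recs_m) == len(records60)
        for a, b in zip(records60, recs_m):
            assert a.leg != b.leg  # legs swap under mirroring
            assert a.fp == pytest.approx(b.fp, abs=1e-12)
            assert a.fp2 == pytest.approx(b.fp2, abs=1e-12)
            np.testing.assert_allclose(a.com_pos, b.com_pos, atol=1e-12)
            np.testing.assert_allclose(a.com_vel, b.com_vel, atol=1e-12)

    def test_translation_leaves_step_outcomes_unchanged(self, trial60,
                                                        events60, records60):
        _, trial, _ = trial60
        c = 0.37
        shifted = fpc.TrialTimeSeries(
            force_time=trial.force_time, fz=trial.fz,
            cop_ml={k: v + c for k, v in trial.cop_ml.items()},
            cop_ap=trial.cop_ap,
            combined_cop_ml=trial.combined_cop_ml + c,
            combined_cop_ap=trial.combined_cop_ap,
            kin_time=trial.kin_time, com_ml=trial.com_ml + c,
            foot_ml={k: v + c for k, v in trial.foot_ml.items()},
            emg_time=None, emg=None, body_mass=trial.body_mass)
        recs_s = fpc.extract_step_records(shifted, events60, n_strides=60,
                                          include_emg=False)
        for a, b in zip(records60, recs_s):
            assert b.fp == pytest.approx(a.fp, abs=1e-9)
            assert b.fp2 == pytest.approx(a.fp2, abs=1e-9)
            np.testing.assert_allclose(a.com_pos, b.com_pos, atol=1e-9)

    def test_requested_stride_count_is_retained(self, records60):
        assert len(records60) == 120
        assert sum(r.leg == "L" for r in records60) == 60

    def test_warns_when_fewer_strides_than_requested(self, trial60, events60):
        _, trial, _ = trial60
        with pytest.warns(UserWarning, match="complete steps"):
            fpc.extract_step_records(trial, events60, n_strides=500,
                                     include_emg=False)


class TestConditionMetrics:
    def test_constant_widths(self):
        recs = _fake_records([0.10, 0.10, 0.10])
        m = fpc.condition_metrics(recs)
        assert m["mean_step_width"] == pytest.approx(0.10)
        assert m["step_width_variability"] == pytest.approx(0.0)

    def test_two_point_standard_deviation(self):
        m = fpc.condition_metrics(_fake_records([0.08, 0.12]))
        assert m["mean_step_width"] == pytest.approx(0.10)
        assert m["step_width_variability"] == pytest.approx(0.02828, abs=1e-4)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fpc.condition_metrics([])


def _fake_records(fps, stride=1.1):
    recs = []
    for i, fp in enumerate(fps):
        recs.append(fpc.StepRecord(
            leg="L" if i % 2 else "R", t_toe_off=i, t_heel_strike=i + 0.4,
            fp=fp, fp2=fp, com_pos=np.zeros(51), com_vel=np.zeros(51),
            stride_duration=stride))
    return recs
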