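"""The foot-placement and muscle regression models."""

import numpy as np
import pytest

import fpcontrol as fpc
from fpcontrol.models import RankDeficientError, permutation_null_r2

G = 9.81


def _demean(a):
    a = np.asarray(a, dtype=float)
    return a - a.mean(axis=0)


class TestOlsDemeaned:
    def test_identity_regression(self):
        x = _demean(np.arange(10.0))
        beta, r2 = fpc.ols_demeaned(x, x)
        assert beta[0] == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_orthogonal_design_equals_univariate_slopes(self):
        rng = np.random.default_rng(1)
        a = _demean(rng.normal(size=40))
        b = _demean(rng.normal(size=40))
        b -= a * (a @ b) / (a @ a)  # orthogonalise
        y = _demean(2.0 * a - 0.5 * b + 0.1 * rng.normal(size=40))
        beta, _ = fpc.ols_demeaned(np.column_stack([a, b]), y)
        assert beta[0] == pytest.approx((a @ y) / (a @ a), rel=1e-10)
        assert beta[1] == pytest.approx((b @ y) / (b @ b), rel=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = _demean(rng.normal(size=(20, 2)))
        y = _demean(rng.normal(size=20))
        beta, _ = fpc.ols_demeaned(X, y)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(beta, oracle, atol=1e-10)

    def test_r2_equals_squared_correlation_of_fit(self):
        rng = np.random.default_rng(5)
        X = _demean(rng.normal(size=(60, 2)))
        y = _demean(X @ [1.0, -0.4] + rng.normal(size=60))
        beta, r2 = fpc.ols_demeaned(X, y)
        fitted = X @ beta
        assert r2 == pytest.approx(np.corrcoef(fitted, y)[0, 1] ** 2,
                                   rel=1e-10)

    def test_rank_deficiency_names_columns(self):
        x = _demean(np.arange(10.0))
        with pytest.raises(RankDeficientError, match=r"\[0, 1\]"):
            fpc.ols_demeaned(np.column_stack([x, 2 * x]), x)

    def test_more_predictors_than_rows_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            fpc.ols_demeaned(np.ones((2, 3)), np.zeros(2))

    def test_undemeaned_input_rejected(self):
        with pytest.raises(ValueError, match="demeaned"):
            fpc.ols_demeaned(np.arange(10.0) + 5.0, _demean(np.arange(10.0)))


class TestFitFpModel:
    def test_noiseless_walker_recovers_gains_exactly(self):
        """With zero placement noise the regression is the generating rule."""
        cfg = fpc.make_config("normal", "steady", seed=1, n_strides=40,
                              fp_noise_sd=0.0, include_emg=False)
        trial, truth = fpc.simulate_trial(cfg)
        ev = fpc.detect_events_force(trial.fz, rate=trial.rate_force,
                                     body_weight_n=trial.body_mass * G)
        recs = fpc.extract_step_records(trial, ev, n_strides=cfg.n_strides,
                                        include_emg=False)
        fit = fpc.fit_fp_model(recs, min_steps=3)
        assert fit.r2_ts >= 0.999999
        assert fit.beta_pos_ts == pytest.approx(truth.effective_k_pos,
                                                abs=1e-6)
        assert fit.beta_vel_ts == pytest.approx(truth.effective_k_vel,
                                                abs=1e-6)

    def test_unit_rescaling_rescales_coefficients(self, records60):
        fit_m = fpc.fit_fp_model(records60)
        recs_cm = []
        for r in records60:
            recs_cm.append(fpc.StepRecord(
                leg=r.leg, t_toe_off=r.t_toe_off,
                t_heel_strike=r.t_heel_strike, fp=r.fp, fp2=r.fp2,
                com_pos=r.com_pos * 100.0, com_vel=r.com_vel,
                stride_duration=r.stride_duration))
        fit_cm = fpc.fit_fp_model(recs_cm)
        np.testing.assert_allclose(fit_cm.beta_pos, fit_m.beta_pos / 100.0,
                                   rtol=1e-9)
        np.testing.assert_allclose(fit_cm.r2, fit_m.r2, rtol=1e-9)

    def test_shuffled_outcome_sits_in_permutation_null(self, records60):
        """Shuffled step widths carry no signal: across many shuffles the
        R^2 almost always stays below the permutation-null 97.5%."""
        rng = np.random.default_rng(0)
        fp = np.array([r.fp for r in records60])
        X = _demean(np.column_stack([[r.com_pos[50] for r in records60],
                                     [r.com_vel[50] for r in records60]]))
        cut = np.quantile(permutation_null_r2(X, fp, n_perm=300, rng=1), 0.975)
        below = sum(
            fpc.ols_demeaned(X, _demean(rng.permutation(fp)))[1] < cut
            for _ in range(20))
        assert below >= 18

    def test_minimum_step_count_enforced(self, records60):
        with pytest.raises(ValueError, match="at least"):
            fpc.fit_fp_model(records60[:10], min_steps=50)


class TestMuscleModel:
    def test_signs_recovered_on_synthetic_trial(self, emg_trial):
        _, _, _, records = emg_trial
        m = fpc.fit_muscle_model_from_records(records)
        assert m.beta_gm > 0
        assert m.beta_al < 0
        assert 0 < m.r2 < 1

    def test_duplicated_features_rank_deficient(self):
        rng = np.random.default_rng(2)
        g = fpc.znorm_trial(rng.normal(size=30))
        y = fpc.znorm_trial(rng.normal(size=30))
        with pytest.raises(RankDeficientError):
            fpc.fit_muscle_model(y, g, g.copy())

    def test_unnormalised_features_rejected(self):
        rng = np.random.default_rng(3)
        y = fpc.znorm_trial(rng.normal(size=30))
        with pytest.raises(ValueError, match="z-normalised"):
            fpc.fit_muscle_model(y, rng.normal(size=30) + 5.0, y)

    def test_uncoupled_emg_gives_null_r2(self):
        """With generator coupling off, the muscle model has no signal."""
        cfg = fpc.make_config("normal", "steady", seed=4, n_strides=60,
                              emg_gain=0.0)
        trial, _ = fpc.simulate_trial(cfg)
        ev = fpc.detect_events_force(trial.fz, rate=trial.rate_force,
                                     body_weight_n=trial.body_mass * G)
        recs = fpc.extract_step_records(trial, ev, n_strides=cfg.n_strides)
        m = fpc.fit_muscle_model_from_records(recs)
        fp2 = fpc.znorm_trial([r.fp2 for r in recs])
        X = np.column_stack([fpc.znorm_trial([r.emg_gm_swing for r in recs]),
                             fpc.znorm_trial([r.emg_al_swing for r in recs])])
        null = permutation_null_r2(X, fp2, n_perm=300, rng=0)
        assert m.r2 < np.quantile(null, 0.975)


class TestFisherTransform:
    def test_zero_maps_to_zero(self):
        assert fpc.fisher_transform(0.0) == 0.0

    def test_closed_form_at_r2_064(self):
        assert fpc.fisher_transform(0.64) == pytest.approx(
            0.5 * np.log(1.8 / 0.2), rel=1e-12)

    def test_monotone_on_grid(self):
        grid = np.linspace(0, 0.99, 50)
        z = fpc.fisher_transform(grid)
        assert np.all(np.diff(z) > 0)

    def test_unity_flagged_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert np.isinf(fpc.fisher_transform(1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fpc.fisher_transform(1.2)

    def test_r2_scale_option(self):
        assert fpc.fisher_transform(0.5, scale="r2") == \
            pytest.approx(np.arctanh(0.5))


class TestNoiseMonotonicity:
    def test_pure_noise_steps_do_not_raise_expected_r2(self, records60):
        """Appending unpredictable steps can only dilute the fit."""
        rng = np.random.default_rng(8)
        base = fpc.fit_fp_model(records60).r2_ts
        diluted = []
        for _ in range(5):
            extra = []
            for r in records60[:40]:
                extra.append(fpc.StepRecord(
                    leg=r.leg, t_toe_off=r.t_toe_off,
                    t_heel_strike=r.t_heel_strike,
                    fp=float(rng.normal(0.12, 0.02)), fp2=r.fp2,
                    com_pos=r.com_pos, com_vel=r.com_vel,
                    stride_duration=r.stride_duration))
            diluted.append(fpc.fit_fp_model(list(records60) + extra).r2_ts)
        assert np.mean(diluted) < base
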