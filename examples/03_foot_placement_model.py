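"""Fit the foot placement model and recover the walker's controller gains.

FP = beta_pos * CoM_pos(i) + beta_vel * CoM_vel(i) + eps(i), fitted per
swing phase i = 1..51 on demeaned variables.  Because the synthetic
walker literally places its feet by this rule, the terminal-swing fit
should recover the generator's gains, and R^2(i) — the degree of foot
placement control — should rise toward heel strike.
"""

import fpcontrol as fpc

cfg = fpc.make_config("normal", "steady", seed=11, n_strides=200,
                      include_emg=False)
trial, truth = fpc.simulate_trial(cfg)

ev = fpc.detect_events_force(trial.fz, rate=trial.rate_force,
                             body_weight_n=trial.body_mass * 9.81)
records = fpc.extract_step_records(trial, ev, n_strides=cfg.n_strides,
                                   include_emg=False)
fit = fpc.fit_fp_model(records)

print(f"steps fitted: {fit.n_steps}")
print(f"terminal swing (i=51): beta_pos={fit.beta_pos_ts:.3f} "
      f"(true {truth.effective_k_pos:.2f}), beta_vel={fit.beta_vel_ts:.3f} "
      f"(true {truth.effective_k_vel:.2f}), R^2={fit.r2_ts:.3f}")
print(f"mid swing      (i=25): beta_pos={fit.beta_pos_mid:.3f}, "
      f"beta_vel={fit.beta_vel_mid:.3f}, R^2={fit.r2_mid:.3f}")
print("R^2 rises through swing as the CoM state pins down the landing spot:")
for i in (1, 13, 25, 38, 51):
    print(f"  phase {i:2d}: R^2 = {fit.r2[i - 1]:.3f}")

z = fpc.fisher_transform(fit.r2_ts)
print(f"Fisher z of terminal-swing R^2 (atanh of the multiple correlation): "
      f"{z:.3f}")
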