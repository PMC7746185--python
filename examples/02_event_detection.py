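"""Detect gait events two ways and compare them with the ground truth.

Heel strikes and toe-offs come either from per-belt vertical-force
threshold crossings (5% body weight) or from the combined-CoP butterfly
trace.  On synthetic data both should sit within a couple of 200 Hz
samples of the generator's event times.
"""

import numpy as np

import fpcontrol as fpc

cfg = fpc.make_config("normal", "steady", seed=7, n_strides=60, include_emg=False)
trial, truth = fpc.simulate_trial(cfg)

ev_force = fpc.detect_events_force(trial.fz, rate=trial.rate_force,
                                   body_weight_n=trial.body_mass * 9.81)
ev_fly = fpc.detect_events_butterfly(trial.combined_cop_ml,
                                     trial.combined_cop_ap, trial.total_fz,
                                     rate=trial.rate_force)

for name, ev in (("force threshold", ev_force), ("butterfly", ev_fly)):
    errs = []
    for leg in "LR":
        true_idx = np.rint(truth.heel_strike_times[leg] * trial.rate_force)
        for d in ev.hs_idx[leg]:
            errs.append(np.abs(true_idx - d).min())
    errs = np.asarray(errs)
    print(f"{name:16s}: {len(errs)} heel strikes, "
          f"median |error| = {np.median(errs):.0f} samples, "
          f"max = {errs.max():.0f} samples "
          f"({100 * np.mean(errs <= 2):.1f}% within +/-2)")

# A step is toe-off -> heel strike of the swinging foot; its midpoint is
# mid-swing, the 25th of the 51 phase points used by the regression model.
steps = ev_force.steps("L")
to, hs = steps[10]
print(f"example left step: toe-off at sample {to}, heel strike at {hs}, "
      f"duration {(hs - to) / trial.rate_force * 1000:.0f} ms")
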