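"""Simulate one synthetic walking trial and look at its raw channels.

The walker is a lateral inverted pendulum whose foot placement follows
its measured CoM state.  We simulate 60 strides of steady walking at
normal speed and print what the generator produced.
"""

import numpy as np

import fpcontrol as fpc

cfg = fpc.make_config("normal", "steady", seed=1, n_strides=60)
trial, truth = fpc.simulate_trial(cfg)

print(f"belt speed          : {cfg.belt_speed:.3f} m/s (1.25*sqrt(leg length))")
print(f"imposed cadence     : {cfg.stride_frequency:.2f} Hz")
print(f"realized cadence    : {fpc.realized_stride_frequency(truth):.4f} Hz "
      "(read back from ground-truth heel-strike times)")
print(f"force samples       : {trial.force_time.size} @ {trial.rate_force:.0f} Hz")
print(f"kinematic samples   : {trial.kin_time.size} @ {trial.rate_kin:.0f} Hz")
print(f"EMG samples/channel : {trial.emg_time.size} @ {trial.rate_emg:.0f} Hz")
print(f"CoM ML excursion    : {trial.com_ml.min():+.3f} .. {trial.com_ml.max():+.3f} m")
fp = np.concatenate(list(truth.fp_lateral.values()))
print(f"lateral step width  : {fp.mean() * 1000:.1f} +/- {fp.std() * 1000:.1f} mm "
      "(ground truth; positive = lateral)")

# The combined centre of pressure sweeps between the feet every step —
# the classic butterfly trace used for gait event detection.
mid = slice(2000, 2400)
print(f"combined CoP ML over two strides: "
      f"{trial.combined_cop_ml[mid].min():+.3f} .. "
      f"{trial.combined_cop_ml[mid].max():+.3f} m")
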