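# Methods

## The analysis pipeline

The pipeline quantifies step-by-step mediolateral foot-placement control.
Per trial it runs: gait event detection → CoM and per-step outcome
extraction → EMG swing features → the two regression models → Fisher
transformation; per cohort it adds the 2×2 repeated-measures comparison
of condition (constrained vs steady) by speed (normal vs slow).

**Events.** Heel strike and toe-off are detected at the force rate
(200 Hz). The force-threshold detector marks the first sample at or above
5 % body weight (heel strike) and the first below it (toe-off), debounced
with a 0.2 s minimum gap; the threshold value is a configuration knob
because the percentage is conventional, not principled. The butterfly
detector finds the rapid mediolateral sweeps of the combined CoP (the
double-support weight transfers): a transfer is a span where the smoothed
ML CoP velocity exceeds 0.30 m/s; its direction assigns the landing leg,
the onset is refined to the sharpest single-sample move of the raw trace
(the weight-acceptance kick), and the toe-off is placed at the subsequent
anteroposterior CoP reversal from backward to forward travel. Transfers
sweeping < 2 cm are dropped with a warning (ambiguous), as are transfers
truncated by the record boundary. This is a faithful-in-spirit butterfly
method validated against the force-threshold detector and the generator's
ground truth (±2 samples), not a bit-level reimplementation of any
particular published operator sequence.

**Steps and phases.** A step is toe-off → next ipsilateral heel strike
(the swing of that foot). Predictor series are linearly interpolated onto
51 equally spaced phase points across the step. Following the field's
notation the tested slices are i = 25 ("mid-swing") and i = 51 (terminal
swing). Note a small wrinkle kept deliberately: on a 51-point grid
spanning 0–100 %, index 25 sits at 48 %, one phase step short of the
50 % midpoint; the literal index is retained because that is how the
slices are conventionally labelled, and all comparisons use the same
index on both sides. `GaitEvents.mid_swing_idx` (used for midstance-style
lookups) is by contrast the true temporal midpoint, nearest sample.

**Outcomes.** Midstance of a foot is the temporal midpoint of its stance
(heel strike → toe-off); since the foot is stationary on the belt around
midstance, the extracted position is insensitive to the exact instant.
FP = swing-foot ML position at midstance minus the contralateral foot at
*its* midstance (signed step width); FP2 = swing foot at midstance minus
the CoM at toe-off. CoM_pos is the CoM relative to the stance foot at the
stance foot's midstance (a fixed per-step reference); CoM_vel is the
forward difference of the 50 Hz CoM divided by the time step, last value
repeated. Kinematics are interpolated at event times defined on the
200 Hz grid rather than rounded to 50 Hz samples, to avoid phase bias at
slow cadence. All step-level quantities are mirrored into a leg frame
with lateral positive, so left and right steps pool; analyses keep the
final `n_strides` complete steps per leg.

**EMG.** Zero-lag 2nd-order Butterworth high-pass at 20 Hz, full-wave
rectification, zero-lag 2nd-order Butterworth low-pass at 50 Hz, in that
order (filter order is a knob; the 2 Hz-artefact attenuation test pins
the default). Strides (ipsilateral heel strike to heel strike — the
alignment is configurable since either convention appears in practice)
are normalised to 1000 samples; the swing feature is the median envelope
over the phase interval [0.60, 0.80) — samples 601–800 in 1-based
counting, half-open to avoid double-counting the 80 % point — multiplied
by that window's duration in seconds (a median·time product rather than
an integral, which would amplify artefacts). FP2 and both EMG features
are z-normalised per participant × trial with the sample (n−1) standard
deviation.

**Models.** Both models are ordinary least squares without intercept on
demeaned data (demeaning absorbs the intercept; demeaning is per
participant × condition × trial). R² = 1 − SSE/SST, which on demeaned
data equals the ordinary centred R². Rank-deficient designs raise an
error naming the collinear columns. The foot-placement model is fitted
independently at each of the 51 phases; the muscle model once per trial.

**Fisher transform.** `fisher_transform(r2)` defaults to the
multiple-correlation scale, z = atanh(√R²), because atanh is the variance
stabiliser for correlations and √R² is the multiple correlation;
`scale="r2"` gives atanh(R²) for compatibility with analyses that apply
the transform to R² directly. R² = 1 maps to +inf with a warning.

**Group statistics.** The 2×2 repeated-measures decomposition is
contrast-based: each main effect and the interaction is a
within-participant difference contrast tested with a one-sample t; the
planned post-hocs (constrained vs steady at each speed) are paired t
tests, one-tailed where the hypothesis fixes a direction. This is
algebraically the classical 2×2 within-subject ANOVA (each F with 1
numerator df equals the square of the corresponding contrast t). A JZS
Bayes factor with Cauchy prior scale √2/2 on the standardised effect is
available for one-sample tests, computed by adaptive quadrature of the
non-central-t likelihood over the prior and cross-checked in the tests
against a dense-grid integration and an independent implementation. A
full Bayesian model-averaging repeated-measures ANOVA is intentionally
out of scope: its prior structure is a modelling exercise of its own and
the frequentist contrasts answer the same directional questions here.

## The synthetic walker

The generator exists so that every stage of the pipeline can be verified
by parameter recovery without any external data.

**Dynamics.** Mediolateral CoM motion follows
`x'' = (g/l0)(x − u(t)) − b·x' − κ·x`, an inverted pendulum of leg length
`l0` about the centre of pressure `u`, plus an auxiliary damping `b` and
weak lane-centred stiffness `κ`. The auxiliary terms stand for the
balance mechanisms a point-mass pendulum with stepping cannot express —
hip strategy (angular-momentum control), push-off modulation and visual
lane keeping. They are not decoration: a bare pendulum-plus-stepping
walker (i) cannot walk stably at all once placement feedback is
down-weighted by a target-stepping task, and (ii) returns every placement
error ~6-fold amplified into the next step's state, which pins the
foot-placement model's R² near 1 — neither of which is true of human
walkers. `u` during a stance is the foot position plus a per-stance
corrective ankle shift: gain × the stance-onset deviation from the
nominal cycle state, plus a per-stance fluctuation (`cop_noise_sd`),
clipped to ±`cop_half_width` (0.03 m for shoes, 0.005 m for the 1 cm
ridge). During each double-support episode the CoP moves linearly from
the old to the new foot's value, starting with a 10 % body-weight impact
step at heel strike. Because the dynamics are linear with piecewise-linear
`u(t)`, the state is propagated *exactly* segment by segment (cosh/sinh,
or complex-exponential roots when the auxiliary terms are on) on the
200 Hz grid; kinematics are the 50 Hz decimation. An earlier fixed-step
RK4 design was dropped in favour of the exact propagation — same grid,
no truncation error, faster.

**Controller.** At each heel strike the new foot lands at
`FP = W_off + (1−λ)(k_pos·CoM_pos + k_vel·CoM_vel)` blended with a fixed
lab-frame target line with weight `λ`, plus Gaussian motor noise
(`fp_noise_sd`). Two deliberate design points:

- *The controller consumes the measured state*, i.e. the 50 Hz CoM and
  its forward-difference velocity interpolated at the heel-strike sample
  — exactly what the analysis later computes. The regression is then
  literally the data-generating process, so with zero placement noise the
  fit recovers the gains exactly and R² = 1 (the package's strongest
  self-check). The measured state two kinematic samples past heel strike
  depends weakly (≈1e−4 relative) on the placement itself through the
  load ramp; a 3-cycle fixed-point iteration closes that loop to machine
  precision. Persistent step-to-step excitation in the noiseless case
  comes from the per-stance CoP fluctuation.
- *The nominal offset `W_off` is calibrated at run time*: the realized
  mean step width is linear in the offset with a large
  configuration-dependent slope, so a short noise-free probe simulation
  and a secant iteration pin the realized width to the configured
  `nominal_step_width` (cached per configuration).

**Stability and default parameters.** The closed-loop step-to-step map
(including the double-support ramp and the measurement conventions) was
characterised by injecting unit impulses into the simulator's own noise
streams and reading the placement response. Gains and auxiliary
parameters were chosen on that response surface: stable gait, low
amplification of placement noise, realistic step-width variability
(≈20 mm at 8–12 mm motor noise). The defaults are per speed — normal:
k_pos = 0.60, k_vel = 0.35 s, aux (κ = 3.5 s⁻², b = 3.0 s⁻¹); slow:
k_pos = 0.50, k_vel = 0.25 s, aux (6.5, 4.5) and a baseline target
weight λ = 0.35 — encoding the empirical observation that placement
control matters less, and other mechanisms more, at slow speeds. This
yields steady-state degrees of control R²(ts) ≈ 0.86 (normal) and ≈ 0.66
(slow): the correct ordering and plausible magnitudes, though higher than
the ≈ 0.6/0.4 reported for human treadmill walking — a known limitation
of a generator whose placement rule is exactly the fitted model.

**Conditions.** `fp_constrained` raises the target weight (0.12 normal /
0.78 slow) and the auxiliary recruitment, reproducing the directional
signature of target stepping: lower R², more so at slow speed, and lower
step-width variability. `ankle_constrained` sets the CoP clip to 5 mm and
applies the compensations seen on a ridge: +25 mm nominal step width, a
cadence increase (×1.04 normal, ×1.16 slow) and a placement-noise factor
(1.0 / 1.22; the ridge also degrades placement accuracy). The clip cuts
both the unexplained noise absorption and the explained corrective action
of the ankle strategy; with the compensations the net change in the
degree of control is approximately zero — the constraint is compensated
by wider, quicker stepping rather than by tighter placement control.
These settings are the generator's fixed study conditions, not tuning
knobs of the analysis.

**Signals.** Per-belt vertical forces trade complementarily over double
support (total load constant at body weight); each belt's ML CoP is the
foot position plus its stance shift, the AP CoP a heel-to-toe ramp, so
the combined CoP traces the classic butterfly. Force synthesis is shaped
so that threshold crossings land on the true event samples (an impact
step at heel strike; unloading that reaches ≈8 % body weight one sample
before lift-off). EMG is synthesised post hoc (it does not feed back):
per stride, Gaussian bursts centred at 70 % of the cycle (σ = 5 %)
amplitude-modulate unit-variance 50–150 Hz band noise on a tonic
baseline, plus white sensor noise; the gm burst amplitude increases and
the al amplitude decreases with the ensuing step's lateral deviation
(gain 3 a.u./m, floored at zero). The resulting muscle-model R² (≈ 0.17)
is far above the ≈ 0.03 of real surface EMG — real envelopes carry far
more non-placement-related variability — but the sign structure and the
feature pipeline are what the tests exercise. Anteroposterior dynamics
are not simulated; the AP ramp exists only to give the butterfly detector
its reversal.

**What the generator does not emulate.** Timing variability beyond a
per-participant cadence scale (the metronome of the emulated protocol
fixes cadence within trial), 3-D kinematics and segment inertia, ankle
moments as torques (the constraint is geometric), EMG crosstalk and
motion artefact, treadmill belt interactions, and learning/adaptation
within or across trials. Passing tests therefore certify the *pipeline* —
its algebra, conventions, detectors and statistics — on data with the
assumed structure, not the biological claims themselves.

**Cohorts.** Synthetic cohorts draw leg length ~ N(0.92, 0.05) m (clipped
to 0.80–1.08), body mass ~ N(70, 10) kg and a preferred-cadence scale
~ N(1.00, 0.04) per participant; per-trial seeds derive deterministically
from (cohort seed, participant, cell). Anthropometric mass-regression
tables for segmental CoM estimation are a configurable input with an
illustrative default; unit tests use toy tables with hand-checkable
values, and the synthetic trials carry a precomputed CoM channel (the
generator's own), so the segmental path is exercised separately.

## Numerical choices and degenerate inputs

- Divergent gait (|CoM − CoP| > 1 m) raises `SimulationUnstableError`
  naming the gains.
- `ols_demeaned` checks demeaning (tolerance 1e−8 relative to the data
  scale), requires n > p, and reports collinear columns on rank
  deficiency. R² is clipped to [0, 1] against floating-point undershoot.
- `znorm_trial` rejects constant inputs ("degenerate feature"), testing
  both the sample SD and the range to be robust to floating-point
  residue.
- `normalize_step` requires ≥ 2 samples in the window and rejects NaNs,
  naming the offending span.
- The JZS integral is split at zero (the integrand can be sharply peaked
  on one side); the grid method exists purely as an independent check.
- Problem sizes in the test-suite and acceptance runs (cohorts of 12–30
  participants, 50–200 strides, 20-trial detector sweeps) are chosen so
  each check has clear statistical resolution while the whole validation
  runs in about a minute; all are parameters, not limits.
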