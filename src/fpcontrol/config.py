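"""Simulation configuration for the synthetic lateral-balance walker.

The generator emulates treadmill walking at two speeds under three
experimental conditions:

``steady``
    unconstrained walking; foot placement follows the mediolateral CoM
    state, the stance ankle shifts the CoP within a comfortable margin.
``ankle_constrained``
    walking on a narrow ridge (half-width ``cop_half_width``, default
    0.005 m for a 1 cm ridge) that all but eliminates within-stance CoP
    shifts; walkers compensate with a wider nominal step and a slightly
    higher stride frequency.
``fp_constrained``
    stepping onto projected target lines; the CoM-state contribution to
    placement is down-weighted by ``fp_target_weight``.

Belt speed is normalised to leg length: 1.25 * sqrt(l0) m/s at normal and
0.63 * sqrt(l0) m/s at slow speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

SPEED_COEF = {"normal": 1.25, "slow": 0.63}
CONDITIONS = ("steady", "ankle_constrained", "fp_constrained")

#: study-condition defaults that differ between the two belt speeds.
#: At slow speed, stepping is known to matter relatively less: the walker
#: relaxes placement control toward target-like stepping (baseline
#: ``fp_target_weight``) and leans more on non-stepping balance
#: mechanisms (stronger auxiliary damping/stiffness, softer gains).
_SPEED_DEFAULTS = {
    "normal": {
        "stride_frequency": 0.90, "fp_noise_sd": 0.008,
        "k_pos": 0.60, "k_vel": 0.35,
        "aux_stiffness": 3.5, "aux_damping": 3.0,
        "fp_target_weight": 0.0,
        "fp_constrained_weight": 0.12, "fp_constrained_aux": (4.5, 3.2),
        "ankle_noise_factor": 1.0, "ankle_freq_factor": 1.04,
    },
    "slow": {
        "stride_frequency": 0.70, "fp_noise_sd": 0.012,
        "k_pos": 0.50, "k_vel": 0.25,
        "aux_stiffness": 6.5, "aux_damping": 4.5,
        "fp_target_weight": 0.35,
        "fp_constrained_weight": 0.78, "fp_constrained_aux": (9.5, 5.5),
        "ankle_noise_factor": 1.22, "ankle_freq_factor": 1.16,
    },
}

#: ankle-moment-constrained condition: ridge half-width plus the
#: compensatory strategy (wider steps, higher cadence) seen on the ridge
_ANKLE_CONSTRAINED = {
    "cop_half_width": 0.005,
    "step_width_bonus": 0.025,
}


@dataclass
class SimConfig:
    """All knobs of one synthetic trial.

    Units are SI throughout; gains are those of the step-to-step
    controller ``FP = k_pos * CoM_pos + k_vel * CoM_vel + W + noise``
    expressed in the lateral (swing-side-positive) frame.
    """

    leg_length: float = 0.90  # m, pendulum length
    body_mass: float = 70.0  # kg, scales ground reaction forces
    speed_mode: str = "normal"  # {normal, slow}
    condition: str = "steady"
    stride_frequency: float = 0.90  # Hz
    n_strides: int = 200  # analysed strides per leg
    warmup_strides: int = 5  # extra strides simulated before the analysed set
    k_pos: float = 1.10  # step-to-step position gain, dimensionless
    k_vel: float = 0.44  # step-to-step velocity gain, s
    nominal_step_width: float = 0.12  # m
    fp_noise_sd: float = 0.008  # m, motor noise on each placement
    cop_half_width: float = 0.03  # m, max within-stance CoP excursion
    cop_gain: float = 0.25  # ankle-strategy gain on the stance-onset CoM error
    cop_gain_vel: float = 0.0  # ankle-strategy gain on the stance-onset CoM velocity, s
    cop_noise_sd: float = 0.003  # m, per-stance CoP fluctuation
    fp_target_weight: float = 0.0  # 0 = free walking, 1 = pure target stepping
    aux_stiffness: float = 0.0  # s^-2, auxiliary balance stiffness toward the lane
    aux_damping: float = 0.0  # s^-1, auxiliary lateral damping
    double_support_fraction: float = 0.20  # of the stride (two episodes)
    emg_gain: float = 3.0  # burst-amplitude units per m of lateral deviation
    emg_noise_sd: float = 0.02  # a.u., additive sensor noise
    emg_tonic: float = 0.15  # a.u., baseline activity outside bursts
    include_emg: bool = True
    rate_force: float = 200.0  # Hz
    rate_kin: float = 50.0  # Hz
    rate_emg: float = 2000.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.cop_half_width < 0:
            raise ValueError("cop_half_width must be >= 0")
        if self.fp_noise_sd < 0:
            raise ValueError("fp_noise_sd must be >= 0")
        for name in ("rate_force", "rate_kin", "rate_emg", "stride_frequency"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.speed_mode not in SPEED_COEF:
            raise ValueError(f"unknown speed_mode {self.speed_mode!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.rate_force % self.rate_kin:
            raise ValueError("rate_force must be an integer multiple of rate_kin")
        if not 0.0 <= self.fp_target_weight <= 1.0:
            raise ValueError("fp_target_weight must lie in [0, 1]")

    @property
    def belt_speed(self) -> float:
        """Treadmill belt speed in m/s, normalised to leg length."""
        return SPEED_COEF[self.speed_mode] * self.leg_length ** 0.5

    @property
    def effective_k_pos(self) -> float:
        """Position gain actually applied after any target down-weighting."""
        return (1.0 - self.fp_target_weight) * self.k_pos

    @property
    def effective_k_vel(self) -> float:
        return (1.0 - self.fp_target_weight) * self.k_vel


def make_config(speed_mode: str = "normal", condition: str = "steady",
                seed: int = 0, **overrides) -> SimConfig:
    """Build a :class:`SimConfig` with the study-condition presets applied.

    The presets encode what each experimental condition does to a walker:
    slow walking lowers cadence and raises placement noise (the degree of
    foot-placement control is empirically lower at slow speeds); the
    ankle-moment constraint narrows the CoP margin to the ridge half-width
    and triggers the compensatory wider/faster gait; the foot-placement
    constraint down-weights the CoM-state contribution to placement, more
    strongly at slow speed where target stepping is easier to comply with.
    Explicit ``overrides`` always win over the presets.
    """
    if speed_mode not in _SPEED_DEFAULTS:
        raise ValueError(f"unknown speed_mode {speed_mode!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    sp = _SPEED_DEFAULTS[speed_mode]
    params = {
        "speed_mode": speed_mode,
        "condition": condition,
        "seed": seed,
        "stride_frequency": sp["stride_frequency"],
        "fp_noise_sd": sp["fp_noise_sd"],
        "k_pos": sp["k_pos"],
        "k_vel": sp["k_vel"],
        "aux_stiffness": sp["aux_stiffness"],
        "aux_damping": sp["aux_damping"],
        "fp_target_weight": sp["fp_target_weight"],
    }
    if condition == "ankle_constrained":
        ac = _ANKLE_CONSTRAINED
        params["cop_half_width"] = ac["cop_half_width"]
        params["nominal_step_width"] = (
            SimConfig.nominal_step_width + ac["step_width_bonus"])
        params["stride_frequency"] = sp["stride_frequency"] * sp["ankle_freq_factor"]
        # the ridge both blocks ankle corrections and degrades placement
        # accuracy; the latter keeps the degree of control net-unchanged
        params["fp_noise_sd"] = sp["fp_noise_sd"] * sp["ankle_noise_factor"]
    elif condition == "fp_constrained":
        params["fp_target_weight"] = sp["fp_constrained_weight"]
        params["aux_stiffness"], params["aux_damping"] = sp["fp_constrained_aux"]
    params.update(overrides)
    return SimConfig(**params)


def with_overrides(cfg: SimConfig, **overrides) -> SimConfig:
    """Return a copy of ``cfg`` with fields replaced."""
    return replace(cfg, **overrides)
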