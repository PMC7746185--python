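"""Synthetic lateral-balance walker.

The mediolateral dynamics of treadmill walking are modelled as an
inverted pendulum of length ``l0``::

    x'' = (g / l0) * (x - u(t))

where ``x`` is the mediolateral CoM position and ``u`` the centre of
pressure.  During stance, ``u`` is the stance-foot position plus a
within-stance corrective shift (the ankle strategy), clipped to
``+/- cop_half_width``.  At every heel strike the new foot is placed by a
step-to-step controller in the lateral (swing-side-positive) frame::

    FP = W + (1 - lam) * (k_pos * CoM_pos + k_vel * CoM_vel) + eps

with ``W`` the nominal step width, ``lam`` the target-stepping weight
(zero in free walking) and ``eps`` Gaussian motor noise.  ``CoM_pos`` and
``CoM_vel`` are, deliberately, the *measured* quantities of the
downstream analysis: the 50 Hz CoM trace and its forward-difference
velocity, linearly interpolated at the heel-strike instant.  This makes
the controller the exact data-generating process of the foot-placement
regression, so with zero placement noise the regression recovers the
gains exactly.  The measured state a few samples past heel strike depends
(very weakly, through the double-support load ramp) on the placement
itself; a short fixed-point iteration resolves that circularity to
machine precision.

Because the pendulum is linear and ``u(t)`` piecewise linear in time, the
state is propagated *exactly* segment by segment using the cosh/sinh
closed form, evaluated on the 200 Hz force grid; kinematics are the 50 Hz
decimation of that grid.

Ground reaction forces trade linearly between the belts over each
double-support episode (with a small impact step at heel strike), and the
per-belt CoP traces (mediolateral: foot position + ankle shift;
anteroposterior: a heel-to-toe ramp) combine into the classic butterfly
pattern.  EMG is synthesised last: Gaussian bursts at 60-80% of each
stride, amplitude-modulating 50-150 Hz band noise, with burst amplitude
increasing (gluteus medius) or decreasing (adductor longus) with the
ensuing step's lateral deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .config import SimConfig

G = 9.81  # m/s^2

__all__ = [
    "TrialTimeSeries",
    "SimTruth",
    "SimulationUnstableError",
    "simulate_trial",
    "realized_stride_frequency",
    "propagate_pendulum",
]


class SimulationUnstableError(RuntimeError):
    """The walker diverged; the gain combination does not stabilise gait."""

    def __init__(self, k_pos: float, k_vel: float, excursion: float):
        super().__init__(
            f"simulated CoM diverged (|CoM - CoP| reached {excursion:.2f} m): "
            f"gains k_pos={k_pos:g}, k_vel={k_vel:g} do not stabilise the walker"
        )
        self.k_pos = k_pos
        self.k_vel = k_vel


@dataclass
class TrialTimeSeries:
    """Synchronised raw channels of one trial, at the native rates."""

    force_time: np.ndarray  # s, 200 Hz grid
    fz: dict  # leg -> vertical force, N
    cop_ml: dict  # leg -> per-belt mediolateral CoP, m
    cop_ap: dict  # leg -> per-belt anteroposterior CoP, m
    combined_cop_ml: np.ndarray
    combined_cop_ap: np.ndarray
    kin_time: np.ndarray  # s, 50 Hz grid
    com_ml: np.ndarray  # m
    foot_ml: dict  # leg -> foot marker mediolateral position, m
    emg_time: np.ndarray | None  # s, 2 kHz grid (None if EMG disabled)
    emg: dict | None  # channel name -> a.u. (gm_L, gm_R, al_L, al_R)
    condition: str = "steady"
    speed_mode: str = "normal"
    rate_force: float = 200.0
    rate_kin: float = 50.0
    rate_emg: float = 2000.0
    body_mass: float = 70.0
    leg_length: float = 0.90
    meta: dict = field(default_factory=dict)

    @property
    def total_fz(self) -> np.ndarray:
        return self.fz["L"] + self.fz["R"]


@dataclass
class SimTruth:
    """Ground truth of one synthetic trial (the recovery oracle)."""

    true_k_pos: float
    true_k_vel: float
    effective_k_pos: float  # after target down-weighting
    effective_k_vel: float
    nominal_step_width: float
    heel_strike_times: dict  # leg -> exact times, s
    toe_off_times: dict  # leg -> exact times, s
    placements: dict  # leg -> foot positions at each heel strike, m (treadmill frame)
    fp_lateral: dict  # leg -> realised lateral step width per placement, m
    com_series: np.ndarray  # exact CoM on the kinematic grid, m
    emg_burst_gm: dict | None = None  # leg -> burst amplitude per stride
    emg_burst_al: dict | None = None
    seed: int = 0

    def all_heel_strikes(self) -> np.ndarray:
        return np.sort(np.concatenate(list(self.heel_strike_times.values())))


def propagate_pendulum(x0: float, v0: float, omega: float,
                       u0: float, u1: float, tau: np.ndarray):
    """Exact inverted-pendulum propagation under a linear-in-time CoP.

    Solves ``x'' = omega^2 (x - u(t))`` with ``u`` linear from ``u0`` at
    ``tau=0`` to ``u1`` at ``tau[-1]`` (constant if ``tau[-1] == 0``).
    Returns ``(x, v)`` evaluated at the times in ``tau``.
    """
    tau = np.asarray(tau, dtype=float)
    T = tau[-1] if tau.size and tau[-1] > 0 else 0.0
    b = (u1 - u0) / T if T > 0 else 0.0
    a = u0
    ch = np.cosh(omega * tau)
    sh = np.sinh(omega * tau)
    x = a + b * tau + (x0 - a) * ch + ((v0 - b) / omega) * sh
    v = b + (x0 - a) * omega * sh + (v0 - b) * ch
    return x, v


def _propagate_lateral(x0: float, v0: float, omega: float, damping: float,
                       stiffness: float, u0: float, u1: float,
                       tau: np.ndarray):
    """Segment-exact propagation of the augmented lateral dynamics.

    Solves ``x'' = omega^2 (x - u(t)) - damping * x' - stiffness * x``
    with ``u`` linear in time.  ``damping``/``stiffness`` model balance
    strategies outside the pendulum-plus-stepping core (hip strategy,
    push-off modulation, visual lane keeping); both zero recovers the
    pure inverted pendulum.
    """
    if damping == 0.0 and stiffness == 0.0:
        return propagate_pendulum(x0, v0, omega, u0, u1, tau)
    tau = np.asarray(tau, dtype=float)
    T = tau[-1] if tau.size and tau[-1] > 0 else 0.0
    sigma = (u1 - u0) / T if T > 0 else 0.0
    w2 = omega * omega
    k_eff = stiffness - w2  # x'' + damping x' + k_eff x = -w2 u(t)
    if abs(k_eff) < 1e-12:
        raise ValueError("aux stiffness equal to the pendulum stiffness is "
                         "degenerate; choose a different value")
    beta = -w2 * sigma / k_eff
    alpha = (-w2 * u0 - damping * beta) / k_eff
    disc = complex(damping * damping - 4.0 * k_eff)
    r1 = (-damping + np.sqrt(disc)) / 2.0
    r2 = (-damping - np.sqrt(disc)) / 2.0
    if abs(r1 - r2) < 1e-12:
        raise ValueError("critically damped auxiliary dynamics unsupported; "
                         "perturb the damping value")
    c0 = x0 - alpha
    d0 = v0 - beta
    A = (d0 - r2 * c0) / (r1 - r2)
    B = c0 - A
    e1 = np.exp(r1 * tau)
    e2 = np.exp(r2 * tau)
    x = alpha + beta * tau + (A * e1 + B * e2).real
    v = beta + (A * r1 * e1 + B * r2 * e2).real
    return x, v


def _band_noise(rng: np.random.Generator, n: int, rate: float,
                lo: float = 50.0, hi: float = 150.0) -> np.ndarray:
    """Unit-variance band-limited noise carrier for EMG synthesis."""
    sos = butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def realized_stride_frequency(truth: SimTruth, leg: str = "R") -> float:
    """Mean inverse inter-heel-strike interval of one leg, in Hz."""
    times = np.asarray(truth.heel_strike_times[leg], dtype=float)
    if times.size < 2:
        raise ValueError(
            f"need at least 2 heel strikes on leg {leg!r} to compute a "
            f"stride frequency (got {times.size})")
    return float(np.mean(1.0 / np.diff(times)))


def _offset_calibration_key(cfg: SimConfig):
    return (cfg.leg_length, cfg.stride_frequency, cfg.k_pos, cfg.k_vel,
            cfg.nominal_step_width, cfg.cop_gain, cfg.cop_gain_vel,
            cfg.cop_half_width, cfg.fp_target_weight, cfg.aux_stiffness,
            cfg.aux_damping, cfg.double_support_fraction, cfg.rate_force,
            cfg.rate_kin)


_offset_cache: dict = {}


def _calibrated_offset(cfg: SimConfig, analytic_guess: float) -> float:
    """Secant-calibrate the controller offset so that the noise-free gait
    settles on a symmetric cycle of the configured nominal step width.

    The analytic offset comes from the no-double-support limit cycle; the
    load-transfer ramp and the discrete state-measurement conventions
    shift the true fixed point, which is cheapest to find by running the
    (fast, noise-free) dynamics themselves.
    """
    from .config import with_overrides

    key = _offset_calibration_key(cfg)
    if key in _offset_cache:
        return _offset_cache[key]
    probe = with_overrides(cfg, n_strides=20, warmup_strides=5,
                           fp_noise_sd=0.0, cop_noise_sd=0.0,
                           include_emg=False, seed=0)
    target = cfg.nominal_step_width

    def realized(off):
        _, truth = simulate_trial(probe, _w_off=off)
        fp = np.concatenate([truth.fp_lateral["L"][-8:], truth.fp_lateral["R"][-8:]])
        return float(fp.mean())

    # realized width is (empirically) linear in the offset with a large,
    # configuration-dependent slope; probe two small offsets, solve, refine
    w0, w1 = 0.002, 0.006
    f0, f1 = realized(w0) - target, realized(w1) - target
    for _ in range(4):
        if f1 == f0:
            break
        w2 = w1 - f1 * (w1 - w0) / (f1 - f0)
        try:
            f2 = realized(w2) - target
        except SimulationUnstableError:
            w2 = 0.5 * (w1 + w2)
            f2 = realized(w2) - target
        w0, f0, w1, f1 = w1, f1, w2, f2
        if abs(f1) < 1e-7:
            break
    _offset_cache[key] = w1
    return w1


def simulate_trial(config: SimConfig, _w_off: float | None = None,
                   _fp_kick=None, _cop_kick=None):
    """Simulate one trial; returns ``(TrialTimeSeries, SimTruth)``.

    Deterministic given ``config`` (including its seed).  Raises
    :class:`SimulationUnstableError` when the gain combination lets the
    CoM diverge.
    """
    cfg = config
    rng_dyn, rng_emg = [np.random.Generator(np.random.PCG64(s))
                        for s in np.random.SeedSequence(cfg.seed).spawn(2)]

    omega = math.sqrt(G / cfg.leg_length)
    dt_f = 1.0 / cfg.rate_force
    dt_k = 1.0 / cfg.rate_kin
    decim = int(round(cfg.rate_force / cfg.rate_kin))
    t_step = 1.0 / (2.0 * cfg.stride_frequency)
    t_ds = cfg.double_support_fraction * t_step  # one episode = half the stride total
    n_ds = max(int(round(t_ds * cfg.rate_force)), 9)

    n_events = 2 * (cfg.n_strides + cfg.warmup_strides) + 2
    # lead-in: the tail of a left single-support phase, slightly longer than
    # a swing so the first right step is preceded by a full stance
    lead_in = (t_step - t_ds) + 0.1
    hs_times = lead_in + t_step * np.arange(n_events)
    hs_samples = np.rint(hs_times * cfg.rate_force).astype(int)
    hs_legs = ["R" if j % 2 == 0 else "L" for j in range(n_events)]

    duration = hs_times[-1] + 1.0
    n_f = (int(math.ceil(duration * cfg.rate_force)) // decim) * decim + 1
    n_k = (n_f - 1) // decim + 1

    w_impact = 0.10  # load fraction taken instantly at heel strike
    lam = cfg.fp_target_weight
    W = cfg.nominal_step_width
    h = cfg.cop_half_width

    # Controller offset consistent with a symmetric limit cycle of width W.
    # On that cycle the CoM at heel strike sits midway between the feet
    # (c* = W/2) with lateral velocity v* = omega * (W/2) * S / (1 + C),
    # where C, S are cosh/sinh of omega * step time; the offset makes the
    # controller reproduce FP = W there.
    C_cyc = math.cosh(omega * t_step)
    S_cyc = math.sinh(omega * t_step)
    c_star = W / 2.0
    v_star = omega * c_star * S_cyc / (1.0 + C_cyc)
    w_off = W - cfg.k_pos * c_star - cfg.k_vel * v_star
    if _w_off is not None:
        w_off = _w_off
    else:
        w_off = _calibrated_offset(cfg, w_off)
    # target lines of the foot-placement constraint, fixed in the lab frame
    p_line = {"L": -W / 2.0, "R": W / 2.0}

    # pre-drawn randomness so that EMG synthesis cannot perturb the dynamics
    fp_noise = rng_dyn.standard_normal(n_events) * cfg.fp_noise_sd
    cop_noise = rng_dyn.standard_normal(n_events + 1) * cfg.cop_noise_sd
    if _fp_kick is not None:  # deterministic impulse, for response probing
        fp_noise[_fp_kick[0]] += _fp_kick[1]
    if _cop_kick is not None:
        cop_noise[_cop_kick[0]] += _cop_kick[1]

    x200 = np.zeros(n_f)
    placements = {"L": [], "R": []}
    fp_lateral = {"L": [], "R": []}
    stance_shifts = {"L": [], "R": []}

    # initial single support on the left foot; back-propagate the limit-cycle
    # heel-strike state so the walker starts close to steady gait
    p_foot = {"L": -W / 2.0, "R": W / 2.0}
    x_hs = p_foot["L"] + c_star
    xs, vs = _propagate_lateral(x_hs, v_star, omega, cfg.aux_damping,
                                cfg.aux_stiffness, p_foot["L"], p_foot["L"],
                                np.array([0.0, -lead_in]))
    x, v = float(xs[1]), float(vs[1])
    shift_old = float(np.clip(
        cfg.cop_gain * ((x - p_foot["L"]) - W / 2.0)
        + cfg.cop_gain_vel * (v + v_star) + cop_noise[-1], -h, h))
    u_old = p_foot["L"] + shift_old
    stance_leg = "L"

    def _fill(seg_x, s0):
        x200[s0:s0 + seg_x.size] = seg_x

    def _check(seg_x, u_ref):
        exc = np.max(np.abs(seg_x - u_ref))
        if exc > 1.0:
            raise SimulationUnstableError(cfg.k_pos, cfg.k_vel, float(exc))

    # lead-in: constant CoP under the left foot
    k0 = hs_samples[0]
    tau = np.arange(k0 + 1) * dt_f
    seg_x, seg_v = _propagate_lateral(x, v, omega, cfg.aux_damping,
                                      cfg.aux_stiffness, u_old, u_old, tau)
    _check(seg_x, u_old)
    _fill(seg_x, 0)
    x, v = float(seg_x[-1]), float(seg_v[-1])

    def measured_state(k_hs, head_x):
        """CoM position/velocity at sample ``k_hs`` in the analysis convention.

        Uses the 50 Hz decimated CoM and its forward-difference velocity,
        linearly interpolated at the heel-strike time.  ``head_x`` holds the
        provisional post-heel-strike trajectory for samples > k_hs.
        """
        m = k_hs // decim

        def com_at(j):
            s = j * decim
            return x200[s] if s <= k_hs else head_x[s - k_hs]

        c0, c1, c2 = com_at(m), com_at(m + 1), com_at(m + 2)
        tk = np.array([m * dt_k, (m + 1) * dt_k])
        t_dec = k_hs * dt_f
        pos = float(np.interp(t_dec, tk, np.array([c0, c1])))
        vel = float(np.interp(t_dec, tk,
                              np.array([(c1 - c0) / dt_k, (c2 - c1) / dt_k])))
        return pos, vel

    n_head = 2 * decim + 1  # enough samples to cover two kinematic intervals

    for j in range(n_events):
        k_hs = hs_samples[j]
        new_leg = hs_legs[j]
        s = 1.0 if new_leg == "R" else -1.0
        p_contra = p_foot[stance_leg]

        # fixed-point iteration: the measured state just after heel strike
        # depends weakly on the placement through the load ramp
        def place(c_pos, c_vel):
            p_ctrl = p_contra + s * (w_off + cfg.k_pos * c_pos + cfg.k_vel * c_vel)
            return (1 - lam) * p_ctrl + lam * p_line[new_leg] + s * fp_noise[j]

        def ankle_shift(p):
            # corrective shift on the deviation from the nominal stance-onset
            # state; absorbs part of the placement error within the stance
            err_pos = (x - p) + s * W / 2.0
            err_vel = v - s * v_star
            return float(np.clip(cfg.cop_gain * err_pos
                                 + cfg.cop_gain_vel * err_vel
                                 + cop_noise[j], -h, h))

        p_new = place(s * (x - p_contra), s * v)
        tau_head = np.arange(n_head) * dt_f
        for _ in range(3):
            u_new = p_new + ankle_shift(p_new)
            u_start = (1 - w_impact) * u_old + w_impact * u_new
            u_head_end = u_start + (u_new - u_start) * (n_head - 1) / n_ds
            head_x, _ = _propagate_lateral(x, v, omega, cfg.aux_damping,
                                           cfg.aux_stiffness, u_start,
                                           u_head_end, tau_head)
            c_pos, c_vel = measured_state(k_hs, head_x)
            p_new = place(s * (c_pos - p_contra), s * c_vel)
        fp = s * (p_new - p_contra)

        shift_new = ankle_shift(p_new)
        u_new = p_new + shift_new
        placements[new_leg].append(p_new)
        fp_lateral[new_leg].append(fp)
        stance_shifts[new_leg].append(shift_new)

        # double support: CoP sweeps from the old to the new foot
        u_start = (1 - w_impact) * u_old + w_impact * u_new
        tau = np.arange(n_ds + 1) * dt_f
        seg_x, seg_v = _propagate_lateral(x, v, omega, cfg.aux_damping,
                                          cfg.aux_stiffness, u_start, u_new, tau)
        _check(seg_x, 0.5 * (u_start + u_new))
        _fill(seg_x, k_hs)
        x, v = float(seg_x[-1]), float(seg_v[-1])

        # single support on the new foot
        k_end = hs_samples[j + 1] if j + 1 < n_events else n_f - 1
        n_ss = k_end - (k_hs + n_ds)
        tau = np.arange(n_ss + 1) * dt_f
        seg_x, seg_v = _propagate_lateral(x, v, omega, cfg.aux_damping,
                                          cfg.aux_stiffness, u_new, u_new, tau)
        _check(seg_x, u_new)
        _fill(seg_x, k_hs + n_ds)
        x, v = float(seg_x[-1]), float(seg_v[-1])

        p_foot[new_leg] = p_new
        stance_leg = new_leg
        u_old = u_new

    # ------------------------------------------------------------------ truth
    hs_by_leg = {leg: np.array([hs_times[j] for j in range(n_events)
                                if hs_legs[j] == leg]) for leg in "LR"}
    # a foot's toe-off follows the next contralateral heel strike by t_ds;
    # the initial left stance toes off after the very first heel strike
    to_by_leg = {leg: np.array([hs_times[j + 1] + t_ds for j in range(n_events - 1)
                                if hs_legs[j] == leg]) for leg in "LR"}
    to_by_leg["L"] = np.concatenate([[hs_times[0] + t_ds], to_by_leg["L"]])
    com_kin = x200[::decim].copy()

    # -------------------------------------------------------- force channels
    force_time = np.arange(n_f) * dt_f
    bw = cfg.body_mass * G
    fz = {"L": np.zeros(n_f), "R": np.zeros(n_f)}
    cop_ml = {"L": np.full(n_f, np.nan), "R": np.full(n_f, np.nan)}
    cop_ap = {"L": np.full(n_f, np.nan), "R": np.full(n_f, np.nan)}
    ap_heel, ap_toe = -0.12, 0.18

    stance_events = []  # (leg, k_hs, k_to, p, shift)
    for j in range(n_events):
        leg = hs_legs[j]
        i_leg = sum(1 for m in range(j) if hs_legs[m] == leg)
        k_hs = hs_samples[j]
        k_to = (hs_samples[j + 1] + n_ds) if j + 1 < n_events else n_f - 1
        stance_events.append((leg, k_hs, min(k_to, n_f - 1),
                              placements[leg][i_leg], stance_shifts[leg][i_leg]))
    # initial left stance before the first heel strike
    stance_events.insert(0, ("L", 0, hs_samples[0] + n_ds, -W / 2.0, shift_old))

    for leg, k_hs, k_to, p, sh in stance_events:
        n_st = k_to - k_hs
        if n_st <= 0:
            continue
        idx = np.arange(k_hs, k_to + 1)
        if k_hs == 0:  # initial stance starts fully loaded
            load = np.ones(idx.size)
        else:
            ramp = np.minimum((idx - k_hs) / n_ds, 1.0)
            load = w_impact + (1 - w_impact) * ramp
        if k_to < n_f - 1:  # no toe-off for a stance reaching the trial end
            tail = idx > (k_to - n_ds)
            # unload towards ~8% body weight, lifting off at the toe-off
            # sample itself: the threshold crossing then marks toe-off exactly
            tail_load = np.maximum(
                (1 - w_impact) * (k_to - idx[tail]) / n_ds, 0.08)
            tail_load[idx[tail] == k_to] = 0.0
            load[tail] = tail_load
        fz[leg][idx] = np.maximum(fz[leg][idx], load * bw)
        cop_ml[leg][idx] = p + sh
        cop_ap[leg][idx] = ap_heel + (ap_toe - ap_heel) * (idx - k_hs) / max(n_st, 1)

    total = fz["L"] + fz["R"]
    # per-belt CoP is undefined for an unloaded belt; hold the last defined value
    for leg in "LR":
        cop_ml[leg] = _ffill(cop_ml[leg])
        cop_ap[leg] = _ffill(cop_ap[leg])
    with np.errstate(invalid="ignore"):
        comb_ml = np.where(total > 0,
                           (fz["L"] * cop_ml["L"] + fz["R"] * cop_ml["R"])
                           / np.where(total > 0, total, 1.0), np.nan)
        comb_ap = np.where(total > 0,
                           (fz["L"] * cop_ap["L"] + fz["R"] * cop_ap["R"])
                           / np.where(total > 0, total, 1.0), np.nan)

    # --------------------------------------------------------- foot markers
    kin_time = np.arange(n_k) * dt_k
    foot_ml = {}
    for leg in "LR":
        pos0 = -W / 2.0 if leg == "L" else W / 2.0
        knots_t = [0.0]
        knots_p = [pos0]
        hs_l = hs_by_leg[leg]
        pl = placements[leg]
        for t_hs, p in zip(hs_l, pl):
            # swing starts at this foot's previous toe-off
            t_sw = t_hs - (t_step - t_ds)
            knots_t += [t_sw, t_hs]
            knots_p += [knots_p[-1], p]
        series = np.interp(kin_time, knots_t, knots_p)  # piecewise linear placeholder
        # smooth the swing transitions with a cosine blend
        for i in range(1, len(knots_t) - 1, 2):
            t0, t1 = knots_t[i], knots_t[i + 1]
            p0, p1 = knots_p[i], knots_p[i + 1]
            m = (kin_time >= t0) & (kin_time <= t1)
            w = 0.5 * (1 - np.cos(np.pi * (kin_time[m] - t0) / (t1 - t0)))
            series[m] = p0 + (p1 - p0) * w
        foot_ml[leg] = series

    # ----------------------------------------------------------------- EMG
    emg_time = None
    emg = None
    burst_gm = None
    burst_al = None
    if cfg.include_emg:
        n_e = int(round(duration * cfg.rate_emg)) + 1
        emg_time = np.arange(n_e) / cfg.rate_emg
        emg = {}
        burst_gm = {"L": [], "R": []}
        burst_al = {"L": [], "R": []}
        for leg in "LR":
            fp_arr = np.asarray(fp_lateral[leg])
            dev = fp_arr - fp_arr.mean() if fp_arr.size else fp_arr
            mod_gm = np.full(n_e, cfg.emg_tonic)
            mod_al = np.full(n_e, cfg.emg_tonic)
            hs_l = hs_by_leg[leg]
            for i in range(len(hs_l) - 1):
                t0, t1 = hs_l[i], hs_l[i + 1]
                T = t1 - t0
                a_gm = max(0.0, 1.0 + cfg.emg_gain * dev[i + 1])
                a_al = max(0.0, 1.0 - cfg.emg_gain * dev[i + 1])
                burst_gm[leg].append(a_gm)
                burst_al[leg].append(a_al)
                c = t0 + 0.70 * T
                sg = 0.05 * T
                lo = max(int((c - 4 * sg) * cfg.rate_emg), 0)
                hi = min(int((c + 4 * sg) * cfg.rate_emg) + 1, n_e)
                tt = emg_time[lo:hi]
                g = np.exp(-0.5 * ((tt - c) / sg) ** 2)
                mod_gm[lo:hi] += a_gm * g
                mod_al[lo:hi] += a_al * g
            for name, mod in (("gm", mod_gm), ("al", mod_al)):
                carrier = _band_noise(rng_emg, n_e, cfg.rate_emg)
                noise = rng_emg.standard_normal(n_e) * cfg.emg_noise_sd
                emg[f"{name}_{leg}"] = mod * carrier + noise
            burst_gm[leg] = np.asarray(burst_gm[leg])
            burst_al[leg] = np.asarray(burst_al[leg])

    trial = TrialTimeSeries(
        force_time=force_time, fz=fz, cop_ml=cop_ml, cop_ap=cop_ap,
        combined_cop_ml=comb_ml, combined_cop_ap=comb_ap,
        kin_time=kin_time, com_ml=com_kin, foot_ml=foot_ml,
        emg_time=emg_time, emg=emg,
        condition=cfg.condition, speed_mode=cfg.speed_mode,
        rate_force=cfg.rate_force, rate_kin=cfg.rate_kin, rate_emg=cfg.rate_emg,
        body_mass=cfg.body_mass, leg_length=cfg.leg_length,
        meta={"seed": cfg.seed, "belt_speed": cfg.belt_speed,
              "stride_frequency": cfg.stride_frequency,
              "n_strides": cfg.n_strides},
    )
    truth = SimTruth(
        true_k_pos=cfg.k_pos, true_k_vel=cfg.k_vel,
        effective_k_pos=cfg.effective_k_pos, effective_k_vel=cfg.effective_k_vel,
        nominal_step_width=W,
        heel_strike_times=hs_by_leg, toe_off_times=to_by_leg,
        placements={leg: np.asarray(placements[leg]) for leg in "LR"},
        fp_lateral={leg: np.asarray(fp_lateral[leg]) for leg in "LR"},
        com_series=com_kin, emg_burst_gm=burst_gm, emg_burst_al=burst_al,
        seed=cfg.seed,
    )
    return trial, truth


def _ffill(a: np.ndarray) -> np.ndarray:
    """Forward/backward-fill NaNs (used to keep unloaded-belt CoP defined)."""
    out = a.copy()
    mask = np.isnan(out)
    if mask.all():
        return out
    idx = np.where(~mask, np.arange(out.size), 0)
    np.maximum.accumulate(idx, out=idx)
    out = out[idx]
    first = np.argmax(~np.isnan(out))
    out[:first] = out[first]
    return out
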