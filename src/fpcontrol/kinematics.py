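"""Centre of mass estimation and per-step outcome variables.

Step-level outcomes follow the standard mediolateral foot-placement
analysis: ``FP`` is the swing foot's mediolateral position at midstance
relative to the contralateral foot at *its* midstance (the signed step
width); ``FP2`` is the swing foot at midstance relative to the CoM at
toe-off.  The predictors are the CoM position (relative to the stance
foot at its midstance) and CoM velocity, time-normalised to 51 samples
over the step (toe-off to heel strike).  All step-level quantities are
mirrored into a leg frame in which lateral is positive, so left and
right steps pool.

Midstance is taken as the temporal midpoint of a foot's stance phase
(heel strike to toe-off); the foot is stationary around midstance, so the
extracted position is insensitive to the exact instant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import GaitEvents, normalize_step, N_PHASE

__all__ = [
    "AnthropometricTable",
    "Segment",
    "StepRecord",
    "compute_com",
    "com_velocity",
    "extract_step_records",
    "condition_metrics",
    "records_to_frame",
]


# --------------------------------------------------------------------------
# anthropometry
# --------------------------------------------------------------------------

@dataclass
class Segment:
    """Kinematics of one body segment: ML positions of its endpoints."""

    name: str
    proximal: np.ndarray  # m, mediolateral position of the proximal endpoint
    distal: np.ndarray
    length: float  # m, longitudinal segment length
    circumference: float  # m


@dataclass
class AnthropometricTable:
    """Per-segment, per-gender mass regressions and CoM fractions.

    ``entries[(segment, gender)] = (intercept, coef_length,
    coef_circumference, com_fraction)``; mass (kg) is predicted from the
    segment length and circumference (m), and the segment CoM sits at
    ``com_fraction`` along the proximal-to-distal longitudinal axis.
    """

    entries: dict

    def __post_init__(self):
        for key, (a, bl, bc, frac) in self.entries.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"CoM fraction for {key} outside [0, 1]: {frac}")

    def coeffs(self, segment: str, gender: str):
        try:
            return self.entries[(segment, gender)]
        except KeyError:
            raise KeyError(
                f"no anthropometric entry for segment {segment!r}, "
                f"gender {gender!r}") from None

    def mass(self, segment: str, gender: str, length: float,
             circumference: float) -> float:
        a, bl, bc, _ = self.coeffs(segment, gender)
        m = a + bl * length + bc * circumference
        if m <= 0:
            raise ValueError(
                f"predicted non-positive mass ({m:.3f} kg) for segment "
                f"{segment!r} (length {length} m, circumference {circumference} m)")
        return m

    def com_fraction(self, segment: str, gender: str) -> float:
        return self.coeffs(segment, gender)[3]

    @classmethod
    def default(cls) -> "AnthropometricTable":
        """An illustrative default table (kg from m).

        These coefficients are generic placeholders of realistic magnitude
        for healthy adults; supply study-specific regression coefficients
        for real analyses.
        """
        base = {
            "foot": (-0.3, 1.0, 4.0, 0.45),
            "shank": (-1.0, 4.0, 8.0, 0.43),
            "thigh": (-2.5, 6.0, 18.0, 0.41),
            "pelvis": (-3.0, 10.0, 25.0, 0.50),
            "trunk": (-5.0, 20.0, 30.0, 0.50),
            "upperarm": (-0.5, 2.0, 6.0, 0.44),
            "forearm": (-0.4, 1.5, 5.0, 0.42),
        }
        entries = {}
        for seg, (a, bl, bc, frac) in base.items():
            entries[(seg, "F")] = (a * 0.95, bl * 0.95, bc * 0.95, frac)
            entries[(seg, "M")] = (a, bl, bc, frac)
        return cls(entries)


def compute_com(segments, table: AnthropometricTable, gender: str = "M") -> np.ndarray:
    """Whole-body CoM as the mass-weighted mean of segment CoMs.

    Each segment's mass comes from the table's linear regression on its
    length and circumference; its CoM lies at the tabulated fraction along
    the proximal-to-distal axis.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("need at least one segment")
    total_mass = 0.0
    weighted = None
    for seg in segments:
        m = table.mass(seg.name, gender, seg.length, seg.circumference)
        frac = table.com_fraction(seg.name, gender)
        com = np.asarray(seg.proximal, dtype=float) + frac * (
            np.asarray(seg.distal, dtype=float) - np.asarray(seg.proximal, dtype=float))
        weighted = m * com if weighted is None else weighted + m * com
        total_mass += m
    return weighted / total_mass


def com_velocity(com, dt: float | None = None, times=None,
                 tol: float = 1e-6) -> np.ndarray:
    """Forward-difference velocity, last value repeated to preserve length."""
    com = np.asarray(com, dtype=float)
    if com.size < 2:
        raise ValueError("need at least 2 samples for a velocity estimate")
    if times is not None:
        times = np.asarray(times, dtype=float)
        dts = np.diff(times)
        if dts.min() <= 0 or (dts.max() - dts.min()) > tol * dts.mean():
            raise ValueError("timestamps are not uniformly spaced")
        dt = float(dts.mean())
    if dt is None or dt <= 0:
        raise ValueError("provide a positive dt or a timestamp vector")
    v = np.empty_like(com)
    v[:-1] = np.diff(com) / dt
    v[-1] = v[-2]
    return v


# --------------------------------------------------------------------------
# step records
# --------------------------------------------------------------------------

@dataclass
class StepRecord:
    """One step's outcomes and its 51-sample predictor trajectories."""

    leg: str
    t_toe_off: float
    t_heel_strike: float
    fp: float  # m, signed step width (lateral positive)
    fp2: float  # m, foot at midstance re CoM at toe-off (lateral positive)
    com_pos: np.ndarray  # (51,), m, re stance foot at its midstance
    com_vel: np.ndarray  # (51,), m/s
    stride_duration: float  # s, ipsilateral heel strike to heel strike
    emg_gm_swing: float | None = None  # a.u. * s
    emg_al_swing: float | None = None

    def __post_init__(self):
        if self.com_pos.shape != (N_PHASE,) or self.com_vel.shape != (N_PHASE,):
            raise ValueError("predictor trajectories must have exactly 51 samples")
        if not np.isfinite(self.fp):
            raise ValueError("FP must be finite")
        if self.leg not in ("L", "R"):
            raise ValueError(f"leg must be 'L' or 'R', got {self.leg!r}")


def _stances(events: GaitEvents, leg: str):
    """(t_hs, t_to) pairs of one foot's stance phases, in seconds."""
    rate = events.rate
    out = []
    tos = events.to_idx[leg]
    for hs in events.hs_idx[leg]:
        nxt = tos[tos > hs]
        if nxt.size:
            out.append((hs / rate, float(nxt[0]) / rate))
    return out


def extract_step_records(trial, events: GaitEvents, com=None, foot_ml=None,
                         n_strides: int | None = None,
                         include_emg: bool = True) -> list:
    """Build per-step records from a trial and its gait events.

    Keeps the final ``n_strides`` complete steps per leg when given (the
    analysis convention of using the last consecutive strides of a trial);
    warns when fewer are available.  EMG swing features are attached when
    the trial carries EMG channels and ``include_emg`` is true.
    """
    if com is None:
        com = trial.com_ml
    if foot_ml is None:
        foot_ml = trial.foot_ml
    kin_t = trial.kin_time
    com = np.asarray(com, dtype=float)
    vel = com_velocity(com, dt=float(kin_t[1] - kin_t[0]))

    envelopes = None
    if include_emg and getattr(trial, "emg", None):
        from .emg import emg_envelope
        envelopes = {ch: emg_envelope(sig, trial.rate_emg)
                     for ch, sig in trial.emg.items()}

    stances = {leg: _stances(events, leg) for leg in ("L", "R")}

    def midstance_pos(leg, t_lo, t_hi):
        """Foot position at the midpoint of the stance covering [t_lo, t_hi]."""
        for t_hs, t_to in stances[leg]:
            if t_hs <= t_lo + 1e-9 and t_to >= t_hi - 1e-9:
                t_mid = 0.5 * (t_hs + t_to)
                return float(np.interp(t_mid, kin_t, foot_ml[leg]))
        return None

    records = {"L": [], "R": []}
    for leg in ("L", "R"):
        contra = "L" if leg == "R" else "R"
        s = 1.0 if leg == "R" else -1.0
        hs_own = events.hs_idx[leg] / events.rate
        for t_to, t_hs in ((a / events.rate, b / events.rate)
                           for a, b in events.steps(leg)):
            ref = midstance_pos(contra, t_to, t_hs)
            own = midstance_pos(leg, t_hs, t_hs)
            prev = hs_own[hs_own < t_to]
            if ref is None or own is None or prev.size == 0:
                continue  # incomplete boundary step
            t_prev_hs = float(prev[-1])
            if t_hs + 1e-9 >= kin_t[-1] or t_prev_hs <= kin_t[0]:
                continue
            fp = s * (own - ref)
            com_at_to = float(np.interp(t_to, kin_t, com))
            fp2 = s * (own - com_at_to)
            cp = normalize_step(s * (com - ref), kin_t, (t_to, t_hs))
            cv = normalize_step(s * vel, kin_t, (t_to, t_hs))
            gm = al = None
            if envelopes is not None:
                from .emg import stride_swing_features
                gm, al = stride_swing_features(
                    envelopes[f"gm_{leg}"], envelopes[f"al_{leg}"],
                    trial.emg_time, t_prev_hs, t_hs)
            records[leg].append(StepRecord(
                leg=leg, t_toe_off=t_to, t_heel_strike=t_hs, fp=fp, fp2=fp2,
                com_pos=cp, com_vel=cv, stride_duration=t_hs - t_prev_hs,
                emg_gm_swing=gm, emg_al_swing=al))

    if n_strides is not None:
        for leg in ("L", "R"):
            if len(records[leg]) < n_strides:
                warnings.warn(
                    f"requested {n_strides} strides but only "
                    f"{len(records[leg])} complete steps on leg {leg}")
            records[leg] = records[leg][-n_strides:]
    out = records["L"] + records["R"]
    out.sort(key=lambda r: r.t_heel_strike)
    return out


def records_to_frame(records) -> pd.DataFrame:
    """Tidy table: one row per step, 51 predictor columns per state variable."""
    rows = []
    for i, r in enumerate(records):
        row = {
            "step": i, "leg": r.leg, "t_toe_off": r.t_toe_off,
            "t_heel_strike": r.t_heel_strike, "fp": r.fp, "fp2": r.fp2,
            "stride_duration": r.stride_duration,
            "emg_gm_swing": r.emg_gm_swing, "emg_al_swing": r.emg_al_swing,
        }
        for j in range(N_PHASE):
            row[f"com_pos_{j + 1}"] = r.com_pos[j]
            row[f"com_vel_{j + 1}"] = r.com_vel[j]
        rows.append(row)
    return pd.DataFrame(rows)


def condition_metrics(records) -> dict:
    """Mean step width, step-width variability and stride frequency."""
    if len(records) < 2:
        raise ValueError("need at least 2 steps for condition metrics")
    fp = np.array([r.fp for r in records], dtype=float)
    dur = np.array([r.stride_duration for r in records], dtype=float)
    return {
        "mean_step_width": float(np.mean(np.abs(fp))),
        "step_width_variability": float(np.std(fp, ddof=1)),
        "stride_frequency": float(1.0 / np.mean(dur)),
    }
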