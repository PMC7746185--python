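"""The two linear models of foot-placement control.

Model 1 (foot placement model) regresses the demeaned signed step width
``FP`` on the demeaned CoM position and velocity at each of the 51 swing
phases::

    FP = beta_pos * CoM_pos(i) + beta_vel * CoM_vel(i) + eps(i)

Its relative explained variance R^2(i) is the *degree of foot placement
control*; coefficients are conventionally examined at mid-swing (i = 25)
and terminal swing (i = 51).

Model 2 (muscle model) regresses the z-normalised ``FP2`` on the
z-normalised gluteus medius and adductor longus swing features::

    FP2 = beta_gm * EMG_gm_swing + beta_al * EMG_al_swing + eps

Both models are ordinary least squares without intercept on demeaned
variables (demeaning absorbs the intercept).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emg import znorm_trial
from .events import N_PHASE, PHASE_MIDSWING, PHASE_TERMINAL

__all__ = [
    "FPModelFit",
    "MuscleModelFit",
    "ols_demeaned",
    "fit_fp_model",
    "fit_muscle_model",
    "fit_muscle_model_from_records",
    "fisher_transform",
    "permutation_null_r2",
]


class RankDeficientError(np.linalg.LinAlgError):
    pass


def ols_demeaned(X, y, check_demeaned: bool = True, tol: float = 1e-8):
    """Least squares without intercept on demeaned data; returns (betas, r2).

    ``X`` is n x p, ``y`` length n; both must already be demeaned (checked
    against ``tol`` relative to the data scale).  Raises on n <= p and on
    rank deficiency, naming the collinear columns.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"y has shape {y.shape}, expected ({n},)")
    if n <= p:
        raise ValueError(f"need more observations than predictors (n={n}, p={p})")
    if check_demeaned:
        scale = max(np.abs(X).max(initial=0.0), np.abs(y).max(initial=0.0), 1e-30)
        if np.abs(X.mean(axis=0)).max() > tol * scale or abs(y.mean()) > tol * scale:
            raise ValueError("predictors and outcome must be demeaned first")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending columns via near-unit pairwise correlations
        bad = set()
        norms = np.linalg.norm(X, axis=0)
        degenerate = np.where(norms < 1e-12 * max(norms.max(), 1e-30))[0]
        bad.update(int(i) for i in degenerate)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = (X.T @ X) / np.outer(np.maximum(norms, 1e-30),
                                     np.maximum(norms, 1e-30))
        for i in range(p):
            for j in range(i + 1, p):
                if abs(C[i, j]) > 1 - 1e-10:
                    bad.update((i, j))
        raise RankDeficientError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"collinear/degenerate columns: {sorted(bad) if bad else 'unknown'}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(y @ y)
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
    return beta, float(np.clip(r2, 0.0, 1.0))


@dataclass
class FPModelFit:
    """Foot-placement model fit: full phase curves plus the tested slices."""

    beta_pos: np.ndarray  # (51,)
    beta_vel: np.ndarray
    r2: np.ndarray
    n_steps: int
    participant: str = ""
    condition: str = ""
    speed: str = ""

    @property
    def beta_pos_mid(self) -> float:
        return float(self.beta_pos[PHASE_MIDSWING - 1])

    @property
    def beta_vel_mid(self) -> float:
        return float(self.beta_vel[PHASE_MIDSWING - 1])

    @property
    def r2_mid(self) -> float:
        return float(self.r2[PHASE_MIDSWING - 1])

    @property
    def beta_pos_ts(self) -> float:
        return float(self.beta_pos[PHASE_TERMINAL - 1])

    @property
    def beta_vel_ts(self) -> float:
        return float(self.beta_vel[PHASE_TERMINAL - 1])

    @property
    def r2_ts(self) -> float:
        return float(self.r2[PHASE_TERMINAL - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant": self.participant, "condition": self.condition,
            "speed": self.speed, "phase": np.arange(1, N_PHASE + 1),
            "beta_pos": self.beta_pos, "beta_vel": self.beta_vel, "r2": self.r2,
        })


@dataclass
class MuscleModelFit:
    beta_gm: float
    beta_al: float
    r2: float
    n_steps: int
    participant: str = ""
    condition: str = ""
    speed: str = ""


def fit_fp_model(records, min_steps: int = 50, **labels) -> FPModelFit:
    """Fit model 1 across steps, one regression per swing phase."""
    records = list(records)
    n = len(records)
    if n < max(min_steps, 3):
        raise ValueError(
            f"need at least {max(min_steps, 3)} steps to fit the foot "
            f"placement model, got {n}")
    fp = np.array([r.fp for r in records], dtype=float)
    pos = np.stack([r.com_pos for r in records])  # (n, 51)
    vel = np.stack([r.com_vel for r in records])
    y = fp - fp.mean()
    pos = pos - pos.mean(axis=0)
    vel = vel - vel.mean(axis=0)
    beta_pos = np.empty(N_PHASE)
    beta_vel = np.empty(N_PHASE)
    r2 = np.empty(N_PHASE)
    degenerate = []
    for i in range(N_PHASE):
        X = np.column_stack([pos[:, i], vel[:, i]])
        try:
            b, r = ols_demeaned(X, y, check_demeaned=False)
        except (RankDeficientError, ValueError):
            degenerate.append(i + 1)
            b, r = np.array([np.nan, np.nan]), np.nan
        beta_pos[i], beta_vel[i] = b
        r2[i] = r
    if degenerate:
        warnings.warn(f"degenerate predictors at phases {degenerate}")
    return FPModelFit(beta_pos=beta_pos, beta_vel=beta_vel, r2=r2,
                      n_steps=n, **labels)


def fit_muscle_model(fp2, emg_gm, emg_al, normalized: bool = True,
                     n_steps: int | None = None, **labels) -> MuscleModelFit:
    """Fit model 2 on z-normalised FP2 and EMG swing features."""
    fp2 = np.asarray(fp2, dtype=float)
    gm = np.asarray(emg_gm, dtype=float)
    al = np.asarray(emg_al, dtype=float)
    if not normalized:
        fp2, gm, al = znorm_trial(fp2), znorm_trial(gm), znorm_trial(al)
    for name, v in (("fp2", fp2), ("emg_gm", gm), ("emg_al", al)):
        if abs(v.mean()) > 1e-6 or abs(v.std(ddof=1) - 1) > 1e-6:
            raise ValueError(
                f"{name} is not z-normalised (mean {v.mean():.3g}, "
                f"sd {v.std(ddof=1):.3g}); znorm_trial it first or pass "
                f"normalized=False")
    X = np.column_stack([gm, al])
    beta, r2 = ols_demeaned(X, fp2, check_demeaned=False)
    return MuscleModelFit(beta_gm=float(beta[0]), beta_al=float(beta[1]),
                          r2=r2, n_steps=n_steps or fp2.size, **labels)


def fit_muscle_model_from_records(records, **labels) -> MuscleModelFit:
    """Convenience: z-normalise FP2 and EMG features of a trial, then fit."""
    recs = [r for r in records if r.emg_gm_swing is not None]
    if len(recs) < 3:
        raise ValueError("need at least 3 steps with EMG features")
    fp2 = np.array([r.fp2 for r in recs])
    gm = np.array([r.emg_gm_swing for r in recs])
    al = np.array([r.emg_al_swing for r in recs])
    return fit_muscle_model(znorm_trial(fp2), znorm_trial(gm), znorm_trial(al),
                            n_steps=len(recs), **labels)


def fisher_transform(r2, scale: str = "r"):
    """Fisher z of an R-squared value.

    ``scale='r'`` (default) applies atanh on the multiple-correlation
    scale, z = atanh(sqrt(R^2)); ``scale='r2'`` applies atanh(R^2)
    directly.  R^2 = 1 maps to +inf with a warning; values outside [0, 1]
    raise.
    """
    r2 = np.asarray(r2, dtype=float)
    if np.any((r2 < 0) | (r2 > 1)):
        raise ValueError("R^2 must lie in [0, 1]")
    if np.any(r2 == 1):
        warnings.warn("R^2 of exactly 1 maps to an infinite Fisher z")
    if scale == "r":
        arg = np.sqrt(r2)
    elif scale == "r2":
        arg = r2
    else:
        raise ValueError("scale must be 'r' or 'r2'")
    with np.errstate(divide="ignore"):
        z = np.arctanh(arg)
    return float(z) if z.ndim == 0 else z


def permutation_null_r2(X, y, n_perm: int = 500, rng=None) -> np.ndarray:
    """Null distribution of R^2 under random permutation of the outcome."""
    rng = np.random.default_rng(rng)
    y = np.asarray(y, dtype=float)
    y = y - y.mean()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    X = X - X.mean(axis=0)
    out = np.empty(n_perm)
    for i in range(n_perm):
        _, out[i] = ols_demeaned(X, rng.permutation(y), check_demeaned=False)
    return out
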