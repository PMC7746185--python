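"""EMG processing: envelope extraction and swing-phase features.

The chain follows common surface-EMG practice for gait: zero-lag
high-pass at 20 Hz (removes movement artefact), full-wave rectification,
zero-lag low-pass at 50 Hz (linear envelope).  Both stages are 2nd-order
Butterworth filters applied forward and backward; the order is a knob.

Strides are time-normalised to 1000 samples; the swing feature of a
stride is the median envelope over the 60-80% stride window (phase
interval [0.60, 0.80), i.e. samples 601-800 of 1000 in 1-based counting)
multiplied by the duration of that window in seconds.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "emg_envelope",
    "normalize_stride",
    "swing_feature",
    "stride_swing_features",
    "znorm_trial",
]

N_STRIDE_SAMPLES = 1000
SWING_WINDOW = (0.60, 0.80)  # phase fraction of the stride cycle


def emg_envelope(raw, rate: float, highpass_hz: float = 20.0,
                 lowpass_hz: float = 50.0, order: int = 2) -> np.ndarray:
    """High-pass, rectify, low-pass — in that order, all zero-lag."""
    raw = np.asarray(raw, dtype=float)
    if rate < 200:
        raise ValueError("EMG sampling rate must be at least 200 Hz")
    bad = ~np.isfinite(raw)
    if bad.any():
        first, last = np.where(bad)[0][[0, -1]]
        raise ValueError(f"non-finite EMG samples in span {first}..{last}")
    sos_hp = butter(order, highpass_hz, btype="highpass", fs=rate, output="sos")
    sos_lp = butter(order, lowpass_hz, btype="lowpass", fs=rate, output="sos")
    rectified = np.abs(sosfiltfilt(sos_hp, raw))
    return sosfiltfilt(sos_lp, rectified)


def normalize_stride(envelope, times, t_start: float, t_end: float,
                     n: int = N_STRIDE_SAMPLES) -> np.ndarray:
    """Time-normalise an envelope over one stride onto ``n`` samples."""
    if t_end <= t_start:
        raise ValueError("stride window must have positive duration")
    phase_t = np.linspace(t_start, t_end, n)
    return np.interp(phase_t, times, envelope)


def swing_feature(stride_envelope, stride_duration_s: float) -> float:
    """Median envelope in the 60-80% stride window times its duration.

    Expects a 1000-sample normalised stride envelope.  The window is
    half-open on the phase axis ([0.60, 0.80)), which maps to samples
    601..800 in 1-based counting.
    """
    env = np.asarray(stride_envelope, dtype=float)
    if env.shape != (N_STRIDE_SAMPLES,):
        raise ValueError(
            f"expected a {N_STRIDE_SAMPLES}-sample stride envelope, "
            f"got shape {env.shape}")
    if stride_duration_s <= 0:
        raise ValueError("stride duration must be positive")
    lo = int(SWING_WINDOW[0] * N_STRIDE_SAMPLES)  # 600 (0-based)
    hi = int(SWING_WINDOW[1] * N_STRIDE_SAMPLES)  # 800 (exclusive)
    window_s = (SWING_WINDOW[1] - SWING_WINDOW[0]) * stride_duration_s
    return float(np.median(env[lo:hi]) * window_s)


def stride_swing_features(env_gm, env_al, times, t_prev_hs: float,
                          t_hs: float):
    """Swing features of one stride for the gm and al channels."""
    dur = t_hs - t_prev_hs
    gm = swing_feature(normalize_stride(env_gm, times, t_prev_hs, t_hs), dur)
    al = swing_feature(normalize_stride(env_al, times, t_prev_hs, t_hs), dur)
    return gm, al


def znorm_trial(values) -> np.ndarray:
    """Demean and scale to unit sample standard deviation (ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to z-normalise")
    sd = v.std(ddof=1)
    if sd == 0 or np.ptp(v) == 0:
        raise ValueError("degenerate feature: zero variance")
    return (v - v.mean()) / sd
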