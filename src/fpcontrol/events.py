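"""Gait event detection and step segmentation.

Heel strikes and toe-offs are detected at the force rate (200 Hz), either
from per-belt vertical-force threshold crossings or from the combined
centre-of-pressure "butterfly" trace.  A *step* is the period between a
toe-off and the subsequent heel strike of the same (swinging) foot;
mid-swing is 50% of that period.  Phase indices at the API surface run
i = 1..51 with i = 25 mid-swing and i = 51 terminal swing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GaitEvents",
    "detect_events_force",
    "detect_events_butterfly",
    "normalize_step",
    "N_PHASE",
    "PHASE_MIDSWING",
    "PHASE_TERMINAL",
]

N_PHASE = 51
PHASE_MIDSWING = 25  # 1-based phase index of mid-swing
PHASE_TERMINAL = 51  # 1-based phase index of terminal swing


class NoGaitEventsError(RuntimeError):
    pass


@dataclass
class GaitEvents:
    """Per-leg heel-strike and toe-off sample indices (force-rate grid)."""

    hs_idx: dict  # leg -> sorted int sample indices
    to_idx: dict
    rate: float = 200.0
    method: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for d in (self.hs_idx, self.to_idx):
            for leg in d:
                d[leg] = np.asarray(d[leg], dtype=int)

    def n_events(self) -> int:
        return sum(v.size for v in self.hs_idx.values()) + \
            sum(v.size for v in self.to_idx.values())

    def steps(self, leg: str):
        """Ipsilateral (toe_off, heel_strike) index pairs: the swing of ``leg``."""
        out = []
        hs = self.hs_idx[leg]
        for to in self.to_idx[leg]:
            nxt = hs[hs > to]
            if nxt.size:
                out.append((int(to), int(nxt[0])))
        return out

    def strides(self, leg: str):
        """Ipsilateral heel-strike to heel-strike index pairs."""
        hs = self.hs_idx[leg]
        return [(int(a), int(b)) for a, b in zip(hs[:-1], hs[1:])]

    def mid_swing_idx(self, leg: str):
        """Sample index at 50% of each step window (nearest sample)."""
        return [int(round(0.5 * (to + hs))) for to, hs in self.steps(leg)]

    def validate(self) -> None:
        """Check per-leg alternation: TO < HS < next TO."""
        for leg in self.hs_idx:
            seq = sorted([(i, "TO") for i in self.to_idx[leg]] +
                         [(i, "HS") for i in self.hs_idx[leg]])
            kinds = [k for _, k in seq]
            for a, b in zip(kinds[:-1], kinds[1:]):
                if a == b:
                    raise ValueError(
                        f"gait events on leg {leg} do not alternate (two "
                        f"consecutive {a} events)")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for leg in sorted(self.hs_idx):
            for i in self.hs_idx[leg]:
                rows.append((leg, "HS", int(i), i / self.rate))
            for i in self.to_idx[leg]:
                rows.append((leg, "TO", int(i), i / self.rate))
        df = pd.DataFrame(rows, columns=["leg", "event_type", "sample_index", "time_s"])
        return df.sort_values(["leg", "sample_index"]).reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rate: float = 200.0) -> "GaitEvents":
        hs = {leg: g.loc[g.event_type == "HS", "sample_index"].to_numpy()
              for leg, g in df.groupby("leg")}
        to = {leg: g.loc[g.event_type == "TO", "sample_index"].to_numpy()
              for leg, g in df.groupby("leg")}
        return cls(hs_idx=hs, to_idx=to, rate=rate)


def _debounce(idx: np.ndarray, min_gap: int) -> np.ndarray:
    if idx.size == 0:
        return idx
    keep = [int(idx[0])]
    for i in idx[1:]:
        if i - keep[-1] >= min_gap:
            keep.append(int(i))
    return np.asarray(keep, dtype=int)


def detect_events_force(fz_by_leg: dict, rate: float = 200.0,
                        threshold_n: float | None = None,
                        body_weight_n: float | None = None,
                        min_gap_s: float = 0.2) -> GaitEvents:
    """Detect gait events from per-belt vertical-force threshold crossings.

    Heel strike is the first sample at or above the threshold, toe-off the
    first sample below it.  The default threshold is 5% of body weight
    (``body_weight_n``); pass ``threshold_n`` to override.  Events closer
    than ``min_gap_s`` to the previous one of the same kind are discarded.
    """
    if threshold_n is None:
        if body_weight_n is None:
            raise ValueError("provide threshold_n or body_weight_n")
        threshold_n = 0.05 * body_weight_n
    if threshold_n <= 0:
        raise ValueError("threshold must be positive")
    min_gap = int(round(min_gap_s * rate))
    hs, to = {}, {}
    for leg, fz in fz_by_leg.items():
        fz = np.asarray(fz, dtype=float)
        if not np.any(fz > 0):
            side = {"L": "left", "R": "right"}.get(leg, leg)
            raise NoGaitEventsError(f"{side} belt is silent (no load recorded)")
        above = fz >= threshold_n
        d = np.diff(above.astype(np.int8))
        hs[leg] = _debounce(np.where(d == 1)[0] + 1, min_gap)
        to[leg] = _debounce(np.where(d == -1)[0] + 1, min_gap)
    if all(v.size == 0 for v in hs.values()) and all(v.size == 0 for v in to.values()):
        raise NoGaitEventsError("no gait events: threshold never crossed")
    return GaitEvents(hs_idx=hs, to_idx=to, rate=rate, method="force")


def detect_events_butterfly(combined_cop_ml, combined_cop_ap, total_force,
                            rate: float = 200.0,
                            smooth_window: int = 3,
                            transfer_velocity: float = 0.30,
                            min_sweep_m: float = 0.02,
                            min_gap_s: float = 0.2) -> GaitEvents:
    """Detect gait events from the combined-CoP butterfly pattern.

    Heel strikes are the onsets of the rapid mediolateral CoP transfer
    toward the new stance side (the departure from a lateral extremum of
    the butterfly); the leg is assigned from the transfer direction.
    Toe-offs are placed at the subsequent anteroposterior CoP reversal
    from backward to forward travel and assigned to the contralateral leg.

    Transfers sweeping less than ``min_sweep_m`` are treated as ambiguous:
    a warning is issued and the event dropped.
    """
    ml = np.asarray(combined_cop_ml, dtype=float)
    ap = np.asarray(combined_cop_ap, dtype=float)
    total = np.asarray(total_force, dtype=float)
    if np.any(~np.isfinite(ml)) or np.any(total <= 0):
        bad = np.where(~np.isfinite(ml) | (total <= 0))[0]
        raise ValueError(
            f"combined CoP undefined on {bad.size} samples "
            f"(first at index {bad[0]}); total vertical force must stay positive")
    if smooth_window > 1:
        kern = np.ones(smooth_window) / smooth_window
        ml_s = np.convolve(ml, kern, mode="same")
        ap_s = np.convolve(ap, kern, mode="same")
    else:
        ml_s, ap_s = ml, ap
    v_ml = np.gradient(ml_s) * rate

    fast = np.abs(v_ml) > transfer_velocity
    if not fast.any():
        warnings.warn("no mediolateral CoP transfers found (standing still?); "
                      "zero gait events detected")
        return GaitEvents(hs_idx={"L": [], "R": []}, to_idx={"L": [], "R": []},
                          rate=rate, method="butterfly")

    # contiguous fast spans = double-support weight transfers
    d = np.diff(fast.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if fast[0]:
        starts.insert(0, 0)
    if fast[-1]:
        ends.append(len(fast))
    min_gap = int(round(min_gap_s * rate))
    merged = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < max(3, min_gap // 8):
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    hs = {"L": [], "R": []}
    to = {"L": [], "R": []}
    max_search = int(round(0.6 * rate))
    guard = smooth_window + 2  # transfers truncated by the record boundary
    d_raw = np.abs(np.diff(ml))
    for s, e in merged:
        if s <= guard or e >= len(ml) - guard:
            continue
        sweep = ml_s[min(e, len(ml_s) - 1)] - ml_s[s]
        direction = np.sign(np.mean(v_ml[s:e]))
        if abs(sweep) < min_sweep_m:
            warnings.warn(f"ambiguous CoP transfer at sample {s} "
                          f"(sweep {abs(sweep) * 1000:.1f} mm); event dropped")
            continue
        # refine the onset on the raw trace: the initial weight acceptance
        # kicks the combined CoP, giving the sharpest single-sample move
        w0, w1 = max(s - 1, 1), min(s + 8, len(d_raw))
        window = d_raw[w0 - 1:w1]
        cand = np.where(window >= 0.4 * window.max())[0]
        onset = w0 + int(cand[0]) if cand.size else s
        hs_leg = "R" if direction > 0 else "L"
        hs[hs_leg].append(onset)
        # toe-off: AP reversal from backward to forward travel
        win_end = min(onset + max_search, len(ap_s))
        if win_end - onset > 2:
            rel = int(np.argmin(ap_s[onset:win_end]))
            to_leg = "L" if hs_leg == "R" else "R"
            to[to_leg].append(onset + rel)
    ev = GaitEvents(hs_idx=hs, to_idx=to, rate=rate, method="butterfly")
    if ev.n_events() == 0:
        warnings.warn("zero gait events detected")
    return ev


def normalize_step(values, times=None, window=None, n: int = N_PHASE) -> np.ndarray:
    """Time-normalise a series over a step window onto ``n`` phase points.

    ``window`` is ``(t_start, t_end)`` on the same axis as ``times`` (when
    ``times`` is omitted the sample index is the time axis).  Linear
    interpolation onto ``n`` equally spaced points; with the default
    ``n = 51``, point 25 (1-based) is mid-swing and point 51 terminal
    swing.  NaNs inside the window raise a ValueError naming the span.
    """
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(values.size, dtype=float)
    else:
        times = np.asarray(times, dtype=float)
    if window is None:
        window = (times[0], times[-1])
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ValueError("step window must have positive duration")
    inside = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
    if inside.sum() < 2:
        raise ValueError("step window must span at least 2 samples")
    if np.any(~np.isfinite(values[inside])):
        bad = times[inside][~np.isfinite(values[inside])]
        raise ValueError(
            f"NaN values inside step window: span {bad.min():g}..{bad.max():g}")
    phase_t = np.linspace(t0, t1, n)
    return np.interp(phase_t, times, values)
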