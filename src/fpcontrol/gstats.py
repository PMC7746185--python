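"""Group-level hypothesis evaluation.

Per-participant outcomes (Fisher-z transformed R^2 values, coefficients,
condition metrics) enter a 2x2 repeated-measures design with factors
condition (constrained vs steady) and speed (normal vs slow).  The
decomposition is contrast-based: each main effect and the interaction is
a within-participant difference contrast tested with a one-sample t; the
planned post-hocs compare constrained against steady at each speed, one-
tailed where the hypothesis fixes a direction.

A JZS (Jeffreys-Zellner-Siow) Bayes factor with Cauchy prior scale
r = sqrt(2)/2 on the standardised effect is available for the one-sample
test, computed by numerical integration of the non-central-t likelihood
over the prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "one_sample_test",
    "jzs_bf_one_sample",
    "rm_2x2",
    "GroupTable",
]

DEFAULT_PRIOR_SCALE = math.sqrt(2) / 2  # JASP's default Cauchy scale


def jzs_bf_one_sample(t: float, n: int, prior_scale: float = DEFAULT_PRIOR_SCALE,
                      method: str = "quad") -> float:
    """JZS Bayes factor BF10 for a one-sample t statistic.

    Integrates the non-central t likelihood over a Cauchy(0, r) prior on
    the standardised effect size delta::

        BF10 = int f_nct(t; df, delta*sqrt(n)) Cauchy(delta; r) ddelta
               / f_t(t; df)

    ``method='quad'`` uses adaptive quadrature; ``method='grid'`` a dense
    fixed trapezoid grid (an independent cross-check of the quadrature).
    """
    df = n - 1
    if df < 1:
        raise ValueError("need n >= 2 for a Bayes factor")

    def integrand(delta):
        return stats.nct.pdf(t, df, delta * math.sqrt(n)) * \
            stats.cauchy.pdf(delta, 0.0, prior_scale)

    if method == "quad":
        num = 0.0
        # split at zero: the integrand can be sharply peaked on one side
        for lo, hi in ((-np.inf, 0.0), (0.0, np.inf)):
            val, _ = integrate.quad(integrand, lo, hi, limit=200)
            num += val
    elif method == "grid":
        width = max(10.0 * prior_scale, 3.0 * abs(t) / math.sqrt(n) + 10.0)
        grid = np.linspace(-width, width, 20001)
        num = float(np.trapezoid(integrand(grid), grid))
    else:
        raise ValueError("method must be 'quad' or 'grid'")
    den = stats.t.pdf(t, df)
    return float(num / den)


def one_sample_test(values, popmean: float = 0.0,
                    alternative: str = "two-sided",
                    bayes: bool = True,
                    prior_scale: float = DEFAULT_PRIOR_SCALE) -> dict:
    """One-sample t test, optionally with a JZS Bayes factor.

    Returns a dict with ``t``, ``df``, ``p``, ``mean``, ``n`` and (when
    ``bayes``) ``bf10`` (two-sided prior, regardless of ``alternative``).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3 or not np.all(np.isfinite(v)):
        raise ValueError("need at least 3 finite values")
    if v.std(ddof=1) == 0:
        raise ValueError("zero variance: one-sample t is undefined")
    res = stats.ttest_1samp(v, popmean, alternative=alternative)
    out = {
        "t": float(res.statistic), "df": int(v.size - 1),
        "p": float(res.pvalue), "mean": float(v.mean()), "n": int(v.size),
    }
    if bayes:
        out["bf10"] = jzs_bf_one_sample(out["t"], v.size, prior_scale)
    return out


@dataclass
class GroupTable:
    """One row per participant x condition x speed; see :func:`rm_2x2`."""

    data: pd.DataFrame

    def __post_init__(self):
        required = {"participant", "condition", "speed"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"group table misses columns {sorted(missing)}")
        dup = self.data.duplicated(["participant", "condition", "speed"])
        if dup.any():
            raise ValueError("duplicate participant x condition x speed keys")


def _pivot_complete(df: pd.DataFrame, outcome: str, conditions, speeds):
    wide = df.pivot_table(index="participant", columns=["condition", "speed"],
                          values=outcome, aggfunc="first")
    missing = []
    for c in conditions:
        for s in speeds:
            if (c, s) not in wide.columns:
                missing.append((c, s))
    if missing:
        raise ValueError(f"missing cells in 2x2 design: {missing}")
    cells = wide[[(c, s) for c in conditions for s in speeds]]
    incomplete = cells.isna().any(axis=1)
    if incomplete.any():
        raise ValueError(
            f"participants with missing cells: {list(wide.index[incomplete])}")
    return wide


def rm_2x2(table, outcome: str, conditions=None, speeds=("normal", "slow"),
           posthoc_alternative: str = "two-sided", bayes: bool = False) -> dict:
    """2x2 repeated-measures decomposition of ``outcome``.

    ``conditions`` is the ordered pair (steady-like level, constrained
    level); effects are expressed as constrained minus steady and slow
    minus normal.  Returns a dict with ``main_condition``, ``main_speed``,
    ``interaction`` and per-speed ``posthoc`` entries, each a one-sample
    test of the corresponding within-participant contrast.
    """
    df = table.data if isinstance(table, GroupTable) else GroupTable(table).data
    if conditions is None:
        levels = list(pd.unique(df["condition"]))
        if len(levels) != 2:
            raise ValueError(
                f"outcome table has condition levels {levels}; pass the "
                f"(steady, constrained) pair explicitly")
        conditions = ("steady", [l for l in levels if l != "steady"][0]) \
            if "steady" in levels else tuple(levels)
    wide = _pivot_complete(df, outcome, conditions, speeds)
    c0, c1 = conditions
    s0, s1 = speeds
    diff_cond = {s: wide[(c1, s)] - wide[(c0, s)] for s in speeds}
    diff_speed = {c: wide[(c, s1)] - wide[(c, s0)] for c in conditions}

    def contrast_test(values, alternative="two-sided"):
        return one_sample_test(np.asarray(values), alternative=alternative,
                               bayes=bayes)

    out = {
        "conditions": conditions,
        "speeds": speeds,
        "n": int(wide.shape[0]),
        "main_condition": contrast_test(
            0.5 * (diff_cond[s0] + diff_cond[s1])),
        "main_speed": contrast_test(
            0.5 * (diff_speed[c0] + diff_speed[c1])),
        "interaction": contrast_test(diff_cond[s1] - diff_cond[s0]),
        "posthoc": {s: contrast_test(diff_cond[s],
                                     alternative=posthoc_alternative)
                    for s in speeds},
    }
    return out
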