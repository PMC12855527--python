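"""Two-sample t-test power and per-group sample-size planning.

Power is computed exactly from the noncentral t distribution with
df = 2n - 2 and noncentrality d*sqrt(n/2), matching the convention of
standard power calculators.  Sample sizes solve the continuous power
equation and round up to the next whole participant per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .corpus import Corpus

__all__ = [
    "PowerQuery",
    "PowerCurve",
    "power_two_sample_t",
    "n_per_group",
    "power_curve",
    "underpowered_share",
]


@dataclass(frozen=True)
class PowerQuery:
    d: float
    alpha: float = 0.05
    target_power: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.target_power < 1):
            raise ValueError("alpha and target_power must lie in (0, 1)")


@dataclass
class PowerCurve:
    d: float
    n_grid: np.ndarray
    power: np.ndarray
    n_80: int | None  # first grid point at or above 80% power


def power_two_sample_t(d: float, n_per_group: float, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test at effect size d, n per group."""
    if n_per_group < 2:
        raise ValueError("need at least 2 participants per group")
    df = 2.0 * n_per_group - 2.0
    ncp = d * math.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    if np.isnan(lower):  # negligible opposite-tail mass at extreme df
        lower = 0.0
    if np.isnan(upper):
        upper = stats.norm.sf(tcrit - ncp)
    return float(upper + lower)


def n_per_group(query: PowerQuery) -> int:
    """Smallest whole n per group attaining the target power.

    Solves the continuous power equation in n and rounds up.
    """
    if query.d == 0:
        raise ValueError("d must be nonzero for sample-size solving")
    d = abs(query.d)

    def gap(n: float) -> float:
        return power_two_sample_t(d, n, query.alpha) - query.target_power

    lo, hi = 2.0, 8.0
    while gap(hi) < 0:
        lo, hi = hi, hi * 2.0
        if hi > 1e8:
            raise ValueError("target power unattainable at this effect size")
    if gap(lo) >= 0:
        return 2
    root = optimize.brentq(gap, lo, hi, xtol=1e-8)
    return int(math.ceil(root - 1e-9))


def power_curve(d_values, n_grid, alpha: float = 0.05) -> list[PowerCurve]:
    """One power-vs-n curve per effect size, marking the 80% crossing."""
    n_grid = np.asarray(list(n_grid), float)
    if n_grid.size == 0 or len(list(d_values)) == 0:
        raise ValueError("grids must be non-empty")
    curves = []
    for d in d_values:
        pw = np.array([power_two_sample_t(d, n, alpha) for n in n_grid])
        above = np.nonzero(pw >= 0.8)[0]
        curves.append(
            PowerCurve(
                d=float(d),
                n_grid=n_grid,
                power=pw,
                n_80=int(n_grid[above[0]]) if above.size else None,
            )
        )
    return curves


def underpowered_share(
    corpus: Corpus,
    d_by_outcome: dict[str, float],
    alpha: float = 0.05,
    target: float = 0.8,
) -> dict[str, float]:
    """Retrospective audit: share of effects whose per-group n (= N/2) falls
    short of the target power at the outcome class's pooled effect size."""
    out: dict[str, float] = {}
    for outcome, d in d_by_outcome.items():
        sub = corpus.df[corpus.df["outcome_label"] == outcome]
        n = sub["n_total"].dropna().astype(float) / 2.0
        if len(n) == 0:
            out[outcome] = float("nan")
            continue
        under = [power_two_sample_t(d, max(ni, 2.0), alpha) < target for ni in n]
        out[outcome] = float(np.mean(under))
    return out
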