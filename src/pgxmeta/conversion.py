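"""Standardised-mean-difference derivation from reported statistics.

Inputs encountered in the pharmacogenomics literature are handled in a fixed
order of preference: group means and SDs, then medians with interquartile
ranges (recovered to means/SDs by the Wan method), then odds ratios (logistic
conversion), then two-sample t statistics.  Every path yields an SMD together
with its large-sample sampling variance, which downstream weighting requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupStats",
    "QuartileStats",
    "EffectEstimate",
    "smd_from_group_stats",
    "mean_sd_from_quartiles",
    "smd_from_odds_ratio",
    "smd_to_odds_ratio",
    "smd_from_t",
    "smd_sampling_variance",
    "convert_table",
]

_LOGISTIC = math.sqrt(3.0) / math.pi  # SD ratio of standard logistic to normal


@dataclass(frozen=True)
class GroupStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be positive")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class QuartileStats:
    q1: float
    median: float
    q3: float
    n: int

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("require q1 <= median <= q3")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class EffectEstimate:
    """An SMD with sampling variance and the conversion path that produced it."""

    smd: float
    variance: float
    method: str  # means | quartiles | odds_ratio | t_statistic
    hedges_corrected: bool = False
    correction_factor: float | None = None


def smd_sampling_variance(smd: float, n1: int, n2: int) -> float:
    """Large-sample variance of an SMD: N/(n1*n2) + d^2/(2N)."""
    n = n1 + n2
    return n / (n1 * n2) + smd * smd / (2.0 * n)


def _hedges_j(df: int) -> float:
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def smd_from_group_stats(g1: GroupStats, g2: GroupStats, hedges: bool = False) -> EffectEstimate:
    """Cohen's d (optionally Hedges-corrected g) from two groups' means and SDs."""
    df = g1.n + g2.n - 2
    s_pooled = math.sqrt(((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df)
    if s_pooled == 0:
        raise ValueError("degenerate input: zero pooled SD")
    d = (g1.mean - g2.mean) / s_pooled
    v = smd_sampling_variance(d, g1.n, g2.n)
    if hedges:
        j = _hedges_j(df)
        return EffectEstimate(d * j, v * j * j, "means", True, j)
    return EffectEstimate(d, v, "means")


def mean_sd_from_quartiles(q: QuartileStats) -> GroupStats:
    """Recover approximate mean and SD from median + IQR (Wan method).

    mean = (q1 + median + q3)/3; sd = IQR / (2 * Phi^-1((0.75n - 0.125)/(n + 0.25))).
    The denominator tends to 2*0.6745 as n grows, so the SD estimate shrinks
    with n for a fixed IQR.
    """
    iqr = q.q3 - q.q1
    if iqr == 0:
        raise ValueError("zero spread: q3 == q1")
    mean = (q.q1 + q.median + q.q3) / 3.0
    eta = stats.norm.ppf((0.75 * q.n - 0.125) / (q.n + 0.25))
    sd = iqr / (2.0 * eta)
    return GroupStats(mean=mean, sd=sd, n=q.n)


def smd_from_odds_ratio(odds_ratio: float, var_log_or: float | None = None) -> EffectEstimate:
    """Logistic-distribution conversion of an odds ratio to an SMD.

    d = ln(OR) * sqrt(3)/pi; the variance maps by the square of the same factor.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    d = math.log(odds_ratio) * _LOGISTIC
    if var_log_or is None:
        v = float("nan")
    else:
        if var_log_or < 0:
            raise ValueError("var_log_or must be non-negative")
        v = var_log_or * _LOGISTIC**2
    return EffectEstimate(d, v, "odds_ratio")


def smd_to_odds_ratio(smd: float) -> float:
    """Exact inverse of :func:`smd_from_odds_ratio`: OR = exp(d * pi/sqrt(3))."""
    if not math.isfinite(smd):
        raise ValueError("smd must be finite")
    return math.exp(smd / _LOGISTIC)


def smd_from_t(t: float, n1: int, n2: int) -> EffectEstimate:
    """SMD from a two-sample t statistic: d = t * sqrt(1/n1 + 1/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    d = t * math.sqrt(1.0 / n1 + 1.0 / n2)
    return EffectEstimate(d, smd_sampling_variance(d, n1, n2), "t_statistic")


# ---------------------------------------------------------------------------
# batch conversion

_MEANS_COLS = ["mean1", "sd1", "n1", "mean2", "sd2", "n2"]
_QUART_COLS = ["q1_1", "median1", "q3_1", "n1", "q1_2", "median2", "q3_2", "n2"]


def _row_has(row: pd.Series, cols: list[str]) -> bool:
    return all(c in row.index and pd.notna(row[c]) for c in cols)


def convert_table(raw: pd.DataFrame, hedges: bool = False) -> pd.DataFrame:
    """Convert a table of raw statistics to corpus rows, one effect per row.

    For each row the first applicable path in the order of preference
    means > quartiles > odds ratio > t statistic is used; the chosen path is
    recorded in a ``method`` column.  Moderator columns are passed through.
    Rows with no applicable path are dropped with a ``method`` of ``none`` in
    the returned diagnostics attribute ``.attrs["skipped"]``.
    """
    out_rows = []
    skipped = []
    passthrough = [
        c
        for c in ("effect_id", "study_id", "drug", "drug_class", "enzyme",
                  "outcome_label", "phenotype", "continent")
        if c in raw.columns
    ]
    for idx, row in raw.iterrows():
        est = None
        n1 = n2 = None
        try:
            if _row_has(row, _MEANS_COLS):
                n1, n2 = int(row["n1"]), int(row["n2"])
                est = smd_from_group_stats(
                    GroupStats(row["mean1"], row["sd1"], n1),
                    GroupStats(row["mean2"], row["sd2"], n2),
                    hedges=hedges,
                )
            elif _row_has(row, _QUART_COLS):
                n1, n2 = int(row["n1"]), int(row["n2"])
                g1 = mean_sd_from_quartiles(QuartileStats(row["q1_1"], row["median1"], row["q3_1"], n1))
                g2 = mean_sd_from_quartiles(QuartileStats(row["q1_2"], row["median2"], row["q3_2"], n2))
                est = smd_from_group_stats(g1, g2, hedges=hedges)
                est = EffectEstimate(est.smd, est.variance, "quartiles",
                                     est.hedges_corrected, est.correction_factor)
            elif _row_has(row, ["odds_ratio"]):
                var_lor = row["var_log_or"] if _row_has(row, ["var_log_or"]) else None
                est = smd_from_odds_ratio(row["odds_ratio"], var_lor)
                if math.isnan(est.variance):
                    if _row_has(row, ["n1", "n2"]):
                        n1, n2 = int(row["n1"]), int(row["n2"])
                        est = EffectEstimate(
                            est.smd, smd_sampling_variance(est.smd, n1, n2), "odds_ratio"
                        )
                    else:
                        raise ValueError("odds ratio without var_log_or or group sizes")
                elif _row_has(row, ["n1", "n2"]):
                    n1, n2 = int(row["n1"]), int(row["n2"])
            elif _row_has(row, ["t_stat", "n1", "n2"]):
                n1, n2 = int(row["n1"]), int(row["n2"])
                est = smd_from_t(row["t_stat"], n1, n2)
            else:
                raise ValueError("no convertible statistics")
        except ValueError as exc:
            skipped.append(f"row {idx}: {exc}")
            continue
        rec = {c: row[c] for c in passthrough}
        rec.update(
            smd=est.smd,
            smd_variance=est.variance,
            n_group1=n1,
            n_group2=n2,
            n_total=(n1 + n2) if n1 is not None else np.nan,
            method=est.method,
        )
        out_rows.append(rec)
    out = pd.DataFrame(out_rows)
    out.attrs["skipped"] = skipped
    return out
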