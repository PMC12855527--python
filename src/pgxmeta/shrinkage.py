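"""Winner's-curse correction via a signal-to-noise-ratio prior.

Published effect estimates that cross a significance threshold tend to
exaggerate the underlying effect.  Following the empirical-Bayes recipe, the
observed z-scores of a literature are modelled as z = mu + eps with
eps ~ N(0, 1) and the true signal-to-noise ratio mu drawn from a zero-mean
normal mixture fitted to the z-score marginal by maximum likelihood (EM).
The conjugate posterior mean E[mu | z] then gives a bias-reduced estimate,
and the exaggeration ratio z / E[mu | z] quantifies the expected inflation:
a low-powered literature (small fitted prior SDs) shrinks harder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Corpus

__all__ = [
    "ZScore",
    "SNRPrior",
    "ShrinkageResult",
    "z_scores",
    "fit_snr_prior",
    "shrinkage",
    "mean_shrinkage",
    "posterior_estimate",
    "shrinkage_report",
]


@dataclass(frozen=True)
class ZScore:
    effect_id: str
    z: float
    outcome_label: str


@dataclass
class SNRPrior:
    """Zero-mean normal mixture for the true signal-to-noise ratio mu."""

    weights: np.ndarray
    sds: np.ndarray  # component SDs of mu (not of the z marginal)
    outcome_label: str = ""
    loglik: float = float("nan")

    def marginal_variance(self) -> float:
        return float(np.sum(self.weights * (self.sds**2 + 1.0)))


@dataclass
class ShrinkageResult:
    z: np.ndarray
    posterior_mean: np.ndarray  # E[mu | z]
    factor: np.ndarray  # z / E[mu | z]; NaN where z == 0

    @property
    def mean_factor(self) -> float:
        ok = np.isfinite(self.factor)
        return float(np.mean(self.factor[ok]))


def z_scores(corpus: Corpus) -> list[ZScore]:
    """Signed z = smd / sqrt(variance) per record."""
    df = corpus.df
    z = df["smd"].to_numpy(float) / np.sqrt(df["smd_variance"].to_numpy(float))
    return [
        ZScore(e, float(zi), o)
        for e, zi, o in zip(df["effect_id"], z, df["outcome_label"])
    ]


def _em_fit(z: np.ndarray, v0: np.ndarray, w0: np.ndarray, max_iter: int = 2000, tol: float = 1e-10):
    """EM for z ~ sum_k w_k N(0, v_k) with v_k >= 1 (v_k = s_k^2 + 1)."""
    v = v0.copy()
    w = w0.copy()
    z2 = z**2
    ll_old = -np.inf
    for _ in range(max_iter):
        dens = w[None, :] * stats.norm.pdf(z[:, None], scale=np.sqrt(v)[None, :])
        total = dens.sum(axis=1)
        total = np.clip(total, 1e-300, None)
        ll = float(np.sum(np.log(total)))
        r = dens / total[:, None]
        nk = r.sum(axis=0)
        w = nk / len(z)
        with np.errstate(invalid="ignore", divide="ignore"):
            v_new = (r * z2[:, None]).sum(axis=0) / nk
        v = np.where(nk > 1e-12, np.clip(v_new, 1.0, None), v)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    return w, v, ll


def fit_snr_prior(zs, n_components: int = 3, outcome_label: str = "") -> SNRPrior:
    """Maximum-likelihood SNR prior from observed z-scores.

    Deterministic given the data and component count: components start at SDs
    {0.5, 1.5, 4} scaled by the sample SD of z, with equal weights.  If a
    component collapses (weight or signal variance vanishing), the fit is
    retried with one component fewer.
    """
    z = np.asarray([s.z if isinstance(s, ZScore) else float(s) for s in zs], float)
    if len(z) < 20:
        raise ValueError("need at least 20 z-scores to fit a prior")
    scale = max(float(np.std(z)), 1e-6)
    base = np.array([0.5, 1.5, 4.0])[:n_components]
    v0 = (base * scale) ** 2 + 1.0
    w0 = np.full(n_components, 1.0 / n_components)
    w, v, ll = _em_fit(z, v0, w0)
    s2 = v - 1.0
    collapsed = (w < 1e-6) | ((s2 < 1e-8) & (n_components > 1))
    if collapsed.any() and n_components > 1:
        warnings.warn(
            f"{int(collapsed.sum())} component(s) collapsed; refitting with "
            f"{n_components - 1} component(s)",
            stacklevel=2,
        )
        return fit_snr_prior(z, n_components - 1, outcome_label)
    return SNRPrior(weights=w, sds=np.sqrt(np.clip(s2, 0.0, None)),
                    outcome_label=outcome_label, loglik=ll)


def _posterior_mean(prior: SNRPrior, z: np.ndarray) -> np.ndarray:
    """Conjugate closed form: E[mu|z] = sum_k wtilde_k(z) z s_k^2/(s_k^2+1)."""
    s2 = prior.sds**2
    marg_var = s2 + 1.0
    dens = prior.weights[None, :] * stats.norm.pdf(
        z[:, None], scale=np.sqrt(marg_var)[None, :]
    )
    dens = dens / np.clip(dens.sum(axis=1, keepdims=True), 1e-300, None)
    return (dens * (s2 / marg_var)[None, :]).sum(axis=1) * z


def shrinkage(prior: SNRPrior, z) -> ShrinkageResult:
    """Posterior means and exaggeration ratios for one or more z values."""
    z = np.atleast_1d(np.asarray(z, float))
    post = _posterior_mean(prior, z)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(z != 0, z / post, np.nan)
    return ShrinkageResult(z=z, posterior_mean=post, factor=factor)


def mean_shrinkage(prior: SNRPrior, zs) -> float:
    """Unweighted mean exaggeration ratio over the supplied z set (z=0 excluded)."""
    z = np.asarray([s.z if isinstance(s, ZScore) else float(s) for s in zs], float)
    z = z[z != 0]
    if len(z) == 0:
        raise ValueError("no nonzero z-scores to average over")
    return shrinkage(prior, z).mean_factor


def posterior_estimate(prior: SNRPrior, smd: float, se: float) -> float:
    """Bias-reduced effect on the SMD scale: E[mu | z = smd/se] * se."""
    if se <= 0:
        raise ValueError("se must be positive")
    return float(_posterior_mean(prior, np.array([smd / se]))[0] * se)


def shrinkage_report(corpus: Corpus, n_components: int = 3) -> tuple[dict[str, SNRPrior], pd.DataFrame]:
    """Per-outcome-class priors and a per-effect shrinkage table."""
    priors: dict[str, SNRPrior] = {}
    frames = []
    for outcome, sub in corpus.df.groupby("outcome_label"):
        z = sub["smd"].to_numpy(float) / np.sqrt(sub["smd_variance"].to_numpy(float))
        prior = fit_snr_prior(z, n_components, outcome_label=outcome)
        priors[outcome] = prior
        res = shrinkage(prior, z)
        frames.append(
            pd.DataFrame(
                {
                    "effect_id": sub["effect_id"].to_numpy(),
                    "outcome_label": outcome,
                    "z": res.z,
                    "posterior_mean_z": res.posterior_mean,
                    "shrinkage_factor": res.factor,
                }
            )
        )
    return priors, pd.concat(frames, ignore_index=True)
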