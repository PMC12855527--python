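"""Cluster-robust inference for CHE fits: CR2 sandwich, Satterthwaite df,
Wald contrasts and Holm multiplicity correction.

The CR2 (bias-reduced linearisation) estimator rescales each study's residual
cross-product by an adjustment matrix A_j chosen so that, if the working model
(the fitted marginal covariance) were exactly right, the rescaled
cross-product would be unbiased for the study's true covariance.  Degrees of
freedom per contrast follow from a Satterthwaite approximation to the
distribution of the variance estimator, which for meta-analyses with a
moderate number of studies is substantially smaller than clusters-minus-p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .che import INTERACTION_CELLS, REMLFit

__all__ = [
    "RobustFit",
    "ContrastResult",
    "cr2_vcov",
    "wald_contrast",
    "holm_adjust",
    "phenotype_contrast_battery",
]


@dataclass
class RobustFit:
    base: REMLFit
    robust_vcov: np.ndarray
    df: np.ndarray  # Satterthwaite df per coefficient
    se: np.ndarray
    ci: np.ndarray  # (p, 2)
    p: np.ndarray
    level: float = 0.95
    _work: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.base.beta_names,
                "estimate": self.base.beta,
                "se_robust": self.se,
                "df": self.df,
                "ci_lower": self.ci[:, 0],
                "ci_upper": self.ci[:, 1],
                "p": self.p,
            }
        )


@dataclass
class ContrastResult:
    name: str
    weights: np.ndarray
    estimate: float
    se: float
    df: float
    p: float


def _psd_sqrt(mat: np.ndarray, inverse: bool = False, floor_frac: float = 1e-10) -> np.ndarray:
    """Symmetric (inverse) square root with eigenvalue flooring."""
    w, V = np.linalg.eigh(0.5 * (mat + mat.T))
    floor = floor_frac * max(w.max(), 0.0) if w.size else 0.0
    w = np.clip(w, max(floor, 1e-300), None)
    d = 1.0 / np.sqrt(w) if inverse else np.sqrt(w)
    return (V * d) @ V.T


def cr2_vcov(fit: REMLFit, level: float = 0.95) -> RobustFit:
    """CR2 cluster-robust covariance with per-coefficient Satterthwaite df.

    Clusters are the studies of the fitted corpus; the working covariance is
    the fitted CHE marginal covariance, so the GLS point estimates are
    untouched and only their covariance and reference distribution change.
    """
    if not fit.converged:
        raise ValueError("base fit did not converge")
    work = fit._work
    studies = work["studies"]
    if len(studies) < 2:
        raise ValueError("robust inference needs at least 2 clusters")
    from .che import _study_cov  # fitted working covariance per study

    M = fit.vcov_beta  # (X' W X)^{-1} with W the working-model inverse covariance
    p = len(fit.beta)
    per_cluster = []
    meat = np.zeros((p, p))
    for st in studies:
        C = _study_cov(st, work["structure"], work["params"])
        W = np.linalg.inv(C)
        X = st["X"]
        e = st["y"] - X @ fit.beta
        G = C - X @ M @ X.T  # E[e_j e_j'] under the working model
        U = _psd_sqrt(C)
        A = U @ _psd_sqrt(U @ G @ U, inverse=True) @ U
        K = A @ W @ X  # (k_j x p); adjusted, weighted design
        g = K.T @ e
        meat += np.outer(g, g)
        per_cluster.append({"K": K, "X": X, "C": C, "e": e})
    V_rob = M @ meat @ M
    V_rob = 0.5 * (V_rob + V_rob.T)

    rfit = RobustFit(
        base=fit,
        robust_vcov=V_rob,
        df=np.empty(p),
        se=np.sqrt(np.diag(V_rob)),
        ci=np.empty((p, 2)),
        p=np.empty(p),
        level=level,
        _work={"clusters": per_cluster, "M": M},
    )
    for i in range(p):
        w = np.zeros(p)
        w[i] = 1.0
        res = wald_contrast(rfit, w, name=fit.beta_names[i])
        rfit.df[i] = res.df
        rfit.p[i] = res.p
        tcrit = stats.t.ppf(0.5 + level / 2, res.df)
        rfit.ci[i] = (fit.beta[i] - tcrit * res.se, fit.beta[i] + tcrit * res.se)
    return rfit


def _satterthwaite_df(rfit: RobustFit, w: np.ndarray) -> float:
    """df = (sum_j t_jj)^2 / sum_jk t_jk^2 for the CR2 variance of w'beta.

    t_jk = p_j' (C_j delta_jk - X_j M X_k') p_k with p_j = K_j M w; this is the
    covariance structure of the per-cluster score contributions under the
    working model.
    """
    M = rfit._work["M"]
    clusters = rfit._work["clusters"]
    Mw = M @ w
    diag_own = []
    S = []  # s_j = X_j' p_j
    for cl in clusters:
        pj = cl["K"] @ Mw
        diag_own.append(pj @ cl["C"] @ pj)
        S.append(cl["X"].T @ pj)
    S = np.asarray(S)  # (J, p)
    cross = S @ M @ S.T  # (J, J): s_j' M s_k
    T = -cross
    T[np.diag_indices_from(T)] += np.asarray(diag_own)
    num = T.trace() ** 2
    den = float((T * T).sum())
    return float(num / den) if den > 0 else float(len(clusters) - 1)


def wald_contrast(rfit: RobustFit, weights, name: str = "") -> ContrastResult:
    """t-type Wald test of w'beta with CR2 SE and Satterthwaite df."""
    w = np.asarray(weights, float)
    if w.shape != rfit.base.beta.shape:
        raise ValueError("contrast length must match number of coefficients")
    if np.all(w == 0):
        raise ValueError("all-zero contrast")
    est = float(w @ rfit.base.beta)
    se = float(np.sqrt(w @ rfit.robust_vcov @ w))
    df = _satterthwaite_df(rfit, w)
    if se > 0:
        p = float(2.0 * stats.t.sf(abs(est / se), df))
    else:
        p = 1.0 if est == 0 else 0.0

    return ContrastResult(name=name, weights=w, estimate=est, se=se, df=df, p=p)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the original order."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def phenotype_contrast_battery(rfit: RobustFit) -> pd.DataFrame:
    """All phenotype comparisons of the interaction fit, Holm-corrected.

    Three families: the 6 pairwise phenotype comparisons within proximal
    outcomes, the 6 within distal outcomes, and the 4 distal-minus-proximal
    comparisons (one per phenotype).
    """
    names = rfit.base.beta_names
    expected = [f"{o}:{p}" for o, p in INTERACTION_CELLS]
    missing = [n for n in expected if n not in names]
    if missing:
        raise ValueError(f"fit is missing interaction cells: {missing}")
    index = {n: names.index(n) for n in expected}
    phenos = ["poor", "intermediate", "rapid", "ultrarapid"]
    rows = []

    def run(name: str, plus: str, minus: str, family: str) -> None:
        w = np.zeros(len(names))
        w[index[plus]] += 1.0
        w[index[minus]] -= 1.0
        res = wald_contrast(rfit, w, name=name)
        rows.append(
            {
                "family": family,
                "test": name,
                "estimate": res.estimate,
                "se": res.se,
                "df": res.df,
                "p": res.p,
            }
        )

    for outcome in ("proximal", "distal"):
        for a, b in combinations(phenos, 2):
            # later phenotype minus earlier, e.g. "intermediate - poor"
            run(
                f"{b} metaboliser - {a} metaboliser ({outcome})",
                f"{outcome}:{b}",
                f"{outcome}:{a}",
                f"within_{outcome}",
            )
    for phe in phenos:
        run(
            f"distal - proximal ({phe} metaboliser)",
            f"distal:{phe}",
            f"proximal:{phe}",
            "distal_vs_proximal",
        )

    table = pd.DataFrame(rows)
    table["p_holm"] = np.nan
    for family, sub in table.groupby("family"):
        table.loc[sub.index, "p_holm"] = holm_adjust(sub["p"].to_numpy())
    return table
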