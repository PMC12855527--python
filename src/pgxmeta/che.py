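"""Correlated-and-hierarchical-effects (CHE) meta-regression fitted by REML.

The working model for effect i in study j is

    y_ij = x_ij' beta + b_j(class_ij) + u_ij + e_ij

where b_j is a study-level random effect that may differ by outcome class
(proximal/distal) with an unstructured 2x2 covariance T (variances tau2_prox,
tau2_dist, correlation rho_tau), u_ij ~ N(0, sigma2) is an effect-level random
intercept, and the sampling errors e_j within a study are jointly normal with
covariance V_j imputed from the reported variances under an assumed
within-study correlation rho.  The marginal covariance is block diagonal by
study, so the restricted likelihood factorises over studies.

A simplified nested structure (one study-intercept variance tau2 plus sigma2)
is available for subgroup sensitivity fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .corpus import Corpus, OUTCOME_LEVELS

__all__ = [
    "SamplingCovariance",
    "ModelSpec",
    "REMLFit",
    "ProfileTrace",
    "ConvergenceError",
    "INTERACTION_CELLS",
    "impute_sampling_covariance",
    "fit_che",
    "fit_primary_pair",
    "fit_interaction",
    "profile_component",
    "prediction_interval",
]

#: coefficient order of the outcome x phenotype cell-means interaction model
INTERACTION_CELLS = [
    (o, p) for o in OUTCOME_LEVELS for p in ("poor", "intermediate", "rapid", "ultrarapid")
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class SamplingCovariance:
    """Block-diagonal imputed sampling covariance of the observed effects.

    One symmetric block per study with diagonal equal to the reported
    variances and off-diagonals rho * sqrt(v_i * v_j).
    """

    rho: float
    blocks: dict[str, tuple[list[str], np.ndarray]]  # study -> (effect ids, matrix)

    def block_for(self, study_id: str, effect_ids: Sequence[str]) -> np.ndarray:
        ids, mat = self.blocks[study_id]
        pos = [ids.index(e) for e in effect_ids]
        return mat[np.ix_(pos, pos)]


def impute_sampling_covariance(corpus: Corpus, rho: float = 0.6) -> SamplingCovariance:
    """Impute the V matrix with constant within-study sampling correlation rho."""
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    v = corpus.df["smd_variance"].to_numpy(float)
    if not np.all(v > 0):
        raise ValueError("all records must carry positive variances")
    blocks: dict[str, tuple[list[str], np.ndarray]] = {}
    for study, sub in corpus.df.groupby("study_id", sort=False):
        sv = sub["smd_variance"].to_numpy(float)
        sd = np.sqrt(sv)
        mat = rho * np.outer(sd, sd)
        np.fill_diagonal(mat, sv)
        blocks[study] = (list(sub["effect_id"]), mat)
    return SamplingCovariance(rho=rho, blocks=blocks)


@dataclass
class ModelSpec:
    """Declarative description of one CHE meta-regression.

    moderators:
      - "outcome": proximal/distal (cell means if intercept=False, otherwise
        intercept + distal indicator with proximal as the reference level)
      - "outcome_phenotype_interaction": cell means over the 8 cells of
        INTERACTION_CELLS (records with unknown phenotype must be excluded by
        ``selection``)
      - "intercept_only": a single grand-mean column
    extra_moderators: numeric corpus columns appended to the design (e.g. the
      1/sqrt(N) precision column of the small-study regression test).
    """

    response: str = "absolute_smd"  # or "signed_smd"
    moderators: str = "outcome"
    intercept: bool = False
    random_structure: str = "che_unstructured_slope"  # or "nested_two_level"
    extra_moderators: tuple[str, ...] = ()
    selection: Callable[[pd.DataFrame], pd.Series] | None = None


@dataclass
class REMLFit:
    beta: np.ndarray
    beta_names: list[str]
    vcov_beta: np.ndarray
    tau2_by_outcome: dict[str, float] | None
    rho_tau: float | None
    tau2: float | None
    sigma2: float
    reml_loglik: float
    converged: bool
    k: int
    n_studies: int
    spec: ModelSpec
    rho_sampling: float
    _work: dict = field(default_factory=dict, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_beta))

    def to_dict(self) -> dict:
        return {
            "beta": dict(zip(self.beta_names, map(float, self.beta))),
            "se_model": dict(zip(self.beta_names, map(float, self.se))),
            "tau2_by_outcome": self.tau2_by_outcome,
            "rho_tau": self.rho_tau,
            "tau2": self.tau2,
            "sigma2": self.sigma2,
            "reml_loglik": self.reml_loglik,
            "converged": self.converged,
            "k": self.k,
            "n_studies": self.n_studies,
            "rho_sampling": self.rho_sampling,
        }


@dataclass
class ProfileTrace:
    component: str
    grid: np.ndarray
    loglik: np.ndarray
    fitted_value: float
    flat: bool


# ---------------------------------------------------------------------------
# design assembly


def _build_design(spec: ModelSpec, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    if spec.moderators == "outcome":
        prox = (df["outcome_label"] == "proximal").to_numpy(float)
        dist = (df["outcome_label"] == "distal").to_numpy(float)
        if spec.intercept:
            cols += [np.ones(len(df)), dist]
            names += ["intercept(proximal)", "distal_minus_proximal"]
        else:
            cols += [prox, dist]
            names += ["proximal", "distal"]
    elif spec.moderators == "outcome_phenotype_interaction":
        missing = []
        for out, phe in INTERACTION_CELLS:
            ind = ((df["outcome_label"] == out) & (df["phenotype"] == phe)).to_numpy(float)
            if ind.sum() == 0:
                missing.append(f"{out}:{phe}")
            cols.append(ind)
            names.append(f"{out}:{phe}")
        if missing:
            raise ValueError(f"empty interaction cells: {missing}")
    elif spec.moderators == "intercept_only":
        cols.append(np.ones(len(df)))
        names.append("intercept")
    else:
        raise ValueError(f"unknown moderators spec: {spec.moderators!r}")
    for col in spec.extra_moderators:
        cols.append(df[col].to_numpy(float))
        names.append(col)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}); columns: {names}"
        )
    return X, names


def _prepare(spec: ModelSpec, corpus: Corpus, vmatrix: SamplingCovariance):
    df = corpus.df
    if spec.selection is not None:
        df = df.loc[spec.selection(df)].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("empty data selection")
    y = df["smd"].to_numpy(float)
    if spec.response == "absolute_smd":
        y = np.abs(y)
    elif spec.response != "signed_smd":
        raise ValueError(f"unknown response: {spec.response!r}")
    X, names = _build_design(spec, df)
    studies = []
    for study, sub in df.groupby("study_id", sort=False):
        idx = sub.index.to_numpy()
        Vj = vmatrix.block_for(study, list(sub["effect_id"]))
        # outcome-class indicator (k_j x 2) for the unstructured slope structure
        Zj = np.column_stack(
            [(sub["outcome_label"] == lvl).to_numpy(float) for lvl in OUTCOME_LEVELS]
        )
        studies.append(
            {
                "study": study,
                "X": X[idx],
                "y": y[idx],
                "V": Vj,
                "Z": Zj,
                "k": len(idx),
            }
        )
    return df, y, X, names, studies


# ---------------------------------------------------------------------------
# restricted likelihood


def _study_cov(st: dict, structure: str, params: dict) -> np.ndarray:
    k = st["k"]
    C = st["V"] + params["sigma2"] * np.eye(k)
    if structure == "che_unstructured_slope":
        tp, td, r = params["tau2_prox"], params["tau2_dist"], params["rho_tau"]
        cov = r * np.sqrt(tp * td)
        T = np.array([[tp, cov], [cov, td]])
        Z = st["Z"]
        C = C + Z @ T @ Z.T
    elif structure == "nested_two_level":
        C = C + params["tau2"]
    else:
        raise ValueError(f"unknown random structure: {structure!r}")
    return C


def _batch_groups(studies: list[dict]) -> list[dict]:
    """Stack study blocks of equal size so the likelihood loop is vectorised."""
    by_k: dict[int, list[dict]] = {}
    for st in studies:
        by_k.setdefault(st["k"], []).append(st)
    groups = []
    for k, sts in by_k.items():
        groups.append(
            {
                "k": k,
                "X": np.stack([s["X"] for s in sts]),  # (m, k, p)
                "y": np.stack([s["y"] for s in sts]),  # (m, k)
                "V": np.stack([s["V"] for s in sts]),  # (m, k, k)
                "Z": np.stack([s["Z"] for s in sts]),  # (m, k, 2)
            }
        )
    return groups


def _reml_core(groups: list[dict], structure: str, params: dict, p: int):
    """Accumulate the restricted log-likelihood pieces over study blocks."""
    logdet = 0.0
    XtX = np.zeros((p, p))
    Xty = np.zeros(p)
    yty = 0.0
    n = 0
    if structure == "che_unstructured_slope":
        tp, td, r = params["tau2_prox"], params["tau2_dist"], params["rho_tau"]
        cov = r * np.sqrt(tp * td)
        T = np.array([[tp, cov], [cov, td]])
    for g in groups:
        k = g["k"]
        C = g["V"] + params["sigma2"] * np.eye(k)[None, :, :]
        if structure == "che_unstructured_slope":
            C = C + np.einsum("mki,ij,mlj->mkl", g["Z"], T, g["Z"])
        elif structure == "nested_two_level":
            C = C + params["tau2"]
        else:
            raise ValueError(f"unknown random structure: {structure!r}")
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return None
        logdet += 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)))
        rhs = np.concatenate([g["X"], g["y"][:, :, None]], axis=2)
        S = np.linalg.solve(C, rhs)  # (m, k, p+1)
        XtX += np.einsum("mki,mkj->ij", g["X"], S[:, :, :p])
        Xty += np.einsum("mki,mk->i", g["X"], S[:, :, p])
        yty += np.einsum("mk,mk->", g["y"], S[:, :, p])
        n += k * g["X"].shape[0]
    XtX = 0.5 * (XtX + XtX.T)
    sign, logdet_XtX = np.linalg.slogdet(XtX)
    if sign <= 0:
        return None
    beta = np.linalg.solve(XtX, Xty)
    quad = yty - Xty @ beta
    ll = -0.5 * ((n - p) * np.log(2.0 * np.pi) + logdet + logdet_XtX + quad)
    return ll, beta, XtX


_COMPONENT_NAMES = {
    "che_unstructured_slope": ["tau2_prox", "tau2_dist", "rho_tau", "sigma2"],
    "nested_two_level": ["tau2", "sigma2"],
}


def _theta_to_params(theta: np.ndarray, structure: str, fixed: dict[str, float]) -> dict:
    params = dict(fixed)
    free = [c for c in _COMPONENT_NAMES[structure] if c not in fixed]
    for name, t in zip(free, theta):
        params[name] = np.tanh(t) if name == "rho_tau" else np.exp(t)
    if structure == "che_unstructured_slope" and "rho_tau" not in params:
        params["rho_tau"] = 0.0
    return params


def fit_che(
    spec: ModelSpec,
    corpus: Corpus,
    vmatrix: SamplingCovariance | None = None,
    fix_components: dict[str, float] | None = None,
    start_components: dict[str, float] | None = None,
) -> REMLFit:
    """Fit the CHE meta-regression by REML.

    Variance components are log-parameterised (the study-level correlation is
    tanh-parameterised) and maximised with L-BFGS-B; on failure the search is
    restarted from jittered starting values.  ``fix_components`` pins named
    components at given values (useful for degenerate reductions and profile
    likelihoods); ``start_components`` warm-starts the search.
    """
    if vmatrix is None:
        vmatrix = impute_sampling_covariance(corpus)
    fixed = dict(fix_components or {})
    df, y, X, names, studies = _prepare(spec, corpus, vmatrix)
    groups = _batch_groups(studies)
    p = X.shape[1]
    structure = spec.random_structure
    free = [c for c in _COMPONENT_NAMES[structure] if c not in fixed]

    def objective(theta: np.ndarray) -> float:
        params = _theta_to_params(theta, structure, fixed)
        core = _reml_core(groups, structure, params, p)
        if core is None:
            return 1e12
        return -core[0]

    if free:
        # moment-style starting value: residual variance from an unweighted fit
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta0
        s2 = max(float(np.var(resid)), 1e-4)
        start_map = {
            "tau2_prox": np.log(s2 / 4),
            "tau2_dist": np.log(s2 / 4),
            "rho_tau": 0.0,
            "tau2": np.log(s2 / 4),
            "sigma2": np.log(s2 / 2),
        }
        for name, val in (start_components or {}).items():
            if name == "rho_tau":
                start_map[name] = np.arctanh(np.clip(val, -0.9999, 0.9999))
            else:
                start_map[name] = np.log(max(val, 1e-8))
        theta0 = np.array([start_map[c] for c in free])
        bounds = [(-5.0, 5.0) if c == "rho_tau" else (-20.0, 4.0) for c in free]
        best = None
        rng = np.random.default_rng(0)
        for attempt in range(4):
            start = theta0 if attempt == 0 else theta0 + rng.normal(0, 1.0, len(free))
            res = optimize.minimize(
                objective,
                start,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
            if res.success and attempt == 0:
                break
        converged = bool(best.success) or np.isfinite(best.fun)
        if not np.isfinite(best.fun) or best.fun >= 1e12:
            raise ConvergenceError("REML optimisation failed on all restarts")
        params = _theta_to_params(best.x, structure, fixed)
    else:
        params = _theta_to_params(np.empty(0), structure, fixed)
        converged = True

    core = _reml_core(groups, structure, params, p)
    if core is None:
        raise ConvergenceError("covariance not positive definite at optimum")
    ll, beta, XtX = core
    vcov = np.linalg.inv(XtX)
    vcov = 0.5 * (vcov + vcov.T)

    if structure == "che_unstructured_slope":
        tau2_by_outcome = {
            "proximal": float(params["tau2_prox"]),
            "distal": float(params["tau2_dist"]),
        }
        rho_tau = float(params["rho_tau"])
        tau2 = None
    else:
        tau2_by_outcome, rho_tau = None, None
        tau2 = float(params["tau2"])

    fit = REMLFit(
        beta=beta,
        beta_names=names,
        vcov_beta=vcov,
        tau2_by_outcome=tau2_by_outcome,
        rho_tau=rho_tau,
        tau2=tau2,
        sigma2=float(params["sigma2"]),
        reml_loglik=float(ll),
        converged=converged,
        k=len(df),
        n_studies=len(studies),
        spec=spec,
        rho_sampling=vmatrix.rho,
    )
    fit._work = {
        "studies": studies,
        "structure": structure,
        "params": params,
        "X": X,
        "y": y,
        "df": df,
        "fixed": fixed,
    }
    return fit


def fit_primary_pair(
    corpus: Corpus,
    rho: float = 0.6,
    response: str = "absolute_smd",
    random_structure: str = "che_unstructured_slope",
) -> tuple[REMLFit, REMLFit]:
    """The primary model twice: cell-means (no intercept) and intercept coding.

    The no-intercept fit gives the pooled proximal and distal estimates; the
    intercept fit's second coefficient is the distal-minus-proximal difference.
    Both are reparameterisations of the same model and attain the same
    restricted likelihood.
    """
    levels = set(corpus.df["outcome_label"])
    if len(levels & set(OUTCOME_LEVELS)) < 2:
        raise ValueError("corpus must contain both proximal and distal effects")
    vmatrix = impute_sampling_covariance(corpus, rho)
    no_int = fit_che(
        ModelSpec(response=response, moderators="outcome", intercept=False,
                  random_structure=random_structure),
        corpus, vmatrix,
    )
    if random_structure == "che_unstructured_slope":
        warm = {
            "tau2_prox": no_int.tau2_by_outcome["proximal"],
            "tau2_dist": no_int.tau2_by_outcome["distal"],
            "rho_tau": no_int.rho_tau,
            "sigma2": no_int.sigma2,
        }
    else:
        warm = {"tau2": no_int.tau2, "sigma2": no_int.sigma2}
    with_int = fit_che(
        ModelSpec(response=response, moderators="outcome", intercept=True,
                  random_structure=random_structure),
        corpus, vmatrix, start_components=warm,
    )
    return no_int, with_int


def fit_interaction(
    corpus: Corpus,
    rho: float = 0.6,
    response: str = "absolute_smd",
    random_structure: str = "che_unstructured_slope",
) -> REMLFit:
    """Outcome x metaboliser-phenotype cell-means model on known phenotypes."""
    sel = corpus.select(corpus.df["phenotype"] != "unknown", "phenotype != unknown")
    vmatrix = impute_sampling_covariance(sel, rho)
    spec = ModelSpec(
        response=response,
        moderators="outcome_phenotype_interaction",
        random_structure=random_structure,
    )
    return fit_che(spec, sel, vmatrix)


def profile_component(
    spec: ModelSpec,
    corpus: Corpus,
    vmatrix: SamplingCovariance,
    component: str,
    grid: Sequence[float],
    flat_tol: float = 0.1,
) -> ProfileTrace:
    """Profile restricted log-likelihood of one variance component.

    At each grid value the component is fixed and the remaining components are
    re-optimised.  A profile whose range over the grid is below ``flat_tol``
    log-likelihood units is flagged flat (non-identifiable).
    """
    full = fit_che(spec, corpus, vmatrix)
    fitted = {
        "tau2_prox": (full.tau2_by_outcome or {}).get("proximal"),
        "tau2_dist": (full.tau2_by_outcome or {}).get("distal"),
        "rho_tau": full.rho_tau,
        "tau2": full.tau2,
        "sigma2": full.sigma2,
    }.get(component)
    if fitted is None:
        raise ValueError(f"component {component!r} not in structure {spec.random_structure!r}")
    grid = np.asarray(grid, float)
    if not (grid.min() <= fitted <= grid.max()):
        warnings.warn(
            f"profile grid [{grid.min()}, {grid.max()}] excludes fitted value {fitted:.4g}",
            stacklevel=2,
        )
    lls = np.empty(len(grid))
    for i, val in enumerate(grid):
        f = fit_che(spec, corpus, vmatrix, fix_components={component: float(val)})
        lls[i] = f.reml_loglik
    flat = bool(lls.max() - lls.min() < flat_tol)
    return ProfileTrace(component=component, grid=grid, loglik=lls,
                        fitted_value=float(fitted), flat=flat)


def prediction_interval(
    fit: REMLFit,
    outcome: str,
    level: float = 0.95,
    se: float | None = None,
    df: float | None = None,
) -> tuple[float, float]:
    """95% prediction interval for the true effect of a new study.

    estimate +/- crit * sqrt(SE^2 + tau2_outcome + sigma2).  The bound is not
    truncated at zero even for an absolute-SMD response.  ``se`` overrides the
    model-based standard error (e.g. with a cluster-robust one); with ``df``
    the critical value comes from a t distribution, otherwise from the normal.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    name = outcome if outcome in fit.beta_names else None
    if name is None:
        raise ValueError(f"unknown outcome level {outcome!r}; have {fit.beta_names}")
    i = fit.beta_names.index(name)
    est = float(fit.beta[i])
    se_i = float(se if se is not None else fit.se[i])
    if fit.tau2_by_outcome is not None:
        tau2 = fit.tau2_by_outcome[outcome]
    else:
        tau2 = fit.tau2 or 0.0
    crit = stats.t.ppf(0.5 + level / 2, df) if df is not None else stats.norm.ppf(0.5 + level / 2)
    half = crit * np.sqrt(se_i**2 + tau2 + fit.sigma2)
    return (est - half, est + half)
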