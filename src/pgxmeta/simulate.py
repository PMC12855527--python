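"""Synthetic effect-size corpora with the hierarchical structure the CHE
model assumes.

Each study draws a pair of correlated study-level deviations (one per outcome
class), each effect adds an effect-level deviation and correlated sampling
noise whose variance follows the SMD variance formula at the effect's sample
size.  Defaults mirror the shape and headline parameters of the psychiatric
pharmacogenomics literature this package analyses: 184 studies averaging ~11
effects each, 56% proximal effects, pooled absolute SMDs 0.481 (proximal) and
0.278 (distal), between-study variances 0.062/0.017, effect-level variance
0.164 and within-study sampling correlation 0.6.

Randomness is drawn from per-study seed sequences derived from the single
config seed, so corpora are reproducible and earlier studies' draws do not
change when more studies are appended.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .conversion import smd_to_odds_ratio
from .corpus import Corpus, corpus_from_frame

__all__ = ["SimConfig", "SimCorpus", "simulate_corpus", "simulate_raw_groups"]

_LOGISTIC_SQ = 3.0 / np.pi**2

_DRUGS = {
    "risperidone": (0.20, "antipsychotic", "CYP2D6"),
    "escitalopram": (0.13, "antidepressant", "CYP2C19"),
    "aripiprazole": (0.08, "antipsychotic", "CYP2D6"),
    "haloperidol": (0.07, "antipsychotic", "CYP2D6"),
    "sertraline": (0.07, "antidepressant", "CYP2C19"),
    "clozapine": (0.07, "antipsychotic", "CYP1A2"),
    "venlafaxine": (0.07, "antidepressant", "CYP2D6"),
    "other": (0.31, "unknown/multiple", "CYP2D6"),
}
_CONTINENTS = {"Europe": 0.63, "Asia": 0.23, "North America": 0.10, "Oceania": 0.04}


@dataclass(frozen=True)
class SimConfig:
    n_studies: int = 184
    effects_per_study_mean: float = 11.4  # 1 + Poisson(mean - 1)
    p_proximal: float = 0.56
    true_beta_proximal: float = 0.481
    true_beta_distal: float = 0.278
    tau2_proximal: float = 0.062
    tau2_distal: float = 0.017
    rho_tau: float = 0.5
    sigma2: float = 0.164
    rho_sampling: float = 0.6
    n_range: tuple[float, float] = (20.0, 400.0)  # log-uniform per-effect total N
    phenotype_mix: tuple[float, float, float, float] = (0.255, 0.482, 0.067, 0.196)
    signed: bool = False  # attach random signs (for funnel/shrinkage testing)
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if self.effects_per_study_mean < 1:
            raise ValueError("effects_per_study_mean must be >= 1")
        for v in (self.tau2_proximal, self.tau2_distal, self.sigma2):
            if v < 0:
                raise ValueError("variances must be non-negative")
        if not (abs(self.rho_tau) <= 1 and 0 <= self.rho_sampling < 1):
            raise ValueError("correlations out of range")
        if not np.isclose(sum(self.phenotype_mix), 1.0):
            raise ValueError("phenotype_mix must sum to 1")
        if not (0 <= self.p_proximal <= 1):
            raise ValueError("p_proximal must lie in [0, 1]")


@dataclass
class SimCorpus:
    corpus: Corpus
    config: SimConfig
    study_effects: pd.DataFrame  # per-study realised (b_proximal, b_distal)
    effect_truth: pd.DataFrame  # per-effect latent truth theta and deviation u


_PHENOS = ("poor", "intermediate", "rapid", "ultrarapid")


def simulate_corpus(config: SimConfig | None = None, **overrides) -> SimCorpus:
    """Draw one corpus; fully reproducible from ``config.seed``."""
    config = replace(config or SimConfig(), **overrides)
    config.validate()
    T = np.array(
        [
            [config.tau2_proximal,
             config.rho_tau * np.sqrt(config.tau2_proximal * config.tau2_distal)],
            [config.rho_tau * np.sqrt(config.tau2_proximal * config.tau2_distal),
             config.tau2_distal],
        ]
    )
    chol_T = np.linalg.cholesky(T + 1e-15 * np.eye(2))
    drugs = list(_DRUGS)
    p_drug = np.array([_DRUGS[d][0] for d in drugs])
    conts = list(_CONTINENTS)
    p_cont = np.array(list(_CONTINENTS.values()))
    log_lo, log_hi = np.log(config.n_range[0]), np.log(config.n_range[1])

    rows, study_rows, truth_rows = [], [], []
    eid = 0
    for j in range(config.n_studies):
        rng = np.random.default_rng([config.seed, j])
        b = chol_T @ rng.standard_normal(2)  # (b_proximal, b_distal)
        k = 1 + rng.poisson(config.effects_per_study_mean - 1.0)
        drug = drugs[rng.choice(len(drugs), p=p_drug)]
        continent = conts[rng.choice(len(conts), p=p_cont)]
        is_prox = rng.random(k) < config.p_proximal
        u = rng.normal(0.0, np.sqrt(config.sigma2), k)
        ntot = np.exp(rng.uniform(log_lo, log_hi, k))
        n1 = np.maximum(np.round(ntot / 2.0), 2.0)
        n2 = np.maximum(np.round(ntot) - n1, 2.0)
        ntot = n1 + n2
        theta = np.where(is_prox, config.true_beta_proximal, config.true_beta_distal)
        theta = theta + np.where(is_prox, b[0], b[1]) + u
        v_truth = ntot / (n1 * n2) + theta**2 / (2.0 * ntot)
        # correlated sampling errors within the study
        sd = np.sqrt(v_truth)
        V = config.rho_sampling * np.outer(sd, sd)
        np.fill_diagonal(V, v_truth)
        eps = np.linalg.cholesky(V) @ rng.standard_normal(k)
        y = theta + eps
        if config.signed:
            signs = np.where(rng.random(k) < 0.5, -1.0, 1.0)
            y = y * signs
            theta = theta * signs
        phenos = [_PHENOS[i] for i in rng.choice(4, k, p=np.array(config.phenotype_mix))]
        study_id = f"study_{j:04d}"
        study_rows.append({"study_id": study_id, "b_proximal": b[0], "b_distal": b[1]})
        for i in range(k):
            rows.append(
                {
                    "effect_id": f"effect_{eid:05d}",
                    "study_id": study_id,
                    "smd": y[i],
                    "smd_variance": v_truth[i],
                    "n_total": int(ntot[i]),
                    "n_group1": int(n1[i]),
                    "n_group2": int(n2[i]),
                    "drug": drug,
                    "drug_class": _DRUGS[drug][1],
                    "enzyme": _DRUGS[drug][2],
                    "outcome_label": "proximal" if is_prox[i] else "distal",
                    "phenotype": phenos[i],
                    "continent": continent,
                }
            )
            truth_rows.append(
                {"effect_id": f"effect_{eid:05d}", "theta": theta[i], "u": u[i],
                 "v_truth": v_truth[i]}
            )
            eid += 1

    corpus = corpus_from_frame(
        pd.DataFrame(rows),
        provenance=[f"simulated corpus (seed={config.seed}, n_studies={config.n_studies})"],
        errors="raise",
    )
    return SimCorpus(
        corpus=corpus,
        config=config,
        study_effects=pd.DataFrame(study_rows),
        effect_truth=pd.DataFrame(truth_rows),
    )


def simulate_raw_groups(
    config: SimConfig | None = None,
    frac_quartiles: float = 0.2,
    frac_or: float = 0.1,
    **overrides,
) -> tuple[pd.DataFrame, SimCorpus]:
    """Raw group-level statistics whose implied SMDs match a simulate_corpus draw.

    A configurable fraction of effects is reported as median/IQR (introducing
    the bounded Wan approximation error) or as odds ratios (exact through the
    logistic conversion pair); the rest as group means and SDs (exact).
    Feeding the table through the batch converter reproduces the corpus up to
    those approximation errors.
    """
    sim = simulate_corpus(config, **overrides)
    df = sim.corpus.df
    rng = np.random.default_rng([sim.config.seed, 1 << 20])
    u = rng.random(len(df))
    qnorm = {0.25: -0.6744897501960817, 0.75: 0.6744897501960817}
    rows = []
    for i, row in df.iterrows():
        base = {
            "effect_id": row["effect_id"],
            "study_id": row["study_id"],
            "drug": row["drug"],
            "drug_class": row["drug_class"],
            "enzyme": row["enzyme"],
            "outcome_label": row["outcome_label"],
            "phenotype": row["phenotype"],
            "continent": row["continent"],
        }
        d = row["smd"]
        n1, n2 = int(row["n_group1"]), int(row["n_group2"])
        if u[i] < frac_quartiles:
            # exact normal quartiles of N(d, 1) and N(0, 1)
            base.update(
                q1_1=d + qnorm[0.25], median1=d, q3_1=d + qnorm[0.75], n1=n1,
                q1_2=qnorm[0.25], median2=0.0, q3_2=qnorm[0.75], n2=n2,
            )
        elif u[i] < frac_quartiles + frac_or:
            base.update(
                odds_ratio=smd_to_odds_ratio(d),
                var_log_or=row["smd_variance"] / _LOGISTIC_SQ,
                n1=n1, n2=n2,
            )
        else:
            base.update(mean1=d, sd1=1.0, n1=n1, mean2=0.0, sd2=1.0, n2=n2)
        rows.append(base)
    return pd.DataFrame(rows), sim
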