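"""Publication-bias diagnostics: sample-size funnel data and a
multilevel-adapted Egger regression test.

Standard-error-based funnel plots of SMDs can signal spurious asymmetry
because the SMD and its standard error are mechanically coupled; the
diagnostics here therefore use 1/sqrt(N) as the precision axis and as the
small-study moderator in the regression test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .che import ModelSpec, fit_che, impute_sampling_covariance
from .corpus import Corpus
from .robust import cr2_vcov, wald_contrast

__all__ = ["EggerResult", "precision", "multilevel_egger", "funnel_export"]


@dataclass
class EggerResult:
    slope: float
    se: float
    df: float
    p: float
    model: str


def precision(n_total: float) -> float:
    """Sample-size precision measure 1/sqrt(N)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 1.0 / np.sqrt(n_total)


def multilevel_egger(
    corpus: Corpus,
    rho: float = 0.6,
    response: str = "absolute_smd",
    random_structure: str = "che_unstructured_slope",
) -> EggerResult:
    """Egger-type small-study test within the CHE model.

    The precision column 1/sqrt(N) is added as a moderator alongside the
    outcome moderator; the CR2 robust t-test of its coefficient is the
    asymmetry test (a nonzero slope means small studies report systematically
    different effects).
    """
    n = corpus.df["n_total"]
    if n.isna().any():
        bad = corpus.df.loc[n.isna(), "effect_id"].tolist()
        raise ValueError(f"records missing n_total: {bad}")
    work = corpus.df.copy()
    work["inv_sqrt_n"] = 1.0 / np.sqrt(work["n_total"].astype(float))
    aug = Corpus.__new__(Corpus)
    aug.df = work
    aug.provenance = list(corpus.provenance) + ["added inv_sqrt_n moderator"]
    vmatrix = impute_sampling_covariance(corpus, rho)
    spec = ModelSpec(
        response=response,
        moderators="outcome",
        intercept=False,
        random_structure=random_structure,
        extra_moderators=("inv_sqrt_n",),
    )
    fit = fit_che(spec, aug, vmatrix)
    rfit = cr2_vcov(fit)
    w = np.zeros(len(fit.beta))
    w[fit.beta_names.index("inv_sqrt_n")] = 1.0
    res = wald_contrast(rfit, w, name="egger_slope")
    return EggerResult(
        slope=res.estimate,
        se=res.se,
        df=res.df,
        p=res.p,
        model=f"{response} ~ outcome + inv_sqrt_n, {random_structure}, rho={rho}",
    )


def funnel_export(corpus: Corpus) -> pd.DataFrame:
    """Signed SMD against 1/sqrt(N), one row per effect (plot-ready)."""
    n = corpus.df["n_total"]
    if n.isna().any():
        bad = corpus.df.loc[n.isna(), "effect_id"].tolist()
        raise ValueError(f"records missing n_total: {bad}")
    return pd.DataFrame(
        {
            "effect_id": corpus.df["effect_id"],
            "study_id": corpus.df["study_id"],
            "smd": corpus.df["smd"],
            "precision": 1.0 / np.sqrt(corpus.df["n_total"].astype(float)),
            "outcome_label": corpus.df["outcome_label"],
        }
    )
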