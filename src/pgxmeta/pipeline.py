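"""End-to-end orchestration: run every analysis stage on a corpus and write a
diff-able bundle of JSON/CSV outputs with a manifest.

Stages, in order: extreme-value filtering, descriptive summaries, the primary
no-intercept/intercept model pair (over a rho sensitivity grid) with robust
inference, gene-drug subgroup sensitivity fits, the outcome x phenotype
interaction model with its contrast battery, the multilevel Egger test and
funnel export, power planning from the robust confidence bounds, and
winner's-curse shrinkage per outcome class.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bias import funnel_export, multilevel_egger
from .che import (
    ModelSpec,
    fit_che,
    fit_interaction,
    fit_primary_pair,
    impute_sampling_covariance,
    prediction_interval,
)
from .corpus import Corpus, filter_extreme, read_corpus, summarize
from .power import PowerQuery, n_per_group
from .robust import RobustFit, cr2_vcov, phenotype_contrast_battery
from .shrinkage import shrinkage_report
from .simulate import SimConfig, simulate_corpus

logger = logging.getLogger("pgxmeta")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "export_orchard_data"]


@dataclass
class PipelineConfig:
    corpus_path: str | None = None
    sim: SimConfig | None = None
    rho: float = 0.6
    rho_grid: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    #: None resolves to signed_smd (identity) for unsigned simulated corpora,
    #: whose values are already on the absolute scale, else absolute_smd
    response: str | None = None
    extreme_threshold: float = 5.0
    subgroup_min_effects: int = 100
    run_interaction: bool = True
    run_egger: bool = True
    run_shrinkage: bool = True
    power_alpha: float = 0.05
    power_target: float = 0.8
    out_dir: str = "pgxmeta_report"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.corpus_path is None) == (self.sim is None):
            raise ValueError("exactly one corpus source (corpus_path or sim) required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("sim", None)
        if sim is not None:
            sim = SimConfig(**sim)
        return cls(sim=sim, **raw)


@dataclass
class ReportBundle:
    out_dir: Path
    manifest: dict = field(default_factory=dict)

    def add(self, key: str, filename: str) -> Path:
        self.manifest[key] = filename
        return self.out_dir / filename

    def validate(self) -> None:
        missing = [f for f in self.manifest.values() if not (self.out_dir / f).exists()]
        if missing:
            raise FileNotFoundError(f"manifest files missing: {missing}")

    def write_manifest(self) -> None:
        (self.out_dir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _json_dump(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))


def _robust_summary(rfit: RobustFit) -> dict:
    out = rfit.base.to_dict()
    tab = rfit.to_frame()
    out["robust"] = tab.set_index("coef").to_dict(orient="index")
    return out


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all configured stages; outputs are a pure function of
    (corpus bytes, config, seed)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out_dir)

    response = config.response
    if config.corpus_path is not None:
        corpus = read_corpus(config.corpus_path)
        response = response or "absolute_smd"
    else:
        sim = config.sim
        if sim.seed != config.seed:
            sim = SimConfig(**{**asdict(sim), "seed": config.seed})
        corpus = simulate_corpus(sim).corpus
        response = response or ("absolute_smd" if sim.signed else "signed_smd")
    corpus = filter_extreme(corpus, config.extreme_threshold)
    logger.info("corpus: %d effects from %d studies", len(corpus), corpus.n_studies)

    corpus.df.to_csv(bundle.add("corpus", "corpus_filtered.csv"), index=False)

    for by in ("outcome_label", "phenotype", "enzyme", "drug_class", "continent"):
        summarize(corpus, by).to_csv(bundle.add(f"summary_{by}", f"summary_{by}.csv"))

    # primary model pair across the rho sensitivity grid
    primary = {}
    robust_primary: RobustFit | None = None
    for rho in sorted(set(config.rho_grid) | {config.rho}):
        no_int, with_int = fit_primary_pair(corpus, rho, response=response)
        r_no = cr2_vcov(no_int)
        r_with = cr2_vcov(with_int)
        primary[f"rho={rho}"] = {
            "no_intercept": _robust_summary(r_no),
            "intercept": _robust_summary(r_with),
        }
        if rho == config.rho:
            robust_primary = r_no
            pis = {
                lvl: prediction_interval(no_int, lvl, se=float(r_no.se[i]))
                for i, lvl in enumerate(no_int.beta_names)
            }
            primary[f"rho={rho}"]["prediction_intervals"] = pis
    _json_dump(primary, bundle.add("primary_fits", "primary_fits.json"))
    logger.info("primary fits done (rho grid %s)", sorted(set(config.rho_grid) | {config.rho}))

    # gene-drug subgroup sensitivity fits (nested two-level structure)
    subgroups = {}
    counts = corpus.df.groupby(["enzyme", "drug"]).size()
    for (enzyme, drug), n in counts.items():
        if n < config.subgroup_min_effects:
            continue
        sub = corpus.select(
            (corpus.df["enzyme"] == enzyme) & (corpus.df["drug"] == drug),
            f"subgroup {enzyme}-{drug}",
        )
        if sub.df["outcome_label"].nunique() < 2 or sub.df["study_id"].nunique() < 2:
            continue
        try:
            no_int, with_int = fit_primary_pair(
                sub, config.rho, response=response, random_structure="nested_two_level"
            )
            subgroups[f"{enzyme}-{drug}"] = {
                "n_effects": int(n),
                "no_intercept": _robust_summary(cr2_vcov(no_int)),
                "intercept": _robust_summary(cr2_vcov(with_int)),
            }
        except (ValueError, RuntimeError) as exc:
            subgroups[f"{enzyme}-{drug}"] = {"n_effects": int(n), "error": str(exc)}
    _json_dump(subgroups, bundle.add("subgroup_fits", "subgroup_fits.json"))

    # interaction model + contrasts
    if config.run_interaction:
        known = corpus.df["phenotype"] != "unknown"
        has_cells = (
            corpus.df.loc[known].groupby(["outcome_label", "phenotype"]).size().ge(1).sum() == 8
        )
        if has_cells:
            inter = fit_interaction(corpus, config.rho, response=response)
            r_inter = cr2_vcov(inter)
            _json_dump(_robust_summary(r_inter), bundle.add("interaction_fit", "interaction_fit.json"))
            battery = phenotype_contrast_battery(r_inter)
            battery.to_csv(bundle.add("contrasts", "phenotype_contrasts.csv"), index=False)
        else:
            logger.warning("interaction stage skipped: empty outcome x phenotype cells")

    # publication-bias diagnostics
    if config.run_egger:
        egger = multilevel_egger(corpus, config.rho, response=response)
        _json_dump(
            {"slope": egger.slope, "se": egger.se, "df": egger.df, "p": egger.p,
             "model": egger.model},
            bundle.add("egger", "egger.json"),
        )
        funnel_export(corpus).to_csv(bundle.add("funnel", "funnel.csv"), index=False)

    # power planning from robust CIs of the primary no-intercept fit
    power_rows = []
    for i, lvl in enumerate(robust_primary.base.beta_names):
        for label, d in (
            ("estimate", robust_primary.base.beta[i]),
            ("ci_lower", robust_primary.ci[i, 0]),
            ("ci_upper", robust_primary.ci[i, 1]),
        ):
            if d <= 0:
                continue
            power_rows.append(
                {
                    "outcome": lvl,
                    "effect_basis": label,
                    "d": float(d),
                    "n_per_group": n_per_group(
                        PowerQuery(d=float(d), alpha=config.power_alpha,
                                   target_power=config.power_target)
                    ),
                }
            )
    pd.DataFrame(power_rows).to_csv(bundle.add("power", "power_table.csv"), index=False)

    # winner's-curse shrinkage per outcome class
    if config.run_shrinkage:
        priors, table = shrinkage_report(corpus)
        table.to_csv(bundle.add("shrinkage_table", "shrinkage_table.csv"), index=False)
        _json_dump(
            {
                lvl: {
                    "weights": prior.weights,
                    "sds": prior.sds,
                    "loglik": prior.loglik,
                    "mean_factor": float(
                        np.nanmean(
                            table.loc[table["outcome_label"] == lvl, "shrinkage_factor"]
                        )
                    ),
                }
                for lvl, prior in priors.items()
            },
            bundle.add("shrinkage_priors", "shrinkage_priors.json"),
        )

    # orchard-plot data for the primary fit
    export_orchard_data(robust_primary, corpus).to_csv(
        bundle.add("orchard", "orchard_data.csv"), index=False
    )

    cfg = asdict(config)
    if cfg.get("sim"):
        cfg["sim"] = asdict(config.sim)
    cfg_text = json.dumps(cfg, sort_keys=True, default=str)
    _json_dump(
        {
            "config": cfg,
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "pgxmeta_version": __version__,
            "seed": config.seed,
        },
        bundle.add("provenance", "provenance.json"),
    )
    bundle.write_manifest()
    bundle.validate()
    return bundle


def export_orchard_data(rfit: RobustFit, corpus: Corpus) -> pd.DataFrame:
    """Per-effect |SMD| and precision plus per-class pooled summary rows.

    The summary rows carry the robust confidence interval and the wider
    prediction interval that an orchard plot draws as thick/thin error bars.
    """
    fit = rfit.base
    rows = pd.DataFrame(
        {
            "kind": "effect",
            "outcome_label": corpus.df["outcome_label"],
            "abs_smd": corpus.df["smd"].abs(),
            "precision": 1.0 / np.sqrt(corpus.df["n_total"].astype(float)),
            "estimate": np.nan,
            "ci_lower": np.nan,
            "ci_upper": np.nan,
            "pi_lower": np.nan,
            "pi_upper": np.nan,
        }
    )
    summaries = []
    for i, lvl in enumerate(fit.beta_names):
        pi = prediction_interval(fit, lvl, se=float(rfit.se[i]))
        summaries.append(
            {
                "kind": "summary",
                "outcome_label": lvl,
                "abs_smd": np.nan,
                "precision": np.nan,
                "estimate": float(fit.beta[i]),
                "ci_lower": rfit.ci[i, 0],
                "ci_upper": rfit.ci[i, 1],
                "pi_lower": pi[0],
                "pi_upper": pi[1],
            }
        )
    return pd.concat([rows, pd.DataFrame(summaries)], ignore_index=True)
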