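"""Effect-size corpus: data model, CSV I/O, filtering and descriptive summaries.

The corpus holds one row per effect size (standardised mean difference between
an atypical CYP metaboliser group and normal metabolisers), with the study it
came from and the moderator labels used downstream: the proximal/distal outcome
class, drug, enzyme, metaboliser phenotype and continent.  Effects from the
same study form a cluster; the meta-analytic machinery treats those clusters
as statistically dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "EffectRecord",
    "Corpus",
    "CorpusSummary",
    "SchemaError",
    "CANONICAL_COLUMNS",
    "OUTCOME_LEVELS",
    "PHENOTYPE_LEVELS",
    "ENZYME_LEVELS",
    "DRUG_CLASS_LEVELS",
    "read_corpus",
    "write_corpus",
    "corpus_from_frame",
    "filter_extreme",
    "summarize",
]

CANONICAL_COLUMNS = [
    "effect_id",
    "study_id",
    "smd",
    "smd_variance",
    "n_total",
    "n_group1",
    "n_group2",
    "drug",
    "drug_class",
    "enzyme",
    "outcome_label",
    "phenotype",
    "continent",
]

OUTCOME_LEVELS = ("proximal", "distal")
PHENOTYPE_LEVELS = ("poor", "intermediate", "rapid", "ultrarapid", "unknown")
ENZYME_LEVELS = ("CYP1A2", "CYP2B6", "CYP2C19", "CYP2C9", "CYP2D6", "CYP3A4/5")
DRUG_CLASS_LEVELS = ("antidepressant", "antipsychotic", "unknown/multiple")

#: moderators with a closed vocabulary; summaries report empty levels for these
_CONTROLLED = {
    "outcome_label": OUTCOME_LEVELS,
    "phenotype": PHENOTYPE_LEVELS,
    "enzyme": ENZYME_LEVELS,
    "drug_class": DRUG_CLASS_LEVELS,
}


class SchemaError(ValueError):
    """A mandatory column is missing or unmappable in an input table."""


@dataclass(frozen=True)
class EffectRecord:
    """One standardised mean difference with its study linkage and moderators."""

    effect_id: str
    study_id: str
    smd: float
    smd_variance: float
    n_total: int | None = None
    n_group1: int | None = None
    n_group2: int | None = None
    drug: str = ""
    drug_class: str = "unknown/multiple"
    enzyme: str = ""
    outcome_label: str = "proximal"
    phenotype: str = "unknown"
    continent: str = ""

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if the record is valid)."""
        problems = []
        if not math.isfinite(self.smd):
            problems.append("non-finite smd")
        if not (math.isfinite(self.smd_variance) and self.smd_variance > 0):
            problems.append("non-positive variance")
        if self.n_total is not None and self.n_total < 2:
            problems.append("n_total < 2")
        if self.outcome_label not in OUTCOME_LEVELS:
            problems.append(
                f"outcome_label {self.outcome_label!r} not in {OUTCOME_LEVELS}"
            )
        if self.phenotype not in PHENOTYPE_LEVELS:
            problems.append(f"phenotype {self.phenotype!r} not in {PHENOTYPE_LEVELS}")
        if not self.study_id:
            problems.append("missing study_id")
        return problems


@dataclass
class Corpus:
    """Validated collection of effect records plus free-text provenance."""

    df: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"corpus frame missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_studies(self) -> int:
        return int(self.df["study_id"].nunique())

    def records(self) -> Iterator[EffectRecord]:
        for row in self.df.itertuples(index=False):
            yield EffectRecord(
                effect_id=row.effect_id,
                study_id=row.study_id,
                smd=float(row.smd),
                smd_variance=float(row.smd_variance),
                n_total=None if pd.isna(row.n_total) else int(row.n_total),
                n_group1=None if pd.isna(row.n_group1) else int(row.n_group1),
                n_group2=None if pd.isna(row.n_group2) else int(row.n_group2),
                drug=row.drug,
                drug_class=row.drug_class,
                enzyme=row.enzyme,
                outcome_label=row.outcome_label,
                phenotype=row.phenotype,
                continent=row.continent,
            )

    def select(self, mask: np.ndarray | pd.Series, note: str = "") -> "Corpus":
        sub = self.df.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return Corpus(sub, prov)


@dataclass
class CorpusSummary:
    """Per-level effect/study counts and mean (absolute) SMD for one moderator."""

    by: str
    table: pd.DataFrame  # columns: level, n_effects, n_studies, mean_smd, mean_abs_smd

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _normalise_outcome(value: str) -> str:
    v = str(value).strip().lower()
    if v in OUTCOME_LEVELS:
        return v
    raise ValueError(f"outcome_label {value!r} not mappable to {OUTCOME_LEVELS}")


_PHENOTYPE_ALIASES = {
    "poor": "poor",
    "pm": "poor",
    "intermediate": "intermediate",
    "im": "intermediate",
    "rapid": "rapid",
    "rm": "rapid",
    "ultrarapid": "ultrarapid",
    "ultra-rapid": "ultrarapid",
    "ultra rapid": "ultrarapid",
    "um": "ultrarapid",
}


def _normalise_phenotype(value) -> str:
    if pd.isna(value) or str(value).strip() == "":
        return "unknown"
    return _PHENOTYPE_ALIASES.get(str(value).strip().lower(), "unknown")


def corpus_from_frame(
    df: pd.DataFrame,
    provenance: Iterable[str] = (),
    errors: str = "drop",
) -> Corpus:
    """Validate a raw frame into a Corpus.

    Rows violating record invariants are rejected and listed in the provenance
    (``errors="drop"``, the default) or raise (``errors="raise"``).  A missing
    ``smd_variance`` is derived from the group sizes via the large-sample SMD
    variance formula v = N/(n1*n2) + d^2/(2N).
    """
    df = df.copy()
    mandatory = ["effect_id", "study_id", "smd", "outcome_label"]
    for col in mandatory:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col}")
    if "smd_variance" not in df.columns and not (
        "n_group1" in df.columns and "n_group2" in df.columns
    ):
        raise SchemaError("missing mandatory column: smd_variance (or n_group1+n_group2)")
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col in ("smd_variance", "n_total", "n_group1", "n_group2") else ""

    diagnostics: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    seen_ids: set[str] = set()
    seen_rows: set[tuple] = set()

    smd = pd.to_numeric(df["smd"], errors="coerce")
    var = pd.to_numeric(df["smd_variance"], errors="coerce")
    n1 = pd.to_numeric(df["n_group1"], errors="coerce")
    n2 = pd.to_numeric(df["n_group2"], errors="coerce")
    ntot = pd.to_numeric(df["n_total"], errors="coerce")

    # derive variance / n_total from group sizes where absent
    derivable = var.isna() & n1.notna() & n2.notna() & smd.notna()
    if derivable.any():
        nn = n1[derivable] + n2[derivable]
        var.loc[derivable] = nn / (n1[derivable] * n2[derivable]) + smd[derivable] ** 2 / (2 * nn)
    fill_n = ntot.isna() & n1.notna() & n2.notna()
    ntot.loc[fill_n] = n1[fill_n] + n2[fill_n]

    out_labels = []
    for i in range(len(df)):
        row_problems = []
        if pd.isna(smd.iloc[i]):
            row_problems.append("non-numeric smd")
        if pd.isna(var.iloc[i]) or var.iloc[i] <= 0:
            row_problems.append("non-positive variance")
        try:
            out = _normalise_outcome(df["outcome_label"].iloc[i])
        except ValueError as exc:
            row_problems.append(str(exc))
            out = ""
        out_labels.append(out)
        eid = str(df["effect_id"].iloc[i])
        if eid in seen_ids:
            row_problems.append(f"duplicate effect_id {eid!r}")
        sig = (
            str(df["study_id"].iloc[i]),
            float(smd.iloc[i]) if not pd.isna(smd.iloc[i]) else None,
            float(var.iloc[i]) if not pd.isna(var.iloc[i]) else None,
            out,
        )
        if sig in seen_rows:
            diagnostics.append(f"row {i} ({eid}): exact duplicate effect flagged (retained)")
        seen_rows.add(sig)
        if not str(df["study_id"].iloc[i]).strip():
            row_problems.append("missing study_id")
        if row_problems:
            keep[i] = False
            diagnostics.append(f"row {i} ({eid}): rejected: " + "; ".join(row_problems))
        else:
            seen_ids.add(eid)

    if errors == "raise" and not keep.all():
        raise ValueError("invalid rows:\n" + "\n".join(diagnostics))

    out = pd.DataFrame(
        {
            "effect_id": df["effect_id"].astype(str),
            "study_id": df["study_id"].astype(str),
            "smd": smd,
            "smd_variance": var,
            "n_total": ntot,
            "n_group1": n1,
            "n_group2": n2,
            "drug": df["drug"].fillna("").astype(str),
            "drug_class": df["drug_class"]
            .fillna("")
            .astype(str)
            .str.strip()
            .str.lower()
            .where(lambda s: s.isin(DRUG_CLASS_LEVELS), "unknown/multiple"),
            "enzyme": df["enzyme"].fillna("").astype(str),
            "outcome_label": out_labels,
            "phenotype": [_normalise_phenotype(v) for v in df["phenotype"]],
            "continent": df["continent"].fillna("").astype(str),
        }
    )
    out = out.loc[keep].reset_index(drop=True)
    prov = list(provenance) + diagnostics
    if (~keep).sum():
        prov.append(f"rejected {int((~keep).sum())} invalid rows")
    return Corpus(out, prov)


def read_corpus(path, schema: dict[str, str] | None = None, errors: str = "drop") -> Corpus:
    """Read a corpus CSV (UTF-8, header row, empty string = missing).

    ``schema`` optionally maps canonical column names to the file's column
    names, e.g. ``{"smd": "hedges_g"}``.
    """
    raw = pd.read_csv(path, dtype={"effect_id": str, "study_id": str})
    if schema:
        rename = {}
        for canonical, actual in schema.items():
            if actual not in raw.columns:
                raise SchemaError(f"missing mandatory column: {actual} (mapped to {canonical})")
            rename[actual] = canonical
        raw = raw.rename(columns=rename)
    return corpus_from_frame(raw, provenance=[f"read from {path}"], errors=errors)


def write_corpus(corpus: Corpus, path) -> None:
    corpus.df.to_csv(path, index=False, columns=CANONICAL_COLUMNS)


def filter_extreme(corpus: Corpus, threshold: float = 5.0) -> Corpus:
    """Drop extreme effects: records with |SMD| >= threshold are excluded.

    The boundary itself is excluded (an SMD of exactly ``threshold`` is
    removed); only the strict interior -threshold < SMD < threshold remains.
    Idempotent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mask = corpus.df["smd"].abs() < threshold
    removed = int((~mask).sum())
    return corpus.select(mask, note=f"filter_extreme(threshold={threshold}): removed {removed}")


def summarize(corpus: Corpus, by: str) -> CorpusSummary:
    """Per-level effect counts, study counts and mean (absolute) SMD.

    Levels of controlled-vocabulary moderators that have no records are
    reported with count 0 and NaN means.
    """
    if by not in CANONICAL_COLUMNS or by in ("effect_id", "smd", "smd_variance"):
        valid = [c for c in CANONICAL_COLUMNS if c not in ("effect_id", "smd", "smd_variance")]
        raise ValueError(f"unknown moderator {by!r}; valid choices: {valid}")
    df = corpus.df
    grouped = df.groupby(by, sort=True)
    rows = []
    for level, sub in grouped:
        rows.append(
            {
                "level": level,
                "n_effects": len(sub),
                "n_studies": sub["study_id"].nunique(),
                "mean_smd": sub["smd"].mean(),
                "mean_abs_smd": sub["smd"].abs().mean(),
            }
        )
    present = {r["level"] for r in rows}
    for level in _CONTROLLED.get(by, ()):
        if level not in present:
            rows.append(
                {
                    "level": level,
                    "n_effects": 0,
                    "n_studies": 0,
                    "mean_smd": np.nan,
                    "mean_abs_smd": np.nan,
                }
            )
    table = pd.DataFrame(rows, columns=["level", "n_effects", "n_studies", "mean_smd", "mean_abs_smd"])
    return CorpusSummary(by=by, table=table)
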