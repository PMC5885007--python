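"""Per-individual rare-variant interpretation cascade.

For each individual, carried variants (>= 1 alternative allele) are filtered
first by the reference panel (drop COMMON and LOW_FREQ), then by cohort
frequency (drop FREQUENT among the survivors); the remainder is the
individual's rare set. Rare variants are then joined with predictor calls
(deleterious by at least one program), a ClinVar-like table, and OMIM-style
inheritance, producing carrier/affected interpretations for heterozygous and
homozygous genotypes under AR/AD inheritance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .datatypes import CohortGenotypes

SIGNIFICANCE_MAP = {
    "pathogenic": "pathogenic",
    "likely pathogenic": "likely_pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "benign": "benign",
    "likely benign": "likely_benign",
    "likely_benign": "likely_benign",
    "uncertain significance": "VUS",
    "vus": "VUS",
}

INHERITANCE_LABELS = ("AD", "AR", "UNKNOWN", "n.a.")


def maf_from_counts(
    alt_count: int, n_individuals: int, fold: bool = False
) -> float:
    """Allele frequency alt_count / 2N, optionally folded to <= 0.5."""
    if not 0 <= alt_count <= 2 * n_individuals:
        raise ValueError(
            f"alt_count {alt_count} outside [0, {2 * n_individuals}]"
        )
    f = alt_count / (2 * n_individuals)
    return min(f, 1.0 - f) if fold else f


@dataclass
class CascadeReport:
    sample: str
    total: int
    removed_panel: int  # COMMON or LOW_FREQ in the reference panel
    removed_cohort_frequent: int
    remaining_rare: int
    rare_by_region: dict[str, int]
    rare_known: int  # rare variants present in the dbSNP-like id set

    def conserved(self) -> bool:
        return (
            self.removed_panel + self.removed_cohort_frequent + self.remaining_rare
            == self.total
        )


def rare_filter_cascade(
    cohort: CohortGenotypes,
    classified: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    known_ids: set[str] | None = None,
) -> tuple[list[CascadeReport], dict[str, list[str]]]:
    """Run the two-stage rare-variant filter for every individual.

    ``classified`` is the per-variant table from ``classify_2d`` (indexed by
    key, with ``panel_class`` and ``cohort_class``); every carried variant
    must be classified. Returns per-individual reports and the per-individual
    rare variant keys.
    """
    keys = cohort.keys().to_numpy()
    panel_class = classified["panel_class"]
    cohort_class = classified["cohort_class"]

    reports: list[CascadeReport] = []
    rare_sets: dict[str, list[str]] = {}
    for si, sample in enumerate(cohort.samples):
        carried = keys[cohort.genotypes[si] > 0]
        unknown = [k for k in carried if k not in classified.index]
        if unknown:
            raise ValueError(
                f"{len(unknown)} carried variants lack a classification "
                f"(e.g. {unknown[0]})"
            )
        pc = panel_class.loc[carried]
        cc = cohort_class.loc[carried]
        drop_panel = pc.isin(("COMMON", "LOW_FREQ")).to_numpy()
        drop_freq = (~drop_panel) & (cc == "FREQUENT").to_numpy()
        rare = carried[~drop_panel & ~drop_freq]
        by_region: dict[str, int] = {}
        if regions is not None:
            reg = regions.loc[regions.index.intersection(rare), "region_class"]
            by_region = reg.value_counts().to_dict()
        reports.append(
            CascadeReport(
                sample=sample,
                total=len(carried),
                removed_panel=int(drop_panel.sum()),
                removed_cohort_frequent=int(drop_freq.sum()),
                remaining_rare=len(rare),
                rare_by_region=by_region,
                rare_known=sum(k in (known_ids or set()) for k in rare),
            )
        )
        rare_sets[sample] = list(rare)
    return reports, rare_sets


def pathogenic_consensus(
    predictor_calls: Mapping[str, str]
) -> bool | None:
    """True when at least one predictor calls the variant deleterious;
    None (excluded from pathogenic counts) when every call is missing."""
    seen = [v for v in predictor_calls.values() if v != "missing"]
    if not seen:
        return None
    for v in seen:
        if v not in ("deleterious", "tolerated"):
            raise ValueError(f"unknown predictor call {v!r}")
    return any(v == "deleterious" for v in seen)


@dataclass(frozen=True)
class ClinicalCall:
    key: str
    significance: str  # pathogenic / likely_pathogenic / benign / likely_benign / VUS
    inheritance: str  # AD / AR / UNKNOWN / n.a.
    zygosity: str  # "het" or "hom"

    @property
    def actionable(self) -> bool:
        return self.significance in ("pathogenic", "likely_pathogenic")


def normalize_significance(raw: str) -> str:
    s = SIGNIFICANCE_MAP.get(str(raw).strip().lower())
    if s is None:
        warnings.warn(f"unrecognized clinical significance {raw!r}; using VUS")
        return "VUS"
    return s


def inheritance_flag(call: ClinicalCall) -> str:
    """Phenotype interpretation from inheritance mode and zygosity.

    AR heterozygotes are carriers only; AR homozygotes and any AD genotype
    are expected to show the phenotype; unknown inheritance is uncertain.
    """
    if call.zygosity not in ("het", "hom"):
        raise ValueError(f"zygosity must be 'het' or 'hom', got {call.zygosity!r}")
    if call.inheritance == "AR":
        return "carrier_only" if call.zygosity == "het" else "expected_phenotype"
    if call.inheritance == "AD":
        return "expected_phenotype"
    return "uncertain"


def summarize_individuals(
    reports: Sequence[CascadeReport],
    clinical: Mapping[str, Sequence[ClinicalCall]] | None = None,
) -> pd.DataFrame:
    """Cohort-level summary of the cascade: mean and median per stage, plus
    the number of individuals with zero homozygous pathogenic rare calls."""
    if not reports:
        raise ValueError("need at least one individual report")
    df = pd.DataFrame(
        {
            "total": [r.total for r in reports],
            "removed_panel": [r.removed_panel for r in reports],
            "removed_cohort_frequent": [
                r.removed_cohort_frequent for r in reports
            ],
            "remaining_rare": [r.remaining_rare for r in reports],
            "rare_known": [r.rare_known for r in reports],
        },
        index=[r.sample for r in reports],
    )
    summary = pd.DataFrame(
        {"mean": df.mean(), "median": df.median()}
    )
    if clinical is not None:
        zero_hom = sum(
            not any(
                c.actionable and c.zygosity == "hom" for c in clinical.get(s, ())
            )
            for s in df.index
        )
        summary.attrs["n_without_hom_pathogenic"] = int(zero_hom)
    return summary
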