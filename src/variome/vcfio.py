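"""Standard-format I/O, variant quality filters and region annotation.

VCF is read through cyvcf2 and written as plain VCF 4.2 text (GT only by
default). Internal coordinates are 0-based half-open; VCF positions are
converted at the boundary. Multi-allelic records are split into biallelic
rows keyed by (chrom, pos, ref, alt); per-allele genotypes recode any other
alternative allele as reference.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    MISSING,
    CohortGenotypes,
    GeneModel,
    PanelFrequencies,
)

# Variant quality defaults: sites need 20x depth and a 90% mapping rate;
# indels are dropped when quality < 27 and depth < 6 together, or when
# heterozygous with alternative-allele balance below 0.3.
SNV_MIN_DP = 20
SNV_MIN_MAPPING_RATE = 0.90
INDEL_QUAL_CUTOFF = 27
INDEL_DP_CUTOFF = 6
INDEL_MIN_ALLELE_BALANCE = 0.3


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_cohort_vcf(path: str | Path) -> CohortGenotypes:
    """Read a (multi-)sample VCF into a dosage matrix.

    Multi-allelic records are split into one biallelic row per alternative
    allele; a genotype's dosage for row k counts only allele k, so e.g.
    GT 1/2 contributes dosage 1 to each of the two rows. Missing calls are
    preserved as -1. Positions become 0-based.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosage_cols: list[np.ndarray] = []
    for rec in vcf:
        gts = np.array(rec.genotype.array())[:, :2]  # allele indices, -1 missing
        for ai, alt in enumerate(rec.ALT, start=1):
            missing = (gts < 0).any(axis=1)
            dos = (gts == ai).sum(axis=1).astype(np.int8)
            dos[missing] = MISSING
            rows.append(
                {
                    "chrom": rec.CHROM,
                    "pos": rec.POS - 1,
                    "ref": rec.REF,
                    "alt": alt,
                    "id": rec.ID or ".",
                }
            )
            dosage_cols.append(dos)
    vcf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")
    variants = pd.DataFrame(rows)
    geno = np.stack(dosage_cols, axis=1)
    return CohortGenotypes(samples, variants, geno)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_cohort_vcf(cohort: CohortGenotypes, path: str | Path) -> None:
    """Write genotypes as minimal VCF 4.2 with a GT FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(cohort.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        v = cohort.variants
        ids = v["id"] if "id" in v.columns else ["."] * len(v)
        for j, (chrom, pos, ref, alt, vid) in enumerate(
            zip(v["chrom"], v["pos"], v["ref"], v["alt"], ids)
        ):
            gts = "\t".join(
                _GT_STRINGS[int(g)] for g in cohort.genotypes[:, j]
            )
            fh.write(
                f"{chrom}\t{pos + 1}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Tables and tracks
# ---------------------------------------------------------------------------


def write_panel_tsv(panel: PanelFrequencies, path: str | Path) -> None:
    panel.table.to_csv(path, sep="\t", index=True)


def read_panel_tsv(path: str | Path, populations=None) -> PanelFrequencies:
    table = pd.read_csv(path, sep="\t", index_col="key")
    if populations is None:
        populations = [
            c[3:] for c in table.columns if c.startswith("AF_")
        ]
    return PanelFrequencies(table, populations)


def read_bed(path: str | Path) -> list[tuple]:
    """Read a BED3(+label) track as (chrom, start, end[, label]) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if len(parts) > 3:
                out.append((chrom, start, end, parts[3]))
            else:
                out.append((chrom, start, end))
    return out


def write_bed(intervals, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


# ---------------------------------------------------------------------------
# Quality filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantCallRecord:
    """One per-sample variant call with the QC fields the filters consume."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str
    genotype: str  # "0/0", "0/1", "1/1" or "./."
    dp: int | None = None
    quality: float | None = None
    allele_balance: float | None = None
    mapping_rate: float | None = None

    def __post_init__(self) -> None:
        if self.dp is not None and self.dp < 0:
            raise ValueError("DP must be >= 0")
        if self.allele_balance is not None and not 0 <= self.allele_balance <= 1:
            raise ValueError("allele_balance must be in [0, 1]")


def apply_snv_filters(
    records,
    min_dp: int = SNV_MIN_DP,
    min_mapping_rate: float = SNV_MIN_MAPPING_RATE,
) -> tuple[list[VariantCallRecord], Counter]:
    """Keep SNV calls with DP >= 20 and mapping rate >= 0.90 (inclusive).

    Returns the passing records and a removal log counting, per rule, how
    many records each rule rejected (a record failing both rules counts in
    both) plus ``skipped_missing_fields``.
    """
    passing = []
    log: Counter = Counter()
    for rec in records:
        if rec.dp is None or rec.mapping_rate is None:
            log["skipped_missing_fields"] += 1
            warnings.warn(
                f"record {rec.chrom}:{rec.pos} skipped: missing DP/mapping_rate"
            )
            continue
        fail_dp = rec.dp < min_dp
        fail_map = rec.mapping_rate < min_mapping_rate
        if fail_dp:
            log["low_depth"] += 1
        if fail_map:
            log["low_mapping_rate"] += 1
        if not (fail_dp or fail_map):
            passing.append(rec)
    log["kept"] = len(passing)
    return passing, log


def apply_indel_filters(
    records,
    qual_cutoff: float = INDEL_QUAL_CUTOFF,
    dp_cutoff: int = INDEL_DP_CUTOFF,
    min_allele_balance: float = INDEL_MIN_ALLELE_BALANCE,
) -> tuple[list[VariantCallRecord], Counter]:
    """Drop indels with (quality < 27 AND DP < 6), and heterozygous indels
    with allele balance < 0.3. The first rule is a conjunction: a low-quality
    call at adequate depth survives it."""
    passing = []
    log: Counter = Counter()
    for rec in records:
        if rec.dp is None or rec.quality is None:
            log["skipped_missing_fields"] += 1
            warnings.warn(
                f"record {rec.chrom}:{rec.pos} skipped: missing DP/quality"
            )
            continue
        fail_lowq = rec.quality < qual_cutoff and rec.dp < dp_cutoff
        fail_ab = (
            rec.genotype == "0/1"
            and rec.allele_balance is not None
            and rec.allele_balance < min_allele_balance
        )
        if fail_lowq:
            log["low_quality_low_depth"] += 1
        if fail_ab:
            log["het_low_allele_balance"] += 1
        if not (fail_lowq or fail_ab):
            passing.append(rec)
    log["kept"] = len(passing)
    return passing, log


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------


def annotate_region(
    chrom: str, pos: int, model: GeneModel, key: str | None = None
) -> tuple[str, str | None]:
    """Region class for a position, plus the coding effect when relevant.

    A chromosome absent from the model yields intergenic with a warning.
    The coding effect is looked up from the model's per-variant mapping and
    reported only for coding/splice_site positions.
    """
    if chrom not in model.chromosomes():
        warnings.warn(f"chromosome {chrom!r} absent from gene model")
        return "intergenic", None
    region = model.region_at(chrom, pos)
    effect = None
    if region in ("coding", "splice_site") and key is not None:
        effect = model.coding_effects.get(key)
    return region, effect


def annotate_cohort_regions(
    cohort: CohortGenotypes, model: GeneModel
) -> pd.DataFrame:
    """Vectorized region/effect annotation for every cohort variant."""
    keys = cohort.keys()
    chroms_known = model.chromosomes()
    regions, effects = [], []
    for key, chrom, pos in zip(keys, cohort.variants["chrom"], cohort.variants["pos"]):
        if chrom not in chroms_known:
            regions.append("intergenic")
            effects.append(None)
            continue
        region = model.region_at(chrom, int(pos))
        regions.append(region)
        effects.append(
            model.coding_effects.get(key)
            if region in ("coding", "splice_site")
            else None
        )
    return pd.DataFrame(
        {"key": keys, "region_class": regions, "coding_effect": effects}
    ).set_index("key")
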