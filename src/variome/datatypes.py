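"""Core in-memory containers shared by all pipeline stages.

Conventions
-----------
* Genomic coordinates are 0-based, half-open everywhere inside the package;
  VCF positions are converted at I/O.
* Diploid genotypes are stored as alternative-allele dosages: 0 (hom-ref),
  1 (het), 2 (hom-alt), with -1 marking a missing call.
* A variant is keyed by the string ``"{chrom}:{pos}:{ref}:{alt}"`` (0-based
  position), which makes multi-allelic sites distinct rows after splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

MISSING = -1

DEFAULT_POPULATIONS = ("AFR", "EUR", "AMR", "SAS", "EAS")

#: Region classes ordered from least to most functionally specific; the last
#: matching class wins when annotations overlap.
REGION_PRECEDENCE = ("intergenic", "intron", "UTR", "coding", "splice_site")

CODING_EFFECTS = (
    "synonymous",
    "non_synonymous",
    "frame_shift",
    "stop_gain",
    "splice_site",
    "none",
)

SV_TYPES = ("INV", "ITX", "INS", "DEL", "DUP", "CNV_DEL", "CNV_DUP")


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def classify_vtype(ref: str, alt: str) -> str:
    """SNV / INS / DEL from allele strings; indels must be shorter than 100 bp."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    delta = abs(len(ref) - len(alt))
    if delta < 1 or delta >= 100:
        raise ValueError(
            f"indel length {delta} outside the supported 1-99 bp range "
            f"({ref}>{alt})"
        )
    return "INS" if len(alt) > len(ref) else "DEL"


class CohortGenotypes:
    """Samples x variant-sites dosage matrix with site metadata.

    Parameters
    ----------
    samples : sequence of sample identifiers
    variants : DataFrame with columns ``chrom, pos, ref, alt`` (``pos``
        0-based) and optionally ``id`` and ``vtype``; one row per biallelic
        variant.
    genotypes : int array of shape (n_samples, n_variants) holding dosages
        0/1/2 or -1 for missing.
    """

    def __init__(
        self,
        samples: Sequence[str],
        variants: pd.DataFrame,
        genotypes: np.ndarray,
    ) -> None:
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.shape != (len(samples), len(variants)):
            raise ValueError(
                f"genotype matrix shape {genotypes.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        bad = ~np.isin(genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype dosages must be 0, 1, 2 or -1 (missing)")
        variants = variants.reset_index(drop=True).copy()
        if "vtype" not in variants.columns:
            variants["vtype"] = [
                classify_vtype(r, a)
                for r, a in zip(variants["ref"], variants["alt"])
            ]
        self.samples = list(samples)
        self.variants = variants
        self.genotypes = genotypes

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def keys(self) -> pd.Series:
        v = self.variants
        return (
            v["chrom"].astype(str)
            + ":"
            + v["pos"].astype(str)
            + ":"
            + v["ref"]
            + ":"
            + v["alt"]
        )

    # -- summaries ------------------------------------------------------
    def alt_allele_counts(self) -> np.ndarray:
        """Alternative-allele count per site over called genotypes."""
        g = self.genotypes
        return np.where(g == MISSING, 0, g).sum(axis=0)

    def called_chromosomes(self) -> np.ndarray:
        """Number of called chromosomes (2 x called genotypes) per site."""
        return 2 * (self.genotypes != MISSING).sum(axis=0)

    def dosages(self, missing_as_ref: bool = True) -> np.ndarray:
        """Dosage matrix with missing calls optionally recoded as hom-ref."""
        g = self.genotypes.astype(np.int8)
        if missing_as_ref:
            g = np.where(g == MISSING, 0, g)
        return g

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def subset_samples(self, samples: Sequence[str]) -> "CohortGenotypes":
        idx = [self.sample_index(s) for s in samples]
        return CohortGenotypes(list(samples), self.variants, self.genotypes[idx])


class PanelFrequencies:
    """Per-variant allele counts/frequencies for a set of reference groups.

    Wraps a DataFrame indexed by variant key with per-group columns
    ``AF_<group>``, ``AC_<group>``, ``AN_<group>``.
    """

    def __init__(self, table: pd.DataFrame, populations: Sequence[str] = DEFAULT_POPULATIONS):
        self.populations = list(populations)
        for pop in self.populations:
            for col in (f"AF_{pop}", f"AN_{pop}"):
                if col not in table.columns:
                    raise ValueError(f"panel table missing column {col}")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, key: str) -> bool:
        return key in self.table.index

    def mafs(self, key: str) -> dict[str, float]:
        """Folded minor-allele frequency per group; {} when absent."""
        if key not in self.table.index:
            return {}
        row = self.table.loc[key]
        out = {}
        for pop in self.populations:
            af = float(row[f"AF_{pop}"])
            out[pop] = min(af, 1.0 - af)
        return out

    def allele_counts(self, key: str) -> dict[str, tuple[int, int]]:
        """(alt allele count, total allele number) per group; {} when absent."""
        if key not in self.table.index:
            return {}
        row = self.table.loc[key]
        out = {}
        for pop in self.populations:
            an = int(row[f"AN_{pop}"])
            ac_col = f"AC_{pop}"
            if ac_col in self.table.columns:
                ac = int(row[ac_col])
            else:
                ac = int(round(float(row[f"AF_{pop}"]) * an))
            out[pop] = (ac, an)
        return out


@dataclass(frozen=True)
class IntervalCall:
    """A typed genomic interval call (SV or CNV) from one sample."""

    chrom: str
    start: int
    end: int
    svtype: str
    sample: str
    copy_number: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.svtype.startswith("CNV_") and self.copy_number is None:
            raise ValueError(f"{self.svtype} call requires copy_number")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class UnifiedCluster:
    """Reciprocal-overlap cluster of calls with averaged coordinates."""

    chrom: str
    start: int
    end: int
    svtype: str
    members: tuple[IntervalCall, ...]
    carrier_count: int
    novel: bool | None = None
    repeat_composition: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


class GeneModel:
    """Region-class annotation: labelled half-open intervals per chromosome.

    Overlapping annotations are resolved by fixed precedence
    (splice_site > coding > UTR > intron > intergenic); positions outside any
    interval are intergenic. A per-variant coding-effect mapping (variant key
    -> effect) rides along, as effect prediction is consumed, not computed.
    """

    def __init__(
        self,
        intervals: Iterable[tuple[str, int, int, str]],
        coding_effects: Mapping[str, str] | None = None,
    ) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self.intervals = []
        for chrom, start, end, region in intervals:
            if region not in REGION_PRECEDENCE:
                raise ValueError(f"unknown region class {region!r}")
            if end <= start or start < 0:
                raise ValueError(f"bad interval [{start}, {end})")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, region)
            self.intervals.append((chrom, start, end, region))
        self.coding_effects = dict(coding_effects or {})
        for eff in self.coding_effects.values():
            if eff not in CODING_EFFECTS:
                raise ValueError(f"unknown coding effect {eff!r}")

    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def region_at(self, chrom: str, pos: int) -> str:
        tree = self._trees.get(chrom)
        if tree is None:
            return "intergenic"
        hits = {iv.data for iv in tree.at(pos)}
        if not hits:
            return "intergenic"
        # highest-precedence class wins
        return max(hits, key=REGION_PRECEDENCE.index)


@dataclass
class KnownSets:
    """Membership databases consulted during annotation and prioritization."""

    dbsnp_ids: set[str] = field(default_factory=set)
    panel: PanelFrequencies | None = None
    clinvar: pd.DataFrame | None = None  # index: variant id or key
    dgv_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
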