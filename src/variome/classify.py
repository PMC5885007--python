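"""Two-dimensional frequency classification, rare-variant ratios and the
novel-allele accumulation curve.

A variant is classified jointly by its reference-panel frequency profile and
its cohort allele count:

* panel axis — COMMON when the folded MAF is >= 5% in all continental
  groups; LOW_FREQ when MAF >= 0.1% in at least one group; RARE when MAF is
  below 0.1% everywhere; ABSENT when the variant is not in the panel at all.
* cohort axis — FREQUENT when the cohort carries the alternative allele at
  least three times (on 2N chromosomes), RARE otherwise.

The rare-variant ratio (RVR) for a genomic region class is the number of
cohort-rare variants divided by the number of cohort-frequent variants in
that class; elevated RVR in coding sequence is the signature of purifying
selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import CohortGenotypes, PanelFrequencies

PANEL_CLASSES = ("COMMON", "LOW_FREQ", "RARE", "ABSENT")
COHORT_CLASSES = ("FREQUENT", "RARE")

COMMON_MAF = 0.05
LOW_MAF = 0.001
COHORT_FREQUENT_MIN_COUNT = 3


def classify_panel_frequency(
    mafs: Mapping[str, float],
    common_maf: float = COMMON_MAF,
    low_maf: float = LOW_MAF,
) -> str:
    """Panel-side class from per-group folded MAFs; {} means ABSENT."""
    if not mafs:
        return "ABSENT"
    values = list(mafs.values())
    for v in values:
        if not 0.0 <= v <= 0.5:
            raise ValueError(f"folded MAF must be in [0, 0.5], got {v}")
    if all(v >= common_maf for v in values):
        return "COMMON"
    if any(v >= low_maf for v in values):
        return "LOW_FREQ"
    return "RARE"


def classify_cohort_frequency(
    alt_allele_count: int, threshold: int = COHORT_FREQUENT_MIN_COUNT
) -> str:
    """FREQUENT when the alternative allele is seen >= 3 times, else RARE."""
    if alt_allele_count < 1:
        raise ValueError("an unobserved variant has no cohort class")
    return "FREQUENT" if alt_allele_count >= threshold else "RARE"


@dataclass(frozen=True)
class FrequencyClass2D:
    key: str
    panel_class: str
    cohort_class: str
    cohort_count: int
    mafs: dict[str, float]


def classify_2d(
    cohort: CohortGenotypes,
    panel: PanelFrequencies,
    common_maf: float = COMMON_MAF,
    low_maf: float = LOW_MAF,
    cohort_threshold: int = COHORT_FREQUENT_MIN_COUNT,
    count_carriers: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Joint classification of every cohort variant observed at least once.

    Returns (per-variant table, 2-D contingency summary). ``count_carriers``
    switches the cohort axis from alternative-allele counts to carrier
    (individual) counts. Variants with zero observed alternative alleles are
    left out: they have no cohort class.
    """
    keys = cohort.keys().to_numpy()
    if count_carriers:
        counts = (cohort.genotypes > 0).sum(axis=0)
    else:
        counts = cohort.alt_allele_counts()

    rows = []
    for key, count in zip(keys, counts):
        if count < 1:
            continue
        mafs = panel.mafs(key)
        rows.append(
            {
                "key": key,
                "panel_class": classify_panel_frequency(mafs, common_maf, low_maf),
                "cohort_class": classify_cohort_frequency(
                    int(count), cohort_threshold
                ),
                "cohort_count": int(count),
            }
        )
    per_variant = pd.DataFrame(
        rows, columns=["key", "panel_class", "cohort_class", "cohort_count"]
    ).set_index("key")

    summary = (
        per_variant.groupby(["panel_class", "cohort_class"], observed=False)
        .size()
        .reindex(
            pd.MultiIndex.from_product(
                [PANEL_CLASSES, COHORT_CLASSES],
                names=["panel_class", "cohort_class"],
            ),
            fill_value=0,
        )
        .rename("n_variants")
        .reset_index()
    )
    return per_variant, summary


@dataclass(frozen=True)
class RvrResult:
    region_class: str
    n_rare: int
    n_frequent: int
    rvr: float | None  # None when no frequent variants exist

    @property
    def defined(self) -> bool:
        return self.rvr is not None


def compute_rvr(
    classified: pd.DataFrame,
    regions: pd.DataFrame,
    by_effect: bool = False,
) -> list[RvrResult]:
    """Rare/frequent ratio per region class (or per coding effect).

    ``classified`` is the per-variant table from :func:`classify_2d`;
    ``regions`` carries ``region_class`` (and ``coding_effect``) indexed by
    variant key. With ``by_effect`` the grouping key becomes the coding
    effect for coding variants (e.g. ``coding:non_synonymous``).
    """
    joined = classified.join(regions, how="inner")
    if by_effect:
        group = np.where(
            joined["coding_effect"].notna(),
            joined["region_class"].astype(str)
            + ":"
            + joined["coding_effect"].astype(str),
            joined["region_class"],
        )
    else:
        group = joined["region_class"]
    out = []
    for cls, sub in joined.groupby(group):
        n_rare = int((sub["cohort_class"] == "RARE").sum())
        n_freq = int((sub["cohort_class"] == "FREQUENT").sum())
        rvr = n_rare / n_freq if n_freq > 0 else None
        out.append(RvrResult(str(cls), n_rare, n_freq, rvr))
    return out


def accumulation_curve(
    cohort: CohortGenotypes,
    known: Iterable[str] = (),
    order: Sequence[str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Novel alternative alleles added by each successive sample.

    A (site, alt) pair is novel for sample i when sample i carries the
    alternative allele and the key is neither in ``known`` nor carried by
    any earlier sample. ``order`` fixes the sample order explicitly; ``seed``
    instead draws a random permutation. The curve total equals the size of
    the union of novel alleles regardless of order.
    """
    if order is not None and seed is not None:
        raise ValueError("give either an explicit order or a seed, not both")
    samples = list(cohort.samples)
    if order is None:
        if seed is not None:
            rng = np.random.default_rng(seed)
            samples = [samples[i] for i in rng.permutation(len(samples))]
    else:
        samples = list(order)

    known_set = set(known)
    keys = cohort.keys().to_numpy()
    seen: set[str] = set()
    rows = []
    for i, sample in enumerate(samples, start=1):
        si = cohort.sample_index(sample)
        carried = keys[cohort.genotypes[si] > 0]
        novel = [k for k in carried if k not in known_set and k not in seen]
        seen.update(novel)
        rows.append({"rank": i, "sample": sample, "novel_alleles": len(novel)})
    return pd.DataFrame(rows)
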