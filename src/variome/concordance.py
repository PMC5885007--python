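"""Precision/recall and genotype concordance against array genotypes.

Site presence is defined as carrying at least one alternative allele; the
confusion counts compare presence between sequencing calls and the array
over the shared (site, sample) grid. Genotype concordance is the fraction of
exactly matching diploid genotypes, per sample or per locus, with missing
genotypes on either side excluded from numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CohortGenotypes


@dataclass(frozen=True)
class ConcordanceReport:
    TP: int
    FP: int
    FN: int

    @property
    def precision(self) -> float | None:
        denom = self.TP + self.FP
        return self.TP / denom if denom else None

    @property
    def recall(self) -> float | None:
        denom = self.TP + self.FN
        return self.TP / denom if denom else None


def _align(calls: CohortGenotypes, array: CohortGenotypes):
    """Shared samples and variant keys, as aligned dosage matrices."""
    samples = [s for s in calls.samples if s in set(array.samples)]
    call_keys = calls.keys()
    array_keys = array.keys()
    shared = call_keys[call_keys.isin(set(array_keys))]
    if len(shared) == 0 or not samples:
        raise ValueError("no shared (site, sample) grid to compare")
    ci = pd.Index(call_keys)
    ai = pd.Index(array_keys)
    c_idx = ci.get_indexer(shared)
    a_idx = ai.get_indexer(shared)
    c_rows = [calls.sample_index(s) for s in samples]
    a_rows = [array.sample_index(s) for s in samples]
    g_call = calls.genotypes[np.ix_(c_rows, c_idx)]
    g_arr = array.genotypes[np.ix_(a_rows, a_idx)]
    return samples, list(shared), g_call, g_arr


def site_presence_confusion(
    calls: CohortGenotypes, array: CohortGenotypes
) -> ConcordanceReport:
    """TP/FP/FN of alternative-allele presence on the shared grid.

    Missing genotypes count as absence on the side where they occur, since
    the assay made no positive claim there.
    """
    _, _, g_call, g_arr = _align(calls, array)
    present_call = g_call > 0
    present_arr = g_arr > 0
    tp = int((present_call & present_arr).sum())
    fp = int((present_call & ~present_arr).sum())
    fn = int((~present_call & present_arr).sum())
    return ConcordanceReport(tp, fp, fn)


def genotype_concordance(
    calls: CohortGenotypes,
    array: CohortGenotypes,
    level: str = "sample",
    threshold: float = 0.99,
) -> pd.DataFrame:
    """Exact-genotype concordance per sample or per locus.

    Returns a table with columns ``n_compared``, ``n_match``, ``concordance``
    (NaN when nothing is comparable) indexed by sample or by locus key; the
    per-locus table's attrs carry ``n_above_threshold``, the count of loci
    whose concordance exceeds ``threshold``.
    """
    if level not in ("sample", "locus"):
        raise ValueError(f"unknown level {level!r}")
    samples, shared, g_call, g_arr = _align(calls, array)
    comparable = (g_call >= 0) & (g_arr >= 0)
    match = comparable & (g_call == g_arr)
    axis = 1 if level == "sample" else 0
    n_comp = comparable.sum(axis=axis)
    n_match = match.sum(axis=axis)
    with np.errstate(invalid="ignore"):
        conc = np.where(n_comp > 0, n_match / np.maximum(n_comp, 1), np.nan)
    index = samples if level == "sample" else shared
    out = pd.DataFrame(
        {"n_compared": n_comp, "n_match": n_match, "concordance": conc},
        index=index,
    )
    if level == "locus":
        defined = out["concordance"].notna()
        out.attrs["n_above_threshold"] = int(
            (out.loc[defined, "concordance"] > threshold).sum()
        )
        out.attrs["n_defined"] = int(defined.sum())
    return out


def overall_concordance(per_locus: pd.DataFrame) -> float | None:
    """Weighted mean of per-locus concordances = overall genotype
    concordance (weights = comparable genotypes per locus)."""
    n = per_locus["n_compared"].sum()
    if n == 0:
        return None
    return float(per_locus["n_match"].sum() / n)
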