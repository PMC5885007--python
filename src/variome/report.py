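"""Cohort-level summary tables mirroring standard variome reporting."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CohortGenotypes, KnownSets


def percentage(numerator: float, denominator: float) -> float:
    """100 * numerator / denominator rounded to two decimals (report style)."""
    if denominator == 0:
        return 0.0
    return round(100.0 * numerator / denominator, 2)


def report_cohort_summary(
    cohort: CohortGenotypes, known: KnownSets
) -> pd.DataFrame:
    """Totals, known-set membership with percentages, per-sample averages.

    Rows are split by variant type (SNV vs indel). Percentages are reported
    to two decimals; underlying counts stay exact.
    """
    keys = cohort.keys().to_numpy()
    observed = cohort.alt_allele_counts() > 0
    vtypes = cohort.variants["vtype"].to_numpy()
    is_snv = vtypes == "SNV"

    ids = (
        cohort.variants["id"].to_numpy()
        if "id" in cohort.variants.columns
        else np.array(["."] * len(keys))
    )
    in_dbsnp = np.array(
        [
            (k in known.dbsnp_ids) or (i in known.dbsnp_ids)
            for k, i in zip(keys, ids)
        ]
    )
    in_panel = (
        np.array([k in known.panel for k in keys])
        if known.panel is not None
        else np.zeros(len(keys), dtype=bool)
    )
    carried_per_sample = (cohort.genotypes > 0).sum(axis=1)

    rows = []
    for label, mask in (("SNV", is_snv), ("indel", ~is_snv)):
        m = mask & observed
        total = int(m.sum())
        n_panel = int((m & in_panel).sum())
        n_dbsnp = int((m & in_dbsnp).sum())
        per_sample = float(
            ((cohort.genotypes > 0) & m[None, :]).sum(axis=1).mean()
        )
        rows.append(
            {
                "variant_type": label,
                "total": total,
                "known_in_panel": n_panel,
                "pct_known_in_panel": percentage(n_panel, total),
                "known_in_dbsnp": n_dbsnp,
                "pct_known_in_dbsnp": percentage(n_dbsnp, total),
                "novel": total - n_dbsnp,
                "avg_per_sample": round(per_sample, 2),
            }
        )
    out = pd.DataFrame(rows).set_index("variant_type")
    out.attrs["n_samples"] = cohort.n_samples
    out.attrs["avg_carried_per_sample"] = float(carried_per_sample.mean())
    return out
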