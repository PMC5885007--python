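"""Fisher's-exact allele enrichment across population groups.

Each variant is tested group-by-group: the group's alternative/reference
chromosome counts against the pooled counts of every other group (the cohort
itself participates as group ``KOR``). A group is called enriched when the
sample odds ratio exceeds 3 and the two-sided exact p-value is below 0.05;
the Venn partition then counts, for each non-empty subset of groups, the
variants enriched in exactly that subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

OR_THRESHOLD = 3.0
P_THRESHOLD = 0.05

#: relative slack when comparing table probabilities in the two-sided sum,
#: matching the usual implementation of Fisher's test
_P_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) = group-1 alt/ref chromosomes, (c, d) = group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    enriched: bool


def odds_ratio(table: ContingencyTable2x2) -> float:
    """Sample odds ratio (a*d)/(b*c), Haldane-corrected (+0.5 on every cell)
    when any cell is zero."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


@lru_cache(maxsize=200_000)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric outcomes no more likely
    than the observed table, at fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1.0 + _P_REL_TOL)].sum())
    return min(p, 1.0)


def fisher_exact(
    table: ContingencyTable2x2,
    or_threshold: float = OR_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> EnrichmentResult:
    """Two-sided Fisher's exact test plus the enrichment verdict.

    Both row margins must be positive (each group must contribute
    chromosomes); zero column margins are legal and give p = 1.
    """
    r1, r2, _, _ = table.margins
    if r1 == 0 or r2 == 0:
        raise ValueError("both groups need a positive chromosome total")
    p = _fisher_p(table.a, table.b, table.c, table.d)
    orr = odds_ratio(table)
    return EnrichmentResult(orr, p, orr > or_threshold and p < p_threshold)


def variant_enrichment(
    cohort_counts: pd.DataFrame,
    panel_counts: Mapping[str, pd.DataFrame],
    or_threshold: float = OR_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    comparison: str = "pooled",
) -> pd.DataFrame:
    """Per-variant, per-group enrichment flags.

    Parameters
    ----------
    cohort_counts : DataFrame indexed by variant key with columns
        ``alt`` and ``total`` (cohort chromosomes).
    panel_counts : mapping group label -> DataFrame indexed by variant key
        with columns ``alt`` and ``total``.
    comparison : ``"pooled"`` tests each group against the pooled remaining
        groups; ``"vs_cohort"`` tests each panel group pairwise against the
        cohort (and the cohort against the pooled panel).

    A variant missing from the panel is tested for the cohort group only,
    with the panel side taken as the pooled panel totals and zero
    alternative alleles.

    Returns a boolean DataFrame (variants x groups) of enriched flags with
    group columns ordered ``KOR`` first.
    """
    if comparison not in ("pooled", "vs_cohort"):
        raise ValueError(f"unknown comparison mode {comparison!r}")
    groups = ["KOR", *panel_counts.keys()]
    pooled_total = {
        g: int(df["total"].iloc[0]) if len(df) else 0
        for g, df in panel_counts.items()
    }

    flags = pd.DataFrame(
        False, index=cohort_counts.index, columns=groups, dtype=bool
    )
    for key, row in cohort_counts.iterrows():
        counts: dict[str, tuple[int, int]] = {
            "KOR": (int(row["alt"]), int(row["total"]))
        }
        in_panel = True
        for g, df in panel_counts.items():
            if key in df.index:
                counts[g] = (int(df.at[key, "alt"]), int(df.at[key, "total"]))
            else:
                in_panel = False
        if not in_panel:
            # cohort-only test against an all-reference pooled panel
            alt_rest = 0
            tot_rest = sum(pooled_total.values())
            if tot_rest > 0:
                a, t = counts["KOR"]
                res = fisher_exact(
                    ContingencyTable2x2(a, t - a, alt_rest, tot_rest - alt_rest),
                    or_threshold,
                    p_threshold,
                )
                flags.at[key, "KOR"] = res.enriched
            continue
        for g in groups:
            a, t = counts[g]
            if comparison == "pooled" or g == "KOR":
                others = [counts[h] for h in groups if h != g]
            else:
                others = [counts["KOR"]]
            alt_rest = sum(x for x, _ in others)
            tot_rest = sum(x for _, x in others)
            if t == 0 or tot_rest == 0:
                continue
            res = fisher_exact(
                ContingencyTable2x2(a, t - a, alt_rest, tot_rest - alt_rest),
                or_threshold,
                p_threshold,
            )
            flags.at[key, g] = res.enriched
    return flags


def venn_partition(flags: pd.DataFrame) -> pd.Series:
    """Counts per non-empty group subset; every flagged variant lands in
    exactly one cell (the subset of groups it is enriched in)."""
    flagged = flags[flags.any(axis=1)]
    subsets = flagged.apply(
        lambda row: frozenset(flags.columns[row.to_numpy(dtype=bool)]), axis=1
    )
    if len(subsets) == 0:
        return pd.Series(dtype=int)
    return subsets.value_counts().rename("n_variants")


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; the default pipeline uses raw p)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
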