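"""Spurious-call filtering, reciprocal-overlap clustering and unification of
SV/CNV interval calls, plus novelty annotation, repeat composition and CNV
carrier enrichment.

Calls overlapping unassembled reference blocks ('N' gaps) are removed when
any of three rules fires: reciprocal overlap above 10% with a single gap,
more than half the call covered by gaps in total, or more than two distinct
gap blocks intersected. Surviving calls are clustered per (chromosome, type)
by single-linkage on reciprocal overlap above 70%, and each cluster is
unified to the rounded mean of member starts and ends.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

import math

import pandas as pd
from intervaltree import IntervalTree

from .datatypes import IntervalCall, UnifiedCluster
from .enrich import ContingencyTable2x2, fisher_exact

RO_CLUSTER_THRESHOLD = 0.7
GAP_RO_THRESHOLD = 0.10
GAP_COVERAGE_THRESHOLD = 0.50
GAP_BLOCK_LIMIT = 2
MIN_CALL_LENGTH = 100

CNV_OR_THRESHOLD = 10.0
CNV_P_THRESHOLD = 0.01
CNV_MIN_CARRIERS = 5  # strictly more than five carriers required

REPEAT_CLASSES = ("SINE", "LINE", "LTR", "DNA", "simple", "none")


def reciprocal_overlap(
    a: tuple[str, int, int], b: tuple[str, int, int]
) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when disjoint or on different
    chromosomes (by contract, not an error)."""
    if a[0] != b[0]:
        return 0.0
    ov = min(a[2], b[2]) - max(a[1], b[1])
    if ov <= 0:
        return 0.0
    return min(ov / (a[2] - a[1]), ov / (b[2] - b[1]))


def _gap_trees(
    gaps: Iterable[tuple[str, int, int]]
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in gaps:
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    return trees


def _union_coverage(intervals: list[tuple[int, int]]) -> int:
    covered = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s >= last_end:
            covered += e - s
            last_end = e
        elif e > last_end:
            covered += e - last_end
            last_end = e
    return covered


def filter_spurious(
    calls: Sequence[IntervalCall],
    gaps: Iterable[tuple[str, int, int]],
    gap_ro: float = GAP_RO_THRESHOLD,
    gap_coverage: float = GAP_COVERAGE_THRESHOLD,
    gap_blocks: int = GAP_BLOCK_LIMIT,
) -> tuple[list[IntervalCall], pd.DataFrame]:
    """Remove calls colliding with assembly gaps; log which rule fired.

    Removal when ANY of: (i) reciprocal overlap > ``gap_ro`` with a single
    gap; (ii) union gap coverage of the call > ``gap_coverage``; (iii) number
    of distinct gap blocks intersected > ``gap_blocks``. Idempotent, and
    adding gaps can only remove more calls.
    """
    trees = _gap_trees(gaps)
    passing = []
    rows = []
    for call in calls:
        tree = trees.get(call.chrom)
        hits = sorted(tree.overlap(call.start, call.end)) if tree else []
        pieces = [
            (max(call.start, iv.begin), min(call.end, iv.end)) for iv in hits
        ]
        rule_ro = any(
            reciprocal_overlap(
                (call.chrom, call.start, call.end),
                (call.chrom, iv.begin, iv.end),
            )
            > gap_ro
            for iv in hits
        )
        rule_cov = (
            _union_coverage(pieces) / call.length > gap_coverage
            if pieces
            else False
        )
        rule_blocks = len(hits) > gap_blocks
        removed = rule_ro or rule_cov or rule_blocks
        if removed:
            rows.append(
                {
                    "chrom": call.chrom,
                    "start": call.start,
                    "end": call.end,
                    "sample": call.sample,
                    "svtype": call.svtype,
                    "rule_gap_ro": rule_ro,
                    "rule_gap_coverage": rule_cov,
                    "rule_gap_blocks": rule_blocks,
                }
            )
        else:
            passing.append(call)
    log = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "sample",
            "svtype",
            "rule_gap_ro",
            "rule_gap_coverage",
            "rule_gap_blocks",
        ],
    )
    return passing, log


class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_calls(
    calls: Sequence[IntervalCall],
    threshold: float = RO_CLUSTER_THRESHOLD,
    inclusive: bool = False,
) -> list[list[IntervalCall]]:
    """Single-linkage clusters of calls by reciprocal overlap.

    Calls are partitioned by (chromosome, svtype) first; within a partition,
    two calls are linked when their reciprocal overlap exceeds ``threshold``
    (or meets it, with ``inclusive=True``, matching the >=70% convention
    used for CNV merging). Connected components are returned sorted by
    (chrom, svtype, start), independent of input order.
    """
    by_part: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, call in enumerate(calls):
        by_part[(call.chrom, call.svtype)].append(i)

    dsu = _DSU(len(calls))
    for idxs in by_part.values():
        idxs = sorted(idxs, key=lambda i: (calls[i].start, calls[i].end))
        # sweep: only pairs whose spans can still overlap
        for ii, i in enumerate(idxs):
            for j in idxs[ii + 1 :]:
                if calls[j].start >= calls[i].end:
                    break
                ro = reciprocal_overlap(
                    (calls[i].chrom, calls[i].start, calls[i].end),
                    (calls[j].chrom, calls[j].start, calls[j].end),
                )
                if ro >= threshold if inclusive else ro > threshold:
                    dsu.union(i, j)

    groups: dict[int, list[IntervalCall]] = defaultdict(list)
    for i, call in enumerate(calls):
        groups[dsu.find(i)].append(call)
    clusters = [
        sorted(g, key=lambda c: (c.start, c.end, c.sample))
        for g in groups.values()
    ]
    clusters.sort(key=lambda g: (g[0].chrom, g[0].svtype, g[0].start, g[0].end))
    return clusters


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def unify_cluster(cluster: Sequence[IntervalCall]) -> UnifiedCluster:
    """Average member starts/ends (rounded half away from zero) and count
    distinct carrier samples."""
    if not cluster:
        raise ValueError("cannot unify an empty cluster")
    chroms = {c.chrom for c in cluster}
    types = {c.svtype for c in cluster}
    if len(chroms) > 1 or len(types) > 1:
        raise ValueError("cluster members must share chromosome and svtype")
    start = _round_half_away(sum(c.start for c in cluster) / len(cluster))
    end = _round_half_away(sum(c.end for c in cluster) / len(cluster))
    return UnifiedCluster(
        chrom=cluster[0].chrom,
        start=start,
        end=end,
        svtype=cluster[0].svtype,
        members=tuple(cluster),
        carrier_count=len({c.sample for c in cluster}),
    )


#: DGV-style databases record CNVs as loss/gain; map call types accordingly
_TYPE_COMPAT = {
    "DEL": {"DEL", "CNV_DEL"},
    "CNV_DEL": {"DEL", "CNV_DEL"},
    "DUP": {"DUP", "CNV_DUP"},
    "CNV_DUP": {"DUP", "CNV_DUP"},
    "INS": {"INS"},
    "INV": {"INV"},
    "ITX": {"ITX"},
}


def annotate_novelty(
    unified: UnifiedCluster,
    db: Iterable[tuple[str, int, int, str]],
    threshold: float = 0.70,
) -> bool:
    """True (novel) unless some database interval of compatible type
    reciprocally overlaps the unified interval by >= ``threshold``."""
    compat = _TYPE_COMPAT.get(unified.svtype, {unified.svtype})
    me = (unified.chrom, unified.start, unified.end)
    for chrom, s, e, svtype in db:
        if svtype in compat and reciprocal_overlap(me, (chrom, s, e)) >= threshold:
            unified.novel = False
            return False
    unified.novel = True
    return True


def repeat_composition(
    unified: Sequence[UnifiedCluster],
    repeats: Sequence[tuple[str, int, int, str]],
    length_bins: Sequence[int],
) -> pd.DataFrame:
    """Per length-bin, per repeat-class covered base fraction.

    ``length_bins`` are ascending edges; intervals fall into bins
    [edge_i, edge_{i+1}). Overlapping repeat annotations are resolved by
    input order precedence: bases already claimed by an earlier annotation
    are not re-counted. Fractions are (claimed bases of that class) /
    (total unified bases in the bin), so with non-overlapping tracks the
    class fractions in one bin sum to <= 1.
    """
    for *_, cls in repeats:
        if cls not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {cls!r}")
    edges = list(length_bins)
    if edges != sorted(edges) or len(edges) < 2:
        raise ValueError("length_bins must be ascending with >= 2 edges")
    labels = [f"[{a},{b})" for a, b in zip(edges, edges[1:])]

    total = {lab: 0 for lab in labels}
    covered: dict[tuple[str, str], int] = Counter()
    for uc in unified:
        bin_lab = None
        for lab, lo, hi in zip(labels, edges, edges[1:]):
            if lo <= uc.length < hi:
                bin_lab = lab
                break
        if bin_lab is None:
            continue
        total[bin_lab] += uc.length
        claimed: list[tuple[int, int]] = []
        comp: dict[str, int] = Counter()
        for chrom, s, e, cls in repeats:
            if chrom != uc.chrom:
                continue
            s, e = max(s, uc.start), min(e, uc.end)
            if e <= s:
                continue
            # subtract already-claimed sub-intervals (input-order precedence)
            pieces = [(s, e)]
            for cs, ce in claimed:
                pieces = [
                    part
                    for ps, pe in pieces
                    for part in ((ps, min(pe, cs)), (max(ps, ce), pe))
                    if part[1] > part[0]
                ]
            for ps, pe in pieces:
                comp[cls] += pe - ps
                claimed.append((ps, pe))
        for cls, bases in comp.items():
            covered[(bin_lab, cls)] += bases
        uc.repeat_composition = {
            cls: bases / uc.length for cls, bases in comp.items()
        }

    data = {
        cls: [
            covered[(lab, cls)] / total[lab] if total[lab] else 0.0
            for lab in labels
        ]
        for cls in REPEAT_CLASSES
        if cls != "none"
    }
    return pd.DataFrame(data, index=pd.Index(labels, name="length_bin"))


def cnv_enrichment(
    unified: Sequence[UnifiedCluster],
    n_cohort: int,
    panel_carriers: Mapping[str, tuple[int, int]],
    or_threshold: float = CNV_OR_THRESHOLD,
    p_threshold: float = CNV_P_THRESHOLD,
    min_carriers: int = CNV_MIN_CARRIERS,
) -> pd.DataFrame:
    """Cohort-enrichment flags for unified CNVs on carrier-count tables.

    ``panel_carriers`` maps each continental group to (carriers, group size)
    for the matched CNV region. A CNV is flagged when, against ANY group, the
    carrier odds ratio exceeds ``or_threshold`` with Fisher p below
    ``p_threshold``, and the cohort has strictly more than ``min_carriers``
    carriers.
    """
    rows = []
    for uc in unified:
        best_or, best_p, hit = 0.0, 1.0, False
        for group, (carriers, size) in panel_carriers.items():
            if size <= 0:
                raise ValueError(f"group {group} has non-positive size")
            res = fisher_exact(
                ContingencyTable2x2(
                    uc.carrier_count,
                    n_cohort - uc.carrier_count,
                    carriers,
                    size - carriers,
                ),
                or_threshold,
                p_threshold,
            )
            if res.odds_ratio > best_or:
                best_or, best_p = res.odds_ratio, res.p_value
            if res.odds_ratio > or_threshold and res.p_value < p_threshold:
                hit = True
        rows.append(
            {
                "chrom": uc.chrom,
                "start": uc.start,
                "end": uc.end,
                "svtype": uc.svtype,
                "carriers": uc.carrier_count,
                "best_odds_ratio": best_or,
                "best_p": best_p,
                "enriched": hit and uc.carrier_count > min_carriers,
            }
        )
    return pd.DataFrame(rows)
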