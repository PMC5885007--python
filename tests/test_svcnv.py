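"""Reciprocal overlap, spurious-call filters, clustering vs a brute-force
oracle, unification, novelty, repeat composition and CNV enrichment."""

import numpy as np
import pandas as pd
import pytest

import variome as v
from variome.svcnv import _round_half_away


def IC(chrom, start, end, svtype="DEL", sample="S0", cn=None):
    return v.IntervalCall(chrom, start, end, svtype, sample, copy_number=cn)


class TestReciprocalOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 0, 100), ("chr1", 10, 110), 0.9),
            (("chr1", 0, 100), ("chr1", 0, 100), 1.0),
            (("chr1", 0, 10), ("chr1", 0, 100), 0.1),  # nesting penalized
            (("chr1", 0, 10), ("chr1", 50, 60), 0.0),
            (("chr1", 0, 100), ("chr2", 0, 100), 0.0),
        ],
    )
    def test_fraction(self, a, b, expected):
        assert v.reciprocal_overlap(a, b) == pytest.approx(expected)
        assert v.reciprocal_overlap(b, a) == pytest.approx(expected)


class TestSpuriousFilter:
    def test_majority_gap_coverage_removed(self):
        calls = [IC("chr1", 1000, 2000)]
        gaps = [("chr1", 1000, 1600)]  # 60% of the call
        passing, log = v.filter_spurious(calls, gaps)
        assert not passing
        assert log.iloc[0]["rule_gap_coverage"]

    def test_three_tiny_gap_blocks_removed(self):
        calls = [IC("chr1", 0, 10_000)]
        gaps = [("chr1", p, p + 1) for p in (100, 200, 300)]
        passing, log = v.filter_spurious(calls, gaps)
        assert not passing
        assert log.iloc[0]["rule_gap_blocks"]
        # exactly two blocks survive the "more than 2" rule
        passing2, _ = v.filter_spurious(calls, gaps[:2])
        assert passing2 == calls

    def test_single_gap_reciprocal_overlap_rule(self):
        calls = [IC("chr1", 0, 1000)]
        gaps = [("chr1", 500, 1700)]  # RO = min(500/1000, 500/1200) > 0.1
        passing, log = v.filter_spurious(calls, gaps)
        assert not passing
        assert log.iloc[0]["rule_gap_ro"]

    def test_no_overlap_kept(self):
        calls = [IC("chr1", 0, 1000)]
        passing, log = v.filter_spurious(calls, [("chr1", 5000, 6000)])
        assert passing == calls and log.empty

    def test_idempotent_and_monotone(self, genome_with_gaps):
        calls, _ = v.gen_interval_calls(
            30, genome_with_gaps, seed=61, spurious_fraction=0.2
        )
        gaps = list(genome_with_gaps.gaps)
        once, _ = v.filter_spurious(calls, gaps)
        twice, _ = v.filter_spurious(once, gaps)
        assert once == twice
        more_gaps = gaps + [("chr1", 0, 50_000)]
        fewer, _ = v.filter_spurious(calls, more_gaps)
        assert set(id(c) for c in fewer) <= set(id(c) for c in once)


def brute_force_clusters(calls, threshold=0.7, inclusive=False):
    """All-pairs union-find oracle."""
    parent = list(range(len(calls)))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            a, b = calls[i], calls[j]
            if a.chrom != b.chrom or a.svtype != b.svtype:
                continue
            ro = v.reciprocal_overlap(
                (a.chrom, a.start, a.end), (b.chrom, b.start, b.end)
            )
            if (ro >= threshold) if inclusive else (ro > threshold):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(calls)):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestClustering:
    def test_disjoint_calls_are_singletons(self):
        calls = [IC("chr1", 0, 100), IC("chr1", 500, 600)]
        clusters = v.cluster_calls(calls)
        assert sorted(len(c) for c in clusters) == [1, 1]

    def test_single_linkage_chains(self):
        # A~B and B~C above threshold, A~C below: one cluster of three
        a = IC("chr1", 0, 1000)
        b = IC("chr1", 150, 1150)
        c = IC("chr1", 300, 1300)
        assert v.reciprocal_overlap(("chr1", 0, 1000), ("chr1", 300, 1300)) == 0.7
        clusters = v.cluster_calls([a, b, c], threshold=0.7)
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_type_and_chromosome_partition(self):
        calls = [
            IC("chr1", 0, 1000, "DEL"),
            IC("chr1", 0, 1000, "INV"),
            IC("chr2", 0, 1000, "DEL"),
        ]
        assert len(v.cluster_calls(calls)) == 3

    def test_matches_brute_force_oracle_on_jittered_calls(
        self, genome_with_gaps
    ):
        calls, _ = v.gen_interval_calls(
            40, genome_with_gaps, seed=62, n_samples=5, spurious_fraction=0.0
        )
        assert len(calls) >= 100
        clusters = v.cluster_calls(calls, threshold=0.7)
        idx = {id(c): i for i, c in enumerate(calls)}
        got = {frozenset(idx[id(c)] for c in cl) for cl in clusters}
        assert got == brute_force_clusters(calls, threshold=0.7)

    def test_invariant_under_input_permutation(self, genome_with_gaps):
        calls, _ = v.gen_interval_calls(20, genome_with_gaps, seed=63)
        rng = np.random.default_rng(0)
        shuffled = [calls[i] for i in rng.permutation(len(calls))]
        a = {
            frozenset((c.start, c.end, c.sample) for c in cl)
            for cl in v.cluster_calls(calls)
        }
        b = {
            frozenset((c.start, c.end, c.sample) for c in cl)
            for cl in v.cluster_calls(shuffled)
        }
        assert a == b

    def test_inclusive_threshold_for_cnv_merging(self):
        a = IC("chr1", 0, 1000, "CNV_DEL", cn=0)
        b = IC("chr1", 300, 1300, "CNV_DEL", cn=1)  # RO exactly 0.7
        assert len(v.cluster_calls([a, b], 0.7, inclusive=False)) == 2
        assert len(v.cluster_calls([a, b], 0.7, inclusive=True)) == 1


class TestUnify:
    def test_average_coordinates(self):
        uc = v.unify_cluster(
            [IC("chr1", 100, 200), IC("chr1", 110, 210, sample="S1")]
        )
        assert (uc.start, uc.end) == (105, 205)
        assert uc.carrier_count == 2

    def test_singleton_identity(self):
        uc = v.unify_cluster([IC("chr1", 42, 99)])
        assert (uc.start, uc.end) == (42, 99)

    def test_same_sample_counted_once(self):
        uc = v.unify_cluster(
            [IC("chr1", 0, 100, sample="S0"), IC("chr1", 10, 110, sample="S0")]
        )
        assert uc.carrier_count == 1

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            v.unify_cluster([])

    def test_rounding_half_away_from_zero(self):
        assert _round_half_away(2.5) == 3
        assert _round_half_away(3.5) == 4
        assert _round_half_away(-2.5) == -3

    def test_unified_bounds_within_member_ranges(self, genome_with_gaps):
        calls, _ = v.gen_interval_calls(25, genome_with_gaps, seed=64)
        for cl in v.cluster_calls(calls):
            uc = v.unify_cluster(cl)
            starts = [c.start for c in cl]
            ends = [c.end for c in cl]
            assert min(starts) <= uc.start <= max(starts)
            assert min(ends) <= uc.end <= max(ends)


class TestNovelty:
    def _uc(self, start, end, svtype="DEL"):
        cn = 0 if svtype.startswith("CNV_") else None
        return v.unify_cluster([IC("chr1", start, end, svtype, cn=cn)])

    def test_exact_database_match_is_known(self):
        uc = self._uc(1000, 2000)
        assert v.annotate_novelty(uc, [("chr1", 1000, 2000, "DEL")]) is False
        assert uc.novel is False

    def test_empty_database_is_novel(self):
        uc = self._uc(1000, 2000)
        assert v.annotate_novelty(uc, []) is True

    def test_type_compatibility(self):
        uc = self._uc(0, 1000, "CNV_DEL")
        assert v.annotate_novelty(uc, [("chr1", 0, 1000, "DEL")]) is False
        assert v.annotate_novelty(uc, [("chr1", 0, 1000, "DUP")]) is True

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(65)
        db = [
            ("chr1", int(s), int(s + rng.integers(200, 2000)), "DEL")
            for s in rng.integers(0, 1_000_000, size=100)
        ]
        for _ in range(100):
            s = int(rng.integers(0, 1_000_000))
            uc = self._uc(s, s + int(rng.integers(200, 2000)))
            brute = any(
                t == "DEL"
                and v.reciprocal_overlap(
                    (uc.chrom, uc.start, uc.end), (c, a, b)
                )
                >= 0.7
                for c, a, b, t in db
            )
            assert v.annotate_novelty(uc, db) == (not brute)


class TestRepeatComposition:
    def test_interval_inside_single_sine(self):
        uc = v.unify_cluster([IC("chr1", 100, 300)])
        out = v.repeat_composition(
            [uc], [("chr1", 0, 1000, "SINE")], length_bins=[0, 1000]
        )
        assert out.loc["[0,1000)", "SINE"] == pytest.approx(1.0)

    def test_no_repeats_all_zero(self):
        uc = v.unify_cluster([IC("chr1", 100, 300)])
        out = v.repeat_composition([uc], [], length_bins=[0, 1000])
        assert (out.to_numpy() == 0).all()

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(66)
        classes = ["SINE", "LINE", "LTR", "DNA", "simple"]
        repeats = []
        for _ in range(40):
            s = int(rng.integers(0, 9_000))
            repeats.append(
                ("chr1", s, s + int(rng.integers(50, 800)),
                 classes[int(rng.integers(0, 5))])
            )
        unified = [
            v.unify_cluster([IC("chr1", s, s + ln)])
            for s, ln in ((200, 900), (3000, 2500), (7000, 2800))
        ]
        bins = [0, 1000, 3000, 10_000]
        out = v.repeat_composition(unified, repeats, bins)

        # per-base oracle with first-listed-annotation precedence
        genome = np.zeros(10_000, dtype=int)  # 0 = unclaimed
        for k, (_, s, e, cls) in enumerate(repeats, start=1):
            span = genome[s:e]
            span[span == 0] = k
        for lo, hi in zip(bins, bins[1:]):
            lab = f"[{lo},{hi})"
            members = [u for u in unified if lo <= u.length < hi]
            total = sum(u.length for u in members)
            for ci, cls in enumerate(classes):
                claimed = 0
                for u in members:
                    span = genome[u.start : u.end]
                    owners = {
                        k
                        for k in np.unique(span)
                        if k and repeats[k - 1][3] == cls
                    }
                    claimed += int(np.isin(span, list(owners)).sum())
                expected = claimed / total if total else 0.0
                assert out.loc[lab, cls] == pytest.approx(expected)

    def test_fractions_bounded(self):
        uc = v.unify_cluster([IC("chr1", 0, 1000)])
        repeats = [("chr1", 0, 600, "SINE"), ("chr1", 400, 1000, "LINE")]
        out = v.repeat_composition([uc], repeats, [0, 2000])
        assert out.loc["[0,2000)"].sum() <= 1.0 + 1e-12
        assert ((out >= 0) & (out <= 1)).all().all()


class TestCnvEnrichment:
    def _uc(self, carriers):
        members = [
            IC("chr1", 0, 10_000, "CNV_DUP", sample=f"S{i}", cn=3)
            for i in range(carriers)
        ]
        return v.unify_cluster(members) if members else None

    def test_zero_carriers_not_enriched(self):
        uc = v.unify_cluster([IC("chr1", 0, 1000, "CNV_DEL", cn=0)])
        uc.carrier_count = 0
        out = v.cnv_enrichment([uc], 50, {"EAS": (10, 500)})
        assert not out["enriched"].any()

    def test_strong_enrichment_flagged(self):
        from tests.test_enrich import fisher_p_oracle

        uc = self._uc(6)
        out = v.cnv_enrichment(
            [uc], 50, {g: (1, 500) for g in ("AFR", "EUR", "AMR", "SAS", "EAS")}
        )
        orr = (6 * 499) / (44 * 1)
        assert orr > 10
        p = fisher_p_oracle(6, 44, 1, 499)
        assert bool(out["enriched"].iloc[0]) is (p < 0.01)

    def test_exactly_five_carriers_not_enriched(self):
        uc = self._uc(5)
        out = v.cnv_enrichment([uc], 50, {"EAS": (0, 500)})
        assert not out["enriched"].any()

    def test_zero_group_size_rejected(self):
        uc = self._uc(6)
        with pytest.raises(ValueError):
            v.cnv_enrichment([uc], 50, {"EAS": (0, 0)})
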