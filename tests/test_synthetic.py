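"""Generator contracts: determinism, drift moments, Mendelian transmission,
error-rate recovery and truth-table coverage."""

import numpy as np
import pandas as pd
import pytest

import variome as v


class TestPanel:
    def test_zero_fst_reproduces_ancestral_frequency(self):
        panel = v.gen_panel(v.PanelSpec(n_variants=200, fst=0.0, seed=1))
        anc = panel.table["ancestral_af"]
        for pop in panel.populations:
            assert np.allclose(panel.table[f"AF_{pop}"], anc)

    def test_same_seed_identical_panels(self):
        spec = v.PanelSpec(n_variants=150, fst=0.2, seed=7)
        a, b = v.gen_panel(spec), v.gen_panel(spec)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_drift_variance_matches_balding_nichols_moment(self):
        # Var(f | p) = F * p * (1 - p): average the normalized squared
        # deviation over >= 50 replicate panels and compare with F.
        fst = 0.1
        ratios = []
        for seed in range(50):
            panel = v.gen_panel(
                v.PanelSpec(n_variants=400, fst=fst, seed=1000 + seed)
            )
            p = panel.table["ancestral_af"].to_numpy()
            for pop in panel.populations:
                f = panel.table[f"AF_{pop}"].to_numpy()
                ratios.append(np.mean((f - p) ** 2 / (p * (1 - p))))
        est = float(np.mean(ratios))
        assert est == pytest.approx(fst, rel=0.05)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_variants": 0},
            {"n_variants": 10, "fst": 1.0},
            {"n_variants": 10, "allele_number": 1},
            {"n_variants": 10, "ancestral_maf_beta": (0.0, 1.0)},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            v.gen_panel(v.PanelSpec(**kwargs))


class TestCohort:
    def test_empty_panel_rejected(self, small_panel):
        empty = v.PanelFrequencies(
            small_panel.table.iloc[:0], small_panel.populations
        )
        with pytest.raises(ValueError):
            v.gen_cohort(empty, v.CohortSpec(n_samples=5, seed=0))

    def test_same_seed_identical_cohorts(self, small_panel):
        spec = v.CohortSpec(n_samples=10, seed=3)
        (a, ta), (b, tb) = (
            v.gen_cohort(small_panel, spec),
            v.gen_cohort(small_panel, spec),
        )
        assert (a.genotypes == b.genotypes).all()
        pd.testing.assert_frame_equal(ta, tb)

    def test_extreme_frequencies_give_monomorphic_genotypes(
        self, cohort_with_truth
    ):
        cohort, truth = cohort_with_truth
        freq = truth["true_cohort_freq"].to_numpy()
        dos = cohort.dosages()
        zero = freq == 0.0
        assert (dos[:, zero] == 0).all()

    def test_observed_frequency_within_binomial_error(self, small_panel):
        cohort, truth = v.gen_cohort(
            small_panel, v.CohortSpec(n_samples=200, seed=4)
        )
        f = truth["true_cohort_freq"].to_numpy()
        two_n = 2 * cohort.n_samples
        obs = cohort.alt_allele_counts() / two_n
        se = np.sqrt(np.maximum(f * (1 - f), 1e-9) / two_n)
        within = np.abs(obs - f) <= 3 * se + 1e-12
        # 3 sigma should cover ~99.7%; allow a small tail
        assert within.mean() > 0.97

    def test_enriched_variants_spiked_over_panel_frequency(
        self, small_panel, cohort_with_truth
    ):
        _, truth = cohort_with_truth
        enriched = truth[truth["enriched"] & truth["in_panel"]]
        eas = small_panel.table.loc[enriched.index, "AF_EAS"]
        assert (
            enriched["true_cohort_freq"] >= 3.0 * eas.to_numpy() - 1e-9
        ).all()

    def test_truth_table_covers_every_variant_once(self, cohort_with_truth):
        cohort, truth = cohort_with_truth
        keys = cohort.keys()
        assert len(truth) == cohort.n_variants
        assert not truth.index.duplicated().any()
        assert set(truth.index) == set(keys)


class TestPedigree:
    def test_mt_pair_identical_without_error(self, small_panel):
        ped, _ = v.gen_pedigree_cohort(
            small_panel, v.PedigreeSpec(relations=(("a", "b", "MT"),), seed=5)
        )
        assert (ped.genotypes[0] == ped.genotypes[1]).all()

    def test_pc_pair_shares_an_allele_everywhere(self, small_panel):
        ped, _ = v.gen_pedigree_cohort(
            small_panel, v.PedigreeSpec(relations=(("p", "c", "PC"),), seed=6)
        )
        parent, child = ped.genotypes[0], ped.genotypes[1]
        # opposite homozygotes would violate Mendelian transmission
        assert not ((parent == 0) & (child == 2)).any()
        assert not ((parent == 2) & (child == 0)).any()

    def test_duplicate_sample_names_rejected(self):
        with pytest.raises(ValueError):
            v.PedigreeSpec(
                relations=(("a", "b", "MT"), ("b", "c", "PC"))
            ).validate()

    def test_unknown_relation_rejected(self):
        with pytest.raises(ValueError):
            v.PedigreeSpec(relations=(("a", "b", "XX"),)).validate()

    def test_allele_sharing_orders_by_kinship(self):
        # kinship 1/4 (PC, Br), 1/8 (GPC, UN), 1/16 (Co), 0 (UR):
        # mean distance must increase as kinship drops.
        panel = v.gen_panel(v.PanelSpec(n_variants=20_000, fst=0.05, seed=8))
        relations = []
        for rel in ("MT", "PC", "Br", "GPC", "UN", "Co", "UR"):
            for i in range(5):
                relations.append((f"{rel}{i}a", f"{rel}{i}b", rel))
        ped, recs = v.gen_pedigree_cohort(
            panel, v.PedigreeSpec(relations=tuple(relations), seed=9)
        )
        from variome.relatedness import DistanceResult, relationship_ordering

        dos = ped.dosages()
        dists = []
        for a, b, _rel in recs:
            ia, ib = ped.sample_index(a), ped.sample_index(b)
            d = float(np.abs(dos[ia].astype(int) - dos[ib].astype(int)).sum()) / 2
            dists.append(DistanceResult(a, b, d, ped.n_variants))
        means, consistent = relationship_ordering(dists, recs)
        assert consistent, means.to_dict()


class TestIntervalCalls:
    def test_same_seed_identical_calls(self, genome_with_gaps):
        a, ta = v.gen_interval_calls(10, genome_with_gaps, seed=3)
        b, tb = v.gen_interval_calls(10, genome_with_gaps, seed=3)
        assert a == b
        pd.testing.assert_frame_equal(ta, tb)

    def test_zero_jitter_clusters_recover_truth(self, genome_with_gaps):
        calls, truth = v.gen_interval_calls(
            30, genome_with_gaps, seed=4, jitter=0.0, spurious_fraction=0.0
        )
        clusters = v.cluster_calls(calls, threshold=0.7)
        got = {
            frozenset(id(c) for c in cl) for cl in clusters
        }
        want = {
            frozenset(
                id(calls[i]) for i in truth.index[truth["cluster"] == k]
            )
            for k in truth["cluster"].unique()
        }
        assert got == want

    def test_spurious_filter_removes_exactly_truth_flagged(
        self, genome_with_gaps
    ):
        calls, truth = v.gen_interval_calls(
            40, genome_with_gaps, seed=5, spurious_fraction=0.1
        )
        passing, log = v.filter_spurious(calls, genome_with_gaps.gaps)
        kept_truth = [
            calls[i] for i in truth.index[~truth["spurious"]]
        ]
        assert passing == kept_truth
        assert len(log) == int(truth["spurious"].sum())


class TestArrayGenotypes:
    def test_no_error_perfect_concordance(self, cohort_with_truth):
        cohort, _ = cohort_with_truth
        arr = v.gen_array_genotypes(cohort, 0.0, 0.0, seed=6)
        per_sample = v.genotype_concordance(cohort, arr, "sample")
        assert (per_sample["concordance"] == 1.0).all()

    def test_error_rate_recovered_within_binomial_error(self, small_panel):
        cohort, _ = v.gen_cohort(small_panel, v.CohortSpec(n_samples=250, seed=7))
        n_genotypes = cohort.n_samples * cohort.n_variants
        assert n_genotypes >= 100_000
        err = 0.01
        arr = v.gen_array_genotypes(cohort, err, 0.0, seed=8)
        keep = arr.keys()
        idx = pd.Index(cohort.keys()).get_indexer(keep)
        mismatch = (cohort.genotypes[:, idx] != arr.genotypes).mean()
        se = np.sqrt(err * (1 - err) / n_genotypes)
        assert abs(mismatch - err) < 3 * se

    def test_all_missing_concordance_undefined(self, cohort_with_truth):
        cohort, _ = cohort_with_truth
        arr = v.gen_array_genotypes(cohort, 0.0, 1.0, seed=9)
        per_sample = v.genotype_concordance(cohort, arr, "sample")
        assert per_sample["concordance"].isna().all()
        assert (per_sample["n_compared"] == 0).all()
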