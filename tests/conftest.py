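import numpy as np
import pandas as pd
import pytest

import variome as v


@pytest.fixture(scope="session")
def small_panel():
    return v.gen_panel(v.PanelSpec(n_variants=400, fst=0.1, seed=11))


@pytest.fixture(scope="session")
def gene_model():
    """Toy gene: UTR / coding / splice / intron layout on chr1."""
    intervals = []
    step = 100_000
    for start in range(0, 9_900_000, step):
        intervals.append(("chr1", start, start + 1_000, "UTR"))
        pos = start + 1_000
        for _ in range(3):
            intervals.append(("chr1", pos, pos + 4_000, "coding"))
            intervals.append(("chr1", pos + 4_000, pos + 4_050, "splice_site"))
            intervals.append(("chr1", pos + 4_050, pos + 10_000, "intron"))
            pos += 10_000
    return v.GeneModel(intervals)


@pytest.fixture(scope="session")
def cohort_with_truth(small_panel, gene_model):
    cohort, truth = v.gen_cohort(
        small_panel,
        v.CohortSpec(n_samples=30, seed=12, rare_fraction_coding_multiplier=2.0),
        gene_model,
    )
    return cohort, truth


@pytest.fixture(scope="session")
def genome_with_gaps():
    gaps = tuple(
        ("chr1", s, s + 15_000) for s in range(200_000, 9_500_000, 700_000)
    )
    return v.GenomeModel(chrom_lengths={"chr1": 10_000_000}, gaps=gaps)


def make_cohort(dosages, chrom="chr1", start=100):
    """Tiny cohort from an explicit dosage matrix (samples x sites)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_sites = dosages.shape
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": np.arange(start, start + n_sites),
            "ref": ["A"] * n_sites,
            "alt": ["T"] * n_sites,
        }
    )
    samples = [f"P{i}" for i in range(n_samples)]
    return v.CohortGenotypes(samples, variants, dosages)
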