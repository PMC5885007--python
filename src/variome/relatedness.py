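"""Pairwise genetic distance, relatedness ordering and classical MDS.

The genetic distance between two diploid samples is pi = D/N: D sums a
per-site allele-sharing difference (identical genotypes 0, het vs either
hom 0.5, opposite homs 1) and N is the number of compared positions —
typically the callable-genome or site-union size, not just the variant
count. Uncalled genotypes are treated as homozygous reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import squareform, pdist

from .datatypes import CohortGenotypes

#: expected kinship-based ordering of mean pi, closest first; classes inside
#: one tier share a kinship coefficient and are not ordered between them
KINSHIP_TIERS = (("MT",), ("Br", "PC"), ("UN", "GPC"), ("Co",), ("UR",))


@dataclass(frozen=True)
class DistanceResult:
    sample_a: str
    sample_b: str
    D: float
    N: int

    @property
    def pi(self) -> float:
        return self.D / self.N


def _site_differences(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Allele-sharing difference per site: |dosage difference| / 2."""
    return np.abs(a.astype(np.int16) - b.astype(np.int16)) / 2.0


def pairwise_pi(
    a: np.ndarray,
    b: np.ndarray,
    n_compared: int | None = None,
    sample_a: str = "a",
    sample_b: str = "b",
) -> DistanceResult:
    """pi = D/N for two dosage vectors aligned on the same site set.

    Missing dosages (-1) are recoded as homozygous reference before the
    difference is taken. ``n_compared`` defaults to the number of sites in
    the vectors and must not be smaller than it.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must align on the same site set")
    a = np.where(a < 0, 0, a)
    b = np.where(b < 0, 0, b)
    n = a.shape[0] if n_compared is None else int(n_compared)
    if n < a.shape[0]:
        raise ValueError("n_compared must be >= the number of variant sites")
    d = float(_site_differences(a, b).sum())
    return DistanceResult(sample_a, sample_b, d, n)


def distance_matrix(
    cohort: CohortGenotypes,
    metric: str = "pi",
    n_compared: int | None = None,
) -> pd.DataFrame:
    """Symmetric all-pairs distance matrix on dosage vectors.

    ``metric="pi"`` uses the allele-sharing distance above (scaled by
    ``n_compared``); ``metric="canberra"`` uses the Canberra distance on
    dosages, where 0-vs-0 terms contribute nothing.
    """
    if cohort.n_samples < 2:
        raise ValueError("need at least two samples")
    dos = cohort.dosages(missing_as_ref=True).astype(float)
    if (cohort.genotypes == -1).all(axis=1).any():
        raise ValueError("a sample with no called genotypes has no distances")
    if metric == "pi":
        n = cohort.n_variants if n_compared is None else int(n_compared)
        condensed = pdist(dos, metric="cityblock") / 2.0 / n
    elif metric == "canberra":
        condensed = pdist(dos, metric="canberra")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    mat = squareform(condensed)
    return pd.DataFrame(mat, index=cohort.samples, columns=cohort.samples)


def relationship_ordering(
    distances: Sequence[DistanceResult],
    relations: Sequence[tuple[str, str, str]],
) -> tuple[pd.Series, bool]:
    """Mean pi per relation class plus a kinship-consistency verdict.

    The verdict is True when mean pi increases (strictly) across the kinship
    tiers MT < {Br, PC} < {UN, GPC} < Co < UR, comparing tier means for the
    tiers that are present. Pairs without a relation label are excluded.
    """
    labels = {}
    for a, b, rel in relations:
        labels[frozenset((a, b))] = rel
    rows = []
    for d in distances:
        rel = labels.get(frozenset((d.sample_a, d.sample_b)))
        if rel is None:
            continue
        rows.append({"relation": rel, "pi": d.pi})
    if not rows:
        raise ValueError("no labelled pairs")
    df = pd.DataFrame(rows)
    means = df.groupby("relation")["pi"].mean()

    tier_means = []
    for tier in KINSHIP_TIERS:
        present = [m for m in tier if m in means.index]
        if present:
            tier_means.append(float(means[present].mean()))
    consistent = all(x < y for x, y in zip(tier_means, tier_means[1:]))
    return means, consistent


def pairwise_pi_all(
    cohort: CohortGenotypes, n_compared: int | None = None
) -> list[DistanceResult]:
    """pi for every sample pair in the cohort."""
    n = cohort.n_variants if n_compared is None else int(n_compared)
    dos = cohort.dosages(missing_as_ref=True)
    out = []
    for i, j in combinations(range(cohort.n_samples), 2):
        d = float(_site_differences(dos[i], dos[j]).sum())
        out.append(DistanceResult(cohort.samples[i], cohort.samples[j], d, n))
    return out


def mds_embed(matrix: pd.DataFrame | np.ndarray, k: int) -> np.ndarray:
    """Classical (Torgerson) metric scaling of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns the
    top-k coordinates (eigenvalues clipped at zero, descending). For an
    exactly Euclidean matrix and sufficient k the embedding reproduces all
    pairwise distances.
    """
    D = np.asarray(matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("need a square symmetric distance matrix")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}]")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = eigh(B)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)[None, :]


def maf_callrate_prefilter(
    cohort: CohortGenotypes,
    min_maf: float = 0.05,
    min_call_rate: float = 0.95,
    thin_to: int | None = None,
    seed: int = 0,
) -> CohortGenotypes:
    """Site pre-filter applied before embedding: drop low-MAF and low
    call-rate sites, optionally thin randomly to ``thin_to`` sites (a cheap
    stand-in for external LD pruning)."""
    g = cohort.genotypes
    called = g != -1
    call_rate = called.mean(axis=0)
    with np.errstate(invalid="ignore"):
        af = np.where(g == -1, 0, g).sum(axis=0) / np.maximum(
            2 * called.sum(axis=0), 1
        )
    maf = np.minimum(af, 1 - af)
    keep = np.flatnonzero((maf >= min_maf) & (call_rate >= min_call_rate))
    if thin_to is not None and len(keep) > thin_to:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(keep, size=thin_to, replace=False))
    return CohortGenotypes(
        cohort.samples, cohort.variants.iloc[keep], g[:, keep]
    )
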