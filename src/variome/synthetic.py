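"""Synthetic cohort, panel, pedigree, array and SV/CNV call generators.

These generators produce inputs with the statistical structure the analysis
stages assume — continental allele-frequency structure with Balding–Nichols
drift, Hardy–Weinberg cohort genotypes with population-enriched and
cohort-specific variants, Mendelian pedigrees with genotype error, interval
calls jittered around shared loci and partially overlapping assembly gaps —
so every downstream statistic can be checked against recorded truth.

All generators are pure functions of their spec (including its seed):
identical inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_POPULATIONS,
    CohortGenotypes,
    GeneModel,
    IntervalCall,
    PanelFrequencies,
    variant_key,
)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of the continental reference panel generator.

    fst may be a single drift parameter applied to every population or a
    mapping population -> drift; ancestral MAFs are drawn from
    0.5 * Beta(a, b) so they live on (0, 0.5].
    """

    n_variants: int
    populations: tuple[str, ...] = DEFAULT_POPULATIONS
    fst: float | dict[str, float] = 0.1
    ancestral_maf_beta: tuple[float, float] = (0.5, 0.5)
    allele_number: int = 1000
    chrom: str = "chr1"
    genome_length: int = 10_000_000
    seed: int = 0

    def fst_for(self, pop: str) -> float:
        f = self.fst[pop] if isinstance(self.fst, dict) else self.fst
        return float(f)

    def validate(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.allele_number < 2:
            raise ValueError("allele_number must be >= 2")
        if not self.populations:
            raise ValueError("populations must be non-empty")
        for pop in self.populations:
            f = self.fst_for(pop)
            if not 0.0 <= f < 1.0:
                raise ValueError(f"fst for {pop} must be in [0, 1), got {f}")
        a, b = self.ancestral_maf_beta
        if a <= 0 or b <= 0:
            raise ValueError("ancestral Beta parameters must be positive")
        if self.genome_length < 2 * self.n_variants:
            raise ValueError("genome_length too small for n_variants")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the study-cohort genotype generator.

    The defaults emulate a 50-sample diploid cohort in which roughly a fifth
    of variants are selectively enriched relative to the East-Asian panel
    frequency, a fifth are absent from the panel altogether, and rare
    variants are over-represented inside coding sequence (purifying
    selection) by the coding multiplier.
    """

    n_samples: int = 50
    enriched_fraction: float = 0.2
    panel_absent_fraction: float = 0.2
    rare_fraction_coding_multiplier: float = 2.0
    base_rare_fraction: float = 0.25
    genotype_error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for name in (
            "enriched_fraction",
            "panel_absent_fraction",
            "base_rare_fraction",
            "genotype_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rare_fraction_coding_multiplier < 0:
            raise ValueError("rare_fraction_coding_multiplier must be >= 0")


RELATION_LABELS = ("MT", "PC", "Br", "GPC", "UN", "Co", "UR")


@dataclass(frozen=True)
class PedigreeSpec:
    """Pairs of related individuals to simulate.

    relations: sequence of (sample_a, sample_b, label) with label one of
    MT (monozygotic twins), PC (parent-child), Br (brothers/siblings),
    GPC (grandparent-grandchild), UN (uncle-nephew), Co (cousins),
    UR (unrelated). Each pair is founded independently from the panel, so
    the construction is acyclic by design; duplicate sample names across
    pairs are rejected.
    """

    relations: tuple[tuple[str, str, str], ...]
    genotype_error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        seen: set[str] = set()
        for a, b, label in self.relations:
            if label not in RELATION_LABELS:
                raise ValueError(f"unknown relation label {label!r}")
            if a == b or a in seen or b in seen:
                raise ValueError(
                    f"sample names must be unique across pairs ({a}, {b})"
                )
            seen.update((a, b))
        if not 0.0 <= self.genotype_error_rate <= 1.0:
            raise ValueError("genotype_error_rate must be in [0, 1]")


@dataclass(frozen=True)
class GenomeModel:
    """Toy genome: chromosome lengths plus gap and repeat interval tracks."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000}
    )
    gaps: tuple[tuple[str, int, int], ...] = ()
    repeats: tuple[tuple[str, int, int, str], ...] = ()  # (+ repeat class)

    def validate(self) -> None:
        for chrom, s, e in self.gaps:
            if chrom not in self.chrom_lengths or not 0 <= s < e <= self.chrom_lengths[chrom]:
                raise ValueError(f"bad gap interval {(chrom, s, e)}")
        for chrom, s, e, _cls in self.repeats:
            if chrom not in self.chrom_lengths or not 0 <= s < e <= self.chrom_lengths[chrom]:
                raise ValueError(f"bad repeat interval {(chrom, s, e)}")


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------


def gen_panel(spec: PanelSpec) -> PanelFrequencies:
    """Draw a continental allele-frequency panel under Balding–Nichols drift.

    Each variant gets an ancestral frequency p from 0.5*Beta(a, b); each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p
    and variance F*p*(1-p). F = 0 reproduces p exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_variants

    pos = np.sort(
        rng.choice(spec.genome_length - 1, size=n, replace=False)
    ).astype(np.int64)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    ref = _BASES[ref_idx]
    alt = _BASES[alt_idx]

    a, b = spec.ancestral_maf_beta
    ancestral = 0.5 * rng.beta(a, b, size=n)
    ancestral = np.clip(ancestral, 1e-6, 0.5)

    keys = [
        variant_key(spec.chrom, int(p), r, al)
        for p, r, al in zip(pos, ref, alt)
    ]
    data: dict[str, np.ndarray] = {
        "chrom": np.full(n, spec.chrom, dtype=object),
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "ancestral_af": ancestral,
    }
    for pop in spec.populations:
        f = spec.fst_for(pop)
        if f == 0.0:
            af = ancestral.copy()
        else:
            c = (1.0 - f) / f
            af = rng.beta(ancestral * c, (1.0 - ancestral) * c)
        an = np.full(n, spec.allele_number, dtype=np.int64)
        ac = np.round(af * an).astype(np.int64)
        data[f"AF_{pop}"] = af
        data[f"AC_{pop}"] = ac
        data[f"AN_{pop}"] = an
    table = pd.DataFrame(data, index=pd.Index(keys, name="key"))
    return PanelFrequencies(table, spec.populations)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def _eas_analog(populations: list[str]) -> str:
    return "EAS" if "EAS" in populations else populations[-1]


def _inject_genotype_errors(
    geno: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric single-allele flips: het -> random hom, hom -> het."""
    if rate <= 0:
        return geno
    flip = rng.random(geno.shape) < rate
    direction = rng.integers(0, 2, size=geno.shape)  # which allele flips
    out = geno.copy()
    het = flip & (geno == 1)
    out[het & (direction == 0)] = 0
    out[het & (direction == 1)] = 2
    out[flip & (geno == 0)] = 1
    out[flip & (geno == 2)] = 1
    return out


def gen_cohort(
    panel: PanelFrequencies,
    spec: CohortSpec,
    gene_model: GeneModel | None = None,
) -> tuple[CohortGenotypes, pd.DataFrame]:
    """Draw Hardy–Weinberg cohort genotypes with recorded truth.

    Cohort variants are the panel variants plus a ``panel_absent_fraction``
    of extra cohort-specific sites. Each variant gets a true cohort
    frequency: rare-targeted variants (probability ``base_rare_fraction``,
    multiplied by ``rare_fraction_coding_multiplier`` inside coding
    sequence) draw a frequency low enough that fewer than three alternative
    alleles are expected; enriched variants (``enriched_fraction`` of the
    non-rare ones) are spiked to at least three times the East-Asian-analog
    panel frequency. Genotypes are Binomial(2, f) per sample with optional
    symmetric single-allele error.

    Returns the genotype matrix and a truth table with one row per variant:
    true cohort frequency, enrichment flag, region class, coding effect and
    panel membership. When ``gene_model`` is given, the invented coding
    effects are added to its ``coding_effects`` mapping so downstream
    annotation sees them.
    """
    spec.validate()
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    rng = np.random.default_rng(spec.seed)

    pt = panel.table
    eas = _eas_analog(panel.populations)
    chrom = pt["chrom"].iloc[0]

    # cohort-specific variants at fresh positions
    n_extra = int(round(spec.panel_absent_fraction * len(pt)))
    taken = set(pt["pos"].tolist())
    lim = int(pt["pos"].max()) + 1_000_000
    extra_pos: list[int] = []
    while len(extra_pos) < n_extra:
        cand = int(rng.integers(0, lim))
        if cand not in taken:
            taken.add(cand)
            extra_pos.append(cand)
    extra_pos = sorted(extra_pos)
    ref_idx = rng.integers(0, 4, size=n_extra)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_extra)) % 4

    variants = pd.DataFrame(
        {
            "chrom": list(pt["chrom"]) + [chrom] * n_extra,
            "pos": list(pt["pos"]) + extra_pos,
            "ref": list(pt["ref"]) + list(_BASES[ref_idx]),
            "alt": list(pt["alt"]) + list(_BASES[alt_idx]),
        }
    )
    in_panel = np.array([True] * len(pt) + [False] * n_extra)
    base_freq = np.concatenate(
        [pt[f"AF_{eas}"].to_numpy(), 0.5 * rng.beta(0.3, 3.0, size=n_extra)]
    )
    n_var = len(variants)

    # region classes from the gene model
    if gene_model is not None:
        region = np.array(
            [
                gene_model.region_at(c, int(p))
                for c, p in zip(variants["chrom"], variants["pos"])
            ],
            dtype=object,
        )
    else:
        region = np.full(n_var, "intergenic", dtype=object)
    coding = np.isin(region, ("coding", "splice_site"))

    # rare targeting, inflated in coding sequence
    p_rare = np.where(
        coding,
        np.minimum(
            spec.base_rare_fraction * spec.rare_fraction_coding_multiplier, 0.95
        ),
        spec.base_rare_fraction,
    )
    rare_target = rng.random(n_var) < p_rare

    two_n = 2 * spec.n_samples
    cohort_freq = np.clip(
        base_freq + rng.normal(0.0, 0.01, size=n_var), 1.0 / two_n, 0.95
    )
    # frequent floor: expected alt count comfortably >= 3
    cohort_freq = np.maximum(cohort_freq, 4.5 / two_n)
    # spiking to >= 3x the base frequency is only attainable below 0.25
    eligible = base_freq <= 0.25
    enriched = (
        (~rare_target) & eligible & (rng.random(n_var) < spec.enriched_fraction)
    )
    spiked = np.minimum(0.9, 3.0 * np.maximum(base_freq, 0.02) * 1.2)
    cohort_freq = np.where(enriched, np.maximum(cohort_freq, spiked), cohort_freq)
    # rare draw: expected alt count below one
    cohort_freq = np.where(
        rare_target, rng.uniform(0.0, 1.0, size=n_var) / two_n, cohort_freq
    )

    geno = rng.binomial(2, cohort_freq[None, :], size=(spec.n_samples, n_var))
    geno = _inject_genotype_errors(
        geno.astype(np.int8), spec.genotype_error_rate, rng
    )

    # coding effects for coding/splice variants
    effects = np.full(n_var, "none", dtype=object)
    eff_choices = np.array(
        ["non_synonymous", "synonymous", "frame_shift", "stop_gain"], dtype=object
    )
    eff_idx = rng.choice(4, size=int(coding.sum()), p=[0.6, 0.3, 0.05, 0.05])
    effects[coding] = eff_choices[eff_idx]
    effects[region == "splice_site"] = "splice_site"

    samples = [f"S{i:03d}" for i in range(spec.n_samples)]
    cohort = CohortGenotypes(samples, variants, geno)

    keys = cohort.keys()
    truth = pd.DataFrame(
        {
            "key": keys,
            "chrom": variants["chrom"],
            "pos": variants["pos"],
            "in_panel": in_panel,
            "true_cohort_freq": cohort_freq,
            "enriched": enriched,
            "rare_target": rare_target,
            "region_class": region,
            "coding_effect": effects,
        }
    ).set_index("key")

    if gene_model is not None:
        gene_model.coding_effects.update(
            {k: e for k, e in zip(keys, effects) if e != "none"}
        )
    return cohort, truth


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


def _founder(n: int, freq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Two haplotypes (2 x n alleles) drawn from population frequencies."""
    return (rng.random((2, n)) < freq[None, :]).astype(np.int8)


def _child(
    p1: np.ndarray, p2: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = p1.shape[1]
    h1 = p1[rng.integers(0, 2, size=n), np.arange(n)]
    h2 = p2[rng.integers(0, 2, size=n), np.arange(n)]
    return np.stack([h1, h2])


def gen_pedigree_cohort(
    panel: PanelFrequencies, spec: PedigreeSpec
) -> tuple[CohortGenotypes, list[tuple[str, str, str]]]:
    """Simulate related pairs with Mendelian transmission from panel founders.

    Founders draw haplotypes from the East-Asian-analog panel frequencies;
    each requested pair is built from its own founders (MT: identical copies;
    PC: child of one founder; Br: two children of a founder couple; GPC:
    grandparent and grandchild; UN: uncle and nephew; Co: first cousins;
    UR: independent founders). Genotype error is injected after transmission.
    """
    spec.validate()
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    rng = np.random.default_rng(spec.seed)
    pt = panel.table
    freq = pt[f"AF_{_eas_analog(panel.populations)}"].to_numpy()
    n = len(freq)

    samples: list[str] = []
    genos: list[np.ndarray] = []
    records: list[tuple[str, str, str]] = []

    for name_a, name_b, label in spec.relations:
        f = lambda: _founder(n, freq, rng)  # noqa: E731
        if label == "MT":
            x = f()
            pair = (x, x.copy())
        elif label == "PC":
            parent = f()
            pair = (parent, _child(parent, f(), rng))
        elif label == "Br":
            p1, p2 = f(), f()
            pair = (_child(p1, p2, rng), _child(p1, p2, rng))
        elif label == "GPC":
            gp = f()
            parent = _child(gp, f(), rng)
            pair = (gp, _child(parent, f(), rng))
        elif label == "UN":
            p1, p2 = f(), f()
            uncle = _child(p1, p2, rng)
            sib = _child(p1, p2, rng)
            pair = (uncle, _child(sib, f(), rng))
        elif label == "Co":
            p1, p2 = f(), f()
            sib1, sib2 = _child(p1, p2, rng), _child(p1, p2, rng)
            pair = (_child(sib1, f(), rng), _child(sib2, f(), rng))
        else:  # UR
            pair = (f(), f())
        for name, hap in zip((name_a, name_b), pair):
            samples.append(name)
            genos.append(hap.sum(axis=0))
        records.append((name_a, name_b, label))

    geno = np.stack(genos).astype(np.int8)
    geno = _inject_genotype_errors(geno, spec.genotype_error_rate, rng)
    variants = pt[["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    return CohortGenotypes(samples, variants, geno), records


# ---------------------------------------------------------------------------
# Interval (SV/CNV) calls
# ---------------------------------------------------------------------------


def _overlaps_gaps(
    chrom: str, start: int, end: int, gaps: tuple[tuple[str, int, int], ...]
) -> bool:
    return any(
        g_chrom == chrom and g_s < end and start < g_e
        for g_chrom, g_s, g_e in gaps
    )


def gen_interval_calls(
    n_per_sample: int,
    genome: GenomeModel,
    seed: int,
    n_samples: int = 5,
    svtype: str = "DEL",
    spurious_fraction: float = 0.1,
    jitter: float = 0.1,
    length_range: tuple[int, int] = (500, 5000),
) -> tuple[list[IntervalCall], pd.DataFrame]:
    """Per-sample interval calls jittered around shared true loci.

    True loci are placed clear of assembly gaps and each is carried by a
    random subset of samples; carriers receive copies whose endpoints are
    jittered by at most ``jitter`` (< 0.15) of the locus length. A
    ``spurious_fraction`` of extra calls is placed so each of the three
    gap-based spurious-call rules fires (single-gap reciprocal overlap >10%,
    gap coverage >50%, more than two gap blocks intersected).

    Returns the calls and a truth table aligned to the call list: sample,
    cluster id (-1 for spurious calls) and spurious flag.
    """
    if not 0.0 <= jitter < 0.15:
        raise ValueError("jitter must be in [0, 0.15)")
    if not 0.0 <= spurious_fraction <= 1.0:
        raise ValueError("spurious_fraction must be in [0, 1]")
    genome.validate()
    rng = np.random.default_rng(seed)
    chroms = list(genome.chrom_lengths)
    samples = [f"S{i:03d}" for i in range(n_samples)]

    n_true = n_per_sample
    calls: list[IntervalCall] = []
    truth_rows: list[dict] = []

    for cluster_id in range(n_true):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        clen = genome.chrom_lengths[chrom]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        for _ in range(1000):
            start = int(rng.integers(0, clen - length))
            if not _overlaps_gaps(chrom, start, start + length, genome.gaps):
                break
        else:
            raise RuntimeError("could not place a call clear of gaps")
        n_carriers = int(rng.integers(1, n_samples + 1))
        carriers = rng.choice(n_samples, size=n_carriers, replace=False)
        for ci in carriers:
            ds = int(round(rng.uniform(-jitter, jitter) * length))
            de = int(round(rng.uniform(-jitter, jitter) * length))
            s, e = start + ds, start + length + de
            if e <= s:
                e = s + 1
            calls.append(IntervalCall(chrom, s, e, svtype, samples[ci]))
            truth_rows.append(
                {"sample": samples[ci], "cluster": cluster_id, "spurious": False}
            )

    # spurious calls riding on gaps, cycling through the three rules
    n_spurious = int(round(spurious_fraction * len(calls)))
    gaps = list(genome.gaps)
    for i in range(n_spurious):
        rule = i % 3
        if not gaps:
            break
        chrom, g_s, g_e = gaps[int(rng.integers(0, len(gaps)))]
        glen = g_e - g_s
        if rule == 0:  # reciprocal overlap with one gap > 10%
            length = int(glen * rng.uniform(1.2, 2.0))
            start = max(0, g_s - int(0.2 * glen))
        elif rule == 1:  # > 50% covered by the gap
            length = max(2, int(glen * rng.uniform(0.5, 0.9)))
            start = g_s + max(0, int((glen - length) * rng.random()))
        else:  # span > 2 gap blocks on the same chromosome
            same = sorted(
                (s, e) for c, s, e in genome.gaps if c == chrom
            )
            if len(same) < 3:
                length = max(2, int(glen * rng.uniform(0.5, 0.9)))
                start = g_s
            else:
                start = max(0, same[0][0] - 10)
                length = same[2][1] + 10 - start
        end = min(start + length, genome.chrom_lengths[chrom])
        sample = samples[int(rng.integers(0, n_samples))]
        calls.append(IntervalCall(chrom, start, end, svtype, sample))
        truth_rows.append({"sample": sample, "cluster": -1, "spurious": True})

    truth = pd.DataFrame(truth_rows)
    return calls, truth


# ---------------------------------------------------------------------------
# Array genotypes
# ---------------------------------------------------------------------------


def gen_array_genotypes(
    genotypes: CohortGenotypes,
    error_rate: float,
    missing_rate: float,
    seed: int,
    site_fraction: float = 1.0,
) -> CohortGenotypes:
    """Array-style re-genotyping of a site subset with error and missingness.

    Each retained genotype is replaced, with probability ``error_rate``, by
    one of the two other dosage values (uniformly), and set missing with
    probability ``missing_rate``.
    """
    for name, v in (
        ("error_rate", error_rate),
        ("missing_rate", missing_rate),
        ("site_fraction", site_fraction),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    rng = np.random.default_rng(seed)
    n_sites = genotypes.n_variants
    n_keep = max(1, int(round(site_fraction * n_sites)))
    keep = np.sort(rng.choice(n_sites, size=n_keep, replace=False))

    g = genotypes.genotypes[:, keep].copy()
    err = rng.random(g.shape) < error_rate
    shift = rng.integers(1, 3, size=g.shape)  # +1 or +2 mod 3 changes dosage
    g = np.where(err & (g >= 0), (g + shift) % 3, g).astype(np.int8)
    miss = rng.random(g.shape) < missing_rate
    g[miss] = -1
    return CohortGenotypes(
        genotypes.samples, genotypes.variants.iloc[keep], g
    )
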