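# Methods

This note documents the statistical procedures implemented in `variome`,
the synthetic-data generators used to exercise them, the numerical choices
made where the design was genuinely open, and the limits of what the test
suite demonstrates.

## Variant representation and quality filters

Variants are biallelic records keyed by `(chrom, pos, ref, alt)` with
0-based half-open coordinates internally; VCF positions are converted at
I/O and multi-allelic records are split into per-allele rows (a genotype's
dosage for row k counts only allele k, so GT 1/2 contributes dosage 1 to
each row). Indels are restricted to 1–99 bp.

SNV calls pass QC when read depth ≥ 20 and the site's mapping rate ≥ 0.90;
both bounds are inclusive. "Mapping rate" is consumed as an input column —
recomputing it from alignments is out of scope, and read-level semantics
vary by caller. Indel calls are removed when quality < 27 **and** depth < 6
(a conjunction: a low-quality call at adequate depth survives), and when
heterozygous with alternative-allele balance < 0.3. Filters are idempotent
and log per-rule removal counts.

Region annotation assigns exactly one class per position with precedence
splice_site > coding > UTR > intron > intergenic — the most functionally
specific label wins when annotation intervals overlap. Coding effects
(synonymous, non-synonymous, frame-shift, stop-gain, splice-site) are
consumed as a per-variant mapping; effect prediction itself is not
reimplemented.

## Two-dimensional frequency classification

Panel-side classes use folded minor-allele frequencies per continental
group: COMMON requires MAF ≥ 0.05 in all groups, LOW_FREQ requires
MAF ≥ 0.001 in at least one, RARE otherwise, ABSENT when the variant has
no panel record. ABSENT is kept distinct from RARE because
population-specific variants behave differently from globally rare ones in
every downstream statistic. Cohort-side classes threshold the alternative
allele count over the cohort's 2N chromosomes at 3 (FREQUENT when ≥ 3).
The count is of alleles, not carriers — consistent with how the per-variant
MAF is computed from allele counts — but a carrier-count mode
(`count_carriers=True`) is provided since either convention is defensible.
Classification is a partition: every variant observed at least once lands
in exactly one of the eight cells, and the rule is monotone in each MAF.

The rare-variant ratio for a region class is `n_rare / n_frequent`;
a class with no frequent variants yields an explicitly undefined RVR
rather than infinity. The novel-allele accumulation curve counts, for each
successive sample, the (site, alt) pairs carried by that sample and absent
from both the known set and all earlier samples; the curve total equals
the union size for every ordering.

## Enrichment testing

Each group (the cohort plus the five panel groups) is tested against the
pooled chromosome counts of the remaining groups. The comparison set is
not canonical, so a pairwise-vs-cohort mode exists behind a flag. The
p-value is the two-sided Fisher exact probability, computed by summing
hypergeometric outcomes no more likely than the observed table (relative
slack 1e-7, the convention used by standard implementations); the odds
ratio is the sample estimate (ad)/(bc) with a Haldane +0.5 correction on
all cells only when a cell is zero. A variant is enriched in a group when
OR > 3 and p < 0.05. Two-sidedness costs little here because the OR
threshold enforces direction. No multiple-testing correction is applied by
default, matching the raw-threshold definition of the statistic; a
Benjamini–Hochberg helper is available. Null simulations at equal
frequency flag well under 5% of variants because the joint OR/p rule is
conservative.

The Venn partition assigns each enriched variant to the exact subset of
groups that flagged it; cells are disjoint and exhaustive over flagged
variants.

## Relatedness

π = D/N with the allele-sharing per-site difference (0, 0.5, 1 for
identical, het-vs-hom, opposite-hom pairs) — the only per-site definition
bounded by [0, 1] for diploid genotypes. Uncalled genotypes are treated as
homozygous reference. N, the number of compared positions, is an explicit
input defaulting to the number of aligned sites: with real data the
callable-genome size is the meaningful denominator, and absolute π values
depend on it, so only the ordering of relation-class means (by kinship
coefficient: MT, then sibling/parent–child at 1/4, then
uncle–nephew/grandparent–grandchild at 1/8, cousins at 1/16, unrelated at
0) is treated as a testable property, not the magnitudes.

The embedding is classical (Torgerson) metric scaling — double-centering
of squared distances followed by eigendecomposition, eigenvalues clipped
at zero — chosen over iterative non-metric MDS because it is deterministic
and exactly recoverable on Euclidean inputs (the suite checks
reproduction to 1e-9 relative error). The distance is Canberra on dosage
vectors (0-vs-0 terms contribute nothing), after a MAF ≥ 0.05 / call-rate
pre-filter; linkage-based pruning is external to this package and is
approximated, when needed, by random thinning.

## Array concordance

Site presence means carrying ≥ 1 alternative allele; TP/FP/FN count
presence agreement over the shared (site, sample) grid, precision =
TP/(TP+FP), recall = TP over array-present genotypes. Genotype concordance
is the fraction of exactly matching diploid genotypes per sample or per
locus; missing genotypes on either side are excluded from numerator and
denominator (standard array-QC practice; an empty comparable set yields an
explicit undefined value, not zero). Per-locus concordances weighted by
comparable counts reproduce the overall concordance exactly.

## SV/CNV processing

Reciprocal overlap of two intervals is min(shared/len(a), shared/len(b)),
zero across chromosomes by contract. A call is spurious when any of three
gap-collision rules fires: reciprocal overlap > 0.10 with a single gap
interval; union gap coverage > 0.50 of the call; more than 2 distinct gap
blocks intersected. Rule (i) is evaluated per gap and rule (ii) on the
union, the two defensible readings of an ambiguous criterion; the removal
log records which rule(s) fired. The filter is idempotent and monotone in
the gap track.

Clustering is single-linkage over the graph whose edges are call pairs
(same chromosome and type) with reciprocal overlap above the threshold —
strictly above 0.7 for SVs, inclusively ≥ 0.7 for CNV merging
(`inclusive=True`), following the two conventions in circulation.
Single-linkage connected components are order-invariant, which the suite
verifies against an all-pairs union-find oracle. Unification averages
member starts and ends, rounding half away from zero so coordinates are
integral and bit-reproducible; the unified endpoints always lie within the
member ranges (the unified *length* need not). Carrier count is distinct
samples, not member calls. Novelty is the absence of any
compatible-type database interval at ≥ 70% reciprocal overlap
(deletion-type calls match loss records, duplication-type match gain).
ITX two-breakend records are handled as their spanning interval.

Repeat composition reports, per length bin and repeat class
(SINE/LINE/LTR/DNA/simple), the fraction of unified bases covered, with
overlapping annotations resolved by input-order precedence; a per-base
oracle on small instances checks the interval arithmetic. CNV enrichment
flags a unified CNV when against **any** continental group the
carrier-count odds ratio exceeds 10 with Fisher p < 0.01, and the cohort
has strictly more than five carriers.

## Prioritization cascade

Per individual, carried variants (≥ 1 alternative allele; hom-ref sites
are not part of an individual's variant set) are removed first when
panel-COMMON or LOW_FREQ, then when cohort-FREQUENT among the survivors;
removals plus survivors equal the carried total by construction, and the
rare set shrinks weakly as the cohort threshold decreases. Pathogenicity
consensus is "deleterious by at least one predictor"; all-missing
predictor rows are excluded as undefined rather than counted as benign.
Clinical significance strings are normalized case-insensitively through an
explicit table (unrecognized → VUS with a warning). Inheritance
interpretation: AR heterozygote → carrier only; AR homozygote or any AD
genotype → phenotype expected; unknown inheritance → uncertain.

## Synthetic data

The generators define the conditions under which the statistics are
validated:

* **Panel** — ancestral MAFs from 0.5·Beta(0.5, 0.5) (a U-shaped folded
  spectrum, most mass at low frequency); per-population frequencies from
  Balding–Nichols drift Beta(p(1−F)/F, (1−p)(1−F)/F), default F = 0.1 per
  group and 1000 chromosomes per group. F = 0 reproduces the ancestral
  frequency exactly, and the drift variance F·p(1−p) is recovered by a
  50-replicate Monte-Carlo moment check.
* **Cohort** — 50 diploid samples by default, mirroring a mid-size
  population-reference cohort. Each variant's true cohort frequency tracks
  the East-Asian-analog panel frequency; 25% of variants are targeted rare
  (expected alt count < 1), doubled to 50% inside coding sequence
  (multiplier 2.0) to emulate purifying selection; 20% of eligible
  variants are spiked to ≥ 3× their panel frequency; 20% of sites are
  absent from the panel. Genotypes are Binomial(2, f) per sample with
  optional symmetric single-allele error (het → random hom, hom → het) —
  the simplest error model that produces nonzero twin distances.
* **Pedigrees** — each requested pair is founded independently from panel
  frequencies and built by explicit Mendelian transmission, so MT pairs
  are identical and parent–child pairs share an allele at every site
  before error injection; the construction is acyclic by design.
* **Interval calls** — true loci (default 500–5000 bp) are placed clear of
  assembly gaps and shared across random sample subsets with endpoint
  jitter below 15% of length; spurious calls are placed so each of the
  three gap rules fires, and the truth table records cluster identity and
  spuriousness per call.
* **Array genotypes** — per-genotype replacement by one of the other two
  dosages with the given error rate, plus missingness.

All generators are pure functions of (spec, seed) via
`numpy.random.default_rng`; no global state.

What the synthetic data does **not** emulate: linkage disequilibrium
(sites are independent), sequencing-error/read-level structure, realistic
site-frequency spectra per population, genome-scale variant counts, or
real gap/repeat annotation geometry. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated models, not
end-to-end accuracy on real WGS cohorts; in particular, absolute π values,
RVR magnitudes and enrichment counts on real data depend on callable
genome size, caller error and LD, which are outside this package.

## Problem sizes and numerics

The validation suites run at desk scale by design: Fisher agreement is
enumerated exhaustively for group margins up to 30 (≈ 245k tables) against
an exact integer-arithmetic reference; type-I control uses 10,000 null
variants; power uses 1,000 spiked variants in a 200-sample cohort; kinship
ordering uses 20,000 sites with genotype error 1e-3 and ten replicate
pairs per relation; clustering oracles use ~200 jittered calls; MDS
separation uses three populations at Fst 0.05, 20 samples each, 1,500
sites. Tolerances follow the generating models (3 binomial standard errors
for rate recovery; 1e-9 for exact linear-algebra identities). Ties in the
two-sided Fisher sum are included via a 1e-7 relative slack; averaged SV
coordinates round half away from zero; degenerate inputs (empty panels,
all-missing samples, zero denominators) raise errors or return explicit
undefined flags rather than silent zeros.

## Known limitations

Enrichment testing loops per variant and is comfortable at tens of
thousands of variants, not tens of millions; the VCF writer emits GT only;
breakend-level SV semantics are reduced to spanning intervals; and the
prioritization cascade consumes externally computed effect and predictor
annotations without validating their provenance.
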