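"""End-to-end pipeline driver: simulate -> classify -> enrich -> relatedness
/ concordance / SV merge -> prioritize -> report, with a provenance manifest.

The run is a pure function of the configuration (which embeds the seed):
re-running with the same config yields byte-identical TSV outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import classify_2d, compute_rvr
from .datatypes import GeneModel, KnownSets
from .enrich import variant_enrichment, venn_partition
from .prioritize import rare_filter_cascade, summarize_individuals
from .relatedness import distance_matrix
from .report import report_cohort_summary
from .svcnv import cluster_calls, filter_spurious, unify_cluster
from .synthetic import (
    CohortSpec,
    GenomeModel,
    PanelSpec,
    gen_cohort,
    gen_interval_calls,
    gen_panel,
)
from .vcfio import annotate_cohort_regions, write_cohort_vcf, write_panel_tsv


@dataclass
class RunConfig:
    """Configuration of a demo end-to-end run on synthetic inputs."""

    out_dir: str
    seed: int = 0
    n_variants: int = 2000
    n_samples: int = 50
    fst: float = 0.1
    allele_number: int = 1000
    enriched_fraction: float = 0.2
    panel_absent_fraction: float = 0.2
    rare_fraction_coding_multiplier: float = 2.0
    cohort_threshold: int = 3
    common_maf: float = 0.05
    low_maf: float = 0.001
    or_threshold: float = 3.0
    p_threshold: float = 0.05
    sv_calls_per_sample: int = 20
    sv_samples: int = 5
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {k: raw.pop(k) for k in list(raw) if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra = raw
        return cfg

    def validate(self) -> None:
        if self.n_variants < 1 or self.n_samples < 2:
            raise ValueError("n_variants >= 1 and n_samples >= 2 required")
        for name in ("common_maf", "low_maf", "p_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _demo_gene_model(genome_length: int) -> GeneModel:
    """Alternating gene structure covering ~15% of the toy genome."""
    intervals = []
    gene_span = 50_000
    step = 200_000
    for start in range(0, genome_length - gene_span, step):
        intervals.append(("chr1", start, start + 2_000, "UTR"))
        pos = start + 2_000
        for _ in range(4):
            intervals.append(("chr1", pos, pos + 3_000, "coding"))
            intervals.append(("chr1", pos + 3_000, pos + 3_050, "splice_site"))
            intervals.append(("chr1", pos + 3_050, pos + 9_000, "intron"))
            pos += 9_000
        intervals.append(("chr1", pos, pos + 2_000, "UTR"))
    return GeneModel(intervals)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on generated inputs; returns the manifest dict.

    Every output TSV/VCF is written under ``config.out_dir`` and listed in
    ``manifest.json`` with its sha256 checksum, alongside versions, seeds
    and thresholds.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        df.to_csv(path, sep="\t", **kwargs)
        written.append(path)

    stage = "simulate"
    try:
        panel_spec = PanelSpec(
            n_variants=config.n_variants,
            fst=config.fst,
            allele_number=config.allele_number,
            seed=config.seed,
        )
        panel = gen_panel(panel_spec)
        gene_model = _demo_gene_model(panel_spec.genome_length)
        cohort_spec = CohortSpec(
            n_samples=config.n_samples,
            enriched_fraction=config.enriched_fraction,
            panel_absent_fraction=config.panel_absent_fraction,
            rare_fraction_coding_multiplier=config.rare_fraction_coding_multiplier,
            seed=config.seed + 1,
        )
        cohort, truth = gen_cohort(panel, cohort_spec, gene_model)
        write_panel_tsv(panel, out / "panel.tsv")
        written.append(out / "panel.tsv")
        write_cohort_vcf(cohort, out / "cohort.vcf")
        written.append(out / "cohort.vcf")
        save(truth, "truth.tsv")

        stage = "classify"
        classified, summary = classify_2d(
            cohort,
            panel,
            common_maf=config.common_maf,
            low_maf=config.low_maf,
            cohort_threshold=config.cohort_threshold,
        )
        save(classified, "classification.tsv")
        save(summary, "classification_summary.tsv", index=False)
        regions = annotate_cohort_regions(cohort, gene_model)
        save(regions, "regions.tsv")
        rvr = compute_rvr(classified, regions, by_effect=True)
        save(
            pd.DataFrame(
                [
                    {
                        "region": r.region_class,
                        "n_rare": r.n_rare,
                        "n_frequent": r.n_frequent,
                        "rvr": r.rvr,
                    }
                    for r in rvr
                ]
            ),
            "rvr.tsv",
            index=False,
        )

        stage = "enrich"
        keys = cohort.keys()
        counts = cohort.alt_allele_counts()
        totals = cohort.called_chromosomes()
        observed = counts > 0
        cohort_counts = pd.DataFrame(
            {"alt": counts[observed], "total": totals[observed]},
            index=pd.Index(keys[observed], name="key"),
        )
        panel_counts = {
            pop: pd.DataFrame(
                {
                    "alt": panel.table[f"AC_{pop}"],
                    "total": panel.table[f"AN_{pop}"],
                }
            )
            for pop in panel.populations
        }
        flags = variant_enrichment(
            cohort_counts,
            panel_counts,
            or_threshold=config.or_threshold,
            p_threshold=config.p_threshold,
        )
        save(flags, "enrichment_flags.tsv")
        venn = venn_partition(flags)
        venn_df = pd.DataFrame(
            {
                "groups": ["+".join(sorted(s)) for s in venn.index],
                "n_variants": venn.to_numpy(),
            }
        )
        save(venn_df.sort_values("groups"), "venn.tsv", index=False)

        stage = "relatedness"
        dist = distance_matrix(cohort, metric="pi")
        save(dist, "distance_pi.tsv")

        stage = "svmerge"
        genome = GenomeModel(
            chrom_lengths={"chr1": panel_spec.genome_length},
            gaps=tuple(
                ("chr1", s, s + 20_000)
                for s in range(
                    100_000, panel_spec.genome_length - 20_000, 1_000_000
                )
            ),
        )
        calls, sv_truth = gen_interval_calls(
            config.sv_calls_per_sample,
            genome,
            seed=config.seed + 2,
            n_samples=config.sv_samples,
        )
        passing, removal_log = filter_spurious(calls, genome.gaps)
        clusters = cluster_calls(passing)
        unified = [unify_cluster(c) for c in clusters]
        save(removal_log, "sv_removals.tsv", index=False)
        save(
            pd.DataFrame(
                [
                    {
                        "chrom": u.chrom,
                        "start": u.start,
                        "end": u.end,
                        "svtype": u.svtype,
                        "carriers": u.carrier_count,
                    }
                    for u in unified
                ]
            ),
            "sv_unified.tsv",
            index=False,
        )

        stage = "prioritize"
        reports, _rare = rare_filter_cascade(cohort, classified, regions)
        cascade = pd.DataFrame(
            [
                {
                    "sample": r.sample,
                    "total": r.total,
                    "removed_panel": r.removed_panel,
                    "removed_cohort_frequent": r.removed_cohort_frequent,
                    "remaining_rare": r.remaining_rare,
                }
                for r in reports
            ]
        )
        save(cascade, "cascade.tsv", index=False)
        save(summarize_individuals(reports), "cascade_summary.tsv")

        stage = "report"
        known = KnownSets(dbsnp_ids=set(), panel=panel)
        save(report_cohort_summary(cohort, known), "cohort_summary.tsv")
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "cohort_threshold": config.cohort_threshold,
            "common_maf": config.common_maf,
            "low_maf": config.low_maf,
            "or_threshold": config.or_threshold,
            "p_threshold": config.p_threshold,
        },
        "outputs": {p.name: _sha256(p) for p in written},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
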