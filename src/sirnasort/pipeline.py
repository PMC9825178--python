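"""End-to-end orchestration: reads -> catalog -> CE -> composition -> report.

The pure in-memory path (:func:`analyze`) is the unit the simulator-based
tests and the acceptance checks drive; :func:`run_end_to_end` wraps it with
file I/O, optional adapter trimming, and a JSON audit report of the counts
at every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import catalog as cat
from . import ce as ce_mod
from . import composition as comp_mod
from . import seqio

log = logging.getLogger("sirnasort")


class ConfigurationError(ValueError):
    """Invalid or missing configuration; raised before any computation."""


@dataclass(frozen=True)
class PipelineConfig:
    precursor_reads: str
    sirna_reads: str
    clusters_bed: str | None = None
    genome_fasta: str | None = None
    cluster_fasta: str | None = None  # alternative to BED + genome
    adapter: str | None = None  # None -> skip trimming
    min_overlap: int = 8
    min_read_length: int = 15
    catalog_params: cat.CatalogParams = field(default_factory=cat.CatalogParams)
    n_bins: int = 4
    g1_filters: tuple[str, ...] = ("A",)
    sirna_length_range: tuple[int, int] | None = None
    fractional: bool = False
    outdir: str = "sirnasort_out"

    def validate(self) -> None:
        if self.n_bins < 1:
            raise ConfigurationError("n_bins must be >= 1")
        for p in (self.precursor_reads, self.sirna_reads):
            if not Path(p).exists():
                raise ConfigurationError(f"input file not found: {p}")
        if self.cluster_fasta:
            if not Path(self.cluster_fasta).exists():
                raise ConfigurationError(f"input file not found: {self.cluster_fasta}")
        elif self.clusters_bed and self.genome_fasta:
            for p in (self.clusters_bed, self.genome_fasta):
                if not Path(p).exists():
                    raise ConfigurationError(f"input file not found: {p}")
        else:
            raise ConfigurationError(
                "cluster references require either cluster_fasta or clusters_bed + genome_fasta"
            )


@dataclass
class AnalysisResult:
    catalog_all: list[cat.P4RNA]
    catalog: list[cat.P4RNA]
    records: list[ce_mod.CERecord]
    composition_g1: comp_mod.CompositionTable
    stability: dict[str, comp_mod.StabilityClassTable]
    trends: dict[str, float]
    counts: dict[str, int]


def analyze(
    precursor_reads: Sequence[seqio.SmallRNARead],
    sirna_reads: Sequence[seqio.SmallRNARead],
    clusters: seqio.ReferenceSet,
    catalog_params: cat.CatalogParams | None = None,
    n_bins: int = 4,
    g1_filters: Sequence[str] = ("A",),
    sirna_length_range: tuple[int, int] | None = None,
    fractional: bool = False,
) -> AnalysisResult:
    """Catalog construction, CE binning and composition in memory."""
    mapped = seqio.map_reads_bulk(precursor_reads, clusters)
    candidates = cat.collapse_by_five_prime(mapped)
    kept = cat.filter_catalog(candidates, catalog_params)
    if len(kept) < n_bins:
        raise ValueError(
            f"only {len(kept)} species survive the filters; cannot form {n_bins} bins"
        )
    counts = ce_mod.count_anchored_sirnas(
        kept, sirna_reads, fractional=fractional, length_range=sirna_length_range
    )
    records = ce_mod.assign_bins(ce_mod.compute_ce(counts, kept), n_bins=n_bins)
    composition_g1 = comp_mod.positional_frequency(records, position=1)
    stability = {g1: comp_mod.stability_bias(records, g1) for g1 in g1_filters}
    trends: dict[str, float] = {}
    if n_bins >= 2:
        for nt in comp_mod.NUCLEOTIDES:
            trends[f"g1_{nt}"] = comp_mod.trend_summary(composition_g1, nt)
        for g1, table in stability.items():
            try:
                trends[f"g2_weak_given_g1_{g1}"] = comp_mod.trend_summary(table, "weak")
            except ValueError:
                log.warning("g2 trend for g1=%s skipped: fewer than 2 populated bins", g1)
    mapped_read_ids = {r.id for r, _ in mapped}
    counts_report = {
        "precursor_species_in": len(precursor_reads),
        "precursor_reads_in": sum(r.count for r in precursor_reads),
        "precursor_species_mapped": len(mapped_read_ids),
        "precursor_reads_mapped": sum(
            r.count for r in precursor_reads if r.id in mapped_read_ids
        ),
        "species_pre_filter": len(candidates),
        "species_post_filter": len(kept),
        "sirna_species_in": len(sirna_reads),
        "sirna_reads_in": sum(r.count for r in sirna_reads),
        **{
            f"bin_{b}_n": c.n
            for b, c in sorted(composition_g1.bins.items())
        },
    }
    return AnalysisResult(
        catalog_all=candidates,
        catalog=kept,
        records=records,
        composition_g1=composition_g1,
        stability=stability,
        trends=trends,
        counts=counts_report,
    )


def trim_reads(
    reads: Sequence[seqio.SmallRNARead],
    adapter: str,
    min_overlap: int = 8,
    min_length: int = 15,
) -> tuple[list[seqio.SmallRNARead], dict[str, int]]:
    """Trim all reads; discards those falling below the length floor."""
    kept: list[seqio.SmallRNARead] = []
    n_trimmed = n_discarded = 0
    for r in reads:
        res = seqio.trim_adapter(r, adapter, min_overlap=min_overlap, min_length=min_length)
        if res.trimmed:
            n_trimmed += 1
        if res.read is None:
            n_discarded += 1
        else:
            kept.append(res.read)
    return kept, {"reads_trimmed": n_trimmed, "reads_discarded_short": n_discarded}


def run_end_to_end(config: PipelineConfig) -> dict:
    """Run the full analysis from files and write all declared outputs.

    Returns the report dict (also written as ``report.json``).  Identical
    inputs and configuration give identical outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("reading inputs")
    precursors = seqio.read_small_rnas(config.precursor_reads)
    sirnas = seqio.read_small_rnas(config.sirna_reads)
    if config.cluster_fasta:
        clusters = seqio.read_fasta_references(config.cluster_fasta, kind="cluster")
    else:
        clusters = seqio.read_cluster_references(config.clusters_bed, config.genome_fasta)

    trim_stats: dict[str, int] = {}
    if config.adapter:
        log.info("trimming 3' adapter")
        precursors, s1 = trim_reads(
            precursors, config.adapter, config.min_overlap, config.min_read_length
        )
        sirnas, s2 = trim_reads(
            sirnas, config.adapter, config.min_overlap, config.min_read_length
        )
        trim_stats = {f"precursor_{k}": v for k, v in s1.items()}
        trim_stats.update({f"sirna_{k}": v for k, v in s2.items()})

    try:
        result = analyze(
            precursors,
            sirnas,
            clusters,
            catalog_params=config.catalog_params,
            n_bins=config.n_bins,
            g1_filters=config.g1_filters,
            sirna_length_range=config.sirna_length_range,
            fractional=config.fractional,
        )
    except Exception as exc:
        raise RuntimeError(f"analysis stage failed: {exc}") from exc

    files = {
        "catalog_tsv": "catalog.tsv",
        "catalog_fasta": "catalog.fasta",
        "ce_tsv": "ce_table.tsv",
        "composition_g1_tsv": "composition_g1.tsv",
    }
    cat.write_catalog_tsv(result.catalog, outdir / files["catalog_tsv"])
    cat.write_catalog_fasta(result.catalog, outdir / files["catalog_fasta"])
    ce_mod.write_ce_tsv(result.records, outdir / files["ce_tsv"])
    comp_mod.write_composition_tsv(result.composition_g1, outdir / files["composition_g1_tsv"])
    for g1, table in result.stability.items():
        name = f"stability_g1_{g1}.tsv"
        files[f"stability_{g1}_tsv"] = name
        comp_mod.write_composition_tsv(table, outdir / name)

    report = {
        "config": {
            "precursor_reads": config.precursor_reads,
            "sirna_reads": config.sirna_reads,
            "adapter": config.adapter,
            "n_bins": config.n_bins,
            "g1_filters": list(config.g1_filters),
            "min_length_exclusive": config.catalog_params.min_length_exclusive
            if config.catalog_params
            else cat.CatalogParams().min_length_exclusive,
            "min_reads_exclusive": config.catalog_params.min_reads_exclusive
            if config.catalog_params
            else cat.CatalogParams().min_reads_exclusive,
        },
        "counts": {**trim_stats, **result.counts},
        "trends": result.trends,
        "files": files,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("report written to %s", outdir / "report.json")
    return report
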