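"""Config-driven orchestration of the analysis stages.

Thin glue over the library modules: validates a configuration, runs the
stages (simulate -> curate -> annotate -> landscape -> gene-context ->
regulation), echoes every threshold into output headers, and writes a
machine-readable manifest with checksums so a run is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import annotation as ann
from . import formats, genecontext, landscape, regulation
from . import curation as cur
from . import simulate as sim

__all__ = ["PipelineConfig", "validate", "run_demo"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds, defaulting to the study's printed values."""

    seed: int = 0
    out_dir: str = "mobilome_out"
    intact_max_divergence: float = 20.0
    intact_min_coverage: float = 0.80
    tandem_overlap_threshold: float = 0.60
    cluster_identity: float = 0.80
    cluster_coverage: float = 0.80
    dedup_identity: float = 0.95
    dedup_coverage: float = 0.95
    te_gene_filter: float = 0.70
    proximal_bp: int = 500
    copy_proximal_fraction: float = 0.01
    read_min_nt: int = 20
    read_max_nt: int = 24
    count_prefilter: int = 10
    window_bp: int = 100_000
    sdr_window_bp: int = 50_000
    subtelomere_window_bp: int = 5_000
    metaprofile_bin_bp: int = 10
    metaprofile_flank_bp: int = 10_000
    metaprofile_body_bp: int = 1_000
    ltr_max_gap: int = 500

    def provenance(self) -> dict:
        return asdict(self)


def validate(config: PipelineConfig) -> list:
    """Return a list of configuration problems (empty when valid)."""
    errors = []
    if config.proximal_bp < 0:
        errors.append("proximal_bp must be non-negative")
    for name in ("cluster_identity", "cluster_coverage", "dedup_identity",
                 "dedup_coverage", "te_gene_filter", "tandem_overlap_threshold",
                 "intact_min_coverage", "copy_proximal_fraction"):
        v = getattr(config, name)
        if not 0 < v <= 1:
            errors.append(f"{name} must be in (0, 1]")
    if not 0 < config.intact_max_divergence <= 100:
        errors.append("intact_max_divergence must be in (0, 100]")
    if config.read_min_nt > config.read_max_nt:
        errors.append("read_min_nt exceeds read_max_nt")
    for name in ("window_bp", "sdr_window_bp", "subtelomere_window_bp",
                 "metaprofile_bin_bp", "metaprofile_flank_bp", "metaprofile_body_bp"):
        if getattr(config, name) <= 0:
            errors.append(f"{name} must be positive")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_demo(seed: int = 0, out_dir: str | Path = "mobilome_demo",
             config: PipelineConfig | None = None,
             sim_config: sim.SimulationConfig | None = None) -> dict:
    """Full synthetic end-to-end run; returns the manifest dict.

    Simulates a multi-megabase genome with planted parameters, then runs
    library curation, copy annotation, compartment landscape, gene-context
    and regulation-association stages, writing TSV/JSON outputs plus a
    manifest with checksums.  Deterministic given the seed.
    """
    cfg = config or PipelineConfig(seed=seed)
    problems = validate(cfg)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = cfg.provenance()
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "parameters": meta,
        "stages": {},
        "outputs": {},
    }

    def record(stage, **results):
        manifest["stages"][stage] = results

    t0 = time.time()
    scfg = sim_config or sim.default_config(seed=seed)
    result = sim.plant_genome(scfg)
    truth = sim.plant_regulation(result.truth.copies, scfg.srna_plan, scfg.peak_plan, seed + 1)
    peaks = sim.simulate_peaks(truth, scfg.peak_plan, seed + 2, result.chrom_lengths)
    reads_by_stage = {
        stage: sim.simulate_reads(truth, scfg.srna_plan, stage, seed + 3 + i,
                                  result.genome, result.chrom_lengths)
        for i, stage in enumerate(scfg.srna_plan.stages)
    }
    formats.write_fasta(
        {f"{r.id}#{r.classification}": r.sequence for r in result.library},
        out / "library.fa",
    )
    formats.write_repeatmasker_out(result.hits, out / "hits.out")
    formats.write_gff3(result.genes, out / "genes.gff3")
    formats.write_bed(result.compartments.intervals, out / "compartments.bed")
    formats.write_bed(result.tandem, out / "tandem.bed")
    formats.write_tsv(truth, out / "truth_copies.tsv", meta)
    formats.write_tsv(result.truth.genes, out / "truth_genes.tsv", meta)
    record("simulate", n_copies=len(truth), n_genes=len(result.truth.genes),
           n_reads=sum(len(r) for r in reads_by_stage.values()), n_peaks=len(peaks),
           elapsed_s=round(time.time() - t0, 2))

    # --- library curation
    t0 = time.time()
    clusters80 = cur.cluster_library(result.library, cfg.cluster_identity, cfg.cluster_coverage)
    reclassified, conflicts = cur.reclassify_by_cluster(clusters80, result.library)
    clusters95 = cur.cluster_library(reclassified, cfg.dedup_identity, cfg.dedup_coverage)
    library, removed = cur.deduplicate(reclassified, clusters95)
    formats.write_tsv(
        pd.DataFrame(
            [(c.representative, ",".join(c.members)) for c in clusters80],
            columns=["representative", "members"],
        ),
        out / "clusters_80.tsv", meta,
    )
    record("curate_library", n_clusters_80=len(clusters80), n_conflicts=len(conflicts),
           n_removed=len(removed), n_final=len(library),
           elapsed_s=round(time.time() - t0, 2))

    # --- copy annotation
    t0 = time.time()
    consensus_lengths = {r.id: r.length for r in result.library}
    copies = ann.merge_fragments(result.hits, consensus_lengths)
    annotation = ann.resolve_precedence(copies, result.tandem)
    genome_size = sum(result.chrom_lengths.values())
    summary = ann.summarize_by_superfamily(annotation, genome_size)
    formats.write_tsv(summary, out / "superfamily_summary.tsv", meta)
    land = ann.divergence_landscape(copies)
    formats.write_tsv(land, out / "divergence_landscape.tsv", meta)
    record("annotate_copies", n_copies=len(copies),
           te_bp=annotation.total_te_bp(),
           te_genome_pct=round(annotation.total_te_bp() / genome_size * 100, 2),
           elapsed_s=round(time.time() - t0, 2))

    # --- landscape
    t0 = time.time()
    genes = result.genes
    cds_by_chrom: dict = {}
    for g in genes:
        for tx in g.transcripts:
            cds_by_chrom.setdefault(g.chrom, []).extend(tx.cds)
    windows = landscape.make_windows(result.chrom_lengths, cfg.window_bp)
    wstats = landscape.window_density(annotation, windows, cds_by_chrom, result.compartments)
    formats.write_tsv(wstats, out / "window_stats.tsv", meta)
    # small compartments get the finer window size for the between-group test
    cmp_stats = wstats
    counts = wstats[~wstats["partial"]]["compartment"].value_counts()
    if (counts < 4).any() and cfg.sdr_window_bp < cfg.window_bp:
        fine = landscape.make_windows(result.chrom_lengths, cfg.sdr_window_bp)
        cmp_stats = landscape.window_density(annotation, fine, cds_by_chrom,
                                             result.compartments)
    full = cmp_stats[~cmp_stats["partial"]]
    sizes = full["compartment"].value_counts()
    usable = sizes[sizes >= 2].index
    report = None
    if len(usable) >= 2:
        report = landscape.compare_compartments(full[full["compartment"].isin(usable)])
    ratios = {
        label: landscape.cut_copy_ratio(annotation, result.compartments.by_label(label))
        for label in result.compartments.labels()
        if label not in ("centromere", "subtelomere_anchor")
    }
    enrich = landscape.superfamily_enrichment(annotation, result.compartments)
    formats.write_tsv(enrich, out / "superfamily_enrichment.tsv", meta)
    record("landscape",
           compartment_test=(
               {"test": report.test, "statistic": report.statistic,
                "p_value": report.p_value}
               if report is not None else "skipped: fewer than two usable groups"
           ),
           cut_copy_ratios={k: (None if not v["defined"] else round(v["ratio"], 4))
                            for k, v in ratios.items()},
           mean_density_by_compartment={
               k: round(float(v), 4)
               for k, v in wstats[~wstats["partial"]].groupby("compartment")["te_density"].mean().items()
           },
           elapsed_s=round(time.time() - t0, 2))

    # --- gene context
    t0 = time.time()
    kept_genes, removed_tx = genecontext.filter_te_genes(genes, annotation, cfg.te_gene_filter)
    partition = genecontext.partition_site_classes(kept_genes, result.chrom_lengths, cfg.proximal_bp)
    density = genecontext.site_class_density(annotation, partition)
    formats.write_tsv(density, out / "site_class_density.tsv", meta)
    site_classes = [
        genecontext.assign_copy_site_class(c, partition, cfg.copy_proximal_fraction)
        for c in copies
    ]
    record("gene_context", n_genes_kept=len(kept_genes), n_tx_removed=len(removed_tx),
           te_fraction_by_class={r.site_class: round(r.te_fraction, 4)
                                 for r in density.itertuples()},
           elapsed_s=round(time.time() - t0, 2))

    # --- regulation
    t0 = time.time()
    filtered = {
        stage: regulation.filter_reads_by_length(r, cfg.read_min_nt, cfg.read_max_nt)
        for stage, r in reads_by_stage.items()
    }
    assoc = regulation.build_association_table(copies, filtered, peaks,
                                               site_classes=site_classes)
    formats.write_tsv(assoc, out / "association_table.tsv", meta)
    flags = regulation.flag_srna_associated(assoc)
    inter = regulation.intersection_stats(assoc)
    count_cols = [c for c in assoc.columns if c.startswith("count_")]
    prefiltered = regulation.prefilter_counts(
        assoc.set_index("copy_id")[count_cols], cfg.count_prefilter
    )
    formats.write_tsv(prefiltered.reset_index(), out / "count_matrix_prefiltered.tsv", meta)
    record("regulation",
           srna=flags,
           peak_overlap_intact=float(assoc.loc[assoc["intact"], "peak_associated"].mean()),
           peak_overlap_nonintact=float(assoc.loc[~assoc["intact"], "peak_associated"].mean()),
           p_srna_given_peak_intact=inter["intact"]["p_srna_given_peak"],
           n_prefiltered=len(prefiltered),
           elapsed_s=round(time.time() - t0, 2))

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
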