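"""Synthetic mobilome with planted, recoverable parameters.

Generates genomes, TE libraries, copy annotations, gene models, small-RNA
alignments and broad peaks whose true parameters are recorded in a truth
table, so that every downstream stage of the pipeline can be validated
without external data.  The default configuration reproduces the study
conditions of the system this package models: compartment TE densities of
0.22 (autosomes), 0.39 (PARs), 0.51 (male SDR) and 0.65 (female SDR),
cut:copy base ratios of 0.48 / 0.71 / 0.79 / 0.52, a divergence mixture
placing ~53% of TE bp below 5% divergence, a compact gene space with
median intergenic tracts of ~1.3 kb and ~524-bp introns, 20-24 nt sRNA
reads with a 21-nt mode and a 0.8 probability of a 5' U, preferential sRNA
coverage of intact copies (0.647 vs 0.218), and broad peaks on 30.2% of
intact vs 23.1% of non-intact copies with a 0.736 conditional sRNA
probability on peak-marked intact copies.

Divergence is substitution-only by default so the realized value has a
closed binomial form; reads are emitted directly as alignments (mapping is
out of scope).  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import TECopy, classify_intact, mechanism_of
from .curation import ConsensusRecord
from .formats import (
    GeneModel,
    Interval,
    ReadAlignment,
    RepeatHit,
    Transcript,
    classification_subclass,
)
from .landscape import CompartmentMap

__all__ = [
    "FamilyPlan",
    "ChromPlan",
    "GenePlan",
    "SrnaPlan",
    "PeakPlan",
    "SimulationConfig",
    "TruthTable",
    "SimulationResult",
    "default_config",
    "simulate_library",
    "mutate_copy",
    "plant_genome",
    "plant_regulation",
    "simulate_peaks",
    "simulate_reads",
    "simulate_copy_set",
    "simulate_family_expression",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class FamilyPlan:
    family_id: str
    classification: str  # "Class/Superfamily"
    consensus_length: int
    autonomous: bool = True

    @property
    def mechanism(self) -> str:
        return mechanism_of(self.classification)


@dataclass(frozen=True)
class ChromPlan:
    chrom_id: str
    length: int
    segments: tuple  # of (label, start, end)
    anchor: tuple | None = None  # (position, '+'|'-') subtelomere anchor


@dataclass(frozen=True)
class GenePlan:
    enabled: bool = True
    span_fraction_cap: float = 0.60  # hard cap on genic span per segment
    exon_count: tuple = (2, 8)
    exon_len_median: int = 230
    intron_len_median: int = 524
    intergenic_median: int = 1302
    # occasional gene-free "repeat island" gaps keep the intergenic median
    # near the typical tract length while leaving room for giant elements
    island_prob: float = 0.10
    island_median: int = 10000
    utr_len: tuple = (80, 250)
    mono_exonic_prob: float = 0.10


@dataclass(frozen=True)
class SrnaPlan:
    stages: tuple = ("vegetative_gametophyte", "fertile_gametophyte", "gametes")
    p_covered_intact: float = 0.647
    p_covered_nonintact: float = 0.218
    p_covered_intact_peak: float | None = 0.736  # conditional coupling
    mean_reads_per_copy: float = 8.0
    length_probs: tuple = ((20, 0.13), (21, 0.50), (22, 0.15), (23, 0.12), (24, 0.10))
    u5_prob: float = 0.8
    background_fraction: float = 0.05


@dataclass(frozen=True)
class PeakPlan:
    p_peak_intact: float = 0.302
    p_peak_nonintact: float = 0.231
    # flanks default to zero so a peak never leaks onto a neighbouring
    # copy, keeping the planted association probabilities recoverable
    flank_mean: int = 0
    body_fraction: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chrom_plan: tuple = ()
    family_plan: tuple = ()
    density_targets: dict = field(default_factory=dict)
    cut_copy_targets: dict = field(default_factory=dict)
    # divergence mixture: young copies uniform on [0, young_max), the rest
    # uniform on [young_max, old_max)
    young_fraction: float = 0.53
    young_max_divergence: float = 5.0
    old_max_divergence: float = 30.0
    truncation_prob: float = 0.30
    truncation_mean_frac: float = 0.30
    truncation_max_frac: float = 0.90
    unknown_bp_fraction: float = 0.05
    fragment_prob: float = 0.10
    tandem_fraction: float = 0.03
    # introns attract insertions more than their size share alone would
    # give, emulating the observed high intronic TE content
    intron_placement_bias: float = 3.0
    gene_plan: GenePlan = field(default_factory=GenePlan)
    srna_plan: SrnaPlan = field(default_factory=SrnaPlan)
    peak_plan: PeakPlan = field(default_factory=PeakPlan)
    emit_sequence: bool = True
    subtelomere_boost: tuple | None = None  # (extent_bp, density)


def default_families() -> tuple:
    return (
        FamilyPlan("Copia-1_sim", "LTR/Copia", 5000),
        FamilyPlan("Gypsy-1_sim", "LTR/Gypsy", 6000),
        FamilyPlan("RTEX-1_sim", "LINE/RTE-X", 3000),
        FamilyPlan("RTEXN-1_sim", "LINE/RTE-X", 600, autonomous=False),
        FamilyPlan("Ngaro-1_sim", "DIRS/Ngaro", 5000),
        FamilyPlan("Chlamys-1_sim", "PLE/Chlamys", 3000),
        FamilyPlan("Helitron-1_sim", "Helitron/Helitron", 4000),
        FamilyPlan("TcMar-1_sim", "DNA/Mariner-Tc1", 4400),
        FamilyPlan("TcMarN-1_sim", "DNA/Mariner-Tc1", 300, autonomous=False),
        FamilyPlan("Harbinger-1_sim", "DNA/Harbinger", 3000),
        FamilyPlan("KDZ-1_sim", "DNA/KDZ", 12000),
        FamilyPlan("EnSpm-1_sim", "DNA/EnSpm", 8000),
        FamilyPlan("Unknown-1_sim", "Unknown", 1000),
    )


def default_chromosomes(include_female_sdr: bool = False) -> tuple:
    chroms = [
        ChromPlan("chr1", 2_000_000, (("autosome", 0, 2_000_000),)),
        ChromPlan("chr2", 1_500_000, (("autosome", 0, 1_500_000),)),
        ChromPlan(
            "chrV",
            1_500_000,
            (
                ("PAR", 0, 600_000),
                ("SDR_male", 600_000, 1_100_000),
                ("PAR", 1_100_000, 1_500_000),
            ),
        ),
    ]
    if include_female_sdr:
        chroms.append(ChromPlan("chrU", 500_000, (("SDR_female", 0, 500_000),)))
    return tuple(chroms)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    cfg = SimulationConfig(
        seed=seed,
        chrom_plan=default_chromosomes(),
        family_plan=default_families(),
        density_targets={
            "autosome": 0.22,
            "PAR": 0.39,
            "SDR_male": 0.51,
            "SDR_female": 0.65,
        },
        cut_copy_targets={
            "autosome": 0.48,
            "PAR": 0.71,
            "SDR_male": 0.79,
            "SDR_female": 0.52,
        },
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class TruthTable:
    """Planted ground truth: one row per emitted copy / gene."""

    copies: pd.DataFrame
    genes: pd.DataFrame


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: dict | None  # chrom -> sequence string
    chrom_lengths: dict
    library: list  # of ConsensusRecord
    hits: list  # of RepeatHit
    genes: list  # of GeneModel
    tandem: list  # of Interval
    compartments: CompartmentMap
    truth: TruthTable

    def te_copies(self) -> list:
        """Truth copies materialized as TECopy objects (one per link group)."""
        from .annotation import merge_fragments

        lengths = {r.id: r.length for r in self.library}
        return merge_fragments(self.hits, lengths)


# ------------------------------------------------------------- sequences


def _random_seq_array(rng, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n, dtype=np.int64)]


def simulate_library(family_plan, seed: int = 0) -> list:
    """Random consensus sequences, one per planned family."""
    plans = list(family_plan)
    if not plans:
        raise ValueError("family plan is empty")
    ids = [p.family_id for p in plans]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate family_id in family plan")
    rng = np.random.default_rng(seed)
    out = []
    for p in plans:
        seq = _random_seq_array(rng, p.consensus_length).tobytes().decode()
        out.append(ConsensusRecord(p.family_id, seq, p.classification, curated=False))
    return out


def mutate_copy(
    consensus: str, divergence: float, truncation: int, seed: int | np.random.Generator = 0
) -> tuple[str, float]:
    """Substitute per site with probability divergence/100, then 5'-truncate.

    Returns the copy sequence (beginning at consensus position
    ``truncation``) and the realized divergence (% mismatches over the
    surviving aligned length).
    """
    if not 0 <= divergence <= 50:
        raise ValueError("divergence must be in [0, 50]")
    if truncation >= len(consensus):
        raise ValueError("truncation must be shorter than the consensus")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = _CODE[np.frombuffer(consensus.encode(), dtype=np.uint8)]
    hit = rng.random(codes.shape[0]) < divergence / 100.0
    shift = rng.integers(1, 4, codes.shape[0], dtype=np.int64)
    mutated = np.where(hit, (codes + shift) % 4, codes)
    kept = mutated[truncation:]
    mismatches = int(hit[truncation:].sum())
    realized = 100.0 * mismatches / kept.shape[0]
    return _BASES[kept].tobytes().decode(), realized


_RC = {0: 3, 1: 2, 2: 1, 3: 0}


def _revcomp_codes(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


# ------------------------------------------------------------- genes


def _make_gene(rng, plan: GenePlan, chrom: str, pos: int, limit: int, gid: str):
    strand = "+" if rng.random() < 0.5 else "-"
    mono = rng.random() < plan.mono_exonic_prob
    n_exons = 1 if mono else int(rng.integers(plan.exon_count[0], plan.exon_count[1] + 1))
    exon_lens = np.maximum(
        60, rng.lognormal(np.log(plan.exon_len_median), 0.5, n_exons)
    ).astype(int)
    intron_lens = np.maximum(
        80, rng.lognormal(np.log(plan.intron_len_median), 0.6, max(n_exons - 1, 0))
    ).astype(int)
    exons = []
    cur = pos
    for i in range(n_exons):
        exons.append((cur, cur + int(exon_lens[i])))
        cur += int(exon_lens[i])
        if i < n_exons - 1:
            cur += int(intron_lens[i])
    if cur > limit:
        return None
    u5 = int(rng.integers(*plan.utr_len))
    u3 = int(rng.integers(*plan.utr_len))
    first, last = exons[0], exons[-1]
    if n_exons == 1:  # both UTRs share the exon; keep >=30 bp of CDS
        cap = (first[1] - first[0] - 30) // 2
        u5, u3 = min(u5, cap), min(u3, cap)
    elif strand == "+":  # UTR5 on first exon, UTR3 on last
        u5 = min(u5, first[1] - first[0] - 30)
        u3 = min(u3, last[1] - last[0] - 30)
    else:  # UTR5 on last exon, UTR3 on first
        u5 = min(u5, last[1] - last[0] - 30)
        u3 = min(u3, first[1] - first[0] - 30)
    u5, u3 = max(u5, 0), max(u3, 0)
    if strand == "+":
        utr5 = [(first[0], first[0] + u5)]
        utr3 = [(last[1] - u3, last[1])]
    else:
        utr5 = [(last[1] - u5, last[1])]
        utr3 = [(first[0], first[0] + u3)]
    if n_exons == 1:
        lo = first[0] + (u5 if strand == "+" else u3)
        hi = first[1] - (u3 if strand == "+" else u5)
        cds = [(lo, hi)]
    else:
        cds = []
        for i, (s, e) in enumerate(exons):
            s2, e2 = s, e
            if i == 0:
                s2 = s + (u5 if strand == "+" else u3)
            if i == n_exons - 1:
                e2 = e - (u3 if strand == "+" else u5)
            if s2 < e2:
                cds.append((s2, e2))
    tx = Transcript(f"{gid}.1", gid, chrom, strand, exons=exons, cds=cds, utr5=utr5, utr3=utr3)
    return GeneModel(gid, chrom, strand, [tx])


# --------------------------------------------------------- copy drawing


def _draw_divergence(rng, cfg: SimulationConfig) -> float:
    if rng.random() < cfg.young_fraction:
        return float(rng.uniform(0.0, cfg.young_max_divergence))
    return float(rng.uniform(cfg.young_max_divergence, cfg.old_max_divergence))


def _draw_truncation(rng, cfg: SimulationConfig, length: int) -> int:
    if rng.random() >= cfg.truncation_prob:
        return 0
    t = int(rng.exponential(cfg.truncation_mean_frac * length))
    return min(t, int(cfg.truncation_max_frac * length))


class _FreeSpace:
    """Non-overlapping free segments with origin tags, for TE placement."""

    def __init__(self):
        self.pieces = []  # (start, end, origin, gene_id)

    def add(self, start, end, origin, gene_id=""):
        if end - start >= 50:
            self.pieces.append([start, end, origin, gene_id])

    def largest(self) -> int:
        return max((p[1] - p[0] for p in self.pieces), default=0)

    def place(self, rng, length, intron_bias: float = 1.0):
        """Pick a slot for a copy of ``length``; returns (start, origin, gene_id)."""
        fits = [i for i, p in enumerate(self.pieces) if p[1] - p[0] >= length]
        if not fits:
            return None
        weights = np.array(
            [
                (self.pieces[i][1] - self.pieces[i][0] - length + 1)
                * (intron_bias if self.pieces[i][2] == "intron" else 1.0)
                for i in fits
            ],
            dtype=float,
        )
        pick = fits[int(rng.choice(len(fits), p=weights / weights.sum()))]
        s, e, origin, gid = self.pieces.pop(pick)
        offset = int(rng.integers(0, e - s - length + 1))
        start = s + offset
        self.add(s, start, origin, gid)
        self.add(start + length, e, origin, gid)
        return start, origin, gid


# ------------------------------------------------------------- planting


def plant_genome(config: SimulationConfig):
    """Generate the full synthetic dataset for one configuration.

    Returns a :class:`SimulationResult` whose truth table records, for
    every planted copy, its family, realized divergence, truncation,
    consensus coverage, intact status, compartment and site class.
    """
    for label, f in config.density_targets.items():
        if f >= 0.95:
            raise ValueError(f"density target {f} for {label} is infeasible (>= 0.95)")
        if f < 0:
            raise ValueError("density targets must be non-negative")
    rng = np.random.default_rng(config.seed)
    library = simulate_library(config.family_plan, seed=int(rng.integers(2**31)))
    consensus = {r.id: _CODE[np.frombuffer(r.sequence.encode(), np.uint8)] for r in library}
    fam_by_id = {p.family_id: p for p in config.family_plan}

    cut_fams = [p for p in config.family_plan if p.mechanism == "cut"]
    copy_fams = [p for p in config.family_plan if p.mechanism == "copy"]
    unk_fams = [p for p in config.family_plan if p.mechanism == "unknown"]

    genome: dict = {}
    chrom_lengths: dict = {}
    hits: list = []
    genes: list = []
    tandem: list = []
    comp_intervals: list = []
    copy_rows: list = []
    gene_rows: list = []
    link_counter = 0
    gene_counter = 0

    for chrom in config.chrom_plan:
        chrom_lengths[chrom.chrom_id] = chrom.length
        seq = _random_seq_array(rng, chrom.length) if config.emit_sequence else None
        units = _planting_units(chrom, config)
        for label, seg_start, seg_end, te_frac in units:
            seg_len = seg_end - seg_start
            free = _FreeSpace()
            intron_map: dict = {}
            # genes first: sequential layout; intergenic gaps are a mixture
            # of typical tracts (median ~1.3 kb) and occasional gene-free
            # "repeat island" gaps that host the giant elements
            gene_span_bp = 0
            gp = config.gene_plan

            def draw_gap():
                if rng.random() < gp.island_prob:
                    return int(rng.lognormal(np.log(gp.island_median), 0.5))
                return int(rng.lognormal(np.log(gp.intergenic_median), 0.6))

            if gp.enabled:
                pos = seg_start + draw_gap()
                prev_end = seg_start
                while pos < seg_end - 2000 and gene_span_bp < gp.span_fraction_cap * seg_len:
                    gene_counter += 1
                    g = _make_gene(rng, gp, chrom.chrom_id, pos, seg_end, f"g{gene_counter:05d}")
                    if g is None:
                        break
                    lo, hi = g.span
                    genes.append(g)
                    gene_span_bp += hi - lo
                    free.add(prev_end, lo, "intergenic")
                    for s, e in g.transcripts[0].introns:
                        free.add(s, e, "intron", g.gene_id)
                        intron_map.setdefault(g.gene_id, []).append((s, e))
                    cds_bp = sum(e - s for s, e in g.transcripts[0].cds)
                    gene_rows.append(
                        {
                            "gene_id": g.gene_id,
                            "chrom": chrom.chrom_id,
                            "start": lo,
                            "end": hi,
                            "strand": g.strand,
                            "mono_exonic": g.mono_exonic,
                            "cds_bp": cds_bp,
                            "compartment": label,
                        }
                    )
                    prev_end = hi
                    pos = hi + draw_gap()
                free.add(prev_end, seg_end, "intergenic")
            else:
                free.add(seg_start, seg_end, "intergenic")
            # TE planting: bp budgets per mechanism hit the compartment
            # density and cut:copy targets; a drawn copy that does not fit
            # any free slot is 5'-truncated to the largest available slot,
            # so budgets are met exactly (to ~50 bp) wherever feasible
            te_target = int(te_frac * seg_len)
            unk_target = int(config.unknown_bp_fraction * te_target) if unk_fams else 0
            mech_target = te_target - unk_target
            r = config.cut_copy_targets.get(label, 0.5)
            cut_target = int(mech_target * r / (1.0 + r)) if cut_fams else 0
            copy_target = mech_target - cut_target if copy_fams else 0
            budgets = {"cut": cut_target, "copy": copy_target, "unknown": unk_target}
            pools = {"cut": cut_fams, "copy": copy_fams, "unknown": unk_fams}
            while True:
                mech = max(budgets, key=lambda m: budgets[m])
                if budgets[mech] < 50 or free.largest() < 50:
                    break
                fams = pools[mech]
                fam = fams[int(rng.integers(0, len(fams)))]
                trunc = _draw_truncation(rng, config, fam.consensus_length)
                glen = fam.consensus_length - trunc
                cap = min(budgets[mech], free.largest())
                if glen > cap:
                    trunc = fam.consensus_length - cap
                    glen = cap
                div = _draw_divergence(rng, config)
                slot = free.place(rng, glen, config.intron_placement_bias)
                if slot is None:  # pragma: no cover - cap guarantees a fit
                    break
                budgets[mech] -= glen
                start, origin, host_gene = slot
                strand = "+" if rng.random() < 0.5 else "-"
                link_counter += 1
                mutated, realized = _mutate_codes(rng, consensus[fam.family_id], div, trunc)
                if seq is not None:
                    ins = _revcomp_codes(mutated) if strand == "-" else mutated
                    seq[start : start + glen] = _BASES[ins]
                frag_hits = _emit_hits(
                    rng, config, fam, chrom.chrom_id, start, glen, trunc, realized,
                    strand, link_counter,
                )
                hits.extend(frag_hits)
                coverage = glen / fam.consensus_length
                copy_rows.append(
                    {
                        "copy_id": f"{chrom.chrom_id}:{link_counter}",
                        "chrom": chrom.chrom_id,
                        "start": start,
                        "end": start + glen,
                        "strand": strand,
                        "family_id": fam.family_id,
                        "classification": fam.classification,
                        "subclass": classification_subclass(fam.classification),
                        "mechanism": fam.mechanism,
                        "autonomous": fam.autonomous,
                        "length": glen,
                        "truncation": trunc,
                        "divergence": realized,
                        "consensus_coverage": coverage,
                        "intact": classify_intact(realized, coverage),
                        "compartment": label,
                        "site_class": "intronic" if origin == "intron" else "intergenic",
                        "host_gene": host_gene,
                        "link_id": link_counter,
                        "n_fragments": len(frag_hits),
                    }
                )
            # tandem arrays in the remaining free space
            tandem_target = int(config.tandem_fraction * seg_len)
            placed = 0
            while placed < tandem_target:
                tlen = int(rng.integers(200, 2000))
                slot = free.place(rng, tlen)
                if slot is None:
                    break
                tandem.append(
                    Interval(chrom.chrom_id, slot[0], slot[0] + tlen, ".", "tandem")
                )
                placed += tlen
        for label, s, e in chrom.segments:
            comp_intervals.append(Interval(chrom.chrom_id, s, e, ".", label))
        if chrom.anchor is not None:
            pos = chrom.anchor[0]
            comp_intervals.append(
                Interval(chrom.chrom_id, max(0, pos - 1), pos + 1, ".", "subtelomere_anchor")
            )
        if seq is not None:
            genome[chrom.chrom_id] = seq.tobytes().decode()

    truth = TruthTable(
        copies=pd.DataFrame(copy_rows),
        genes=pd.DataFrame(gene_rows),
    )
    return SimulationResult(
        config=config,
        genome=genome if config.emit_sequence else None,
        chrom_lengths=chrom_lengths,
        library=library,
        hits=hits,
        genes=genes,
        tandem=tandem,
        compartments=CompartmentMap(comp_intervals),
        truth=truth,
    )


def _planting_units(chrom: ChromPlan, config: SimulationConfig):
    """Segments to plant, splitting out a boosted subtelomeric zone if any."""
    units = []
    boost = config.subtelomere_boost
    for label, s, e in chrom.segments:
        frac = config.density_targets.get(label, 0.0)
        if boost is not None and chrom.anchor is not None:
            pos, direction = chrom.anchor
            extent, dens = boost
            zs, ze = (pos, pos + extent) if direction == "+" else (pos - extent, pos)
            if s < ze and zs < e:
                zs2, ze2 = max(s, zs), min(e, ze)
                if s < zs2:
                    units.append((label, s, zs2, frac))
                units.append((label, zs2, ze2, dens))
                if ze2 < e:
                    units.append((label, ze2, e, frac))
                continue
        units.append((label, s, e, frac))
    return units


def _mutate_codes(rng, codes: np.ndarray, divergence: float, trunc: int):
    hit = rng.random(codes.shape[0]) < divergence / 100.0
    shift = rng.integers(1, 4, codes.shape[0], dtype=np.int64)
    mutated = np.where(hit, (codes + shift) % 4, codes)[trunc:]
    realized = 100.0 * int(hit[trunc:].sum()) / mutated.shape[0]
    return mutated, realized


def _emit_hits(rng, config, fam, chrom, start, glen, trunc, realized, strand, link_id):
    """One or two abutting RepeatMasker-style hits for a planted copy.

    The copy covers consensus [trunc, L); with probability fragment_prob it
    is emitted as two fragments sharing the link id (for a minus-strand
    copy the genomic-left fragment carries the consensus-right span).
    """
    cons_len = fam.consensus_length
    spans: list  # (gstart, gend, cstart, cend)
    if rng.random() < config.fragment_prob and glen >= 200:
        k = int(rng.integers(50, glen - 50))
        if strand == "+":
            spans = [
                (start, start + k, trunc, trunc + k),
                (start + k, start + glen, trunc + k, cons_len),
            ]
        else:
            spans = [
                (start, start + k, cons_len - k, cons_len),
                (start + k, start + glen, trunc, cons_len - k),
            ]
    else:
        spans = [(start, start + glen, trunc, cons_len)]
    out = []
    for gs, ge, cs, ce in spans:
        out.append(
            RepeatHit(
                chrom=chrom,
                start=gs,
                end=ge,
                strand=strand,
                family_id=fam.family_id,
                classification=fam.classification,
                consensus_start=cs,
                consensus_end=ce,
                divergence_pct=realized,
                score=float(ge - gs),
                link_id=link_id,
            )
        )
    return out


# ----------------------------------------------------------- regulation


def plant_regulation(
    copies: pd.DataFrame, srna_plan: SrnaPlan, peak_plan: PeakPlan, seed: int
) -> pd.DataFrame:
    """Draw per-copy peak and sRNA targeting flags.

    Peaks are Bernoulli by intact status.  sRNA targeting is drawn once per
    copy (a targeted copy produces reads in every stage, matching the
    all-stage association definition).  When the conditional probability
    P(sRNA | intact, peak) is configured, the probability for peak-free
    intact copies is adjusted so the intact marginal is preserved.
    """
    rng = np.random.default_rng(seed)
    df = copies.copy()
    intact = df["intact"].to_numpy(dtype=bool)
    p_peak = np.where(intact, peak_plan.p_peak_intact, peak_plan.p_peak_nonintact)
    df["has_peak"] = rng.random(len(df)) < p_peak
    p_srna = np.where(intact, srna_plan.p_covered_intact, srna_plan.p_covered_nonintact)
    cond = srna_plan.p_covered_intact_peak
    if cond is not None and peak_plan.p_peak_intact < 1.0:
        p_nopeak = (
            srna_plan.p_covered_intact - peak_plan.p_peak_intact * cond
        ) / (1.0 - peak_plan.p_peak_intact)
        if not 0.0 <= p_nopeak <= 1.0:
            raise ValueError("conditional sRNA probability incompatible with the marginal")
        p_srna = np.where(
            intact & df["has_peak"].to_numpy(), cond,
            np.where(intact, p_nopeak, p_srna),
        )
    df["srna_targeted"] = rng.random(len(df)) < p_srna
    return df


def simulate_peaks(
    copies: pd.DataFrame, peak_plan: PeakPlan, seed: int, chrom_lengths: dict
) -> list:
    """One broad peak per flagged copy, covering >= body_fraction of it."""
    rng = np.random.default_rng(seed)
    peaks = []
    for row in copies.itertuples():
        if not row.has_peak:
            continue
        length = row.end - row.start
        if peak_plan.body_fraction >= 1.0:
            fl = peak_plan.flank_mean
            s = row.start - (int(rng.exponential(fl)) if fl > 0 else 0)
            e = row.end + (int(rng.exponential(fl)) if fl > 0 else 0)
        else:
            span = max(int(np.ceil(peak_plan.body_fraction * length)), 1)
            off = int(rng.integers(0, length - span + 1))
            s, e = row.start + off, row.start + off + span
        s = max(0, s)
        e = min(chrom_lengths[row.chrom], e)
        peaks.append(Interval(row.chrom, s, e, ".", f"peak_{row.copy_id}"))
    return peaks


def simulate_reads(
    copies: pd.DataFrame,
    srna_plan: SrnaPlan,
    stage: str,
    seed: int,
    genome: dict | None = None,
    chrom_lengths: dict | None = None,
) -> list:
    """Per-stage sRNA alignments over targeted copies, plus background.

    Reads fall fully inside their source copy, lengths follow the
    configured 20-24 nt distribution (21-nt mode), and when the genome is
    available read positions are rejection-sampled so the 5' genomic base
    is T-equivalent with probability ``u5_prob``.
    """
    if srna_plan.mean_reads_per_copy <= 0:
        return []
    rng = np.random.default_rng(seed)
    lengths = np.array([l for l, _ in srna_plan.length_probs])
    probs = np.array([p for _, p in srna_plan.length_probs])
    probs = probs / probs.sum()
    reads = []
    counter = 0

    def emit(chrom, lo, hi):
        nonlocal counter
        rlen = int(rng.choice(lengths, p=probs))
        if hi - lo < rlen:
            return
        strand = "+" if rng.random() < 0.5 else "-"
        want_u = rng.random() < srna_plan.u5_prob
        start = None
        if genome is not None and chrom in genome:
            seq = genome[chrom]
            for _ in range(40):
                cand = int(rng.integers(lo, hi - rlen + 1))
                base = seq[cand] if strand == "+" else {"A": "T", "C": "G", "G": "C", "T": "A"}.get(seq[cand + rlen - 1], "N")
                if (base == "T") == want_u:
                    start = cand
                    break
        if start is None:
            start = int(rng.integers(lo, hi - rlen + 1))
        counter += 1
        reads.append(
            ReadAlignment(f"{stage}_r{counter}", chrom, start, start + rlen, strand, 1)
        )

    targeted = copies[copies["srna_targeted"]] if "srna_targeted" in copies else copies
    for row in targeted.itertuples():
        n = 1 + rng.poisson(max(srna_plan.mean_reads_per_copy - 1, 0))
        for _ in range(n):
            emit(row.chrom, row.start, row.end)
    if srna_plan.background_fraction > 0 and chrom_lengths:
        n_bg = int(
            len(reads) * srna_plan.background_fraction / (1 - srna_plan.background_fraction)
        )
        chroms = sorted(chrom_lengths)
        sizes = np.array([chrom_lengths[c] for c in chroms], dtype=float)
        for _ in range(n_bg):
            c = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
            lo = int(rng.integers(0, chrom_lengths[c] - 30))
            emit(c, lo, lo + 30)
    return reads


def simulate_copy_set(
    n_copies: int,
    intact_fraction: float = 0.5,
    seed: int = 0,
    copy_length_range: tuple = (300, 3000),
    gap: int = 200,
    chrom: str = "chrSim",
    n_families: int = 40,
) -> tuple:
    """Lightweight copy layout for regulation-parameter recovery.

    Places ``n_copies`` abutting copies (with fixed gaps) on one synthetic
    chromosome, drawing divergence/coverage consistent with the requested
    intact fraction.  Returns (copies DataFrame, TECopy list,
    chrom_lengths) without generating any sequence.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pos = gap
    for i in range(n_copies):
        length = int(rng.integers(*copy_length_range))
        if rng.random() < intact_fraction:
            div = float(rng.uniform(0, 15))
            cov = float(rng.uniform(0.85, 1.0))
        elif rng.random() < 0.5:
            div = float(rng.uniform(25, 45))
            cov = float(rng.uniform(0.85, 1.0))
        else:
            div = float(rng.uniform(0, 15))
            cov = float(rng.uniform(0.3, 0.7))
        rows.append(
            {
                "copy_id": f"{chrom}:{i + 1}",
                "chrom": chrom,
                "start": pos,
                "end": pos + length,
                "strand": "+" if rng.random() < 0.5 else "-",
                "family_id": f"fam{i % n_families}",
                "classification": "DNA/Mariner-Tc1" if i % 2 else "LTR/Copia",
                "length": length,
                "divergence": div,
                "consensus_coverage": cov,
                "intact": classify_intact(div, cov),
            }
        )
        pos += length + gap
    df = pd.DataFrame(rows)
    copies = [
        TECopy(
            r["copy_id"], r["chrom"], r["start"], r["end"], r["strand"],
            r["family_id"], r["classification"],
            divergence_pct=r["divergence"], consensus_coverage=r["consensus_coverage"],
        )
        for r in rows
    ]
    return df, copies, {chrom: pos}


def simulate_family_expression(
    family_table: pd.DataFrame, seed: int = 0, weight_srna: float = 0.60,
    weight_peak: float = 0.52, noise: float = 1.55,
) -> pd.DataFrame:
    """Per-family TPM rank-coupled to sRNA abundance (+) and peak overlap (-).

    A Gaussian-copula construction: normal scores of the observed family
    ranks are combined as ``w_s z_srna - w_p z_peak + noise`` and
    exponentiated to a TPM scale, producing weak positive/negative rank
    correlations of roughly +0.3 / -0.3 at the default weights.
    """
    from scipy.stats import norm, rankdata

    rng = np.random.default_rng(seed)
    df = family_table.copy()
    n = len(df)

    def zscores(v):
        return norm.ppf((rankdata(v) - 0.5) / n)

    latent = (
        weight_srna * zscores(df["mean_cpm_intact"].to_numpy(dtype=float))
        - weight_peak * zscores(df["mean_peak_overlap"].to_numpy(dtype=float))
        + noise * rng.standard_normal(n)
    )
    df["tpm"] = np.exp(latent) * 10.0
    return df
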