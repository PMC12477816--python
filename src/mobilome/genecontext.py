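"""TE distribution relative to genes.

Builds the disjoint site-class partition of the genome (CDS, 5'/3' UTR,
intron, gene-proximal and gene-distal intergenic), filters out gene models
that are themselves TE-derived, classifies individual TE copies by site
class, and runs the downstream comparisons: copy length/divergence between
site classes, nearest-TE distance bins, the genic TE:CDS ratio against
expression, and the gene-age x intronic-TE superfamily contingency
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv
from .stats import GroupTestReport, chi_square_independence, compare_groups, spearman

__all__ = [
    "SiteClassPartition",
    "filter_te_genes",
    "partition_site_classes",
    "site_class_density",
    "assign_copy_site_class",
    "compare_copy_properties",
    "nearest_te_distance",
    "genic_te_cds_ratio",
    "expression_vs_te",
    "age_mosaic",
]

SITE_CLASSES = ("CDS", "UTR5", "UTR3", "intron", "intergenic_proximal", "intergenic_distal")
GENIC_CLASSES = ("CDS", "UTR5", "UTR3", "intron")


@dataclass
class SiteClassPartition:
    """Disjoint labelling of every genomic base, per chromosome.

    ``classes[chrom][label]`` is a merged (n,2) interval array; per
    chromosome the six labels tile [0, length) exactly.
    """

    classes: dict  # chrom -> {label: (n,2) array}
    chrom_lengths: dict
    proximal_bp: int

    def bp(self, label: str) -> int:
        return sum(
            int((arr[label][:, 1] - arr[label][:, 0]).sum()) if len(arr[label]) else 0
            for arr in self.classes.values()
        )


def filter_te_genes(genes: list, annotation, threshold: float = 0.70) -> tuple[list, list]:
    """Drop transcripts whose CDS is mostly TE.

    The intersect fraction is TE-covered CDS bp over CDS bp, per transcript;
    transcripts strictly above ``threshold`` are removed, and a gene is
    retained while it keeps at least one transcript.  Returns
    (retained genes, removed transcript ids).
    """
    te = annotation.te_by_chrom()
    retained = []
    removed = []
    for g in genes:
        kept_tx = []
        for tx in g.transcripts:
            cds_bp = sum(e - s for s, e in tx.cds)
            if cds_bp == 0:
                kept_tx.append(tx)
                continue
            ov = iv.intersect_length(tx.cds, te.get(g.chrom, []))
            if ov / cds_bp > threshold:
                removed.append(tx.transcript_id)
            else:
                kept_tx.append(tx)
        if kept_tx:
            g2 = type(g)(g.gene_id, g.chrom, g.strand, kept_tx)
            retained.append(g2)
    return retained, removed


def partition_site_classes(
    genes: list, chrom_lengths: dict, proximal_bp: int = 500
) -> SiteClassPartition:
    """Label every base with exactly one site class.

    Overlapping transcripts of a gene (and overlapping genes) are resolved
    by the precedence ladder CDS > UTR5 > UTR3 > intron; remaining bases
    are intergenic, proximal when within ``proximal_bp`` of any gene span
    boundary (either flank of either neighbour), else distal.
    """
    per_chrom: dict = {}
    for chrom, length in chrom_lengths.items():
        pools = {label: [] for label in GENIC_CLASSES}
        spans = []
        for g in genes:
            if g.chrom != chrom:
                continue
            spans.append(g.span)
            for tx in g.transcripts:
                pools["CDS"].extend(tx.cds)
                pools["UTR5"].extend(tx.utr5)
                pools["UTR3"].extend(tx.utr3)
                pools["intron"].extend(tx.introns)
        classes = {}
        claimed = np.empty((0, 2), dtype=np.int64)
        for label in GENIC_CLASSES:
            merged = iv.merge(pools[label]) if pools[label] else np.empty((0, 2), np.int64)
            merged = iv.subtract(merged, claimed)
            classes[label] = merged
            claimed = iv.merge(np.vstack([claimed, merged])) if len(merged) else claimed
        intergenic = iv.complement(claimed, length)
        if spans:
            prox_zone = []
            for lo, hi in spans:
                prox_zone.append((max(0, lo - proximal_bp), lo))
                prox_zone.append((hi, min(length, hi + proximal_bp)))
            prox_zone = [p for p in prox_zone if p[0] < p[1]]
            proximal = iv.intersect(intergenic, prox_zone) if prox_zone else np.empty((0, 2), np.int64)
        else:
            proximal = np.empty((0, 2), dtype=np.int64)
        distal = iv.subtract(intergenic, proximal)
        classes["intergenic_proximal"] = proximal
        classes["intergenic_distal"] = distal
        per_chrom[chrom] = classes
    return SiteClassPartition(per_chrom, dict(chrom_lengths), proximal_bp)


def site_class_density(annotation, partition: SiteClassPartition) -> pd.DataFrame:
    """TE / tandem / non-repeat fraction of each site class."""
    te = annotation.te_by_chrom()
    tandem = annotation.tandem_by_chrom()
    rows = []
    for label in SITE_CLASSES:
        total = te_bp = tandem_bp = 0
        for chrom, classes in partition.classes.items():
            arr = classes[label]
            if len(arr) == 0:
                continue
            total += int((arr[:, 1] - arr[:, 0]).sum())
            te_bp += iv.intersect_length(arr, te.get(chrom, []))
            tandem_bp += iv.intersect_length(arr, tandem.get(chrom, []))
        rows.append(
            {
                "site_class": label,
                "bp": total,
                "te_fraction": te_bp / total if total else 0.0,
                "tandem_fraction": tandem_bp / total if total else 0.0,
                "nonrepeat_fraction": (total - te_bp - tandem_bp) / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def assign_copy_site_class(copy, partition: SiteClassPartition, min_proximal_frac: float = 0.01) -> str:
    """Site class of one TE copy.

    A copy overlapping genic bases takes the majority genic label; a fully
    intergenic copy is proximal iff strictly more than ``min_proximal_frac``
    of its length lies within the gene-proximal zone, else distal.
    """
    classes = partition.classes.get(copy.chrom)
    if classes is None:
        raise KeyError(f"chromosome {copy.chrom} not in partition")
    span = [(copy.start, copy.end)]
    genic = {
        label: iv.intersect_length(span, classes[label]) for label in GENIC_CLASSES
    }
    if sum(genic.values()) > 0:
        return max(GENIC_CLASSES, key=lambda lab: genic[lab])
    prox = iv.intersect_length(span, classes["intergenic_proximal"])
    if prox / copy.length > min_proximal_frac:
        return "intergenic_proximal"
    return "intergenic_distal"


def compare_copy_properties(
    copies_by_class: dict,
    max_divergence: float | None = None,
    adjust: str = "bonferroni",
) -> dict:
    """Length and divergence comparisons between site-class groups.

    Returns {'length': report, 'divergence': report}; both use the shared
    Kruskal-Wallis/Dunn (or Wilcoxon) engine.  ``max_divergence`` (e.g. 30)
    restricts the divergence comparison to copies at or below it, matching
    the usual exclusion of deeply degraded copies.
    """
    if any(len(v) == 0 for v in copies_by_class.values()):
        raise ValueError("empty site-class group")
    length_groups = {
        k: np.array([c.length for c in v], dtype=float) for k, v in copies_by_class.items()
    }
    div_groups = {}
    for k, v in copies_by_class.items():
        divs = [c.divergence_pct for c in v]
        if max_divergence is not None:
            divs = [d for d in divs if d <= max_divergence]
        div_groups[k] = np.array(divs, dtype=float)
    return {
        "length": compare_groups(length_groups, adjust=adjust),
        "divergence": compare_groups(div_groups, adjust=adjust),
    }


_DISTANCE_BINS = ((0, 500, "<=500bp"), (500, 1000, "500bp-1kb"), (1000, 2000, "1-2kb"))


def nearest_te_distance(genes: list, copies: list, max_bp: int = 2000) -> pd.DataFrame:
    """Distance from each gene span to the nearest intergenic TE copy.

    Intronic copies must be excluded by the caller (pass intergenic copies
    only).  Distance is the gap between the gene span and the copy (0 when
    abutting or overlapping); bins are [0,500], (500,1000], (1000,2000] and
    beyond ``max_bp``.  The intact flag of the nearest copy is reported.
    """
    by_chrom: dict = {}
    for c in copies:
        by_chrom.setdefault(c.chrom, []).append(c)
    rows = []
    for g in genes:
        lo, hi = g.span
        best, best_copy = None, None
        for c in by_chrom.get(g.chrom, []):
            gap = max(c.start - hi, lo - c.end, 0)
            if best is None or gap < best:
                best, best_copy = gap, c
        if best is None or best > max_bp:
            rows.append(
                {"gene_id": g.gene_id, "distance": np.nan, "bin": f">{max_bp}bp",
                 "nearest_intact": pd.NA}
            )
            continue
        label = next(lab for lo_b, hi_b, lab in _DISTANCE_BINS if lo_b <= best <= hi_b and (best > lo_b or lo_b == 0))
        rows.append(
            {"gene_id": g.gene_id, "distance": best, "bin": label,
             "nearest_intact": best_copy.intact}
        )
    return pd.DataFrame(rows)


def genic_te_cds_ratio(gene, annotation) -> float:
    """Genic TE bp (introns + UTRs, i.e. the non-CDS gene body) over CDS bp.

    Mono-exonic genes are excluded from this analysis (their expression
    behaves differently); callers should skip them, and passing one raises.
    """
    if gene.mono_exonic:
        raise ValueError(f"gene {gene.gene_id} is mono-exonic; excluded from TE:CDS ratio")
    te = annotation.te_by_chrom().get(gene.chrom, [])
    lo, hi = gene.span
    cds = iv.merge([c for tx in gene.transcripts for c in tx.cds])
    cds_bp = int((cds[:, 1] - cds[:, 0]).sum()) if len(cds) else 0
    if cds_bp == 0:
        raise ValueError(f"gene {gene.gene_id} has no CDS")
    body = iv.subtract([(lo, hi)], cds)
    te_bp = iv.intersect_length(body, te)
    return te_bp / cds_bp


def expression_vs_te(ratios: dict, tpm: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of the genic TE:CDS ratio with expression.

    ``ratios``: gene_id -> ratio; ``tpm``: DataFrame indexed by gene_id
    with one column per stage.  Expression is transformed log2(TPM + 1).
    """
    rows = []
    common = [g for g in tpm.index if g in ratios]
    x = np.array([ratios[g] for g in common], dtype=float)
    for stage in tpm.columns:
        y = np.log2(tpm.loc[common, stage].to_numpy(dtype=float) + 1.0)
        rho, p = spearman(x, y)
        rows.append({"stage": stage, "rho": rho, "p_value": p, "n_genes": len(common)})
    return pd.DataFrame(rows)


def age_mosaic(copy_table: pd.DataFrame, gene_ranks: dict) -> dict:
    """Superfamily x gene-age contingency analysis for intronic copies.

    ``copy_table`` needs columns ``classification`` and ``gene_id`` (the
    host gene of each intronic copy); ``gene_ranks`` maps gene_id to a
    phylostratum rank (1 = oldest ... 11 = species-specific).  Returns the
    contingency table, Pearson chi-square and adjusted standardized
    residuals; cells with expected < 5 are flagged.
    """
    df = copy_table.copy()
    df["rank"] = df["gene_id"].map(gene_ranks)
    df = df.dropna(subset=["rank"])
    table = pd.crosstab(df["classification"], df["rank"].astype(int))
    result = chi_square_independence(table.to_numpy())
    result["table"] = table
    result["std_residuals"] = pd.DataFrame(
        result["std_residuals"], index=table.index, columns=table.columns
    )
    return result
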