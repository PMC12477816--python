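"""From repeat hits to defragmented TE copies.

Fragments that share a link id are rejoined into single copies, LTR
terminus-internal-terminus chains are assembled into full-length
retrotransposon copies, copies are classified as intact (divergence
strictly below 20% of the family consensus and consensus coverage strictly
above 80%), TE/tandem overlaps are resolved with TE precedence, and the
divergence landscape (genomic bp per divergence bin, the standard TE-age
proxy) is tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv
from .formats import Interval, RepeatHit, classification_subclass

__all__ = [
    "TECopy",
    "RepeatAnnotation",
    "classify_intact",
    "merge_fragments",
    "assemble_ltr",
    "resolve_precedence",
    "divergence_landscape",
    "summarize_by_superfamily",
    "mechanism_of",
]

INTACT_MAX_DIVERGENCE = 20.0  # strict <
INTACT_MIN_COVERAGE = 0.8  # strict >

# cut-and-paste = DD(E/D) DNA transposons; copy-and-paste = retrotransposons
# (LTR, LINE, DIRS, PLE) and rolling-circle Helitrons
_MECHANISM = {
    "LTR": "copy",
    "LINE": "copy",
    "DIRS": "copy",
    "PLE": "copy",
    "Helitron": "copy",
    "DNA": "cut",
}


def mechanism_of(classification: str) -> str:
    return _MECHANISM.get(classification_subclass(classification), "unknown")


def classify_intact(divergence_pct: float, consensus_coverage: float) -> bool:
    """Strict thresholds on both axes: < 20% divergence AND > 80% coverage."""
    return divergence_pct < INTACT_MAX_DIVERGENCE and consensus_coverage > INTACT_MIN_COVERAGE


@dataclass
class TECopy:
    """A defragmented genomic TE instance."""

    copy_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family_id: str
    classification: str
    fragments: list = field(default_factory=list)
    divergence_pct: float = 0.0  # length-weighted over fragments
    consensus_coverage: float = 0.0  # union on consensus coordinates
    consensus_length: int = 0
    autonomous: str = "unknown"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def subclass(self) -> str:
        return classification_subclass(self.classification)

    @property
    def mechanism(self) -> str:
        return mechanism_of(self.classification)

    @property
    def intact(self) -> bool:
        return classify_intact(self.divergence_pct, self.consensus_coverage)


def merge_fragments(hits: list, consensus_lengths: dict | None = None) -> list:
    """Join hits sharing (chrom, link_id) into single TE copies.

    Copy interval = [min start, max end); divergence is the
    fragment-length-weighted mean; consensus coverage is the union of the
    fragments' consensus spans divided by the consensus length (taken from
    ``consensus_lengths`` by family, else the largest consensus end seen).
    A link group spanning two chromosomes is an error.
    """
    groups: dict = {}
    for h in hits:
        groups.setdefault(h.link_id, []).append(h)
    copies = []
    for link_id in sorted(groups):
        frags = sorted(groups[link_id], key=lambda h: h.start)
        chroms = {h.chrom for h in frags}
        if len(chroms) != 1:
            raise ValueError(f"link group {link_id} spans chromosomes {sorted(chroms)}")
        fam = frags[0].family_id
        lens = np.array([h.length for h in frags], dtype=float)
        divs = np.array([h.divergence_pct for h in frags], dtype=float)
        weighted_div = float((lens * divs).sum() / lens.sum())
        spans = [(h.consensus_start, h.consensus_end) for h in frags]
        covered = iv.total_length(spans)
        if consensus_lengths and fam in consensus_lengths:
            cons_len = consensus_lengths[fam]
        else:
            cons_len = max(h.consensus_end for h in frags)
        copies.append(
            TECopy(
                copy_id=f"{frags[0].chrom}:{link_id}",
                chrom=frags[0].chrom,
                start=min(h.start for h in frags),
                end=max(h.end for h in frags),
                strand=frags[0].strand,
                family_id=fam,
                classification=frags[0].classification,
                fragments=frags,
                divergence_pct=weighted_div,
                consensus_coverage=min(1.0, covered / cons_len),
                consensus_length=cons_len,
            )
        )
    return copies


def assemble_ltr(
    copies: list,
    ltr_internal_pairs: dict,
    consensus_lengths: dict | None = None,
    max_gap: int = 500,
) -> list:
    """Assemble LTR-internal-LTR chains into full-length copies.

    ``ltr_internal_pairs`` maps each LTR-terminus family to its internal
    family.  Three consecutive copies forming terminus/internal/terminus of
    one paired family set, on the same strand, with inter-copy gaps of at
    most ``max_gap`` bp, merge into a single full-length copy whose
    consensus length is 2 x LTR + internal.  Unpaired solo LTRs stay solo.
    """
    by_chrom: dict = {}
    for c in copies:
        by_chrom.setdefault(c.chrom, []).append(c)
    out = []
    for chrom in sorted(by_chrom):
        chain = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        i = 0
        while i < len(chain):
            c = chain[i]
            merged = None
            if c.family_id in ltr_internal_pairs and i + 2 < len(chain):
                internal_fam = ltr_internal_pairs[c.family_id]
                mid, right = chain[i + 1], chain[i + 2]
                gaps_ok = (
                    mid.start - c.end <= max_gap and right.start - mid.end <= max_gap
                )
                if (
                    mid.family_id == internal_fam
                    and right.family_id == c.family_id
                    and mid.strand == c.strand == right.strand
                    and gaps_ok
                ):
                    merged = _merge_ltr_triplet(c, mid, right, consensus_lengths)
            if merged is not None:
                out.append(merged)
                i += 3
            else:
                out.append(c)
                i += 1
    return out


def _merge_ltr_triplet(left, internal, right, consensus_lengths):
    parts = [left, internal, right]
    lens = np.array([p.length for p in parts], dtype=float)
    divs = np.array([p.divergence_pct for p in parts], dtype=float)

    def cons_len(p):
        if consensus_lengths and p.family_id in consensus_lengths:
            return consensus_lengths[p.family_id]
        return p.consensus_length or p.length

    full_len = 2 * cons_len(left) + cons_len(internal)
    covered = sum(p.consensus_coverage * cons_len(p) for p in parts)
    frags = [f for p in parts for f in p.fragments]
    return TECopy(
        copy_id=f"{left.copy_id}+ltr",
        chrom=left.chrom,
        start=left.start,
        end=right.end,
        strand=left.strand,
        family_id=internal.family_id,
        classification=internal.classification,
        fragments=frags,
        divergence_pct=float((lens * divs).sum() / lens.sum()),
        consensus_coverage=min(1.0, covered / full_len),
        consensus_length=int(full_len),
    )


@dataclass
class RepeatAnnotation:
    """TE copies plus tandem intervals after TE-precedence resolution."""

    te_copies: list
    tandem_intervals: list  # clipped so no base is both TE and tandem

    def te_by_chrom(self) -> dict:
        out: dict = {}
        for c in self.te_copies:
            out.setdefault(c.chrom, []).append((c.start, c.end))
        return {k: iv.merge(v) for k, v in out.items()}

    def tandem_by_chrom(self) -> dict:
        out: dict = {}
        for t in self.tandem_intervals:
            out.setdefault(t.chrom, []).append((t.start, t.end))
        return {k: iv.merge(v) for k, v in out.items()}

    def total_te_bp(self) -> int:
        return sum(int((a[:, 1] - a[:, 0]).sum()) for a in self.te_by_chrom().values())


def resolve_precedence(te_copies: list, tandem_intervals: list) -> RepeatAnnotation:
    """Clip tandem intervals to exclude TE-covered bases (TE precedence)."""
    te_by_chrom: dict = {}
    for c in te_copies:
        te_by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    clipped = []
    for t in tandem_intervals:
        te = te_by_chrom.get(t.chrom, [])
        for s, e in iv.subtract([(t.start, t.end)], te):
            clipped.append(Interval(t.chrom, int(s), int(e), t.strand, t.label))
    return RepeatAnnotation(list(te_copies), clipped)


def divergence_landscape(
    copies: list, bin_width: float = 1.0, max_divergence: float | None = None
) -> pd.DataFrame:
    """Genomic bp per (divergence bin, subclass).

    Each copy contributes its genomic length to the bin of its
    length-weighted divergence.  Copies above ``max_divergence`` (when set,
    e.g. 30%) are excluded.
    """
    rows = []
    for c in copies:
        if max_divergence is not None and c.divergence_pct > max_divergence:
            continue
        b = np.floor(c.divergence_pct / bin_width) * bin_width
        rows.append({"bin": float(b), "subclass": c.subclass, "bp": c.length})
    if not rows:
        return pd.DataFrame(columns=["bin", "subclass", "bp"])
    df = pd.DataFrame(rows).groupby(["bin", "subclass"], as_index=False)["bp"].sum()
    return df.sort_values(["bin", "subclass"]).reset_index(drop=True)


def summarize_by_superfamily(annotation: RepeatAnnotation, genome_size: int) -> pd.DataFrame:
    """Per-superfamily family/copy/intact counts and genome percentage."""
    rows = []
    for c in annotation.te_copies:
        rows.append(
            {
                "classification": c.classification,
                "family_id": c.family_id,
                "bp": c.length,
                "intact": c.intact,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["classification", "families", "copies", "intact_copies", "genome_pct"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby("classification")
        .agg(
            families=("family_id", "nunique"),
            copies=("family_id", "size"),
            intact_copies=("intact", "sum"),
            bp=("bp", "sum"),
        )
        .reset_index()
    )
    out["genome_pct"] = out["bp"] / genome_size * 100.0
    return out.drop(columns="bp").sort_values("classification").reset_index(drop=True)
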