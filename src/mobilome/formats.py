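"""Readers and writers for the external formats the pipeline touches.

Every reader normalizes coordinates to the package-internal convention
(0-based, half-open) on the way in; writers convert back to each format's
native convention on the way out.  Dialects handled:

* FASTA (genome and repeat-library; library headers ``name#Class/Superfamily``)
* RepeatMasker ``.out`` annotation tables
* GFF3 gene models (introns derived as inter-exon gaps)
* BED3/6, broadPeak (only chrom/start/end used), bedGraph
* SAM/BAM small-RNA alignments (via pysam) or 6-column BED alignments
* plain TSV tables (via pandas)
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import Interval

__all__ = [
    "RepeatHit",
    "Transcript",
    "GeneModel",
    "ReadAlignment",
    "read_fasta",
    "write_fasta",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_alignments",
    "write_alignments_bed",
    "write_tsv",
    "check_chromosomes",
]


@dataclass
class RepeatHit:
    """One RepeatMasker hit, normalized to 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    family_id: str
    classification: str
    consensus_start: int  # 0-based half-open on the consensus
    consensus_end: int
    divergence_pct: float
    score: float
    link_id: int
    higher_scoring_overlap: bool = False  # the trailing '*' column

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"reversed/negative genomic coordinates on {self.family_id}")
        if not (0 <= self.consensus_start < self.consensus_end):
            raise ValueError(f"reversed consensus coordinates on {self.family_id}")
        if not (0.0 <= self.divergence_pct <= 100.0):
            raise ValueError(f"divergence {self.divergence_pct} outside [0, 100]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def subclass(self) -> str:
        return classification_subclass(self.classification)


_KNOWN_SUBCLASSES = {"LTR", "LINE", "DIRS", "PLE", "DNA", "Helitron", "TandemRepeat"}


def classification_subclass(classification: str) -> str:
    """Map a ``Class/Superfamily`` string to its subclass, else 'Unknown'.

    Unknown classification strings are preserved verbatim elsewhere; only
    the grouping level collapses them to "Unknown".
    """
    head = classification.split("/", 1)[0]
    return head if head in _KNOWN_SUBCLASSES else "Unknown"


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list = field(default_factory=list)  # list of (start, end)
    cds: list = field(default_factory=list)
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)

    @property
    def span(self):
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi

    @property
    def introns(self) -> list:
        """Gaps between consecutive exons."""
        exons = sorted(self.exons)
        out = []
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in transcript {self.transcript_id}")
            if s2 > e1:
                out.append((e1, s2))
        return out

    @property
    def mono_exonic(self) -> bool:
        return len(self.exons) == 1


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list = field(default_factory=list)

    @property
    def span(self):
        lo = min(t.span[0] for t in self.transcripts)
        hi = max(t.span[1] for t in self.transcripts)
        return lo, hi

    @property
    def mono_exonic(self) -> bool:
        return all(t.mono_exonic for t in self.transcripts)


@dataclass
class ReadAlignment:
    """One aligned small-RNA read occurrence."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    multiplicity: int = 1

    @property
    def read_length(self) -> int:
        return self.end - self.start


# ----------------------------------------------------------------- FASTA


def read_fasta(path) -> dict:
    """Read FASTA into an ordered {id: uppercase sequence} dict."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict, path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ------------------------------------------------- RepeatMasker .out


def read_repeatmasker_out(path) -> list:
    """Parse a RepeatMasker ``.out`` table into :class:`RepeatHit` records.

    Handles the standard 3-line header (or none).  Strand ``C`` maps to
    ``-`` and the parenthesized consensus coordinate is resolved so that
    ``consensus_start < consensus_end``; genomic coordinates convert from
    1-based inclusive to 0-based half-open.
    """
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            first = line.split()[0]
            if first in ("SW", "score") or line.startswith("There were no"):
                continue  # header lines
            fields = line.split()
            if len(fields) < 15:
                raise ValueError(f"{path}:{lineno}: malformed row ({len(fields)} fields, need >=15)")
            try:
                score = float(fields[0])
                div = float(fields[1])
                chrom = fields[4]
                qbegin = int(fields[5])
                qend = int(fields[6])
                strand_raw = fields[8]
                family = fields[9]
                classification = fields[10]
                if strand_raw == "+":
                    strand = "+"
                    rbegin = int(fields[11])
                    rend = int(fields[12])
                else:  # 'C' = reverse; columns are (left) end begin
                    strand = "-"
                    rend = int(fields[12])
                    rbegin = int(fields[13])
                link_id = int(fields[14])
                star = len(fields) > 15 and fields[15] == "*"
            except (ValueError, IndexError) as exc:
                if isinstance(exc, ValueError) and "malformed" in str(exc):
                    raise
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if qbegin > qend or qbegin < 1:
                raise ValueError(f"{path}:{lineno}: negative/reversed genomic coordinates")
            hits.append(
                RepeatHit(
                    chrom=chrom,
                    start=qbegin - 1,
                    end=qend,
                    strand=strand,
                    family_id=family,
                    classification=classification,
                    consensus_start=rbegin - 1,
                    consensus_end=rend,
                    divergence_pct=div,
                    score=score,
                    link_id=link_id,
                    higher_scoring_overlap=star,
                )
            )
    return hits


_OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "       class/family         begin  end (left)   ID\n\n"
)


def write_repeatmasker_out(hits, path) -> None:
    """Serialize hits back to the ``.out`` dialect (field-preserving)."""
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for h in hits:
            if h.strand == "+":
                strand = "+"
                rfields = f"{h.consensus_start + 1} {h.consensus_end} (0)"
            else:  # reverse hits print (left) end begin
                strand = "C"
                rfields = f"(0) {h.consensus_end} {h.consensus_start + 1}"
            star = " *" if h.higher_scoring_overlap else ""
            fh.write(
                f"{h.score:7.0f} {h.divergence_pct:5.1f}  0.0  0.0  {h.chrom} "
                f"{h.start + 1} {h.end} (0) {strand} {h.family_id} {h.classification} "
                f"{rfields} {h.link_id}{star}\n"
            )


# ----------------------------------------------------------------- GFF3


def read_gff3(path) -> list:
    """Read GFF3 gene models (gene/mRNA/exon/CDS/UTR features).

    Returns a list of :class:`GeneModel`.  GFF3 is 1-based inclusive;
    stored 0-based half-open.  Introns are derived as inter-exon gaps and
    overlapping exons within one transcript raise an error.
    """
    transcripts: dict = {}
    tx_gene: dict = {}
    gene_strand: dict = {}
    gene_chrom: dict = {}
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GFF3 row: {raw!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            start, end = int(start) - 1, int(end)
            attr = dict(
                kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID", attr.get("gene_id"))
                gene_strand[gid] = strand
                gene_chrom[gid] = chrom
            elif ftype in ("mRNA", "transcript"):
                tid = attr.get("ID")
                parent = attr.get("Parent", tid)
                transcripts.setdefault(
                    tid, Transcript(tid, parent, chrom, strand)
                )
                tx_gene[tid] = parent
            elif ftype in ("exon", "CDS", "five_prime_UTR", "three_prime_UTR"):
                parent = attr.get("Parent")
                if parent is None:
                    raise ValueError(f"{ftype} feature without Parent: {raw!r}")
                tx = transcripts.setdefault(
                    parent, Transcript(parent, tx_gene.get(parent, parent), chrom, strand)
                )
                target = {
                    "exon": tx.exons,
                    "CDS": tx.cds,
                    "five_prime_UTR": tx.utr5,
                    "three_prime_UTR": tx.utr3,
                }[ftype]
                target.append((start, end))
    genes: dict = {}
    for tx in transcripts.values():
        if not tx.exons:
            # tolerate CDS-only annotations: exons = CDS + UTRs
            tx.exons = sorted(tx.cds + tx.utr5 + tx.utr3)
        _ = tx.introns  # raises on overlapping exons
        gid = tx.gene_id
        g = genes.setdefault(
            gid,
            GeneModel(gid, tx.chrom, gene_strand.get(gid, tx.strand)),
        )
        g.transcripts.append(tx)
    return list(genes.values())


def write_gff3(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = g.span
            fh.write(
                f"{g.chrom}\t.\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for tx in g.transcripts:
                tlo, thi = tx.span
                fh.write(
                    f"{g.chrom}\t.\tmRNA\t{tlo + 1}\t{thi}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={g.gene_id}\n"
                )
                for name, ivs in (
                    ("exon", tx.exons),
                    ("CDS", tx.cds),
                    ("five_prime_UTR", tx.utr5),
                    ("three_prime_UTR", tx.utr3),
                ):
                    for s, e in sorted(ivs):
                        fh.write(
                            f"{g.chrom}\t.\t{name}\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t"
                            f"Parent={tx.transcript_id}\n"
                        )


# ------------------------------------------------------ BED / bedGraph


def read_bed(path) -> list:
    """BED3/6/broadPeak into a list of :class:`Interval` (label = name column)."""
    out = []
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            f = raw.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            label = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            out.append(Interval(chrom, start, end, strand, label))
    return out


def write_bed(intervals, path, scores=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = 0 if scores is None else scores[i]
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t{score}\t{iv.strand}\n")


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError("bedGraph rows with start >= end")
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------------------ alignments


def read_alignments(path) -> list:
    """Read small-RNA alignments from SAM/BAM (pysam) or 6-column BED.

    BED columns: chrom, start, end, read_id, multiplicity, strand.
    SAM multiplicity comes from the NH tag when present, else 1.
    """
    path = str(path)
    if path.endswith((".sam", ".bam")):
        import pysam

        out = []
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped:
                    continue
                mult = aln.get_tag("NH") if aln.has_tag("NH") else 1
                out.append(
                    ReadAlignment(
                        read_id=aln.query_name,
                        chrom=aln.reference_name,
                        start=aln.reference_start,
                        end=aln.reference_end,
                        strand="-" if aln.is_reverse else "+",
                        multiplicity=int(mult),
                    )
                )
        return out
    out = []
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            f = raw.rstrip("\n").split("\t")
            out.append(
                ReadAlignment(
                    read_id=f[3],
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[5],
                    multiplicity=int(f[4]) if f[4] else 1,
                )
            )
    return out


def write_alignments_bed(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}\t{r.multiplicity}\t{r.strand}\n")


# -------------------------------------------------------------- helpers


def write_tsv(table: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a TSV with optional ``# key: value`` provenance header lines."""
    with open(path, "w") as fh:
        if metadata:
            for k, v in metadata.items():
                fh.write(f"# {k}: {v}\n")
        table.to_csv(fh, sep="\t", index=False)


def check_chromosomes(items, chrom_lengths: dict) -> None:
    """Reject records on unknown chromosomes or beyond chromosome ends."""
    offenders = []
    for it in items:
        chrom = it.chrom
        end = it.end
        if chrom not in chrom_lengths:
            offenders.append(f"{chrom} (unknown chromosome)")
        elif end > chrom_lengths[chrom]:
            offenders.append(f"{chrom}:{it.start}-{end} exceeds length {chrom_lengths[chrom]}")
    if offenders:
        raise ValueError("records outside the genome: " + "; ".join(sorted(set(offenders))[:10]))
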