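"""Post-processing of a TE consensus library.

Implements the library QC chain used to turn a raw, redundant consensus
collection into a clean annotation library: greedy identity/coverage
clustering (80% for reclassification, 95% for redundancy removal),
cluster-based reclassification against curated models, reclassification of
tandem-repeat artefacts by genomic overlap, deduplication, and majority
consensus building from an alignment.

The pairwise comparison is a Smith-Waterman local alignment
(match +1, mismatch -1, gap -2 by default) with deterministic tie-breaking
(diagonal over up over left; first maximal cell in row-major order), run in
both orientations since TE consensuses have arbitrary strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .intervals import intersect_length

__all__ = [
    "ConsensusRecord",
    "Cluster",
    "pairwise_identity",
    "cluster_library",
    "reclassify_by_cluster",
    "tandem_overlap_reclassify",
    "deduplicate",
    "consensus_from_alignment",
    "parse_library_header",
]

UNCLASSIFIED = "Unknown"


@dataclass
class ConsensusRecord:
    """One TE family consensus sequence."""

    id: str
    sequence: str
    classification: str = UNCLASSIFIED  # "Class/Superfamily" or "Unknown"
    curated: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def classified(self) -> bool:
        return self.classification != UNCLASSIFIED


@dataclass
class Cluster:
    representative: str
    members: list
    identity_threshold: float
    coverage_threshold: float


def parse_library_header(header: str) -> tuple[str, str]:
    """Split a ``name#Class/Superfamily`` library identifier."""
    if "#" in header:
        name, classification = header.split("#", 1)
        return name, classification or UNCLASSIFIED
    return header, UNCLASSIFIED


# ------------------------------------------------------------- alignment

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i

_COMPLEMENT = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    comp = bytes(_COMPLEMENT.get(b, 78) for b in reversed(seq.upper().encode()))
    return comp.decode()


@njit(cache=True)
def _smith_waterman(a, b, match, mismatch, gap):  # pragma: no cover - jitted
    n, m = a.shape[0], b.shape[0]
    prev = np.zeros(m + 1, np.int32)  # rolling score rows
    cur = np.zeros(m + 1, np.int32)
    ptr = np.zeros((n + 1, m + 1), np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        cur[0] = 0
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            v = prev[j - 1] + sub
            p = 1
            u = prev[j] + gap
            if u > v:
                v = u
                p = 2
            left = cur[j - 1] + gap
            if left > v:
                v = left
                p = 3
            if v <= 0:
                v = 0
                p = 0
            cur[j] = v
            ptr[i, j] = p
            if v > best:
                best = v
                bi = i
                bj = j
        prev, cur = cur, prev
    i, j = bi, bj
    matches = 0
    cols = 0
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            if a[i - 1] == b[j - 1]:
                matches += 1
            cols += 1
            i -= 1
            j -= 1
        elif p == 2:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return best, matches, cols, i, bi, j, bj


def pairwise_identity(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
    try_reverse_complement: bool = True,
) -> tuple[float, float]:
    """Best-local-alignment identity and coverage of the shorter sequence.

    identity = matches / alignment columns of the best-scoring local
    alignment; coverage_of_shorter = aligned span on the shorter sequence
    divided by its length.  Both orientations of ``b`` are tried and the
    higher-scoring one used (forward wins ties).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    ea, eb = _encode(a), _encode(b)
    score, matches, cols, a0, a1, b0, b1 = _smith_waterman(ea, eb, match, mismatch, gap)
    if try_reverse_complement:
        rc = _smith_waterman(ea, _encode(reverse_complement(b)), match, mismatch, gap)
        if rc[0] > score:
            score, matches, cols, a0, a1, b0, b1 = rc
    if cols == 0:
        return 0.0, 0.0
    identity = matches / cols
    if len(b) <= len(a):
        coverage = (b1 - b0) / len(b)
    else:
        coverage = (a1 - a0) / len(a)
    return identity, coverage


# ------------------------------------------------------------ clustering


def cluster_library(
    library: list, identity_thr: float, coverage_thr: float
) -> list:
    """Greedy incremental clustering, longest sequence first.

    Sequences are processed sorted by length descending (ties by id); each
    joins the first existing cluster whose *representative* satisfies
    identity >= identity_thr and coverage-of-shorter >= coverage_thr, else
    founds a new cluster.  Clusters partition the library.
    """
    if not (0 < identity_thr <= 1 and 0 < coverage_thr <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    by_id = {r.id: r for r in library}
    if len(by_id) != len(library):
        raise ValueError("duplicate record ids in library")
    order = sorted(library, key=lambda r: (-r.length, r.id))
    clusters: list[Cluster] = []
    for rec in order:
        placed = False
        for cl in clusters:
            rep = by_id[cl.representative]
            ident, cov = pairwise_identity(rep.sequence, rec.sequence)
            if ident >= identity_thr and cov >= coverage_thr:
                cl.members.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(rec.id, [rec.id], identity_thr, coverage_thr))
    return clusters


def reclassify_by_cluster(clusters: list, library: list) -> tuple[list, list]:
    """Propagate classifications within clusters.

    Unclassified members adopt the classification of a curated member
    (preferred) or, failing that, a classified member; ties broken by the
    longest donor.  Clusters whose curated (or, absent curated, classified)
    members disagree are left unchanged and reported as conflicts.

    Returns (new library, conflict cluster representatives).
    """
    by_id = {r.id: r for r in library}
    out = {r.id: ConsensusRecord(r.id, r.sequence, r.classification, r.curated) for r in library}
    conflicts = []
    for cl in clusters:
        members = [by_id[m] for m in cl.members]
        donors = [m for m in members if m.curated and m.classified]
        if not donors:
            donors = [m for m in members if m.classified]
        if not donors:
            continue
        labels = {d.classification for d in donors}
        if len(labels) > 1:
            conflicts.append(cl.representative)
            continue
        label = max(donors, key=lambda d: d.length).classification
        for m in members:
            if not m.classified:
                out[m.id].classification = label
    return list(out.values()), conflicts


def tandem_overlap_reclassify(
    library: list, copies, tandem, threshold: float = 0.60
) -> tuple[list, dict]:
    """Reclassify families whose genomic copies are mostly tandem repeat.

    For each family, the fraction of its cumulative copy length intersecting
    tandem-repeat intervals is computed; families strictly above ``threshold``
    are relabelled ``TandemRepeat``.  Families with zero genomic bp are
    skipped with a warning.  Returns (new library, per-family fractions).
    """
    tandem_by_chrom: dict = {}
    for iv in tandem:
        tandem_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    fam_total: dict = {}
    fam_overlap: dict = {}
    for c in copies:
        fam = c.family_id
        fam_total[fam] = fam_total.get(fam, 0) + (c.end - c.start)
        ov = intersect_length([(c.start, c.end)], tandem_by_chrom.get(c.chrom, []))
        fam_overlap[fam] = fam_overlap.get(fam, 0) + ov
    fractions = {}
    out = []
    for rec in library:
        new = ConsensusRecord(rec.id, rec.sequence, rec.classification, rec.curated)
        total = fam_total.get(rec.id, 0)
        if total == 0:
            warnings.warn(f"family {rec.id} has no genomic copies; skipped")
        else:
            frac = fam_overlap.get(rec.id, 0) / total
            fractions[rec.id] = frac
            if frac > threshold:
                new.classification = "TandemRepeat"
        out.append(new)
    return out, fractions


def deduplicate(library: list, clusters_at_095: list) -> tuple[list, list]:
    """Keep one record per 95%-identity cluster.

    A curated member survives if present (longest curated on ties), else
    the longest member (ties by id).  Returns (library, removed ids).
    """
    by_id = {r.id: r for r in library}
    keep = set()
    removed = []
    for cl in clusters_at_095:
        members = [by_id[m] for m in cl.members]
        curated = [m for m in members if m.curated]
        pool = curated if curated else members
        survivor = sorted(pool, key=lambda r: (-r.length, r.id))[0]
        keep.add(survivor.id)
        removed.extend(m.id for m in members if m.id != survivor.id)
    return [r for r in library if r.id in keep], removed


def consensus_from_alignment(msa: list) -> str:
    """Majority consensus of equal-length gapped sequences.

    Per column: if gaps are the strict majority the column is dropped;
    otherwise the most frequent base wins, ties resolved alphabetically.
    """
    if not msa:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in msa}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    n = len(msa)
    out = []
    for col in zip(*[s.upper() for s in msa]):
        gaps = sum(1 for c in col if c == "-")
        if gaps * 2 > n:
            continue
        counts: dict = {}
        for c in col:
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.append(best)
    return "".join(out)
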