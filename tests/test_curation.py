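"""Library curation: alignment identity against an exhaustive DP oracle,
greedy clustering, reclassification rules, tandem purge, deduplication and
consensus building."""

import numpy as np
import pytest

from conftest import make_copy
from mobilome import curation as cur
from mobilome.formats import Interval


# ----------------------------------------------------------- DP oracle
def oracle_local_alignment(a, b, match=1, mismatch=-1, gap=-2):
    """Naive quadratic Smith-Waterman with the documented tie-breaks
    (diagonal > up > left; first maximal cell in row-major order)."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    P = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            cand = [(H[i - 1][j - 1] + sub, 1), (H[i - 1][j] + gap, 2), (H[i][j - 1] + gap, 3)]
            v, p = cand[0]
            for cv, cp in cand[1:]:
                if cv > v:
                    v, p = cv, cp
            if v <= 0:
                v, p = 0, 0
            H[i][j], P[i][j] = v, p
            if v > best:
                best, bi, bj = v, i, j
    i, j = bi, bj
    matches = cols = 0
    while i > 0 and j > 0 and P[i][j]:
        if P[i][j] == 1:
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif P[i][j] == 2:
            i -= 1
        else:
            j -= 1
        cols += 1
    return best, matches, cols, (i, bi), (j, bj)


def oracle_identity(a, b):
    results = []
    for bb in (b, cur.reverse_complement(b)):
        score, matches, cols, (a0, a1), (b0, b1) = oracle_local_alignment(a, bb)
        ident = matches / cols if cols else 0.0
        cov = ((b1 - b0) / len(b)) if len(b) <= len(a) else ((a1 - a0) / len(a))
        results.append((score, ident, cov))
    fwd, rc = results
    return (fwd[1], fwd[2]) if fwd[0] >= rc[0] else (rc[1], rc[2])


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def mutate(rng, seq, rate):
    bases = "ACGT"
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(bases[(bases.index(c) + rng.integers(1, 4)) % 4])
        else:
            out.append(c)
    return "".join(out)


def test_pairwise_identity_trivial_cases():
    s = "ACGT" * 25
    assert cur.pairwise_identity(s, s) == (1.0, 1.0)
    # exact prefix: full identity, coverage measured on the shorter
    assert cur.pairwise_identity(s, s[:50]) == (1.0, 1.0)
    with pytest.raises(ValueError):
        cur.pairwise_identity(s, "")


def test_pairwise_identity_matches_dp_oracle():
    rng = np.random.default_rng(7)
    for _ in range(8):
        a = random_seq(rng, int(rng.integers(120, 220)))
        b = random_seq(rng, int(rng.integers(120, 220)))
        assert cur.pairwise_identity(a, b) == pytest.approx(oracle_identity(a, b))
    # related pairs with an unambiguous alignment
    for rate in (0.02, 0.1):
        a = random_seq(rng, 200)
        b = mutate(rng, a, rate)
        assert cur.pairwise_identity(a, b) == pytest.approx(oracle_identity(a, b))


def test_pairwise_identity_uses_reverse_complement():
    rng = np.random.default_rng(3)
    a = random_seq(rng, 150)
    ident, cov = cur.pairwise_identity(a, cur.reverse_complement(a))
    assert ident == 1.0 and cov == 1.0


def _records(seqs, **kw):
    return [cur.ConsensusRecord(f"s{i}", s, **kw) for i, s in enumerate(seqs)]


def test_cluster_identical_sequences():
    recs = _records(["ACGTACGTAC" * 10] * 3)
    clusters = cur.cluster_library(recs, 0.8, 0.8)
    assert len(clusters) == 1 and sorted(clusters[0].members) == ["s0", "s1", "s2"]


def test_cluster_divergent_pair_stays_apart():
    rng = np.random.default_rng(5)
    a = random_seq(rng, 200)
    b = mutate(rng, a, 0.30)
    ident, _ = oracle_identity(a, b)
    assert ident < 0.8  # oracle confirms the pair is below threshold
    clusters = cur.cluster_library(_records([a, b]), 0.8, 0.8)
    assert len(clusters) == 2


def test_cluster_idempotent_on_representatives():
    rng = np.random.default_rng(9)
    founders = [random_seq(rng, n) for n in (300, 400, 350)]
    recs = []
    for gi, f in enumerate(founders):
        for ci in range(3):
            recs.append(cur.ConsensusRecord(f"g{gi}m{ci}", mutate(rng, f, 0.02)))
    clusters = cur.cluster_library(recs, 0.8, 0.8)
    assert len(clusters) == 3
    reps = [r for r in recs if r.id in {c.representative for c in clusters}]
    again = cur.cluster_library(reps, 0.8, 0.8)
    assert all(len(c.members) == 1 for c in again)


def test_reclassify_rules():
    recs = [
        cur.ConsensusRecord("cur1", "A" * 120, "LTR/Gypsy", curated=True),
        cur.ConsensusRecord("unk1", "A" * 100),
        cur.ConsensusRecord("unk2", "C" * 100),
        cur.ConsensusRecord("unk3", "C" * 90),
        cur.ConsensusRecord("curA", "G" * 100, "DNA/hAT", curated=True),
        cur.ConsensusRecord("curB", "G" * 110, "LTR/Copia", curated=True),
        cur.ConsensusRecord("unk4", "G" * 80),
    ]
    clusters = [
        cur.Cluster("cur1", ["cur1", "unk1"], 0.8, 0.8),
        cur.Cluster("unk2", ["unk2", "unk3"], 0.8, 0.8),
        cur.Cluster("curB", ["curA", "curB", "unk4"], 0.8, 0.8),
    ]
    out, conflicts = cur.reclassify_by_cluster(clusters, recs)
    by_id = {r.id: r for r in out}
    assert by_id["unk1"].classification == "LTR/Gypsy"
    assert by_id["unk2"].classification == "Unknown"  # all-Unknown cluster
    assert by_id["unk4"].classification == "Unknown"  # curated conflict
    assert conflicts == ["curB"]


def test_tandem_overlap_strict_threshold():
    lib = [cur.ConsensusRecord(f, "A" * 100, "LTR/Copia") for f in ("f61", "f60", "f0")]
    copies = [
        make_copy(start=0, end=100, family="f61"),
        make_copy(start=1000, end=1100, family="f60"),
        make_copy(start=2000, end=2100, family="f0"),
    ]
    tandem = [Interval("chr1", 0, 61), Interval("chr1", 1000, 1060)]
    out, fractions = cur.tandem_overlap_reclassify(lib, copies, tandem)
    by_id = {r.id: r for r in out}
    assert fractions["f61"] == pytest.approx(0.61)
    assert by_id["f61"].classification == "TandemRepeat"  # > 60% reclassified
    assert by_id["f60"].classification == "LTR/Copia"  # exactly 60%: kept
    assert by_id["f0"].classification == "LTR/Copia"


def test_tandem_overlap_order_invariant():
    lib = [cur.ConsensusRecord("f", "A" * 100, "LTR/Copia")]
    copies = [make_copy(start=0, end=100, family="f"),
              make_copy(start=500, end=700, family="f")]
    tandem = [Interval("chr1", 0, 100), Interval("chr1", 500, 600)]
    _, frac_fwd = cur.tandem_overlap_reclassify(lib, copies, tandem)
    _, frac_rev = cur.tandem_overlap_reclassify(lib, copies[::-1], tandem[::-1])
    assert frac_fwd == frac_rev


def test_tandem_overlap_zero_copy_family_warns():
    lib = [cur.ConsensusRecord("lonely", "A" * 50, "LTR/Copia")]
    with pytest.warns(UserWarning, match="lonely"):
        cur.tandem_overlap_reclassify(lib, [], [])


def test_deduplicate_prefers_curated_then_longest():
    a = cur.ConsensusRecord("A", "A" * 1000, "LTR/Gypsy", curated=True)
    b = cur.ConsensusRecord("B", "A" * 5000)
    out, removed = cur.deduplicate([a, b], [cur.Cluster("B", ["A", "B"], 0.95, 0.95)])
    assert [r.id for r in out] == ["A"] and removed == ["B"]
    # n duplicates -> one survivor
    dups = [cur.ConsensusRecord(f"d{i}", "ACGT" * 10) for i in range(5)]
    out, removed = cur.deduplicate(dups, [cur.Cluster("d0", [d.id for d in dups], 0.95, 0.95)])
    assert len(out) == 1 and len(removed) == 4
    # singleton kept
    out, removed = cur.deduplicate([a], [cur.Cluster("A", ["A"], 0.95, 0.95)])
    assert len(out) == 1 and removed == []


def test_consensus_from_alignment():
    assert cur.consensus_from_alignment(["ACGT", "ACGT", "ACGT"]) == "ACGT"
    assert cur.consensus_from_alignment(["AAG", "AAG", "GAG"]) == "AAG"
    # gap-majority column dropped; base tie resolved alphabetically
    assert cur.consensus_from_alignment(["A-C", "--C", "-TC"]) == "C"
    assert cur.consensus_from_alignment(["AC", "AG"]) == "AC"
    with pytest.raises(ValueError):
        cur.consensus_from_alignment([])
    with pytest.raises(ValueError):
        cur.consensus_from_alignment(["AC", "A"])
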