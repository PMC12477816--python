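"""sRNA / peak association: counting semantics, profiles, intersections."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_copy, mask_of
from mobilome import regulation as reg
from mobilome.formats import Interval, ReadAlignment


def read(chrom="chr1", start=0, length=21, strand="+", rid="r", mult=1):
    return ReadAlignment(rid, chrom, start, start + length, strand, mult)


def test_filter_reads_by_length_inclusive():
    reads = [read(length=n, rid=f"r{n}") for n in (19, 20, 22, 24, 25)]
    kept = reg.filter_reads_by_length(reads)
    assert [r.read_length for r in kept] == [20, 22, 24]


def test_count_reads_full_containment_rules():
    copies = [make_copy(start=100, end=400, copy_id="outer"),
              make_copy(start=150, end=300, copy_id="inner")]
    inside_both = read(start=200)
    edge_half = read(start=390)  # extends past the outer copy's end
    inside_outer = read(start=110)
    counts = reg.count_reads_over_copies([inside_both, edge_half, inside_outer], copies)
    # read inside two nested copies counts for both; edge overlap counts 0
    assert counts.tolist() == [2, 1]


def test_count_reads_matches_bruteforce():
    rng = np.random.default_rng(17)
    copies = [make_copy(start=int(s), end=int(s) + int(rng.integers(40, 2000)),
                        copy_id=f"c{i}")
              for i, s in enumerate(rng.integers(0, 200_000, 300))]
    reads = [read(start=int(s), length=int(rng.integers(20, 25)), rid=f"r{i}")
             for i, s in enumerate(rng.integers(0, 200_000, 2000))]
    counts = reg.count_reads_over_copies(reads, copies)
    brute = np.zeros(len(copies), dtype=int)
    for r in reads:
        for ci, c in enumerate(copies):
            if c.start <= r.start and r.end <= c.end:
                brute[ci] += 1
    assert counts.tolist() == brute.tolist()


def test_cpm_linearity():
    assert reg.cpm([10], 10**6)[0] == pytest.approx(10.0)
    assert reg.cpm([0], 100)[0] == 0.0
    assert reg.cpm([5], 2_000_000)[0] == pytest.approx(reg.cpm([5], 1_000_000)[0] / 2)
    with pytest.raises(ValueError):
        reg.cpm([1], 0)


def test_prefilter_counts_interpretations():
    m = pd.DataFrame({"s1": [5, 4, 0, 10], "s2": [5, 5, 0, 10]},
                     index=list("abcd"))
    assert reg.prefilter_counts(m).index.tolist() == ["a", "d"]  # row sums 10, 9, 0, 20
    assert reg.prefilter_counts(m, per_sample=True).index.tolist() == ["d"]


def test_peak_overlap_fractions():
    copies = [make_copy(start=0, end=300, copy_id="c")]
    half = [Interval("chr1", 0, 150)]
    frac, flag = reg.peak_overlap(copies, half)
    assert frac[0] == pytest.approx(0.5) and flag[0]
    frac, flag = reg.peak_overlap(copies, [Interval("chr1", 500, 600)])
    assert frac[0] == 0.0 and not flag[0]
    thirds = [Interval("chr1", 0, 100), Interval("chr1", 200, 300)]
    frac, _ = reg.peak_overlap(copies, thirds)
    assert frac[0] == pytest.approx(2 / 3)


def test_peak_overlap_matches_perbase_union():
    rng = np.random.default_rng(19)
    copies = [make_copy(start=int(s), end=int(s) + int(rng.integers(100, 3000)),
                        copy_id=f"c{i}")
              for i, s in enumerate(rng.integers(0, 90_000, 40))]
    peaks = [Interval("chr1", int(s), int(s) + int(rng.integers(50, 4000)))
             for s in rng.integers(0, 90_000, 30)]
    frac, _ = reg.peak_overlap(copies, peaks)
    peak_mask = mask_of([(p.start, p.end) for p in peaks], 120_000)
    for f, c in zip(frac, copies):
        assert f == pytest.approx(int(peak_mask[c.start:c.end].sum()) / c.length)


def test_strand_and_5prime_profile():
    genome = {"chr1": "T" * 50 + "G" * 50}
    copies = [make_copy(start=0, end=100, strand="+", copy_id="c")]
    plus = read(start=0, length=21, strand="+", rid="p")  # starts on T
    minus = ReadAlignment("m", "chr1", 10, 31, "-", 1)  # genome[30] == 'T' -> 5' A
    out = reg.strand_and_5prime_profile([plus, minus], copies, genome)
    row = out[out["length"] == 21].iloc[0]
    assert row["frac_5p_T"] == pytest.approx(0.5)  # plus read only
    assert row["frac_5p_A"] == pytest.approx(0.5)  # minus read complements T->A
    assert row["sense_fraction"] == pytest.approx(0.5)


def test_strand_profile_minus_read_ending_in_A_is_u():
    genome = {"chr1": "G" * 29 + "A" + "G" * 70}
    copies = [make_copy(start=0, end=100, strand="-", copy_id="c")]
    minus = ReadAlignment("m", "chr1", 9, 30, "-", 1)  # last genomic base = A
    out = reg.strand_and_5prime_profile([minus], copies, genome)
    assert out.iloc[0]["frac_5p_T"] == 1.0  # reverse complement of A
    assert out.iloc[0]["sense_fraction"] == 1.0


def test_association_table_and_flags():
    copies = [make_copy(start=i * 1000, end=i * 1000 + 500, copy_id=f"c{i}",
                        div=5.0 if i < 2 else 40.0, cov=0.95)
              for i in range(4)]
    stage_reads = {
        "s1": [read(start=10, rid="a"), read(start=1010, rid="b")],
        "s2": [read(start=20, rid="c")],
    }
    assoc = reg.build_association_table(copies, stage_reads, [])
    assert assoc["srna_associated"].tolist() == [True, False, False, False]
    flags = reg.flag_srna_associated(assoc)
    assert flags["prop_associated_intact"] == pytest.approx(0.5)
    assert flags["prop_associated_nonintact"] == 0.0
    # all-zero CPM -> nothing associated
    empty = reg.build_association_table(copies, {"s1": []}, [],
                                        library_sizes={"s1": 1})
    assert not empty["srna_associated"].any()


def test_intersection_stats_arithmetic():
    df = pd.DataFrame({
        "srna_associated": [True] * 22 + [False] * 8 + [True] * 3 + [False] * 67,
        "peak_associated": [True] * 22 + [True] * 8 + [False] * 3 + [False] * 67,
        "intact": [True] * 100,
    })
    out = reg.intersection_stats(df)
    assert out["intact"]["peak"] == 30 and out["intact"]["srna"] == 25
    assert out["intact"]["both"] == 22
    assert out["intact"]["p_srna_given_peak"] == pytest.approx(22 / 30)
    disjoint = pd.DataFrame({"srna_associated": [True, False],
                             "peak_associated": [False, True],
                             "intact": [True, True]})
    assert reg.intersection_stats(disjoint)["intact"]["both"] == 0


def test_metaprofile_all_ones_is_flat():
    signal = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [50_000],
                           "value": [1.0]})
    rng = np.random.default_rng(23)
    regions = []
    for i in range(60):
        s = int(rng.integers(2000, 40_000))
        regions.append(Interval("chr1", s, s + int(rng.integers(40, 3000)),
                                "-" if i % 2 else "+"))
    prof = reg.metaprofile(signal, regions, {"chr1": 50_000},
                           body_bp=1000, flank_bp=2000, bin_bp=10)
    inner = prof[~np.isnan(prof)]
    assert np.max(np.abs(inner - 1.0)) < 1e-9


def test_metaprofile_body_rescaling():
    # 500-bp body, 100 body bins -> each bin averages exactly 5 native bp
    values = np.arange(500, dtype=float)
    signal = pd.DataFrame({"chrom": "chr1", "start": np.arange(500),
                           "end": np.arange(1, 501), "value": values})
    region = Interval("chr1", 0, 500, "+")
    prof = reg.metaprofile(signal, [region], {"chr1": 500},
                           body_bp=1000, flank_bp=0, bin_bp=10)
    expected = values.reshape(100, 5).mean(axis=1)
    assert np.allclose(prof, expected)


def test_lift_to_consensus_mapping():
    copy = make_copy(start=100, end=200, cons_len=100)
    pos = np.array([100, 150, 199, 250])
    lifted = reg.lift_to_consensus(copy, pos)
    assert lifted.tolist() == [0, 50, 99, -1]
    minus = make_copy(start=100, end=200, strand="-", cons_len=100)
    minus.fragments[0].strand = "-"
    lifted = reg.lift_to_consensus(minus, np.array([100, 199]))
    assert lifted.tolist() == [99, 0]


def test_consensus_feature_coverage_detects_enrichment():
    rng = np.random.default_rng(29)
    rows = []
    for fam in range(20):
        base = rng.uniform(0.5, 1.5)
        rows.append({"family_id": f"f{fam}", "feature": "left_terminus",
                     "coverage": base * rng.uniform(0.8, 1.2)})
        rows.append({"family_id": f"f{fam}", "feature": "CDS",
                     "coverage": 3 * base * rng.uniform(0.8, 1.2)})
        rows.append({"family_id": f"f{fam}", "feature": "right_terminus",
                     "coverage": base * rng.uniform(0.8, 1.2)})
    out = reg.consensus_feature_coverage(pd.DataFrame(rows))
    assert out["report"].p_value < 0.01
    assert out["feature_means"]["CDS"] > 2 * out["feature_means"]["left_terminus"]


def test_consensus_feature_coverage_uniform_null():
    rng = np.random.default_rng(31)
    rows = [{"family_id": f"f{f}", "feature": feat, "coverage": rng.uniform(0.9, 1.1)}
            for f in range(15) for feat in ("left_terminus", "CDS", "right_terminus")]
    out = reg.consensus_feature_coverage(pd.DataFrame(rows))
    assert out["report"].p_value > 0.05


def test_expression_correlations():
    df = pd.DataFrame({
        "family_id": [f"f{i}" for i in range(20)],
        "tpm": np.arange(20, dtype=float) + 1,
        "mean_cpm_intact": np.arange(20, dtype=float),
        "mean_peak_overlap": np.linspace(1, 0, 20),
    })
    out = reg.expression_correlations(df)
    assert out["rho_srna"] == pytest.approx(1.0)
    assert out["rho_peak"] == pytest.approx(-1.0)
    assert "trend_srna" in out
    assert out["high_overlap_families"] == [f"f{i}" for i in range(5)]
    small = df.head(5)
    with pytest.warns(UserWarning, match="smoothing"):
        out2 = reg.expression_correlations(small)
    assert "trend_srna" not in out2
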