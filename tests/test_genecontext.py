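"""Site-class partitioning and TE-gene analyses."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_copy, mask_of
from mobilome import genecontext as gc
from mobilome.annotation import RepeatAnnotation
from mobilome.formats import GeneModel, Transcript


def simple_gene(gene_id="g1", chrom="chr1", start=1000, strand="+"):
    """Two-exon gene: UTR5 100bp, CDS split by a 300bp intron, UTR3 100bp."""
    exons = [(start, start + 400), (start + 700, start + 1100)]
    cds = [(start + 100, start + 400), (start + 700, start + 1000)]
    tx = Transcript(f"{gene_id}.1", gene_id, chrom, strand, exons=exons, cds=cds,
                    utr5=[(start, start + 100)], utr3=[(start + 1000, start + 1100)])
    return GeneModel(gene_id, chrom, strand, [tx])


def test_filter_te_genes_strict_threshold():
    gene = simple_gene()  # CDS = [1100,1400) + [1700,2000), 600 bp
    def annot(extra):  # covers first CDS exon fully plus `extra` bp of the second
        copies = [make_copy(start=1100, end=1400, copy_id="a"),
                  make_copy(start=1700, end=1700 + extra, copy_id="b")]
        return RepeatAnnotation(copies, [])
    # 426/600 = 71% of CDS covered -> removed
    kept, removed = gc.filter_te_genes([gene], annot(126))
    assert kept == [] and removed == ["g1.1"]
    # exactly 70% -> retained (the inequality is strict)
    kept, removed = gc.filter_te_genes([gene], annot(120))
    assert len(kept) == 1 and removed == []
    kept, _ = gc.filter_te_genes([gene], RepeatAnnotation([], []))
    assert len(kept) == 1


def test_partition_rules():
    gene_a = simple_gene("g1", start=2000)  # span [2000, 3100)
    gene_b = simple_gene("g2", start=6600)  # span [6600, 7700); gap 3500 bp
    part = gc.partition_site_classes([gene_a, gene_b], {"chr1": 10_000})
    classes = part.classes["chr1"]

    def label_at(pos):
        for lab, arr in classes.items():
            for s, e in arr:
                if s <= pos < e:
                    return lab

    assert label_at(2050) == "UTR5"
    assert label_at(2200) == "CDS"
    assert label_at(2500) == "intron"
    assert label_at(3050) == "UTR3"
    # 400 bp downstream of gene A, next gene 3.5 kb away -> proximal
    assert label_at(3500) == "intergenic_proximal"
    # >500 bp from both neighbours -> distal
    assert label_at(4900) == "intergenic_distal"
    # CDS wins over intron when genes overlap
    overlap = simple_gene("g3", start=2350)  # its UTR5/CDS fall in g1's intron
    part2 = gc.partition_site_classes([gene_a, overlap], {"chr1": 10_000})
    cls2 = part2.classes["chr1"]
    in_cds = any(s <= 2500 < e for s, e in cls2["CDS"])
    assert in_cds


def test_partition_tiles_genome_exactly():
    rng = np.random.default_rng(6)
    genes = [simple_gene(f"g{i}", start=int(s))
             for i, s in enumerate(sorted(rng.integers(0, 48_000, 8) * 1))]
    part = gc.partition_site_classes(genes, {"chr1": 50_000})
    classes = part.classes["chr1"]
    total = np.zeros(50_000, dtype=int)
    for arr in classes.values():
        for s, e in arr:
            total[s:e] += 1
    assert (total == 1).all()  # no gaps, no double labels
    assert sum(part.bp(lab) for lab in gc.SITE_CLASSES) == 50_000


def test_partition_zero_genes_all_distal():
    part = gc.partition_site_classes([], {"chr1": 5_000})
    assert part.bp("intergenic_distal") == 5_000


def test_site_class_density_perbase_oracle():
    rng = np.random.default_rng(13)
    length = 100_000
    genes = [simple_gene(f"g{i}", start=int(s))
             for i, s in enumerate(sorted(rng.integers(0, length - 2000, 12)))]
    te = [make_copy(start=int(s), end=int(s) + int(rng.integers(50, 2000)), copy_id=f"c{i}")
          for i, s in enumerate(rng.integers(0, length - 2000, 30))]
    annotation = RepeatAnnotation(te, [])
    part = gc.partition_site_classes(genes, {"chr1": length})
    density = gc.site_class_density(annotation, part)
    te_mask = mask_of([(c.start, c.end) for c in te], length)
    for row in density.itertuples():
        class_mask = mask_of(part.classes["chr1"][row.site_class], length)
        if class_mask.sum() == 0:
            continue
        expected = (te_mask & class_mask).sum() / class_mask.sum()
        assert row.te_fraction == pytest.approx(expected, abs=1e-12)


def test_assign_copy_site_class_thresholds():
    gene = simple_gene("g1", start=5000)  # span [5000, 6100)
    part = gc.partition_site_classes([gene], {"chr1": 100_000})
    # 1000-bp copy with 11 bp inside the 500-bp proximal zone -> proximal
    copy = make_copy(start=6589, end=7589)
    assert gc.assign_copy_site_class(copy, part) == "intergenic_proximal"
    # exactly 1% (10 bp) -> distal (strict >)
    copy = make_copy(start=6590, end=7590)
    assert gc.assign_copy_site_class(copy, part) == "intergenic_distal"
    # fully inside an intron -> intronic
    copy = make_copy(start=5450, end=5650)
    assert gc.assign_copy_site_class(copy, part) == "intron"


def test_compare_copy_properties_planted_contrast():
    rng = np.random.default_rng(21)
    intronic = [make_copy(start=i * 3000, end=i * 3000 + int(rng.integers(100, 500)),
                          div=float(rng.uniform(15, 30)), copy_id=f"i{i}")
                for i in range(80)]
    intergenic = [make_copy(start=500_000 + i * 6000,
                            end=500_000 + i * 6000 + int(rng.integers(1500, 5000)),
                            div=float(rng.uniform(0, 12)), copy_id=f"e{i}")
                  for i in range(80)]
    out = gc.compare_copy_properties({"intron": intronic, "intergenic": intergenic})
    assert out["length"].p_value < 0.01
    assert out["divergence"].p_value < 0.01
    with pytest.raises(ValueError, match="empty"):
        gc.compare_copy_properties({"intron": [], "intergenic": intergenic})


def test_compare_copy_properties_null_calibrated():
    rng = np.random.default_rng(22)
    same = lambda tag: [make_copy(start=i * 3000, end=i * 3000 + 500 + int(rng.integers(0, 100)),
                                  div=float(rng.uniform(0, 30)), copy_id=f"{tag}{i}")
                        for i in range(60)]
    out = gc.compare_copy_properties({"a": same("a"), "b": same("b")})
    assert out["divergence"].p_value > 0.01  # no planted difference


def test_nearest_te_distance_bins():
    gene = simple_gene("g1", start=10_000)  # span [10000, 11100)
    copies = {
        "near": make_copy(start=11_550, end=12_000, copy_id="near"),  # gap 450
        "abut": make_copy(start=11_100, end=11_500, copy_id="abut"),  # gap 0
        "far": make_copy(start=20_000, end=21_000, copy_id="far"),
    }
    out = gc.nearest_te_distance([gene], [copies["near"]])
    assert out.iloc[0]["bin"] == "<=500bp" and out.iloc[0]["distance"] == 450
    out = gc.nearest_te_distance([gene], [copies["abut"]])
    assert out.iloc[0]["distance"] == 0 and out.iloc[0]["bin"] == "<=500bp"
    out = gc.nearest_te_distance([gene], [copies["far"]])
    assert out.iloc[0]["bin"] == ">2000bp"


def test_nearest_te_distance_mirror_symmetric():
    length = 50_000
    gene = simple_gene("g1", start=10_000)
    copy = make_copy(start=13_000, end=14_000)
    d1 = gc.nearest_te_distance([gene], [copy]).iloc[0]["distance"]
    # mirrored coordinates
    gene_m = simple_gene("g2", start=length - 11_100)
    copy_m = make_copy(start=length - 14_000, end=length - 13_000)
    d2 = gc.nearest_te_distance([gene_m], [copy_m]).iloc[0]["distance"]
    assert d1 == d2


def test_genic_te_cds_ratio():
    gene = simple_gene("g1", start=1000)  # CDS 600 bp, intron [1400,1700)
    te_in_intron = RepeatAnnotation([make_copy(start=1400, end=1700)], [])
    # 300 bp of genic TE over 600 bp CDS
    assert gc.genic_te_cds_ratio(gene, te_in_intron) == pytest.approx(0.5)
    assert gc.genic_te_cds_ratio(gene, RepeatAnnotation([], [])) == 0.0
    mono = GeneModel("m1", "chr1", "+", [
        Transcript("m1.1", "m1", "chr1", "+", exons=[(0, 900)], cds=[(100, 800)])
    ])
    with pytest.raises(ValueError, match="mono-exonic"):
        gc.genic_te_cds_ratio(mono, te_in_intron)


def test_expression_vs_te_monotone():
    ratios = {f"g{i}": float(i) for i in range(10)}
    tpm = pd.DataFrame({"GA": [2.0**i for i in range(10)]},
                       index=[f"g{i}" for i in range(10)])
    out = gc.expression_vs_te(ratios, tpm)
    assert out.iloc[0]["rho"] == pytest.approx(1.0)


def test_age_mosaic_chi_square():
    table = pd.DataFrame({
        "classification": ["LINE"] * 30 + ["LTR"] * 30,
        "gene_id": [f"g{i}" for i in range(60)],
    })
    ranks = {}
    for i in range(60):
        if i < 30:
            ranks[f"g{i}"] = 1 if i < 10 else 8
        else:
            ranks[f"g{i}"] = 1 if i < 50 else 8
    out = gc.age_mosaic(table, ranks)
    assert out["table"].to_numpy().tolist() == [[10, 20], [20, 10]]
    assert round(out["chi2"], 3) == 6.667
    with pytest.raises(ValueError):  # degenerate single-rank table
        gc.age_mosaic(table, {g: 1 for g in ranks})
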