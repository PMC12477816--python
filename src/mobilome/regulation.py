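"""Small-RNA and H3K79me2 association with TE copies.

Implements the quantification conventions used throughout the association
analyses: 20-24 nt read-length filtering, full-containment multi-overlap
counting of (possibly multi-mapped) read alignments over copies, CPM
normalization, the >=10-read prefilter ahead of external differential
modelling, association flags and conditional intersection statistics,
5'-nucleotide and strandedness profiles, the scale-regions metaprofile,
coverage of consensus features (termini vs genic sequence), and the
family-level expression correlations with LOESS trend curves.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import intervals as iv
from .stats import (
    chi_square_independence,
    compare_groups,
    spearman,
    wilcoxon_ranksum,
)

__all__ = [
    "filter_reads_by_length",
    "count_reads_over_copies",
    "cpm",
    "prefilter_counts",
    "build_association_table",
    "flag_srna_associated",
    "strand_and_5prime_profile",
    "peak_overlap",
    "intersection_stats",
    "metaprofile",
    "consensus_feature_coverage",
    "expression_correlations",
]


def filter_reads_by_length(reads: list, min_nt: int = 20, max_nt: int = 24) -> list:
    """Keep reads with min_nt <= length <= max_nt (inclusive bounds)."""
    return [r for r in reads if min_nt <= r.read_length <= max_nt]


def count_reads_over_copies(reads: list, copies: list) -> np.ndarray:
    """Full-containment, multi-overlap read counting.

    An alignment is counted for a copy iff its interval is fully contained
    in the copy interval; it is counted for every containing copy, and
    every alignment of a multi-mapped read counts.  Returns an int array
    aligned with ``copies``.
    """
    counts = np.zeros(len(copies), dtype=np.int64)
    by_chrom: dict = {}
    for idx, c in enumerate(copies):
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end, idx))
    index = {}
    for chrom, items in by_chrom.items():
        items.sort()
        starts = np.array([s for s, _, _ in items], dtype=np.int64)
        ends = np.array([e for _, e, _ in items], dtype=np.int64)
        idxs = np.array([i for _, _, i in items], dtype=np.int64)
        index[chrom] = (starts, ends, idxs)
    for r in reads:
        if r.chrom not in index:
            continue
        starts, ends, idxs = index[r.chrom]
        hi = np.searchsorted(starts, r.start, side="right")
        contained = ends[:hi] >= r.end
        counts[idxs[:hi][contained]] += 1
    return counts


def cpm(counts, library_size: int) -> np.ndarray:
    """Counts per million: count / library_size * 1e6.

    ``library_size`` is the total number of filtered mapped reads (distinct
    reads, not alignments).
    """
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return np.asarray(counts, dtype=float) / library_size * 1e6


def prefilter_counts(count_matrix: pd.DataFrame, min_total: int = 10, per_sample: bool = False) -> pd.DataFrame:
    """Keep rows with at least ``min_total`` reads across all samples.

    The default reading sums across samples (row sum >= min_total);
    ``per_sample=True`` applies the stricter every-sample interpretation.
    """
    if per_sample:
        mask = (count_matrix >= min_total).all(axis=1)
    else:
        mask = count_matrix.sum(axis=1) >= min_total
    return count_matrix.loc[mask]


def build_association_table(
    copies: list,
    reads_by_stage: dict,
    peaks: list,
    library_sizes: dict | None = None,
    site_classes: list | None = None,
) -> pd.DataFrame:
    """Per-copy regulatory state table.

    Columns: per-stage counts and CPM, the all-stage sRNA association flag
    (CPM > 0 in every stage), peak overlap fraction and flag, the intact
    flag and optional site class.
    """
    df = pd.DataFrame(
        {
            "copy_id": [c.copy_id for c in copies],
            "family_id": [c.family_id for c in copies],
            "classification": [c.classification for c in copies],
            "intact": [c.intact for c in copies],
            "length": [c.length for c in copies],
        }
    )
    if site_classes is not None:
        df["site_class"] = site_classes
    for stage, reads in reads_by_stage.items():
        counts = count_reads_over_copies(reads, copies)
        lib = (
            library_sizes[stage]
            if library_sizes and stage in library_sizes
            else len({r.read_id for r in reads})
        )
        df[f"count_{stage}"] = counts
        df[f"cpm_{stage}"] = cpm(counts, lib) if lib > 0 else 0.0
    cpm_cols = [c for c in df.columns if c.startswith("cpm_")]
    df["srna_associated"] = (df[cpm_cols] > 0).all(axis=1) if cpm_cols else False
    frac, flag = peak_overlap(copies, peaks)
    df["peak_overlap_fraction"] = frac
    df["peak_associated"] = flag
    return df


def flag_srna_associated(assoc: pd.DataFrame) -> dict:
    """Association proportions by intact status + Wilcoxon on accumulation.

    Proportion of copies with CPM > 0 in every stage, overall and split by
    the intact flag, plus a Wilcoxon rank-sum comparison of mean CPM
    between intact and non-intact copies.
    """
    cpm_cols = [c for c in assoc.columns if c.startswith("cpm_")]
    mean_cpm = assoc[cpm_cols].mean(axis=1)
    intact = assoc["intact"].astype(bool)
    out = {
        "prop_associated": float(assoc["srna_associated"].mean()),
        "prop_associated_intact": float(assoc.loc[intact, "srna_associated"].mean())
        if intact.any()
        else float("nan"),
        "prop_associated_nonintact": float(assoc.loc[~intact, "srna_associated"].mean())
        if (~intact).any()
        else float("nan"),
    }
    if intact.any() and (~intact).any() and intact.sum() > 1 and (~intact).sum() > 1:
        stat, p = wilcoxon_ranksum(mean_cpm[intact], mean_cpm[~intact])
        out["wilcoxon_statistic"] = stat
        out["wilcoxon_p"] = p
    return out


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def strand_and_5prime_profile(reads: list, copies: list, genome: dict) -> pd.DataFrame:
    """Per-length sense/antisense fractions and 5' base composition.

    Sense means the read strand equals the strand of a containing copy;
    the 5' base is taken from the genome at the biological 5' end
    (reverse-complemented for minus-strand reads), so a 5' U in the RNA
    appears as T here.
    """
    by_chrom: dict = {}
    for c in copies:
        by_chrom.setdefault(c.chrom, []).append(c)
    rows = []
    for r in reads:
        host = None
        for c in by_chrom.get(r.chrom, []):
            if c.start <= r.start and r.end <= c.end:
                host = c
                break
        if r.strand == "+":
            base = genome[r.chrom][r.start].upper()
        else:
            base = _COMP.get(genome[r.chrom][r.end - 1].upper(), "N")
        rows.append(
            {
                "length": r.read_length,
                "sense": (host.strand == r.strand) if host else pd.NA,
                "base5": base,
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for length, grp in df.groupby("length"):
        stranded = grp["sense"].dropna()
        rec = {
            "length": int(length),
            "n_reads": len(grp),
            "sense_fraction": float(stranded.mean()) if len(stranded) else float("nan"),
            "antisense_fraction": float(1 - stranded.mean()) if len(stranded) else float("nan"),
        }
        for b in "ACGT":
            rec[f"frac_5p_{b}"] = float((grp["base5"] == b).mean())
        out.append(rec)
    return pd.DataFrame(out).sort_values("length").reset_index(drop=True)


def peak_overlap(copies: list, peaks: list) -> tuple[np.ndarray, np.ndarray]:
    """Per-copy fraction of the copy covered by peaks, and a >=1 bp flag."""
    peaks_by_chrom: dict = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    fracs = np.zeros(len(copies), dtype=float)
    for i, c in enumerate(copies):
        ov = iv.per_interval_overlap([(c.start, c.end)], peaks_by_chrom.get(c.chrom, []))[0]
        fracs[i] = ov / c.length
    return fracs, fracs > 0


def intersection_stats(assoc: pd.DataFrame) -> dict:
    """Venn counts and conditional proportions of sRNA vs peak association.

    Reported overall and stratified by intact status; for intact copies
    with a site-class column, a 2x2 chi-square tests whether peak
    association differs between intergenic and intronic copies.
    """

    def venn(sub: pd.DataFrame) -> dict:
        a = sub["srna_associated"].astype(bool)
        b = sub["peak_associated"].astype(bool)
        both = int((a & b).sum())
        return {
            "n": len(sub),
            "srna": int(a.sum()),
            "peak": int(b.sum()),
            "both": both,
            "p_srna_given_peak": both / int(b.sum()) if b.any() else float("nan"),
            "p_peak_given_srna": both / int(a.sum()) if a.any() else float("nan"),
        }

    out = {
        "all": venn(assoc),
        "intact": venn(assoc[assoc["intact"].astype(bool)]),
        "non_intact": venn(assoc[~assoc["intact"].astype(bool)]),
    }
    if "site_class" in assoc.columns:
        intact = assoc[assoc["intact"].astype(bool)].copy()
        intact["located"] = np.where(
            intact["site_class"].str.startswith("intergenic"), "intergenic",
            np.where(intact["site_class"] == "intron", "intronic", "other"),
        )
        sub = intact[intact["located"].isin(["intergenic", "intronic"])]
        tab = pd.crosstab(sub["located"], sub["peak_associated"].astype(bool))
        if tab.shape == (2, 2) and (tab.to_numpy().sum(axis=1) > 0).all():
            out["site_class_chi2"] = chi_square_independence(tab.to_numpy()) | {
                "table": tab
            }
    return out


def metaprofile(
    signal: pd.DataFrame,
    regions: list,
    chrom_lengths: dict,
    body_bp: int = 1000,
    flank_bp: int = 10000,
    bin_bp: int = 10,
) -> np.ndarray:
    """Scale-regions mean signal profile.

    Each region body is rescaled to ``body_bp / bin_bp`` bins (each the
    mean of the base-level signal it covers); flanks are taken in native
    ``bin_bp`` bins out to ``flank_bp`` on each side.  Minus-strand regions
    are reversed.  Bins without data (off-chromosome flank, zero-length
    slice) are NaN and ignored by the group mean.  Returns the mean profile
    (length 2*flank_bp/bin_bp + body_bp/bin_bp).
    """
    n_body = body_bp // bin_bp
    n_flank = flank_bp // bin_bp
    # cumulative sum / count per chromosome: any [s, e) mean is O(1)
    tracks: dict = {}
    for chrom, grp in signal.groupby("chrom"):
        length = chrom_lengths[chrom]
        arr = np.full(length, np.nan)
        for row in grp.itertuples():
            arr[row.start : min(row.end, length)] = row.value
        ok = ~np.isnan(arr)
        cumval = np.concatenate([[0.0], np.cumsum(np.where(ok, arr, 0.0))])
        cumcnt = np.concatenate([[0], np.cumsum(ok)])
        tracks[chrom] = (cumval, cumcnt, length)

    def span_mean(track, s, e):
        cumval, cumcnt, length = track
        s, e = max(s, 0), min(e, length)
        if s >= e:
            return np.nan
        cnt = cumcnt[e] - cumcnt[s]
        if cnt == 0:
            return np.nan
        return (cumval[e] - cumval[s]) / cnt

    profiles = np.full((len(regions), 2 * n_flank + n_body), np.nan)
    for ri, region in enumerate(regions):
        track = tracks.get(region.chrom)
        if track is None:
            continue
        prof = np.full(2 * n_flank + n_body, np.nan)
        for k in range(n_flank):  # upstream flank, native bins
            s = region.start - flank_bp + k * bin_bp
            prof[k] = span_mean(track, s, s + bin_bp)
        body_len = region.end - region.start
        edges = np.linspace(0, body_len, n_body + 1)  # body rescaled
        for k in range(n_body):
            s = int(np.floor(edges[k]))
            e = max(int(np.ceil(edges[k + 1])), s + 1)
            prof[n_flank + k] = span_mean(
                track, region.start + s, region.start + min(e, body_len)
            )
        for k in range(n_flank):  # downstream flank
            s = region.end + k * bin_bp
            prof[n_flank + n_body + k] = span_mean(track, s, s + bin_bp)
        if region.strand == "-":
            prof = prof[::-1]
        profiles[ri] = prof
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmean(profiles, axis=0)


def consensus_feature_coverage(
    per_family_feature_cov: pd.DataFrame,
    adjust: str = "bh",
) -> dict:
    """Across-feature coverage test with family as the unit.

    Input: long DataFrame with columns family_id, feature, coverage (mean
    depth over feature bp).  Empty features are excluded with a warning.
    Returns the per-feature group report (Kruskal-Wallis + Dunn with
    Benjamini-Hochberg) and the feature means.
    """
    df = per_family_feature_cov.dropna(subset=["coverage"])
    groups = {}
    for feature, grp in df.groupby("feature"):
        vals = grp["coverage"].to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(f"feature {feature!r} has <2 families; excluded")
            continue
        groups[feature] = vals
    report = compare_groups(groups, adjust=adjust)
    means = df.groupby("feature")["coverage"].mean().to_dict()
    return {"report": report, "feature_means": means}


def lift_to_consensus(copy, positions: np.ndarray) -> np.ndarray:
    """Map genomic positions inside a copy to consensus coordinates.

    Each fragment's genomic interval maps linearly onto its consensus span;
    positions outside every fragment return -1.
    """
    out = np.full(positions.shape, -1, dtype=np.int64)
    for frag in copy.fragments:
        inside = (positions >= frag.start) & (positions < frag.end)
        if not inside.any():
            continue
        g_len = frag.end - frag.start
        c_len = frag.consensus_end - frag.consensus_start
        rel = (positions[inside] - frag.start) / g_len
        if frag.strand == "-":
            rel = 1.0 - rel - 1e-12
        out[inside] = frag.consensus_start + np.minimum(
            (rel * c_len).astype(np.int64), c_len - 1
        )
    return out


def expression_correlations(
    family_table: pd.DataFrame,
    lowess_frac: float = 0.75,
    min_families_for_smoothing: int = 10,
    high_overlap_threshold: float = 0.75,
) -> dict:
    """Family-level Spearman correlations of expression with regulation.

    ``family_table`` columns: family_id, tpm, mean_cpm_intact,
    mean_peak_overlap.  Returns both correlations, LOESS trend curves
    (skipped with a warning below ``min_families_for_smoothing``), and the
    families whose mean body overlap exceeds ``high_overlap_threshold``.
    """
    df = family_table.dropna(subset=["tpm"])
    out: dict = {"n_families": len(df)}
    x_expr = np.log2(df["tpm"].to_numpy(dtype=float) + 1.0)
    for key, col in (("srna", "mean_cpm_intact"), ("peak", "mean_peak_overlap")):
        y = df[col].to_numpy(dtype=float)
        rho, p = spearman(y, x_expr)
        out[f"rho_{key}"] = rho
        out[f"p_{key}"] = p
        if len(df) >= min_families_for_smoothing:
            out[f"trend_{key}"] = lowess(x_expr, y, frac=lowess_frac, return_sorted=True)
        else:
            warnings.warn("too few families for LOESS smoothing; skipped")
    out["high_overlap_families"] = df.loc[
        df["mean_peak_overlap"] > high_overlap_threshold, "family_id"
    ].tolist()
    return out
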