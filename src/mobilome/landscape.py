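"""Windowed repeat densities and compartment statistics.

Covers the chromosome-scale analyses: fixed-width window densities of TE,
tandem and CDS sequence (100-kb genome-wide, 50-kb within the small
sex-determining regions, 5-kb windows anchored at the subtelomeric
satellite), compartment comparisons (Kruskal-Wallis + Dunn with Bonferroni,
or Wilcoxon rank-sum for two groups), the cut:copy mechanism ratio,
per-megabase superfamily enrichment (log2 fold change over the autosomes),
and the subtelomere proximity profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv
from .formats import Interval
from .stats import GroupTestReport, compare_groups

__all__ = [
    "CompartmentMap",
    "make_windows",
    "window_density",
    "compare_compartments",
    "cut_copy_ratio",
    "superfamily_enrichment",
    "subtelomere_profile",
]

COMPARTMENT_LABELS = (
    "autosome",
    "PAR",
    "SDR_male",
    "SDR_female",
    "centromere",
    "subtelomere_anchor",
)


@dataclass
class CompartmentMap:
    """Labelled compartment intervals (autosome/PAR/SDR/...)."""

    intervals: list  # of Interval, label in COMPARTMENT_LABELS

    def by_label(self, label: str) -> dict:
        out: dict = {}
        for i in self.intervals:
            if i.label == label:
                out.setdefault(i.chrom, []).append((i.start, i.end))
        return {k: iv.merge(v) for k, v in out.items()}

    def labels(self) -> list:
        seen = []
        for i in self.intervals:
            if i.label not in seen:
                seen.append(i.label)
        return seen

    def majority_label(self, chrom: str, start: int, end: int) -> str:
        """Majority-bp compartment label of a window (ties by label order)."""
        best_label, best_bp = "", -1
        for label in self.labels():
            if label in ("centromere", "subtelomere_anchor"):
                continue  # overlays, not primary compartments
            bp = iv.intersect_length([(start, end)], self.by_label(label).get(chrom, []))
            if bp > best_bp:
                best_label, best_bp = label, bp
        return best_label


def make_windows(
    chrom_lengths: dict,
    width: int,
    anchors: dict | None = None,
) -> pd.DataFrame:
    """Non-overlapping windows per chromosome.

    Plain mode tiles [0, length) from zero; the last partial window is kept
    and flagged.  Anchored mode (``anchors``: chrom -> (position, '+'|'-'))
    numbers windows 1, 2, ... from the anchor toward the centromere: '+'
    walks to increasing coordinates starting at the anchor, '-' to
    decreasing coordinates ending at the anchor.  Chromosomes missing from
    ``anchors`` are skipped in anchored mode.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if anchors is not None:
            if chrom not in anchors:
                continue
            pos, direction = anchors[chrom]
            index = 1
            if direction == "+":
                start = pos
                while start < length:
                    end = min(start + width, length)
                    rows.append((chrom, start, end, end - start < width, index))
                    start = end
                    index += 1
            else:
                end = pos
                while end > 0:
                    start = max(end - width, 0)
                    rows.append((chrom, start, end, end - start < width, index))
                    end = start
                    index += 1
        else:
            start = 0
            while start < length:
                end = min(start + width, length)
                rows.append((chrom, start, end, end - start < width, 0))
                start = end
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "partial", "window_index"])
    return df


def window_density(
    annotation,
    windows: pd.DataFrame,
    cds_by_chrom: dict | None = None,
    compartments: CompartmentMap | None = None,
) -> pd.DataFrame:
    """Per-window covered bp and densities of TE, tandem and CDS sequence.

    Densities are computed after TE/tandem precedence resolution; a repeat
    spanning a window boundary contributes to each window proportionally.
    Also tallies cut- and copy-mechanism TE bp per window for the cut:copy
    ratio, and attaches the majority-bp compartment label when a
    compartment map is given.
    """
    te = annotation.te_by_chrom()
    tandem = annotation.tandem_by_chrom()
    mech: dict = {"cut": {}, "copy": {}}
    for c in annotation.te_copies:
        m = c.mechanism
        if m in mech:
            mech[m].setdefault(c.chrom, []).append((c.start, c.end))
    out = windows.copy()
    for col in ("te_bp", "tandem_bp", "cds_bp", "cut_bp", "copy_bp"):
        out[col] = 0
    for chrom, grp in windows.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        # windows from make_windows abut within a chromosome
        edges = np.concatenate([grp["start"].to_numpy()[:1], grp["end"].to_numpy()])
        cover = {
            "te_bp": te.get(chrom, []),
            "tandem_bp": tandem.get(chrom, []),
            "cds_bp": (cds_by_chrom or {}).get(chrom, []),
            "cut_bp": mech["cut"].get(chrom, []),
            "copy_bp": mech["copy"].get(chrom, []),
        }
        for col, ivs in cover.items():
            vals = iv.coverage_in_windows(ivs, edges)
            out.loc[grp.index, col] = vals
    length = out["end"] - out["start"]
    out["te_density"] = out["te_bp"] / length
    out["tandem_density"] = out["tandem_bp"] / length
    out["cds_density"] = out["cds_bp"] / length
    if compartments is not None:
        out["compartment"] = [
            compartments.majority_label(r.chrom, r.start, r.end)
            for r in out.itertuples()
        ]
    return out


def compare_compartments(
    stats: pd.DataFrame,
    value: str = "te_density",
    group_col: str = "compartment",
    exclude_partial: bool = True,
    adjust: str = "bonferroni",
) -> GroupTestReport:
    """Between-compartment test on window densities.

    Two groups: Wilcoxon rank-sum with continuity correction; more:
    Kruskal-Wallis followed by Dunn's test with Bonferroni adjustment.
    Partial terminal windows are excluded by default since their density
    denominators differ.
    """
    df = stats
    if exclude_partial and "partial" in df:
        df = df[~df["partial"]]
    groups = {name: grp[value].to_numpy() for name, grp in df.groupby(group_col)}
    return compare_groups(groups, adjust=adjust)


def cut_copy_ratio(annotation, region_by_chrom: dict, unit: str = "bp") -> dict:
    """Cut-and-paste over copy-and-paste TE abundance within a region.

    ``unit='bp'`` uses covered bases (default), ``unit='copies'`` counts
    copies whose midpoint falls in the region.  Unknown-subclass TEs are
    excluded from the ratio and reported separately.  When the
    copy-mechanism abundance is zero the ratio is NaN with defined=False.
    """
    totals = {"cut": 0, "copy": 0, "unknown": 0}
    for c in annotation.te_copies:
        region = region_by_chrom.get(c.chrom, [])
        if unit == "bp":
            amount = iv.per_interval_overlap([(c.start, c.end)], region)[0]
        elif unit == "copies":
            mid = (c.start + c.end) // 2
            amount = int(iv.intersect_length([(mid, mid + 1)], region) > 0)
        else:
            raise ValueError("unit must be 'bp' or 'copies'")
        totals[c.mechanism] += int(amount)
    defined = totals["copy"] > 0
    ratio = totals["cut"] / totals["copy"] if defined else float("nan")
    return {
        "ratio": ratio,
        "defined": defined,
        "cut": totals["cut"],
        "copy": totals["copy"],
        "unknown_excluded": totals["unknown"],
        "unit": unit,
    }


def superfamily_enrichment(
    annotation,
    compartments: CompartmentMap,
    reference: str = "autosome",
    epsilon: float = 1.0,
) -> pd.DataFrame:
    """Per-Mb superfamily densities and log2FC versus the reference compartment.

    log2FC = log2((density + eps) / (density_ref + eps)) with eps = 1 bp/Mb;
    a superfamily is flagged enriched in a compartment when log2FC > 1
    (strictly).
    """
    labels = [
        lab for lab in compartments.labels() if lab not in ("centromere", "subtelomere_anchor")
    ]
    sizes = {
        lab: sum(int((a[:, 1] - a[:, 0]).sum()) for a in compartments.by_label(lab).values())
        for lab in labels
    }
    sf_bp: dict = {}
    for c in annotation.te_copies:
        for lab in labels:
            region = compartments.by_label(lab).get(c.chrom, [])
            ov = iv.per_interval_overlap([(c.start, c.end)], region)[0]
            if ov:
                key = (c.classification, lab)
                sf_bp[key] = sf_bp.get(key, 0) + int(ov)
    superfamilies = sorted({k[0] for k in sf_bp})
    rows = []
    for sf in superfamilies:
        dens = {
            lab: sf_bp.get((sf, lab), 0) / (sizes[lab] / 1e6) if sizes[lab] else 0.0
            for lab in labels
        }
        ref = dens.get(reference, 0.0)
        for lab in labels:
            lfc = np.log2((dens[lab] + epsilon) / (ref + epsilon))
            rows.append(
                {
                    "superfamily": sf,
                    "compartment": lab,
                    "density_bp_per_mb": dens[lab],
                    "log2fc_vs_reference": float(lfc),
                    "enriched": bool(lfc > 1.0),
                }
            )
    return pd.DataFrame(rows)


def subtelomere_profile(anchored_stats: pd.DataFrame, value: str = "te_density") -> pd.DataFrame:
    """Median and quartiles of window density per anchored window index.

    Input is the output of :func:`window_density` on anchored windows;
    chromosomes without an anchor are simply absent.
    """
    rows = []
    for idx, grp in anchored_stats.groupby("window_index"):
        vals = grp[value].to_numpy()
        rows.append(
            {
                "window_index": int(idx),
                "n_chromosomes": len(vals),
                "median": float(np.median(vals)),
                "q1": float(np.quantile(vals, 0.25)),
                "q3": float(np.quantile(vals, 0.75)),
            }
        )
    return pd.DataFrame(rows).sort_values("window_index").reset_index(drop=True)
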