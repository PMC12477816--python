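"""Nonparametric test engine shared by the landscape, gene-context and
regulation analyses.

Kruskal-Wallis and chi-square are delegated to scipy; Dunn's tie-corrected
post hoc (with Bonferroni or Benjamini-Hochberg adjustment) is implemented
here, and the two-group comparison is the Wilcoxon rank-sum test with
continuity correction (scipy's asymptotic Mann-Whitney U, which matches R's
``wilcox.test`` default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupTestReport",
    "kruskal_wallis",
    "dunn_posthoc",
    "wilcoxon_ranksum",
    "compare_groups",
    "chi_square_independence",
    "spearman",
]


@dataclass
class GroupTestReport:
    test: str
    statistic: float
    p_value: float
    group_sizes: dict
    posthoc: pd.DataFrame | None = None
    notes: list = field(default_factory=list)


def _validate_groups(groups: dict) -> dict:
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, vals in clean.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} has n={vals.size} < 2")
    return clean


def kruskal_wallis(groups: dict) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and p.

    Degenerate all-identical input returns (0.0, 1.0) rather than the
    0/0 the tie-correction formula would produce.
    """
    clean = _validate_groups(groups)
    pooled = np.concatenate(list(clean.values()))
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*clean.values())
    return float(h), float(p)


def dunn_posthoc(groups: dict, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z tests after Kruskal-Wallis, with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j) )
    where T = sum over tied groups of (t^3 - t).
    """
    clean = _validate_groups(groups)
    names = list(clean)
    pooled = np.concatenate([clean[n] for n in names])
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    offsets = np.cumsum([0] + [clean[n].size for n in names])
    mean_ranks = {
        name: ranks[offsets[i]:offsets[i + 1]].mean() for i, name in enumerate(names)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term / (12.0 * (n_tot - 1))
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            na, nb = clean[a].size, clean[b].size
            se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
            z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if adjust == "bonferroni":
        out["p_adj"] = np.minimum(out["p_raw"] * len(out), 1.0)
    elif adjust in ("bh", "fdr_bh", "benjamini-hochberg"):
        order = np.argsort(out["p_raw"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            idx = order[rank_idx]
            prev = min(prev, out["p_raw"].iloc[idx] * m / (rank_idx + 1))
            adj[idx] = prev
        out["p_adj"] = adj
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum with continuity correction (normal approx)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need n >= 2")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided", use_continuity=True,
                           method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_groups(groups: dict, adjust: str = "bonferroni") -> GroupTestReport:
    """Dispatch: two groups -> Wilcoxon rank-sum; more -> Kruskal-Wallis + Dunn."""
    clean = _validate_groups(groups)
    sizes = {k: int(v.size) for k, v in clean.items()}
    if len(clean) < 2:
        raise ValueError("need at least two groups")
    if len(clean) == 2:
        (a, b) = clean.values()
        stat, p = wilcoxon_ranksum(a, b)
        return GroupTestReport("wilcoxon_ranksum", stat, p, sizes)
    h, p = kruskal_wallis(clean)
    post = dunn_posthoc(clean, adjust=adjust)
    return GroupTestReport("kruskal_wallis", h, p, sizes, posthoc=post)


def chi_square_independence(table) -> dict:
    """Pearson chi-square (no Yates correction) with adjusted residuals.

    Cells with expected count < 5 are flagged.  Any zero row/column margin
    raises.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin in contingency table")
    chi2, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    n = obs.sum()
    with np.errstate(invalid="ignore"):
        std_resid = (obs - expected) / np.sqrt(
            expected * np.outer(1 - row / n, 1 - col / n)
        )
    return {
        "chi2": float(chi2),
        "p_value": float(p),
        "dof": int(dof),
        "expected": expected,
        "std_residuals": std_resid,
        "low_expected": expected < 5,
    }


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank tie handling."""
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
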