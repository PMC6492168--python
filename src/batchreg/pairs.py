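"""Temporal association of lncRNAs with coding genes.

Pairs come from two sources: genomic neighbourhood (gene bodies within
1.5 kb, boundary-inclusive) and predicted triplex interactions.  Pair-level
co-expression is the Pearson correlation of per-gene z-scored expression
across the RNA time points; the distribution of r over pairs with a
differentially expressed lncRNA is compared against the full pair set
(fraction with |r| >= 0.5, kernel densities, two-sample KS on |r|), and TTS
coverage is compared between the highest-|log2FC| DE genes and the
lowest-|log2FC| non-DE genes (one-sided Mann-Whitney U and Welch t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel
from .triplex import InteractionPair


@dataclass
class PairRecord:
    lnc_id: str
    gene_id: str
    relation: str  # neighbor | triplex | both
    distance: int | None = None  # gap between gene bodies (neighbor only)
    r: float | None = None
    lnc_de: bool | None = None
    gene_de: bool | None = None


def neighbor_pairs(
    coding: Sequence[GeneModel], lncs: Sequence[GeneModel], max_dist: int = 1500
) -> list[PairRecord]:
    """lncRNA-coding pairs whose gene bodies overlap or lie within max_dist
    (gap distance, boundary-inclusive; distance 0 when overlapping)."""
    out = []
    by_scaf: dict[str, list[GeneModel]] = {}
    for g in coding:
        by_scaf.setdefault(g.scaffold, []).append(g)
    for l in lncs:
        for g in by_scaf.get(l.scaffold, ()):  # desk scale
            if l.start0 < g.end0 and l.end0 > g.start0:
                gap = 0
            else:
                gap = max(g.start0 - l.end0, l.start0 - g.end0)
            if gap <= max_dist:
                out.append(PairRecord(l.gene_id, g.gene_id, "neighbor", distance=gap))
    out.sort(key=lambda p: (p.lnc_id, p.gene_id))
    return out


def combine_pairs(
    neighbor: Sequence[PairRecord], triplex: Sequence[InteractionPair]
) -> list[PairRecord]:
    """Union of neighbor and triplex pairs with relation tags merged."""
    by_key: dict[tuple[str, str], PairRecord] = {}
    for p in neighbor:
        by_key[(p.lnc_id, p.gene_id)] = PairRecord(
            p.lnc_id, p.gene_id, "neighbor", distance=p.distance
        )
    for t in triplex:
        key = (t.lnc_id, t.gene_id)
        if key in by_key:
            by_key[key].relation = "both"
        else:
            by_key[key] = PairRecord(t.lnc_id, t.gene_id, "triplex")
    return sorted(by_key.values(), key=lambda p: (p.lnc_id, p.gene_id))


def pair_correlation(
    expr: pd.DataFrame,
    pairs: Sequence[PairRecord],
    expressed: set[str] | None = None,
) -> tuple[list[PairRecord], list[PairRecord]]:
    """Fill Pearson r (z-scored FPM across TPs) for each pair.

    Returns (pairs with r, dropped pairs).  Pairs with an unexpressed member
    are dropped; constant trajectories leave r = None (flagged, excluded
    from density summaries).
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 time points")
    x = expr.to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(expr.index)}
    kept, dropped = [], []
    for p in pairs:
        if p.lnc_id not in idx or p.gene_id not in idx or (
            expressed is not None and (p.lnc_id not in expressed or p.gene_id not in expressed)
        ):
            dropped.append(p)
            continue
        a = x[idx[p.lnc_id]]
        b = x[idx[p.gene_id]]
        if a.std() <= 1e-12 or b.std() <= 1e-12:
            p.r = None
            kept.append(p)
            continue
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        p.r = float(np.clip((za * zb).mean(), -1.0, 1.0))
        kept.append(p)
    return kept, dropped


def correlation_distribution_compare(
    pairs_all: Sequence[PairRecord],
    pairs_de_lnc: Sequence[PairRecord],
    min_pairs: int = 50,
    grid: np.ndarray | None = None,
) -> dict:
    """Compare co-expression |r| distributions of two pair sets.

    Reports Silverman-bandwidth kernel densities of r, the fraction with
    |r| >= 0.5 per set, and a two-sample KS test between the |r| values.
    """
    r_all = np.array([p.r for p in pairs_all if p.r is not None])
    r_de = np.array([p.r for p in pairs_de_lnc if p.r is not None])
    if r_all.size < min_pairs or r_de.size < min_pairs:
        raise ValueError(
            f"need >= {min_pairs} pairs with defined r in each set "
            f"(got {r_all.size} and {r_de.size})"
        )
    grid = np.linspace(-1, 1, 201) if grid is None else grid

    def _density(vals: np.ndarray) -> np.ndarray:
        if np.std(vals) <= 1e-12:
            return np.full(grid.size, np.nan)
        return stats.gaussian_kde(vals, bw_method="silverman")(grid)

    ks = stats.ks_2samp(np.abs(r_all), np.abs(r_de), method="asymp")
    return {
        "grid": grid,
        "density_all": _density(r_all),
        "density_de_lnc": _density(r_de),
        "frac_high_all": float((np.abs(r_all) >= 0.5).mean()),
        "frac_high_de_lnc": float((np.abs(r_de) >= 0.5).mean()),
        "ks_stat": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_all": int(r_all.size),
        "n_de_lnc": int(r_de.size),
    }


def coverage_group_compare(
    de_results: pd.DataFrame,
    coverage_pct: Mapping[str, float],
    n: int = 500,
) -> dict:
    """TTS coverage of the n largest-|log2FC| DE genes vs the n smallest-
    |log2FC| non-DE genes (groups disjoint by construction).

    ``coverage_pct`` maps every candidate gene to its TTS coverage (0 for
    genes without any predicted TTS).
    """
    de_mask = de_results["de"].astype(bool)
    abs_lfc = de_results["log2fc"].abs()
    de_genes = abs_lfc[de_mask].sort_values(ascending=False)
    nde_genes = abs_lfc[~de_mask].sort_values(ascending=True)
    n_a = min(n, len(de_genes))
    n_b = min(n, len(nde_genes))
    if n_a == 0 or n_b == 0:
        raise ValueError("one of the fold-change groups is empty")
    group_a = list(de_genes.index[:n_a])
    group_b = list(nde_genes.index[:n_b])
    cov_a = np.array([coverage_pct.get(g, 0.0) for g in group_a])
    cov_b = np.array([coverage_pct.get(g, 0.0) for g in group_b])
    if np.all(cov_a == cov_a[0]) and np.all(cov_b == cov_b[0]) and cov_a[0] == cov_b[0]:
        mwu_p = 1.0
        mwu_stat = float(n_a * n_b / 2)
    else:
        mwu = stats.mannwhitneyu(cov_a, cov_b, alternative="greater")
        mwu_stat, mwu_p = float(mwu.statistic), float(mwu.pvalue)
    tt = stats.ttest_ind(cov_a, cov_b, equal_var=False)
    return {
        "n_high_fc": n_a,
        "n_low_fc": n_b,
        "mean_high": float(cov_a.mean()),
        "mean_low": float(cov_b.mean()),
        "median_high": float(np.median(cov_a)),
        "median_low": float(np.median(cov_b)),
        "mwu_stat": mwu_stat,
        "mwu_pvalue": mwu_p,
        "welch_t": float(tt.statistic) if np.isfinite(tt.statistic) else 0.0,
        "welch_pvalue": float(tt.pvalue) if np.isfinite(tt.pvalue) else 1.0,
        "high_fc_genes": group_a,
        "low_fc_genes": group_b,
    }


def paired_trend_matrix(
    pairs: Sequence[PairRecord],
    expr: pd.DataFrame,
    lnc_cluster: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Long-format z-score trajectory table for pair-wise heatmaps.

    Rows: (pair, member in {lnc, gene}, tp, z), ordered by lncRNA cluster
    then correlation; deterministic under reruns.
    """
    x = expr.to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(expr.index)}
    tps = list(expr.columns)

    def _z(gid: str) -> np.ndarray:
        row = x[idx[gid]]
        sd = row.std()
        return (row - row.mean()) / sd if sd > 1e-12 else np.zeros_like(row)

    ordered = sorted(
        [p for p in pairs if p.lnc_id in idx and p.gene_id in idx],
        key=lambda p: (
            (lnc_cluster or {}).get(p.lnc_id, 0),
            -(p.r if p.r is not None else -2.0),
            p.lnc_id,
            p.gene_id,
        ),
    )
    rows = []
    for p in ordered:
        pair_name = f"{p.lnc_id}|{p.gene_id}"
        for member, gid in (("lnc", p.lnc_id), ("gene", p.gene_id)):
            z = _z(gid)
            for tp, val in zip(tps, z.tolist()):
                rows.append(
                    {"pair": pair_name, "member": member, "tp": tp, "z": val,
                     "lnc_cluster": (lnc_cluster or {}).get(p.lnc_id, 0),
                     "r": p.r}
                )
    return pd.DataFrame(rows)
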