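"""Chromatin-state overlap enrichment, mark-gene flags and the temporal
correlation of histone-mark signal with expression.

Overlap enrichment follows the standard segmentation-vs-target definition at
base-pair resolution:

    fold(state) = (joint / state_bases) / (target_bases / total_bases)

where ``joint`` counts bases both in the state and in the (merged) target
set.  0/0 cases are reported as NaN (undefined), never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, Interval, validate_segmentation
from .triplex import intersect_sorted, merge_intervals, total_length


@dataclass(frozen=True)
class StateEnrichment:
    state: int
    target_name: str
    fold_enrichment: float  # NaN when undefined (0/0)
    bases_joint: int
    bases_state: int
    bases_target: int
    bases_total: int


def overlap_enrichment(
    segmentation: Sequence[Interval],
    targets: Sequence[Interval],
    genome_size: int,
    target_name: str = "target",
    validate: bool = True,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> list[StateEnrichment]:
    """Per-state fold enrichment of a target interval set."""
    if validate:
        validate_segmentation(segmentation, dict(scaffold_lengths) if scaffold_lengths else None)
    tgt_by_scaf: dict[str, list[tuple[int, int]]] = {}
    for iv in targets:
        tgt_by_scaf.setdefault(iv.scaffold, []).append((iv.start, iv.end))
    tgt_by_scaf = {k: merge_intervals(v) for k, v in tgt_by_scaf.items()}
    bases_target = sum(total_length(v) for v in tgt_by_scaf.values())

    seg_by: dict[int, dict[str, list[tuple[int, int]]]] = {}
    for iv in segmentation:
        state = int(iv.label.lstrip("E"))
        seg_by.setdefault(state, {}).setdefault(iv.scaffold, []).append((iv.start, iv.end))

    out = []
    for state in sorted(seg_by):
        bases_state = 0
        joint = 0
        for scaf, ivs in seg_by[state].items():
            merged = merge_intervals(ivs)
            bases_state += total_length(merged)
            joint += total_length(intersect_sorted(merged, tgt_by_scaf.get(scaf, [])))
        if bases_state == 0 or bases_target == 0:
            fold = float("nan")
        else:
            fold = (joint / bases_state) / (bases_target / genome_size)
        out.append(
            StateEnrichment(state, target_name, fold, joint, bases_state, bases_target, genome_size)
        )
    return out


# ---------------------------------------------------------------------------
# mark-gene flags
# ---------------------------------------------------------------------------

PROMOTER_STATES = frozenset({9, 10})
BODY_STATE = 4


def _overlaps_any(lo: int, hi: int, ivs: Sequence[tuple[int, int]]) -> bool:
    for s, e in ivs:
        if s < hi and e > lo:
            return True
        if s >= hi:
            break
    return False


def mark_gene_flags(
    genes: Sequence[GeneModel],
    segmentation: Sequence[Interval],
    peaks: Mapping[str, Sequence[Interval]],
    promoter_half: int = 500,
) -> pd.DataFrame:
    """Per-gene flags for one time point.

    has_k36_e4: gene body overlaps a state-4 segment AND an H3K36me3 peak;
    has_k4_e910 / has_k27ac_e910: TSS+/-500 bp overlaps a state-9/10 segment
    AND the respective mark peak.  Missing mark tracks yield NA columns.
    """
    seg_body: dict[str, list[tuple[int, int]]] = {}
    seg_prom: dict[str, list[tuple[int, int]]] = {}
    for iv in segmentation:
        st = int(iv.label.lstrip("E"))
        if st == BODY_STATE:
            seg_body.setdefault(iv.scaffold, []).append((iv.start, iv.end))
        if st in PROMOTER_STATES:
            seg_prom.setdefault(iv.scaffold, []).append((iv.start, iv.end))
    peak_by: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for mark, ivs in peaks.items():
        d: dict[str, list[tuple[int, int]]] = {}
        for iv in ivs:
            d.setdefault(iv.scaffold, []).append((iv.start, iv.end))
        peak_by[mark] = {k: merge_intervals(v) for k, v in d.items()}
    for d in (seg_body, seg_prom):
        for k in d:
            d[k] = merge_intervals(d[k])

    rows = []
    for g in genes:
        body = (g.start0, g.end0)
        prom = (g.tss0 - promoter_half, g.tss0 + promoter_half)
        body_e4 = _overlaps_any(*body, seg_body.get(g.scaffold, []))
        prom_e910 = _overlaps_any(*prom, seg_prom.get(g.scaffold, []))

        def _mark(mark: str, lo: int, hi: int, state_ok: bool):
            if mark not in peak_by:
                return pd.NA
            return bool(state_ok and _overlaps_any(lo, hi, peak_by[mark].get(g.scaffold, [])))

        rows.append(
            {
                "gene_id": g.gene_id,
                "has_k36_e4": _mark("H3K36me3", *body, body_e4),
                "has_k4_e910": _mark("H3K4me3", *prom, prom_e910),
                "has_k27ac_e910": _mark("H3K27ac", *prom, prom_e910),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def aggregate_flags(per_tp_flags: Sequence[pd.DataFrame], min_frac: float = 0.5) -> pd.DataFrame:
    """A gene carries a mark for trend analysis if flagged in >= min_frac of TPs."""
    stacked = pd.concat(per_tp_flags, keys=range(len(per_tp_flags)))
    frac = stacked.astype(float).groupby(level=1).mean()
    return frac >= min_frac


# ---------------------------------------------------------------------------
# temporal mark-expression correlation
# ---------------------------------------------------------------------------

def zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    x = df.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 1e-12, (x - mean) / np.where(sd > 1e-12, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=df.index, columns=df.columns)


def mark_expression_correlation(
    expr_z: pd.DataFrame,
    signal_z: pd.DataFrame,
    tp_alignment: Mapping[int, int],
) -> pd.DataFrame:
    """Per-gene Pearson r (and two-sided t-based p) across aligned time points.

    ``tp_alignment`` maps RNA TP number (1-based column position of expr_z)
    to chip TP number (1-based column position of signal_z).
    """
    rna_tps = sorted(tp_alignment)
    if len(rna_tps) < 3:
        raise ValueError("need >= 3 aligned time points")
    e = expr_z.to_numpy(dtype=float)[:, [k - 1 for k in rna_tps]]
    genes = expr_z.index
    sig = signal_z.reindex(genes).to_numpy(dtype=float)[:, [tp_alignment[k] - 1 for k in rna_tps]]
    n = len(rna_tps)
    ec = e - e.mean(axis=1, keepdims=True)
    sc = sig - sig.mean(axis=1, keepdims=True)
    denom = np.sqrt((ec**2).sum(axis=1) * (sc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ec * sc).sum(axis=1) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.where(np.isfinite(r), p, np.nan)
    return pd.DataFrame({"r": r, "pvalue": p, "n_tp": n}, index=genes)


def flag_group_fc_distribution(
    de_results: pd.DataFrame, flags: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Partition genes by how many of the three active marks they carry and
    summarise the log2 fold-change distribution per group."""
    flag_cols = ["has_k36_e4", "has_k4_e910", "has_k27ac_e910"]
    common = de_results.index.intersection(flags.index)
    nmarks = flags.loc[common, flag_cols].fillna(False).astype(bool).sum(axis=1)
    group = pd.Series(
        pd.Categorical(
            np.select(
                [nmarks == 3, nmarks == 2, nmarks == 1],
                ["all_three", "exactly_two", "exactly_one"],
                default="none",
            ),
            categories=["all_three", "exactly_two", "exactly_one", "none"],
        ),
        index=common,
        name="mark_group",
    )
    lfc = de_results.loc[common, "log2fc"]
    rows = []
    for name, members in lfc.groupby(group, observed=False):
        if len(members) == 0:
            continue  # empty group: summary omitted
        rows.append(
            {
                "group": name,
                "n": len(members),
                "mean_log2fc": members.mean(),
                "median_log2fc": members.median(),
                "median_abs_log2fc": members.abs().median(),
            }
        )
    return group, pd.DataFrame(rows).set_index("group")
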