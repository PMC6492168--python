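"""TSS-centred CpG methylation metagene profiles with LOESS smoothing.

Each CpG passing the coverage filter (>= 10 reads by default) is assigned a
strand-aware offset from the TSS of every gene whose window contains it
(negative = the gene's 5' side); offsets are kept at 1 bp resolution and all
smoothing is done by LOESS (local linear, tricube weights, span 0.75).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import GeneModel, MethylRecord


@dataclass
class MetaProfile:
    table: pd.DataFrame  # columns: offset, n_cpg, mean_meth, smoothed
    group: str
    window: int
    min_cov: int
    note: str = ""

    @property
    def empty(self) -> bool:
        return len(self.table) == 0

    def mean_in(self, lo: int, hi: int) -> float:
        """CpG-weighted mean methylation over offsets in [lo, hi]."""
        t = self.table[(self.table.offset >= lo) & (self.table.offset <= hi)]
        if not len(t):
            return float("nan")
        return float(np.average(t.mean_meth, weights=t.n_cpg))


def loess_smooth(x: Sequence[float], y: Sequence[float], span: float = 0.75) -> np.ndarray:
    """LOESS (local linear regression, tricube weights) evaluated at x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if x.size < 10:
        warnings.warn("fewer than 10 points; returning y unsmoothed")
        return y.copy()
    fitted = lowess(y, x, frac=span, it=0, return_sorted=False)
    return np.asarray(fitted, dtype=float)


def tss_profile(
    meth_records: Iterable[MethylRecord],
    genes: Sequence[GeneModel],
    window: int = 3000,
    min_cov: int = 10,
    group: str = "",
    span: float = 0.75,
) -> MetaProfile:
    """Metagene methylation profile around the TSSs of one gene group.

    A CpG inside the windows of two genes contributes to both.
    """
    if not genes:
        return MetaProfile(
            pd.DataFrame(columns=["offset", "n_cpg", "mean_meth", "smoothed"]),
            group, window, min_cov, note="empty gene group",
        )
    by_scaf: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaf.setdefault(g.scaffold, []).append(g)
    # sort genes by tss for a windowed sweep over sorted CpGs
    for v in by_scaf.values():
        v.sort(key=lambda g: g.tss0)

    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    recs = [r for r in meth_records if r.coverage >= min_cov]
    recs.sort(key=lambda r: (r.scaffold, r.position))
    for scaf, gset in by_scaf.items():
        tss = np.array([g.tss0 for g in gset])
        strands = [g.strand for g in gset]
        scaf_recs = [r for r in recs if r.scaffold == scaf]
        if not scaf_recs:
            continue
        pos = np.array([r.pos0 for r in scaf_recs])
        fra = np.array([r.meth_fraction for r in scaf_recs])
        lo_idx = np.searchsorted(pos, tss - window, side="left")
        hi_idx = np.searchsorted(pos, tss + window, side="right")
        for gi in range(tss.size):
            sl = slice(lo_idx[gi], hi_idx[gi])
            if sl.start >= sl.stop:
                continue
            off = pos[sl] - tss[gi]
            if strands[gi] == "-":
                off = -off
            for o, f in zip(off.tolist(), fra[sl].tolist()):
                if -window <= o <= window:
                    sums[o] = sums.get(o, 0.0) + f
                    counts[o] = counts.get(o, 0) + 1
    if not sums:
        return MetaProfile(
            pd.DataFrame(columns=["offset", "n_cpg", "mean_meth", "smoothed"]),
            group, window, min_cov, note="no CpGs passed the coverage filter",
        )
    offsets = np.array(sorted(sums))
    mean = np.array([sums[o] / counts[o] for o in offsets.tolist()])
    n = np.array([counts[o] for o in offsets.tolist()])
    smoothed = loess_smooth(offsets, mean, span=span) if offsets.size >= 10 else mean
    table = pd.DataFrame(
        {"offset": offsets, "n_cpg": n, "mean_meth": mean, "smoothed": smoothed}
    )
    return MetaProfile(table, group, window, min_cov)
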