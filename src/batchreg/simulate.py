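"""Seeded synthetic batch-culture dataset with planted structure.

The generator emulates the statistical design of a 9-day CHO batch culture:
RNA-seq every 24 h (9 time points: TP1, TP3, ..., TP17), ChIP-derived
chromatin data every 12 h (18 time points: TP1..TP18), three growth phases
(exponential TP1-7, stationary TP9-11, decline TP13-17 in RNA labels),
negative-binomial counts with four differential-expression trajectory
archetypes, promoter-localised active chromatin states, bimodal promoter
CpG methylation (ON/OFF), histone-mark signal coupled to expression, and
purine-motif triplex interactions planted between lncRNA transcripts and
coding-gene promoters.

Everything is deterministic given the seed (each stage derives an
independent child stream), and the returned :class:`SyntheticTruth` is
sufficient to score every downstream recovery analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    GeneModel,
    GenomeScaffold,
    Interval,
    make_sample_sheet,
    write_bed,
    write_counts,
    write_fasta,
    write_gtf,
    write_methylation,
    write_signal,
    MethylRecord,
)
from .triplex import revcomp

RNA_TP_LABELS = [f"TP{2 * k - 1}" for k in range(1, 10)]  # TP1, TP3, ... TP17
CHIP_TP_LABELS = [f"TP{t}" for t in range(1, 19)]
RNA_HOURS = [17 + 24 * (k - 1) for k in range(1, 10)]
CHIP_HOURS = [17 + 12 * (t - 1) for t in range(1, 19)]
RNA_PHASES = ["exponential"] * 4 + ["stationary"] * 2 + ["decline"] * 3
# RNA time point k is sampled at the same hour as chromatin time point 2k-1
RNA_TO_CHIP = {k: 2 * k - 1 for k in range(1, 10)}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    seed: int = 1
    n_scaffolds: int = 5
    scaffold_len: int = 1_000_000
    n_coding: int = 300
    n_lnc: int = 600
    n_rna_tp: int = 9
    n_chip_tp: int = 18
    phase_boundaries: tuple[float, float] = (102.0, 150.0)  # hours: exp|stat|decline
    frac_expressed: float = 0.8
    frac_de_coding: float = 0.3
    frac_de_lnc: float = 0.15
    frac_unmarked_de: float = 0.12
    archetype_effects: float = 2.0  # peak-to-trough log2 fold change
    nb_dispersion: float = 0.1
    n_planted_pairs: int = 40
    planted_tfo_len: int = 25
    planted_mismatches: int = 0
    frac_planted_lnc_de: float = 0.6
    plant_targets: str = "de"  # 'de' (paper-like) or 'random' (null design)
    coupling_r: float = 0.8
    meth_expressed_mean: float = 0.10
    meth_silent_mean: float = 0.90
    frac_neg_control_lnc: float = 0.2
    coding_len: tuple[int, int] = (1_000, 10_000)
    lnc_len: tuple[int, int] = (200, 2_000)
    max_background_purine_run: int = 15
    baseline_log_mean_coding: float = 5.0  # ln-scale location of baseline counts
    baseline_log_mean_lnc: float = 3.4
    baseline_log_sd: float = 0.8

    def __post_init__(self):
        for f_name in ("n_scaffolds", "scaffold_len", "n_coding", "n_lnc",
                       "n_rna_tp", "n_chip_tp", "n_planted_pairs"):
            if getattr(self, f_name) <= 0:
                raise ConfigError(f"{f_name} must be positive")
        if not 0.0 < self.frac_de_coding < 1.0:
            raise ConfigError("frac_de_coding must be in (0,1)")
        if self.planted_tfo_len < 20:
            raise ConfigError("planted_tfo_len must be >= 20 (minimum triplex length)")
        if self.plant_targets not in ("de", "random"):
            raise ConfigError("plant_targets must be 'de' or 'random'")
        if self.n_rna_tp != 9 or self.n_chip_tp != 18:
            raise ConfigError("the batch design is fixed at 9 RNA / 18 chip time points")


@dataclass
class PlantedPair:
    lnc_id: str
    gene_id: str
    sign: int  # intended correlation sign
    coupled: bool  # lncRNA is differentially expressed
    scaffold: str
    tts_start: int  # plus-strand genome coords of the planted duplex site
    tts_end: int
    rna_motif_start: int  # transcript coords of the TFO
    rna_motif_end: int
    mismatches: int


@dataclass
class SyntheticTruth:
    expressed: dict[str, bool] = field(default_factory=dict)
    de_cluster: dict[str, int] = field(default_factory=dict)  # gene -> archetype 1..4
    lnc_de_cluster: dict[str, int] = field(default_factory=dict)
    unmarked_de: list[str] = field(default_factory=list)
    coupled_genes: list[str] = field(default_factory=list)
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    negative_control_lnc: list[str] = field(default_factory=list)
    motif_regions: list[tuple[str, int, int]] = field(default_factory=list)  # genomic

    def to_json(self, path: str | Path) -> None:
        payload = {
            "expressed": self.expressed,
            "de_cluster": self.de_cluster,
            "lnc_de_cluster": self.lnc_de_cluster,
            "unmarked_de": self.unmarked_de,
            "coupled_genes": self.coupled_genes,
            "planted_pairs": [asdict(p) for p in self.planted_pairs],
            "negative_control_lnc": self.negative_control_lnc,
            "motif_regions": self.motif_regions,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticDataset:
    config: SimConfig
    scaffolds: list[GenomeScaffold]
    genes: list[GeneModel]
    counts: pd.DataFrame  # genes x rna samples
    mu: pd.DataFrame  # expected counts before library scaling
    rna_samples: pd.DataFrame
    chip_samples: pd.DataFrame
    truth: SyntheticTruth
    segmentations: dict[int, list[Interval]] = field(default_factory=dict)  # chip tp -> intervals
    peaks: dict[tuple[str, int], list[Interval]] = field(default_factory=dict)
    signal: dict[str, pd.DataFrame] = field(default_factory=dict)  # mark -> genes x chip tp
    methylation: list[MethylRecord] = field(default_factory=list)

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {s.id: len(s.sequence) for s in self.scaffolds}

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stage])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _cap_purine_runs(codes: np.ndarray, cap: int, rng: np.random.Generator) -> None:
    """Break every homopurine run longer than ``cap`` with pyrimidines."""
    is_pur = (codes == 0) | (codes == 2)  # A or G
    n = codes.size
    boundaries = np.flatnonzero(np.diff(is_pur.astype(np.int8)) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [n]])
    for s, e in zip(starts.tolist(), ends.tolist()):
        if not is_pur[s] or e - s <= cap:
            continue
        for pos in range(s + cap, e, cap + 1):
            codes[pos] = rng.choice([1, 3])  # C or T


def generate_genome(config: SimConfig) -> tuple[list[GenomeScaffold], list[GeneModel]]:
    """Background scaffolds (homopurine runs capped) and non-overlapping genes."""
    rng = _rng(config, 1)
    raw: list[np.ndarray] = []
    for _ in range(config.n_scaffolds):
        codes = rng.integers(0, 4, config.scaffold_len, dtype=np.int8)
        _cap_purine_runs(codes, config.max_background_purine_run, rng)
        raw.append(codes)

    specs: list[tuple[str, int, str]] = []  # (gene_id, length, biotype)
    for i in range(config.n_coding):
        specs.append((f"g{i + 1:04d}", int(rng.integers(*config.coding_len)), "coding"))
    for i in range(config.n_lnc):
        bt = "processed_transcript" if rng.random() < 0.1 else "lncRNA"
        specs.append((f"l{i + 1:04d}", int(rng.integers(*config.lnc_len)), bt))
    order = rng.permutation(len(specs))
    queue = [specs[i] for i in order]

    genes: list[GeneModel] = []
    scaf_idx = 0
    cursor = int(rng.integers(700, 2800))
    prev_coding = False
    while queue:
        if scaf_idx >= config.n_scaffolds:
            raise ConfigError("gene models do not fit on the configured scaffolds")
        gid, length, bt = queue[0]
        # a share of lncRNAs sit within 1.5 kb of the previous coding gene
        if prev_coding and bt != "coding" and rng.random() < 0.35:
            gap = int(rng.integers(50, 1401))
        else:
            gap = int(rng.integers(700, 2800))
        start0 = cursor + gap if genes and genes[-1].scaffold == f"scaf{scaf_idx + 1}" else cursor
        if start0 + length > config.scaffold_len - 700:
            scaf_idx += 1
            cursor = int(rng.integers(700, 2800))
            prev_coding = False
            continue
        queue.pop(0)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=gid,
                scaffold=f"scaf{scaf_idx + 1}",
                strand=strand,
                start=start0 + 1,
                end=start0 + length,
                biotype=bt,
            )
        )
        cursor = start0 + length
        prev_coding = bt == "coding"

    scaffolds = [
        GenomeScaffold(f"scaf{i + 1}", _BASE_BYTES[raw[i]].tobytes().decode())
        for i in range(config.n_scaffolds)
    ]
    genes.sort(key=lambda g: (g.scaffold, g.start))
    return scaffolds, genes


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

# archetype log2 offsets by phase (exponential, stationary, decline), in units
# of half the peak-to-trough effect; cluster 1 decreases monotonically,
# 2 rises at stationary and stays up, 3 rises only in decline, 4 is a
# transient stationary peak.  Shapes are kept mutually separable (max
# pairwise center correlation 0.63 after z-scoring) so soft clustering can
# resolve them at the default noise level.
_ARCHETYPE_PHASE = {
    1: (+1.0, 0.0, -1.0),
    2: (-1.0, +1.0, +1.0),
    3: (-1.0, -1.0, +1.0),
    4: (-0.2, +1.4, -0.6),
}
_ARCHETYPE_PROBS = (0.4, 0.2, 0.2, 0.2)


def archetype_profile(archetype: int, effect: float) -> np.ndarray:
    """Per-RNA-time-point log2 offsets for one trajectory archetype."""
    a, s, d = _ARCHETYPE_PHASE[archetype]
    half = effect / 2.0
    return np.array([a] * 4 + [s] * 2 + [d] * 3, dtype=float) * half


def _draw_counts(mu: np.ndarray, dispersion: float, lib_factors: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    lam = mu * lib_factors[None, :]
    if dispersion <= 0:
        return rng.poisson(lam)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, lam * dispersion))


def generate_expression(config: SimConfig, genes: list[GeneModel],
                        truth: SyntheticTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts (genes x 9 RNA samples) and the expected-count matrix.

    Fills ``truth`` with expressed flags, DE assignments and archetypes.
    """
    rng = _rng(config, 2)
    gene_ids = [g.gene_id for g in genes]
    coding = [g.gene_id for g in genes if g.biotype == "coding"]
    noncoding = [g.gene_id for g in genes if g.biotype != "coding"]

    for gid in gene_ids:
        truth.expressed[gid] = bool(rng.random() < config.frac_expressed)

    # negative-control lncRNAs: never DE, never planted
    nc_pool = [g for g in noncoding if truth.expressed[g]]
    n_nc = int(round(config.frac_neg_control_lnc * len(noncoding)))
    truth.negative_control_lnc = sorted(
        rng.choice(nc_pool, size=min(n_nc, len(nc_pool)), replace=False).tolist()
    )

    expr_coding = [g for g in coding if truth.expressed[g]]
    n_de = int(round(config.frac_de_coding * len(expr_coding)))
    de_genes = rng.choice(expr_coding, size=n_de, replace=False).tolist()
    archetypes = rng.choice([1, 2, 3, 4], size=n_de, p=_ARCHETYPE_PROBS)
    for gid, k in zip(de_genes, archetypes.tolist()):
        truth.de_cluster[gid] = int(k)
    n_unmarked = int(round(config.frac_unmarked_de * n_de))
    truth.unmarked_de = sorted(rng.choice(de_genes, size=n_unmarked, replace=False).tolist())

    lnc_pool = [g for g in nc_pool if g not in set(truth.negative_control_lnc)]
    n_de_lnc = int(round(config.frac_de_lnc * len(lnc_pool)))
    de_lnc = rng.choice(lnc_pool, size=n_de_lnc, replace=False).tolist()
    for gid, k in zip(de_lnc, rng.choice([1, 2, 3, 4], size=n_de_lnc).tolist()):
        truth.lnc_de_cluster[gid] = int(k)

    n_tp = config.n_rna_tp
    mu = np.zeros((len(gene_ids), n_tp))
    idx = {g: i for i, g in enumerate(gene_ids)}
    base = {}
    for g in genes:
        loc = (config.baseline_log_mean_coding if g.biotype == "coding"
               else config.baseline_log_mean_lnc)
        base[g.gene_id] = float(np.exp(rng.normal(loc, config.baseline_log_sd)))
    for gid in gene_ids:
        if not truth.expressed[gid]:
            continue
        effect = config.archetype_effects
        if gid in truth.de_cluster:
            if gid in truth.unmarked_de:
                effect *= 2.0  # unmarked genes carry the largest fold changes
            prof = archetype_profile(truth.de_cluster[gid], effect)
        elif gid in truth.lnc_de_cluster:
            prof = archetype_profile(truth.lnc_de_cluster[gid], effect)
        else:
            prof = np.zeros(n_tp)
        mu[idx[gid]] = base[gid] * np.power(2.0, prof)

    lib = rng.uniform(0.7, 1.3, size=n_tp)
    counts = _draw_counts(mu, config.nb_dispersion, lib, rng)
    cols = [f"rna_{t}" for t in RNA_TP_LABELS]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=cols)
    counts_df.attrs["lib_factors"] = lib
    mu_df = pd.DataFrame(mu, index=gene_ids, columns=cols)
    return counts_df, mu_df


# ---------------------------------------------------------------------------
# triplex planting
# ---------------------------------------------------------------------------

def _promoter_clear(gene: GeneModel, genes_on_scaf: list[GeneModel], half: int = 500) -> bool:
    lo, hi = gene.tss0 - half, gene.tss0 + half
    if lo < 0:
        return False
    for other in genes_on_scaf:
        if other.gene_id == gene.gene_id:
            continue
        if other.start0 < hi and other.end0 > lo:
            return False
    return True


def plant_triplex_pairs(
    config: SimConfig,
    scaffolds: list[GenomeScaffold],
    genes: list[GeneModel],
    counts: pd.DataFrame,
    mu: pd.DataFrame,
    truth: SyntheticTruth,
) -> list[GenomeScaffold]:
    """Write purine TFO/TTS motif copies into the genome and couple trajectories.

    For each planted pair a purine-rich (G fraction >= 0.5) motif is written
    into the lncRNA's gene body (so the transcript carries the TFO) and its
    reverse - the antiparallel purine-strand target - into the coding gene's
    TSS+/-500 promoter window, with ``planted_mismatches`` pyrimidine
    substitutions.  Coupled pairs re-draw the lncRNA trajectory to +/- the
    target's archetype; uncoupled pairs get a sub-threshold-amplitude copy,
    so the intended correlation sign holds on expected values for every pair.
    """
    rng = _rng(config, 3)
    seqs = {s.id: bytearray(s.sequence, "ascii") for s in scaffolds}
    by_scaf: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaf.setdefault(g.scaffold, []).append(g)

    de_coding = [g for g in genes if g.gene_id in truth.de_cluster]
    expr_coding = [g for g in genes if g.biotype == "coding" and truth.expressed[g.gene_id]]
    target_pool = de_coding if config.plant_targets == "de" else expr_coding
    eligible_targets = [g for g in target_pool if _promoter_clear(g, by_scaf[g.scaffold])]
    lnc_pool = [
        g for g in genes
        if g.biotype != "coding"
        and truth.expressed[g.gene_id]
        and g.gene_id not in set(truth.negative_control_lnc)
        and g.length >= config.planted_tfo_len + 20
    ]
    if len(eligible_targets) < config.n_planted_pairs or len(lnc_pool) < config.n_planted_pairs:
        raise ConfigError("not enough eligible genes/lncRNAs to plant the requested pairs")

    targets = rng.choice(len(eligible_targets), size=config.n_planted_pairs, replace=False)
    lncs = rng.choice(len(lnc_pool), size=config.n_planted_pairs, replace=False)
    n_coupled = int(round(config.frac_planted_lnc_de * config.n_planted_pairs))
    L = config.planted_tfo_len
    used_tts: dict[str, list[tuple[int, int]]] = {}

    for p_idx, (ti, li) in enumerate(zip(targets.tolist(), lncs.tolist())):
        gene = eligible_targets[ti]
        lnc = lnc_pool[li]
        # purine motif with G fraction >= 0.5, written 5'->3' on the transcript
        while True:
            motif = "".join(rng.choice(["G", "A"], size=L, p=[0.6, 0.4]))
            if motif.count("G") * 2 >= L:
                break
        # TFO into the lncRNA gene body (strand-aware: transcript must carry it)
        off = int(rng.integers(10, lnc.length - L - 9))
        lseq = seqs[lnc.scaffold]
        if lnc.strand == "+":
            lseq[lnc.start0 + off : lnc.start0 + off + L] = motif.encode()
            rna_start = off
        else:
            gstart = lnc.end0 - off - L
            lseq[gstart : gstart + L] = revcomp(motif).encode()
            rna_start = off
        # TTS: reverse of the motif on the plus strand of the promoter window
        tts_seq = motif[::-1]
        if config.planted_mismatches:
            pos_pool = np.arange(2, L - 2)
            while True:
                mm = rng.choice(pos_pool, size=config.planted_mismatches, replace=False)
                if config.planted_mismatches < 3 or np.all(np.diff(np.sort(mm)) > 1):
                    break
            tts = list(tts_seq)
            for p in mm.tolist():
                tts[p] = "C" if rng.random() < 0.5 else "T"
            tts_seq = "".join(tts)
        attempts = 0
        while True:
            attempts += 1
            if attempts > 100:
                raise ConfigError("could not place a planted TTS without collision")
            t_start = gene.tss0 - 500 + int(rng.integers(0, 1001 - L))
            t_end = t_start + L
            if t_start < 0 or t_end > len(seqs[gene.scaffold]):
                continue
            if any(t_start < e and t_end > s for s, e in used_tts.get(gene.scaffold, [])):
                continue
            break
        seqs[gene.scaffold][t_start:t_end] = tts_seq.encode()
        used_tts.setdefault(gene.scaffold, []).append((t_start, t_end))

        sign = 1 if rng.random() < 0.5 else -1
        coupled = p_idx < n_coupled
        arch = truth.de_cluster.get(gene.gene_id, int(rng.integers(1, 5)))
        prof = archetype_profile(arch, config.archetype_effects) * sign
        if not coupled:
            prof = prof * 0.1  # sub-threshold amplitude: sign holds, DE does not
        base = float(mu.loc[lnc.gene_id].mean())
        if base <= 0:
            base = 30.0
        new_mu = base * np.power(2.0, prof - prof.mean())
        mu.loc[lnc.gene_id] = new_mu
        redraw = np.random.default_rng([int(config.seed) % (2**31), 4, p_idx])
        lib = counts.attrs.get("lib_factors", np.ones(config.n_rna_tp))
        counts.loc[lnc.gene_id] = _draw_counts(
            new_mu[None, :], config.nb_dispersion, lib, redraw
        )[0]
        if coupled:
            truth.lnc_de_cluster[lnc.gene_id] = arch
        truth.planted_pairs.append(
            PlantedPair(
                lnc_id=lnc.gene_id,
                gene_id=gene.gene_id,
                sign=sign,
                coupled=coupled,
                scaffold=gene.scaffold,
                tts_start=t_start,
                tts_end=t_end,
                rna_motif_start=rna_start,
                rna_motif_end=rna_start + L,
                mismatches=config.planted_mismatches,
            )
        )
        truth.motif_regions.append((gene.scaffold, t_start, t_end))
        if lnc.strand == "+":
            truth.motif_regions.append((lnc.scaffold, lnc.start0 + off, lnc.start0 + off + L))
        else:
            truth.motif_regions.append((lnc.scaffold, lnc.end0 - off - L, lnc.end0 - off))

    return [GenomeScaffold(s.id, seqs[s.id].decode()) for s in scaffolds]


# ---------------------------------------------------------------------------
# epigenome
# ---------------------------------------------------------------------------

MARKS = ("H3K36me3", "H3K4me3", "H3K27ac")


def _paint_runs(arr: np.ndarray, scaf: str) -> list[Interval]:
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [arr.size]])
    return [
        Interval(scaf, int(s), int(e), f"E{int(arr[s])}")
        for s, e in zip(starts, ends)
    ]


def generate_epigenome(
    config: SimConfig,
    scaffolds: list[GenomeScaffold],
    genes: list[GeneModel],
    mu: pd.DataFrame,
    truth: SyntheticTruth,
) -> tuple[dict[int, list[Interval]], dict[tuple[str, int], list[Interval]],
           dict[str, pd.DataFrame], list[MethylRecord]]:
    """Segmentations per chip TP, mark peaks + signal, and CpG methylation."""
    rng = _rng(config, 5)
    slen = {s.id: len(s.sequence) for s in scaffolds}
    gene_ids = [g.gene_id for g in genes]
    expressed = truth.expressed
    unmarked = set(truth.unmarked_de)

    # fixed per-gene choices
    silent_state = {g.gene_id: int(rng.choice([1, 3])) for g in genes}
    prom_state = {g.gene_id: int(rng.choice([9, 10])) for g in genes}
    enhancer: dict[str, tuple[int, int, int]] = {}
    for g in genes:
        if expressed[g.gene_id] and rng.random() < 0.5:
            width = int(rng.integers(200, 401))
            side = -1 if rng.random() < 0.5 else 1
            offset = int(rng.integers(600, 1400 - width))
            if side < 0:
                s = max(0, g.start0 - offset - width)
            else:
                s = min(slen[g.scaffold] - width, g.end0 + offset)
            enhancer[g.gene_id] = (s, s + width, int(rng.choice([5, 6, 7, 8])))

    segmentations: dict[int, list[Interval]] = {}
    peaks: dict[tuple[str, int], list[Interval]] = {}
    for tp in range(1, config.n_chip_tp + 1):
        ivs: list[Interval] = []
        tp_peaks: dict[str, list[Interval]] = {m: [] for m in MARKS}
        jitter = int(rng.integers(-60, 61))
        for s in scaffolds:
            arr = np.full(slen[s.id], 2, dtype=np.int16)  # quiescent default
            for g in genes:
                if g.scaffold != s.id:
                    continue
                if g.gene_id in enhancer:
                    es, ee, st = enhancer[g.gene_id]
                    arr[es:ee] = st
            for g in genes:
                if g.scaffold != s.id:
                    continue
                if not expressed[g.gene_id]:
                    arr[g.start0 : g.end0] = silent_state[g.gene_id]
                else:
                    arr[g.start0 : g.end0] = 4
            for g in genes:
                if g.scaffold != s.id or not expressed[g.gene_id]:
                    continue
                p_lo = max(0, g.tss0 - 500 + jitter)
                p_hi = min(slen[s.id], g.tss0 + 500 + jitter)
                arr[p_lo:p_hi] = prom_state[g.gene_id]
                if g.gene_id not in unmarked:
                    body_lo, body_hi = g.start0, g.end0
                    tp_peaks["H3K36me3"].append(Interval(s.id, body_lo, body_hi, "H3K36me3", 1.0))
                    q_lo, q_hi = max(0, g.tss0 - 500), g.tss0 + 500
                    tp_peaks["H3K4me3"].append(Interval(s.id, q_lo, q_hi, "H3K4me3", 1.0))
                    tp_peaks["H3K27ac"].append(Interval(s.id, q_lo, q_hi, "H3K27ac", 1.0))
            ivs.extend(_paint_runs(arr, s.id))
        segmentations[tp] = ivs
        for m in MARKS:
            peaks[(m, tp)] = sorted(tp_peaks[m], key=lambda iv: (iv.scaffold, iv.start))

    # per-mark signal coupled to the expected expression trajectory
    rho = config.coupling_r
    n_chip = config.n_chip_tp
    signal: dict[str, pd.DataFrame] = {}
    logmu = np.log2(mu.to_numpy() + 1.0)
    sd = logmu.std(axis=1, ddof=0)
    zmu = np.zeros_like(logmu)
    var_rows = sd > 1e-9
    zmu[var_rows] = (logmu[var_rows] - logmu[var_rows].mean(axis=1, keepdims=True)) / sd[var_rows][:, None]
    chip_cols = [f"chip_{t}" for t in CHIP_TP_LABELS]
    coupled = [
        gid for gid in gene_ids
        if gid in truth.de_cluster and expressed[gid] and gid not in unmarked
    ]
    truth.coupled_genes = sorted(coupled)
    coupled_set = set(coupled)
    idx = {g: i for i, g in enumerate(gene_ids)}
    # chip TP t aligns to RNA TP ceil(t/2): same hour for odd t
    align = np.array([min((t + 1) // 2, 9) - 1 for t in range(1, n_chip + 1)])
    for m in MARKS:
        mat = np.zeros((len(gene_ids), n_chip))
        noise = rng.normal(size=mat.shape)
        for gid in gene_ids:
            i = idx[gid]
            if not expressed[gid] or gid in unmarked:
                mat[i] = 0.0
                continue
            zrow = zmu[i][align]
            if gid in coupled_set:
                mat[i] = 10.0 + 3.0 * (rho * zrow + np.sqrt(1 - rho**2) * noise[i])
            else:
                mat[i] = 10.0 + 3.0 * noise[i]
        signal[m] = pd.DataFrame(mat, index=gene_ids, columns=chip_cols)

    # CpG methylation: a positional property.  Sites within hypo_radius of an
    # expressed TSS are demethylated (promoter ON); everything else - silent
    # promoters, gene bodies, flanks - carries high background methylation.
    hypo_radius = 600
    expr_tss: dict[str, np.ndarray] = {}
    for g in genes:
        if expressed[g.gene_id]:
            expr_tss.setdefault(g.scaffold, []).append(g.tss0)
    expr_tss = {k: np.sort(np.array(v)) for k, v in expr_tss.items()}
    site_by_scaf: dict[str, set[int]] = {}
    for g in genes:
        window = 3000 if g.biotype == "coding" else 1500
        offs = np.arange(-window, window, 50) + rng.integers(0, 25, size=2 * window // 50)
        pos0 = g.tss0 + (offs if g.strand == "+" else -offs)
        pos0 = pos0[(pos0 >= 0) & (pos0 < slen[g.scaffold])]
        site_by_scaf.setdefault(g.scaffold, set()).update(pos0.tolist())
    records: list[MethylRecord] = []
    kappa = 15.0
    for scaf in sorted(site_by_scaf):
        pos = np.array(sorted(site_by_scaf[scaf]))
        tss = expr_tss.get(scaf, np.array([], dtype=int))
        if tss.size:
            j = np.searchsorted(tss, pos)
            d_right = np.where(j < tss.size, np.abs(tss[np.minimum(j, tss.size - 1)] - pos), np.inf)
            d_left = np.where(j > 0, np.abs(pos - tss[np.maximum(j - 1, 0)]), np.inf)
            near_expressed = np.minimum(d_left, d_right) <= hypo_radius
        else:
            near_expressed = np.zeros(pos.size, bool)
        mean = np.where(near_expressed, config.meth_expressed_mean, config.meth_silent_mean)
        frac = rng.beta(mean * kappa, (1 - mean) * kappa)
        low_cov = rng.random(pos.size) < 0.1
        cov = np.where(low_cov, rng.poisson(5.0, pos.size), rng.poisson(30.0, pos.size))
        for p, f, c in zip(pos.tolist(), frac.tolist(), cov.tolist()):
            records.append(MethylRecord(scaf, int(p) + 1, int(c), float(f)))
    return segmentations, peaks, signal, records


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig | None = None, include_epigenome: bool = True) -> SyntheticDataset:
    """Generate the full synthetic dataset for one seed."""
    config = config or SimConfig()
    truth = SyntheticTruth()
    scaffolds, genes = generate_genome(config)
    counts, mu = generate_expression(config, genes, truth)
    scaffolds = plant_triplex_pairs(config, scaffolds, genes, counts, mu, truth)
    rna_samples = make_sample_sheet("rna", RNA_TP_LABELS, RNA_HOURS, RNA_PHASES)
    chip_samples = make_sample_sheet("chip", CHIP_TP_LABELS, CHIP_HOURS)
    ds = SyntheticDataset(
        config=config,
        scaffolds=scaffolds,
        genes=genes,
        counts=counts,
        mu=mu,
        rna_samples=rna_samples,
        chip_samples=chip_samples,
        truth=truth,
    )
    if include_epigenome:
        seg, peaks, signal, meth = generate_epigenome(config, scaffolds, genes, mu, truth)
        ds.segmentations = seg
        ds.peaks = peaks
        ds.signal = signal
        ds.methylation = meth
    return ds


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write the dataset in the exact formats the io layer reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> Path:
        paths[name] = str(out / name)
        return out / name

    write_fasta(ds.scaffolds, _p("genome.fa"))
    write_gtf(ds.genes, _p("genes.gtf"))
    write_counts(ds.counts, _p("counts.tsv"))
    ds.rna_samples.to_csv(_p("samples_rna.tsv"), sep="\t", index=False)
    ds.chip_samples.to_csv(_p("samples_chip.tsv"), sep="\t", index=False)
    for tp, ivs in ds.segmentations.items():
        write_bed(ivs, _p(f"segmentation_TP{tp:02d}.bed"))
    for (mark, tp), ivs in ds.peaks.items():
        write_bed(ivs, _p(f"peaks_{mark}_TP{tp:02d}.bed"))
    for mark, df in ds.signal.items():
        write_signal(df, _p(f"signal_{mark}.tsv"))
    if ds.methylation:
        write_methylation(ds.methylation, _p("methylation.tsv"))
    ds.truth.to_json(_p("truth.json"))
    return paths
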