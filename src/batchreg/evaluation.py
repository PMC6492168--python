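"""Recovery and calibration metrics on synthetic data with planted truth.

Every function here regenerates its inputs from a seed, runs the package's
own operations, and measures how well planted structure is recovered (or how
well null calibration holds).  The acceptance script and the test suite both
consume these; nothing is cached between runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.optimize
from scipy import stats

from . import chromatin, expression, methylation, pairs as pairmod, triplex
from .io import Interval
from .simulate import (
    RNA_TO_CHIP,
    SimConfig,
    SyntheticDataset,
    archetype_profile,
    simulate_dataset,
)
from .triplex import TriplexParams
from .triplex_oracle import brute_force_hits


def _seed(base: int, offset: int) -> int:
    return (int(base) * 7919 + offset) % (2**31)


# ---------------------------------------------------------------------------
# 1. triplex engine vs exhaustive oracle
# ---------------------------------------------------------------------------

def random_triplex_instance(rng: np.random.Generator) -> tuple[str, str]:
    """One random (RNA, DNA) instance: uniform background plus, most of the
    time, a planted purine-rich motif copy with up to 3 substitutions, so the
    instance set exercises hit-bearing cases as well as empty ones."""
    n = int(rng.integers(25, 160))
    m = int(rng.integers(80, 600))
    rna = rng.choice(list("ACGT"), size=n)
    dna = rng.choice(list("ACGTN"), size=m, p=[0.245, 0.245, 0.245, 0.245, 0.02])
    if rng.random() < 0.85:
        L = int(rng.integers(18, min(32, n - 1, m - 1)))
        motif = rng.choice(list("GA"), size=L, p=[0.6, 0.4])
        i = int(rng.integers(0, n - L + 1))
        j = int(rng.integers(0, m - L + 1))
        rna[i : i + L] = motif
        tts = motif[::-1].copy()
        for p in rng.integers(0, L, size=int(rng.integers(0, 4))):
            tts[p] = rng.choice(list("ACGT"))
        if rng.random() < 0.5:
            dna[j : j + L] = tts
        else:
            comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
            dna[j : j + L] = [comp[b] for b in tts[::-1]]
    if rng.random() < 0.3:  # extra purine-dense noise patch
        L = int(rng.integers(15, 40))
        j = int(rng.integers(0, m - L + 1))
        dna[j : j + L] = rng.choice(list("GACT"), size=L, p=[0.4, 0.4, 0.1, 0.1])
    return "".join(rna), "".join(dna)


def triplex_oracle_agreement(seed: int, n_cases: int = 200) -> dict:
    """Fraction of random instances where the seeded engine's hit set equals
    exhaustive enumeration, plus total hits checked."""
    rng = np.random.default_rng(_seed(seed, 1))
    params = TriplexParams()
    agree = 0
    total_hits = 0
    for _ in range(n_cases):
        rna, dna = random_triplex_instance(rng)
        eng = {
            (h.rna_start, h.rna_end, h.tts_start, h.tts_end, h.dna_strand)
            for h in triplex.find_triplexes(rna, dna, params)
        }
        orc = brute_force_hits(rna, dna, params)
        total_hits += len(orc)
        if eng == orc:
            agree += 1
    return {"agreement_pct": 100.0 * agree / n_cases, "n_cases": n_cases,
            "n_oracle_hits": total_hits}


# ---------------------------------------------------------------------------
# 2. planted lncRNA-gene pair recovery
# ---------------------------------------------------------------------------

def planted_pair_recovery(seed: int, mismatches: int = 0, n_seeds: int = 10) -> dict:
    """Fraction of planted pairs recovered by the full search + mapping path,
    pooled over seed-swept datasets."""
    recovered = planted = 0
    for rep in range(n_seeds):
        cfg = SimConfig(seed=_seed(seed, 100 + rep), planted_mismatches=mismatches)
        ds = simulate_dataset(cfg, include_epigenome=False)
        lnc_ids = [g.gene_id for g in ds.genes
                   if g.biotype != "coding" and ds.truth.expressed[g.gene_id]]
        hits = triplex.search_lnc_targets(ds.scaffolds, ds.genes, lnc_ids)
        found = {
            (p.lnc_id, p.gene_id)
            for p in triplex.map_tts_to_genes(
                hits, ds.genes, scaffold_lengths=ds.scaffold_lengths
            )
        }
        want = {(p.lnc_id, p.gene_id) for p in ds.truth.planted_pairs}
        planted += len(want)
        recovered += len(found & want)
    return {"recovery_pct": 100.0 * recovered / planted, "n_planted": planted,
            "n_datasets": n_seeds}


# ---------------------------------------------------------------------------
# 3. differential-expression operating characteristics
# ---------------------------------------------------------------------------

def de_operating_characteristics(seed: int, dataset: SyntheticDataset | None = None) -> dict:
    """Power and observed FDR of the phase-wise DE calls against planted truth.

    Power is reported separately for coding genes (baseline median ~150
    counts; the |log2FC|=2 design condition) and noncoding genes, whose
    realistically low baseline expression makes them intrinsically harder.
    """
    ds = dataset or simulate_dataset(SimConfig(seed=_seed(seed, 2)), include_epigenome=False)
    expressed = expression.filter_expressed(ds.counts)
    counts = ds.counts.loc[expressed]
    results = [expression.de_test(counts, ds.rna_samples, c) for c in ("ES", "ED")]
    called = set(expression.de_union(results))
    truth_coding = set(ds.truth.de_cluster) & set(expressed)
    truth_nc = set(ds.truth.lnc_de_cluster) & set(expressed)
    truth_expr = truth_coding | truth_nc
    fdr = len(called - truth_expr) / max(len(called), 1)
    return {
        "power_coding": len(called & truth_coding) / len(truth_coding),
        "power_noncoding": len(called & truth_nc) / max(len(truth_nc), 1),
        "power": len(called & truth_expr) / len(truth_expr),
        "fdr": fdr,
        "n_called": len(called),
        "n_true_de": len(truth_expr),
    }


def de_null_type1(seed: int, n_genes: int = 200, reps: int = 20) -> dict:
    """Type-I error of the NB Wald test at nominal p < 0.01 on label-permuted
    null genes (constant expected counts, dispersion 0.1, 4 vs 3 design)."""
    rng = np.random.default_rng(_seed(seed, 3))
    from .simulate import RNA_TP_LABELS, RNA_HOURS, RNA_PHASES
    from .io import make_sample_sheet
    sheet = make_sample_sheet("rna", RNA_TP_LABELS, RNA_HOURS, RNA_PHASES)
    alpha = 0.1
    hits = 0
    total = 0
    for _ in range(reps):
        mu = np.exp(rng.normal(5.0, 0.8, n_genes))
        lam = np.repeat(mu[:, None], 9, axis=1)
        counts = rng.poisson(rng.gamma(1 / alpha, lam * alpha))
        perm = rng.permutation(9)
        df = pd.DataFrame(
            counts[:, perm],
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"rna_{t}" for t in RNA_TP_LABELS],
        )
        res = expression.de_test(df, sheet, "ED")
        hits += int((res.pvalue < 0.01).sum())
        total += n_genes
    return {"type1_at_0.01": hits / total, "n_tests": total}


# ---------------------------------------------------------------------------
# 4. trajectory cluster recovery
# ---------------------------------------------------------------------------

def cluster_recovery(seed: int, dataset: SyntheticDataset | None = None) -> dict:
    ds = dataset or simulate_dataset(SimConfig(seed=_seed(seed, 4)), include_epigenome=False)
    expressed = expression.filter_expressed(ds.counts)
    counts = ds.counts.loc[expressed]
    results = [expression.de_test(counts, ds.rna_samples, c) for c in ("ES", "ED")]
    coding = {g.gene_id for g in ds.genes if g.biotype == "coding"}
    de_coding = [g for g in expression.de_union(results) if g in coding]
    z, _ = expression.vst_zscore(counts)
    clu = expression.fuzzy_cmeans(z.loc[de_coding], c=4, seed=_seed(seed, 5))
    arch = np.array([archetype_profile(k, ds.config.archetype_effects) for k in (1, 2, 3, 4)])
    az = (arch - arch.mean(axis=1, keepdims=True)) / arch.std(axis=1, keepdims=True)
    cz = (clu.centers - clu.centers.mean(axis=1, keepdims=True)) / clu.centers.std(
        axis=1, keepdims=True
    )
    corr = cz @ az.T / arch.shape[1]
    ri, ci = scipy.optimize.linear_sum_assignment(-corr)
    matched = corr[ri, ci]
    mem = clu.membership.to_numpy()
    monotone = all(b <= a + 1e-9 for a, b in zip(clu.objective_trace, clu.objective_trace[1:]))
    return {
        "min_matched_center_corr": float(matched.min()),
        "matched_corrs": [float(x) for x in matched],
        "max_membership_sum_dev": float(np.abs(mem.sum(axis=1) - 1).max()),
        "objective_monotone": bool(monotone),
        "n_genes": len(de_coding),
    }


# ---------------------------------------------------------------------------
# 5. mark-expression coupling recovery
# ---------------------------------------------------------------------------

def coupling_recovery(seed: int, dataset: SyntheticDataset | None = None) -> dict:
    ds = dataset or simulate_dataset(SimConfig(seed=_seed(seed, 6)))
    expressed = expression.filter_expressed(ds.counts)
    z, _ = expression.vst_zscore(ds.counts.loc[expressed])
    out = {}
    corr = chromatin.mark_expression_correlation(
        z, chromatin.zscore_rows(ds.signal["H3K36me3"]), RNA_TO_CHIP
    )
    coupled = [g for g in ds.truth.coupled_genes if g in corr.index]
    sub = corr.loc[coupled].dropna()
    out["frac_positive"] = float((sub.r > 0).mean())
    out["median_r"] = float(sub.r.median())
    out["n_coupled"] = len(sub)
    de = set(ds.truth.de_cluster)
    null = corr.loc[[g for g in corr.index if g not in de]].dropna()
    out["null_type1_at_0.01"] = float((null.pvalue < 0.01).mean())
    out["n_null"] = len(null)
    return out


# ---------------------------------------------------------------------------
# 6. overlap enrichment vs per-base brute force
# ---------------------------------------------------------------------------

def enrichment_correctness(seed: int) -> dict:
    """Compare interval-arithmetic enrichment against per-base counting on a
    random <= 50 kb instance, and check the whole-genome normalisation."""
    rng = np.random.default_rng(_seed(seed, 7))
    L = int(rng.integers(30_000, 50_000))
    # random segmentation into 11 states
    n_seg = int(rng.integers(50, 200))
    cuts = np.sort(rng.choice(np.arange(1, L), size=n_seg - 1, replace=False))
    bounds = [0, *cuts.tolist(), L]
    states = rng.integers(1, 12, size=n_seg)
    seg = [
        Interval("s", a, b, f"E{int(st)}")
        for a, b, st in zip(bounds[:-1], bounds[1:], states.tolist())
    ]
    # random target set (100 intervals, overlaps allowed)
    tgt = []
    for _ in range(100):
        a = int(rng.integers(0, L - 200))
        tgt.append(Interval("s", a, a + int(rng.integers(1, 200))))
    enr = chromatin.overlap_enrichment(seg, tgt, L, scaffold_lengths={"s": L})
    # brute force per-base
    state_arr = np.zeros(L, dtype=np.int16)
    for iv in seg:
        state_arr[iv.start : iv.end] = int(iv.label[1:])
    tmask = np.zeros(L, bool)
    for iv in tgt:
        tmask[iv.start : iv.end] = True
    max_diff = 0.0
    for e in enr:
        joint = int((tmask & (state_arr == e.state)).sum())
        sb = int((state_arr == e.state).sum())
        fold_bf = (joint / sb) / (tmask.sum() / L)
        max_diff = max(max_diff, abs(fold_bf - e.fold_enrichment))
        assert joint == e.bases_joint
    # whole-genome target -> fold exactly 1
    whole = chromatin.overlap_enrichment(
        seg, [Interval("s", 0, L)], L, scaffold_lengths={"s": L}
    )
    whole_dev = max(abs(e.fold_enrichment - 1.0) for e in whole)
    return {"max_abs_fold_diff": float(max_diff), "whole_genome_max_dev": float(whole_dev)}


# ---------------------------------------------------------------------------
# 7. TTS chromatin-state localisation
# ---------------------------------------------------------------------------

def _localization_tables(ds: SyntheticDataset, hits) -> pd.DataFrame:
    merged_by_scaf: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        merged_by_scaf.setdefault(h.scaffold, []).append((h.tts_start, h.tts_end))
    windows_by_scaf: dict[str, list[tuple[int, int]]] = {}
    for g in ds.genes:
        if g.biotype == "coding":
            windows_by_scaf.setdefault(g.scaffold, []).append(
                g.window0(1500, ds.scaffold_lengths[g.scaffold])
            )
    rows = []
    for tp in sorted(ds.segmentations):
        loc = triplex.tts_state_localization(
            merged_by_scaf, ds.segmentations[tp], windows_by_scaf
        )
        for gname, d in loc.items():
            rows.append({"tp": tp, "group": gname, **d})
    return pd.DataFrame(rows)


def promoter_localization(seed: int, dataset: SyntheticDataset | None = None) -> dict:
    ds = dataset or simulate_dataset(SimConfig(seed=_seed(seed, 8)))
    lnc_ids = [g.gene_id for g in ds.genes
               if g.biotype != "coding" and ds.truth.expressed[g.gene_id]]
    hits = triplex.search_lnc_targets(ds.scaffolds, ds.genes, lnc_ids)
    tab = _localization_tables(ds, hits)
    piv = tab.pivot(index="tp", columns="group", values="freq")
    frac_highest = float((piv.idxmax(axis=1) == "promoter").mean())

    # uniform-random TTS null: same number/length of sites, uniform placement
    rng = np.random.default_rng(_seed(seed, 9))
    null_hits = []
    for h in hits:
        L = h.tts_end - h.tts_start
        scaf = ds.scaffolds[int(rng.integers(len(ds.scaffolds)))]
        a = int(rng.integers(0, len(scaf.sequence) - L))
        null_hits.append(
            triplex.TriplexHit(h.lnc_id, scaf.id, h.rna_start, h.rna_end,
                               a, a + L, h.dna_strand, h.n_errors, h.guanine_frac)
        )
    ntab = _localization_tables(ds, null_hits)
    npiv = ntab.pivot(index="tp", columns="group", values="freq")
    # under uniform placement every group's freq estimates the same density,
    # so the promoter group should not stand out
    null_prom_ratio = float((npiv["promoter"] / npiv.mean(axis=1)).mean())
    return {
        "frac_tp_promoter_highest": frac_highest,
        "promoter_to_next_ratio": float(
            (piv["promoter"] / piv.drop(columns="promoter").max(axis=1)).min()
        ),
        "null_promoter_to_mean_ratio": null_prom_ratio,
    }


# ---------------------------------------------------------------------------
# 8. coverage vs fold-change association
# ---------------------------------------------------------------------------

def _coverage_compare(ds: SyntheticDataset, n: int = 500) -> dict:
    expressed = expression.filter_expressed(ds.counts)
    counts = ds.counts.loc[expressed]
    res = expression.de_test(counts, ds.rna_samples, "ED")
    lnc_ids = [g.gene_id for g in ds.genes
               if g.biotype != "coding" and ds.truth.expressed[g.gene_id]]
    hits = triplex.search_lnc_targets(ds.scaffolds, ds.genes, lnc_ids)
    tri_pairs = triplex.map_tts_to_genes(hits, ds.genes, scaffold_lengths=ds.scaffold_lengths)
    merged: dict[str, list[tuple[int, int]]] = {}
    for q in tri_pairs:
        merged.setdefault(q.gene_id, []).extend(q.merged_tts)
    coding = [g for g in ds.genes if g.biotype == "coding" and g.gene_id in set(expressed)]
    cov = {
        g.gene_id: triplex.tts_coverage_pct(
            g, merged.get(g.gene_id, []), scaffold_len=ds.scaffold_lengths[g.scaffold]
        )
        for g in coding
    }
    ed_coding = res.loc[[g.gene_id for g in coding]]
    return pairmod.coverage_group_compare(ed_coding, cov, n=n)


def coverage_association(seed: int, dataset: SyntheticDataset | None = None) -> dict:
    ds = dataset or simulate_dataset(SimConfig(seed=_seed(seed, 10)), include_epigenome=False)
    comp = _coverage_compare(ds)
    return {
        "mwu_pvalue": comp["mwu_pvalue"],
        "mean_high_minus_low": comp["mean_high"] - comp["mean_low"],
        "n_high": comp["n_high_fc"],
        "n_low": comp["n_low_fc"],
    }


NULL_CONFIG = dict(
    n_scaffolds=2, scaffold_len=500_000, n_coding=60, n_lnc=90,
    n_planted_pairs=18, plant_targets="random",
)


def coverage_null_pvalues(seed: int, reps: int = 50) -> dict:
    """Coverage comparison on a null design (TTSs planted on genes chosen
    independently of differential expression), scaled down for replication."""
    ps = []
    for rep in range(reps):
        cfg = SimConfig(seed=_seed(seed, 1000 + rep), **NULL_CONFIG)
        ds = simulate_dataset(cfg, include_epigenome=False)
        comp = _coverage_compare(ds, n=500)
        ps.append(comp["mwu_pvalue"])
    ps = np.array(ps)
    return {
        "frac_p_below_0.05": float((ps <= 0.05).mean()),
        "median_p": float(np.median(ps)),
        "n_reps": reps,
    }


# ---------------------------------------------------------------------------
# 9. co-expression correlation bimodality
# ---------------------------------------------------------------------------

def correlation_bimodality(seed: int, dataset: SyntheticDataset | None = None) -> dict:
    ds = dataset or simulate_dataset(SimConfig(seed=_seed(seed, 11)), include_epigenome=False)
    expressed = expression.filter_expressed(ds.counts)
    counts = ds.counts.loc[expressed]
    results = {c: expression.de_test(counts, ds.rna_samples, c) for c in ("ES", "ED")}
    lnc_ids = [g.gene_id for g in ds.genes
               if g.biotype != "coding" and ds.truth.expressed[g.gene_id]]
    hits = triplex.search_lnc_targets(ds.scaffolds, ds.genes, lnc_ids)
    tri_pairs = triplex.map_tts_to_genes(hits, ds.genes, scaffold_lengths=ds.scaffold_lengths)
    coding_models = [g for g in ds.genes if g.biotype == "coding"]
    lnc_models = [g for g in ds.genes if g.biotype != "coding"]
    nbr = pairmod.neighbor_pairs(coding_models, lnc_models)
    all_pairs = pairmod.combine_pairs(nbr, tri_pairs)
    fpm = expression.cpm(ds.counts)
    kept, _ = pairmod.pair_correlation(fpm, all_pairs, expressed=set(expressed))
    coding_set = {g.gene_id for g in coding_models}
    de_lnc = {
        g for g in expressed if g not in coding_set
        and (results["ES"].loc[g, "de"] or results["ED"].loc[g, "de"])
    }
    de_pairs = [p for p in kept if p.lnc_id in de_lnc]
    comp = pairmod.correlation_distribution_compare(kept, de_pairs)
    same = pairmod.correlation_distribution_compare(kept, kept)
    return {
        "frac_high_all": comp["frac_high_all"],
        "frac_high_de_lnc": comp["frac_high_de_lnc"],
        "n_all": comp["n_all"],
        "n_de_lnc": comp["n_de_lnc"],
        "ks_p_identical_sets": same["ks_pvalue"],
    }


# ---------------------------------------------------------------------------
# 10. methylation ON/OFF profile
# ---------------------------------------------------------------------------

def methylation_onoff(seed: int, dataset: SyntheticDataset | None = None) -> dict:
    ds = dataset or simulate_dataset(SimConfig(seed=_seed(seed, 12)))
    expressed = set(expression.filter_expressed(ds.counts))
    coding = [g for g in ds.genes if g.biotype == "coding"]
    prof_on = methylation.tss_profile(
        ds.methylation, [g for g in coding if g.gene_id in expressed], window=3000
    )
    prof_off = methylation.tss_profile(
        ds.methylation, [g for g in coding if g.gene_id not in expressed], window=3000
    )
    # LOESS sanity: exact line reproduction
    x = np.arange(50, dtype=float)
    line = 2.0 * x + 1.0
    dev_line = float(np.abs(methylation.loess_smooth(x, line) - line).max())
    dev_const = float(np.abs(methylation.loess_smooth(x, np.full(50, 3.3)) - 3.3).max())
    return {
        "expressed_tss500_mean": prof_on.mean_in(-500, 500),
        "silent_tss500_mean": prof_off.mean_in(-500, 500),
        "loess_line_max_dev": dev_line,
        "loess_const_max_dev": dev_const,
    }
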