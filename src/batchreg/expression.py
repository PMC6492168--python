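"""Expression dynamics: normalisation, phase-wise differential expression,
soft clustering, rank-based gene-set analysis and sample PCA.

The differential-expression model is a deliberately simple negative-binomial
fit: median-of-ratios size factors, a per-gene method-of-moments dispersion
pooled within phases, and a Wald statistic on the log2 ratio of phase means
of normalised counts, referred to a t distribution with nA+nB-2 degrees of
freedom (with 4+2+3 single-sample time points per phase the plug-in normal
reference is anticonservative).  A gene is called differentially expressed
when padj < 0.01 AND |log2FC| > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

COMPARISONS = {"ES": ("exponential", "stationary"), "ED": ("exponential", "decline")}


# ---------------------------------------------------------------------------
# filtering and normalisation
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("zero library size")
    return counts * 1e6 / totals


def filter_expressed(counts: pd.DataFrame) -> pd.Index:
    """Genes whose summed CPM across samples exceeds 1 (strict)."""
    row = cpm(counts).sum(axis=1)
    return counts.index[row > 1.0]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    Uses genes with all-positive counts; falls back to total-count ratios
    (with a warning) when no such gene exists.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        logs = np.log(mat[positive])
        geo = logs.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logs - geo, axis=0))
    else:
        warnings.warn("no gene with all-positive counts; using total-count ratios")
        tot = mat.sum(axis=0)
        sf = tot / np.exp(np.mean(np.log(tot)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    sf = size_factors(counts) if sf is None else sf
    return counts / sf


def vst_zscore(counts: pd.DataFrame, sf: pd.Series | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """log2(normalised+1) variance-stabilising surrogate, then per-gene z-score.

    Constant rows become all-zero and are flagged.
    """
    norm = normalized_counts(counts, sf)
    x = np.log2(norm.to_numpy() + 1.0)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] <= 1e-12
    z = np.zeros_like(x)
    ok = ~constant
    z[ok] = (x[ok] - mean[ok]) / sd[ok]
    zdf = pd.DataFrame(z, index=counts.index, columns=counts.columns)
    flags = pd.Series(constant, index=counts.index, name="constant")
    return zdf, flags


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DEParams:
    fdr: float = 0.01
    lfc: float = 1.0
    dispersion_floor: float = 1e-8


def de_test(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    comparison: str,
    params: DEParams | None = None,
) -> pd.DataFrame:
    """Phase-wise NB Wald test.

    Returns a DataFrame with columns gene_id (index), comparison, log2fc,
    stat, pvalue, padj, de (the padj & |lfc| joint call).
    """
    params = params or DEParams()
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    ph_a, ph_b = COMPARISONS[comparison]
    sheet = sample_sheet.set_index("sample_id")
    cols_a = [c for c in counts.columns if sheet.loc[c, "phase"] == ph_a]
    cols_b = [c for c in counts.columns if sheet.loc[c, "phase"] == ph_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 samples in each phase")
    norm = normalized_counts(counts)
    A = norm[cols_a].to_numpy(dtype=float)
    B = norm[cols_b].to_numpy(dtype=float)
    nA, nB = A.shape[1], B.shape[1]
    mA, mB = A.mean(axis=1), B.mean(axis=1)

    # pooled within-phase method-of-moments dispersion: var = mu + alpha*mu^2.
    # The naive estimator divides by the squared sample mean, whose expectation
    # is mu^2 + var/n, biasing alpha down; the denominator is corrected for
    # that, and per-gene estimates (5 df here) are stabilised against a
    # trimmed-mean common dispersion (alpha_used = max(per-gene, common)).
    ssA = ((A - mA[:, None]) ** 2).sum(axis=1)
    ssB = ((B - mB[:, None]) ** 2).sum(axis=1)
    s2 = (ssA + ssB) / (nA + nB - 2)
    mbar = (nA * mA + nB * mB) / (nA + nB)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = (nA * (mA**2 - s2 / nA) + nB * (mB**2 - s2 / nB)) / (nA + nB)
        alpha_g = (s2 - mbar) / denom
    alpha_g = np.where(np.isfinite(alpha_g) & (denom > 0), alpha_g, 0.0)
    well = (mA > 5) & (mB > 5) & (denom > 0)
    if well.sum() >= 10:
        vals = alpha_g[well]
        lo_q, hi_q = np.quantile(vals, [0.05, 0.95])
        alpha_common = float(np.mean(np.clip(vals, lo_q, hi_q)))
    else:
        alpha_common = float(np.median(alpha_g[alpha_g > 0])) if (alpha_g > 0).any() else 0.0
    alpha = np.maximum(np.maximum(alpha_g, alpha_common), params.dispersion_floor)

    eps = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2((mB + eps) / (mA + eps))
        var_log = (1.0 / np.maximum(mA, eps) + alpha) / nA + (
            1.0 / np.maximum(mB, eps) + alpha
        ) / nB
        se = np.sqrt(var_log) / np.log(2.0)
        stat = lfc / se
    both_zero = (mA <= eps) & (mB <= eps)
    stat = np.where(both_zero | ~np.isfinite(stat), 0.0, stat)
    lfc = np.where(both_zero, 0.0, lfc)
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    padj = multipletests(pvalue, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "comparison": comparison,
            "log2fc": lfc,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
        },
        index=counts.index,
    )
    out["de"] = (out.padj < params.fdr) & (out.log2fc.abs() > params.lfc)
    return out


def de_union(results: list[pd.DataFrame]) -> pd.Index:
    """Genes DE in any of the phase-wise comparisons."""
    called = None
    for res in results:
        mask = res["de"]
        called = mask if called is None else (called | mask.reindex(called.index, fill_value=False))
    return called.index[called]


# ---------------------------------------------------------------------------
# fuzzy c-means
# ---------------------------------------------------------------------------

def mestimate(z: np.ndarray) -> float:
    """Fuzzifier estimate of Schwaemmle & Jensen (as used by Mfuzz)."""
    n, d = z.shape
    return float(
        1.0
        + (1418.0 / n + 22.05) * d ** (-2.0)
        + (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134)
    )


@dataclass
class ClusterResult:
    membership: pd.DataFrame  # genes x c, rows sum to 1
    centers: np.ndarray  # c x n_tp
    m: float
    objective_trace: list[float]

    @property
    def assigned(self) -> pd.Series:
        return pd.Series(
            np.argmax(self.membership.to_numpy(), axis=1) + 1,
            index=self.membership.index,
            name="cluster",
        )


def _fcm_once(z: np.ndarray, c: int, m: float, rng: np.random.Generator,
              tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, list[float]]:
    n = z.shape[0]
    u = rng.dirichlet(np.ones(c), size=n)
    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        um = u**m
        centers = (um.T @ z) / um.sum(axis=0)[:, None]
        d2 = ((z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        j = float((um * d2).sum())
        trace.append(j)
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        if prev - j < tol:
            break
        prev = j
    return u, centers, trace


def fuzzy_cmeans(
    z: pd.DataFrame,
    c: int = 4,
    m: float | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    restarts: int = 10,
) -> ClusterResult:
    """Standard fuzzy c-means (Euclidean), best of seeded restarts."""
    if c < 2:
        raise ValueError("c must be >= 2")
    if c > z.shape[0]:
        raise ValueError("more clusters than genes")
    zmat = z.to_numpy(dtype=float)
    m = mestimate(zmat) if m is None else float(m)
    best = None
    for r in range(restarts):
        rng = np.random.default_rng([int(seed) % (2**31), r])
        u, centers, trace = _fcm_once(zmat, c, m, rng, tol, max_iter)
        if any(b > a + 1e-6 * max(1.0, a) for a, b in zip(trace, trace[1:])):
            raise AssertionError("FCM objective increased")
        if best is None or trace[-1] < best[2][-1]:
            best = (u, centers, trace)
    u, centers, trace = best
    mem = pd.DataFrame(u, index=z.index, columns=[f"cluster{i + 1}" for i in range(c)])
    return ClusterResult(mem, centers, m, trace)


# ---------------------------------------------------------------------------
# PCA over samples
# ---------------------------------------------------------------------------

def pca_samples(z: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame, bool]:
    """PCA of samples (genes as features).

    Returns (variance fractions, sample scores, degenerate_flag); a dataset
    with zero total variance sets the flag instead of dividing by zero.
    """
    x = z.to_numpy(dtype=float).T  # samples x genes
    if x.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    xc = x - x.mean(axis=0, keepdims=True)
    total = float((xc**2).sum())
    if total <= 1e-12:
        k = min(x.shape)
        return np.zeros(k), pd.DataFrame(
            np.zeros((x.shape[0], k)), index=z.columns,
            columns=[f"PC{i+1}" for i in range(k)],
        ), True
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    var_frac = (s**2) / (s**2).sum()
    scores = pd.DataFrame(
        u * s, index=z.columns, columns=[f"PC{i + 1}" for i in range(s.size)]
    )
    return var_frac, scores, False


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _es_from_ranked(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score (p=1)."""
    nh = in_set.sum()
    n = in_set.size
    if nh == 0 or nh == n:
        return 0.0
    w = np.abs(weights) * in_set
    wsum = w.sum()
    if wsum <= 0:
        w = in_set.astype(float)
        wsum = w.sum()
    p_hit = np.cumsum(w) / wsum
    p_miss = np.cumsum(~in_set) / (n - nh)
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def gsea_preranked(
    ranked_stats: pd.Series,
    gene_sets: dict[str, set[str]],
    nperm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Preranked GSEA with gene-label permutation and sign-stratified FDR.

    ``ranked_stats`` is keyed by gene; genes are ranked by (stat desc,
    gene_id asc) for determinism.
    """
    s = ranked_stats.copy()
    order = sorted(s.index, key=lambda g: (-s[g], g))
    stats_arr = s.loc[order].to_numpy(dtype=float)
    genes = list(order)
    gidx = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(int(seed) % (2**31))

    rows = []
    null_by_size: dict[int, np.ndarray] = {}
    for name, members in gene_sets.items():
        inter = [g for g in members if g in gidx]
        if len(inter) < min_size:
            continue
        mask = np.zeros(len(genes), dtype=bool)
        mask[[gidx[g] for g in inter]] = True
        es = _es_from_ranked(mask, stats_arr)
        size = len(inter)
        if size not in null_by_size:
            null = np.empty(nperm)
            for i in range(nperm):
                perm = np.zeros(len(genes), dtype=bool)
                perm[rng.choice(len(genes), size=size, replace=False)] = True
                null[i] = _es_from_ranked(perm, stats_arr)
            null_by_size[size] = null
        null = null_by_size[size]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if same.size == 0:
            pval, nes = 1.0, 0.0
        else:
            pval = float((np.abs(same) >= abs(es)).mean())
            nes = float(es / np.abs(same).mean())
        rows.append({"set": name, "size": size, "ES": es, "NES": nes, "pvalue": pval})
    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["size", "ES", "NES", "pvalue"]
    )
    if len(out):
        # sign-stratified FDR on NES, per the standard preranked recipe
        all_null_nes = []
        for size, null in null_by_size.items():
            pos, neg = null[null >= 0], null[null < 0]
            if pos.size:
                all_null_nes.append(pos / pos.mean())
            if neg.size:
                all_null_nes.append(neg / np.abs(neg).mean())
        null_nes = np.concatenate(all_null_nes)
        qs = []
        nes_obs = out["NES"].to_numpy()
        for nes in nes_obs:
            if nes >= 0:
                num = (null_nes >= nes).mean() / max((null_nes >= 0).mean(), 1e-12)
                den = (nes_obs >= nes).mean()
            else:
                num = (null_nes <= nes).mean() / max((null_nes < 0).mean(), 1e-12)
                den = (nes_obs <= nes).mean()
            qs.append(min(1.0, num / max(den, 1e-12)))
        out["fdr_q"] = qs
    return out


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def ora_fisher(
    hit_genes: set[str], universe: set[str], gene_sets: dict[str, set[str]]
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation per set, BH across sets."""
    if not set(hit_genes) <= set(universe):
        raise ValueError("hits must be a subset of the universe")
    hits = set(hit_genes)
    n_u = len(universe)
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & set(universe)
        if not inset:
            continue
        a = len(hits & inset)
        b = len(hits) - a
        c = len(inset) - a
        d = n_u - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"set": name, "overlap": a, "set_size": len(inset),
                     "odds_ratio": odds, "pvalue": p})
    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["overlap", "set_size", "odds_ratio", "pvalue"]
    )
    if len(out):
        out["padj"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    return out
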