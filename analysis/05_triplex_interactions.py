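#!/usr/bin/env python
"""Purine-motif triplex analysis: search every expressed lncRNA transcript
against coding gene bodies +/- 1.5 kb (min length 20, G fraction >= 50%,
error rate <= 20%, <= 2 consecutive errors), map merged target sites to
genes, and run the association analyses - TTS coverage of high- vs low-
fold-change genes, chromatin-state localisation of TTSs over the 18 chip
time points, neighbor/triplex pair co-expression, and the correlation-
distribution comparison for DE-lncRNA pairs.

Reads the dataset written by 01_simulate.py; writes tables under
results/triplex/.
"""

import argparse
import dataclasses
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from batchreg import expression, pairs as pairmod, triplex
from batchreg.io import read_bed_intervals, read_fasta, read_gtf, read_table, write_bed, Interval


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=str, default="results/data")
    ap.add_argument("--out", type=str, default="results/triplex")
    ap.add_argument("--flank", type=int, default=1500)
    args = ap.parse_args()
    data, out = Path(args.data), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    scaffolds = read_fasta(data / "genome.fa")
    genes = read_gtf(data / "genes.gtf")
    counts = read_table(data / "counts.tsv", "counts")
    sheet = pd.read_csv(data / "samples_rna.tsv", sep="\t")
    truth = json.loads((data / "truth.json").read_text())
    scaf_len = {s.id: len(s.sequence) for s in scaffolds}
    expressed = set(expression.filter_expressed(counts))
    coding = {g.gene_id for g in genes if g.biotype == "coding"}
    lnc_ids = [g.gene_id for g in genes
               if g.biotype != "coding" and g.gene_id in expressed]

    print(f"searching {len(lnc_ids)} expressed lncRNA transcripts against "
          f"{len(coding)} coding gene windows (+/-{args.flank} bp)")
    hits = triplex.search_lnc_targets(scaffolds, genes, lnc_ids, flank=args.flank)
    write_bed(
        [Interval(h.scaffold, h.tts_start, h.tts_end, h.lnc_id, float(h.n_errors))
         for h in hits],
        out / "tts_hits.bed",
    )
    tri_pairs = triplex.map_tts_to_genes(hits, genes, flank=args.flank,
                                         scaffold_lengths=scaf_len)
    pd.DataFrame(
        [{"lnc_id": p.lnc_id, "gene_id": p.gene_id, "n_hits": p.n_hits,
          "tts_bases": triplex.total_length(p.merged_tts)} for p in tri_pairs]
    ).to_csv(out / "interaction_pairs.tsv", sep="\t", index=False)
    found = {(p.lnc_id, p.gene_id) for p in tri_pairs}
    planted = {(p["lnc_id"], p["gene_id"]) for p in truth["planted_pairs"]}
    print(f"hits: {len(hits)}, unique lncRNA-gene pairs: {len(tri_pairs)}, "
          f"planted pairs recovered: {len(found & planted)}/{len(planted)}")

    # coverage of high- vs low-fold-change genes
    res_ed = expression.de_test(counts.loc[sorted(expressed)], sheet, "ED")
    merged = {}
    for p in tri_pairs:
        merged.setdefault(p.gene_id, []).extend(p.merged_tts)
    cov = {
        g.gene_id: triplex.tts_coverage_pct(g, merged.get(g.gene_id, []),
                                            flank=args.flank,
                                            scaffold_len=scaf_len[g.scaffold])
        for g in genes if g.biotype == "coding" and g.gene_id in expressed
    }
    comp = pairmod.coverage_group_compare(
        res_ed.loc[[g for g in res_ed.index if g in coding]], cov, n=500
    )
    print(f"TTS coverage, high-|log2FC| DE vs low-|log2FC| NDE genes: "
          f"mean {comp['mean_high']:.3f}% vs {comp['mean_low']:.3f}%, "
          f"one-sided MWU p = {comp['mwu_pvalue']:.2e}")

    # chromatin-state localisation over chip TPs
    merged_scaf, windows_scaf = {}, {}
    for h in hits:
        merged_scaf.setdefault(h.scaffold, []).append((h.tts_start, h.tts_end))
    for g in genes:
        if g.biotype == "coding":
            windows_scaf.setdefault(g.scaffold, []).append(
                g.window0(args.flank, scaf_len[g.scaffold])
            )
    rows = []
    for tp in range(1, 19):
        seg = read_bed_intervals(data / f"segmentation_TP{tp:02d}.bed", labeled=True)
        for gname, d in triplex.tts_state_localization(
            merged_scaf, seg, windows_scaf
        ).items():
            rows.append({"tp": tp, "group": gname, **d})
    loc = pd.DataFrame(rows)
    loc.to_csv(out / "tts_state_localization.tsv", sep="\t", index=False,
               float_format="%.6g")
    piv = loc.pivot(index="tp", columns="group", values="freq")
    print("TTS frequency by state group (mean over TPs):")
    print(piv.mean().round(5).sort_values(ascending=False).to_string())

    # pair co-expression
    coding_models = [g for g in genes if g.biotype == "coding"]
    lnc_models = [g for g in genes if g.biotype != "coding"]
    nbr = pairmod.neighbor_pairs(coding_models, lnc_models, max_dist=args.flank)
    all_pairs = pairmod.combine_pairs(nbr, tri_pairs)
    fpm = expression.cpm(read_table(data / "counts.tsv", "counts"))
    kept, _ = pairmod.pair_correlation(fpm, all_pairs, expressed=expressed)
    res_es = expression.de_test(counts.loc[sorted(expressed)], sheet, "ES")
    de_lnc = {g for g in expressed if g not in coding
              and (res_es.loc[g, "de"] or res_ed.loc[g, "de"])}
    for p in kept:
        p.lnc_de = p.lnc_id in de_lnc
    pd.DataFrame([dataclasses.asdict(p) for p in kept]).to_csv(
        out / "pairs.tsv", sep="\t", index=False, float_format="%.6g"
    )
    dist = pairmod.correlation_distribution_compare(
        kept, [p for p in kept if p.lnc_de]
    )
    print(f"pairs: {dist['n_all']} total, {dist['n_de_lnc']} with DE lncRNA; "
          f"fraction |r|>=0.5: {dist['frac_high_all']:.3f} vs "
          f"{dist['frac_high_de_lnc']:.3f} (KS p = {dist['ks_pvalue']:.2e})")
    lnc_cluster = {k: int(v) for k, v in truth["lnc_de_cluster"].items()}
    trends = pairmod.paired_trend_matrix(
        [p for p in kept if p.lnc_de], fpm, lnc_cluster
    )
    trends.to_csv(out / "paired_trends.tsv", sep="\t", index=False,
                  float_format="%.6g")


if __name__ == "__main__":
    main()
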