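#!/usr/bin/env python
"""Chromatin-state dynamics: overlap enrichment of the 11 states within
expressed vs non-expressed gene bodies, per-gene active-mark flags
(H3K36me3 + state 4 on the body; H3K4me3 / H3K27ac + states 9/10 at
TSS +/- 500 bp), the temporal correlation of mark signal with expression,
and the fold-change distribution of DE genes by mark combination.

Reads the dataset written by 01_simulate.py; writes tables under
results/chromatin/.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import dataclasses

import pandas as pd

from batchreg import chromatin, expression
from batchreg.io import Interval, read_bed_intervals, read_gtf, read_table
from batchreg.simulate import CHIP_TP_LABELS, RNA_TO_CHIP

MARKS = ("H3K36me3", "H3K4me3", "H3K27ac")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=str, default="results/data")
    ap.add_argument("--out", type=str, default="results/chromatin")
    args = ap.parse_args()
    data, out = Path(args.data), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    counts = read_table(data / "counts.tsv", "counts")
    genes = read_gtf(data / "genes.gtf")
    sheet = pd.read_csv(data / "samples_rna.tsv", sep="\t")
    expressed = set(expression.filter_expressed(counts))
    from batchreg.io import read_fasta
    scaf_len = {s.id: len(s.sequence) for s in read_fasta(data / "genome.fa")}
    genome_size = sum(scaf_len.values())

    segs = {
        tp: read_bed_intervals(data / f"segmentation_TP{tp:02d}.bed", labeled=True)
        for tp in range(1, 19)
    }
    peaks = {
        (m, tp): read_bed_intervals(data / f"peaks_{m}_TP{tp:02d}.bed", labeled=True)
        for m in MARKS for tp in range(1, 19)
    }

    # state enrichment within expressed vs silent coding gene bodies (mid-exp TP)
    mid_tp = 5
    rows = []
    for name, keep in (("expressed_coding", True), ("silent_coding", False)):
        targets = [
            Interval(g.scaffold, g.start0, g.end0)
            for g in genes
            if g.biotype == "coding" and (g.gene_id in expressed) == keep
        ]
        for e in chromatin.overlap_enrichment(
            segs[mid_tp], targets, genome_size, target_name=name,
            scaffold_lengths=scaf_len,
        ):
            rows.append(dataclasses.asdict(e))
    enr = pd.DataFrame(rows)
    enr.to_csv(out / "state_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    piv = enr.pivot(index="state", columns="target_name", values="fold_enrichment")
    print(f"state enrichment at TP{mid_tp} (fold):")
    print(piv.round(2).to_string())

    per_tp = [
        chromatin.mark_gene_flags(genes, segs[tp], {m: peaks[(m, tp)] for m in MARKS})
        for tp in range(1, 19)
    ]
    agg = chromatin.aggregate_flags(per_tp)
    agg.to_csv(out / "mark_flags.tsv", sep="\t")
    print("genes flagged in >=50% of TPs:", dict(agg.sum()))

    z, _ = expression.vst_zscore(counts.loc[sorted(expressed)])
    for m in MARKS:
        sig = read_table(data / f"signal_{m}.tsv", "signal")
        corr = chromatin.mark_expression_correlation(
            z, chromatin.zscore_rows(sig), RNA_TO_CHIP
        )
        corr.to_csv(out / f"markcorr_{m}.tsv", sep="\t", float_format="%.6g")
        sig_pos = ((corr.pvalue < 0.01) & (corr.r > 0)).mean()
        print(f"{m}: {100 * sig_pos:.1f}% of genes significantly (p<0.01) "
              f"positively correlated with expression")

    res_ed = expression.de_test(counts.loc[sorted(expressed)], sheet, "ED")
    coding = {g.gene_id for g in genes if g.biotype == "coding"}
    de_coding = res_ed.index[(res_ed.de) & res_ed.index.isin(coding)]
    group, summary = chromatin.flag_group_fc_distribution(res_ed.loc[de_coding], agg)
    summary.to_csv(out / "fc_by_mark_group.tsv", sep="\t", float_format="%.6g")
    print("|log2FC| of DE coding genes by active-mark combination:")
    print(summary.round(3).to_string())


if __name__ == "__main__":
    main()
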