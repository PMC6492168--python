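#!/usr/bin/env python
"""Expression dynamics: expressed-gene filter, phase-wise differential
expression (exponential vs stationary, exponential vs decline), fuzzy
c-means clustering of the DE coding genes, sample PCA, preranked GSEA
against the planted archetype gene sets, and Fisher over-representation.

Reads the dataset written by 01_simulate.py and writes tables under
results/expression/.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from batchreg import expression
from batchreg.io import read_gtf, read_table, write_gmt, read_gmt


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=str, default="results/data")
    ap.add_argument("--out", type=str, default="results/expression")
    ap.add_argument("--fdr", type=float, default=0.01)
    ap.add_argument("--lfc", type=float, default=1.0)
    args = ap.parse_args()
    data = Path(args.data)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    counts = read_table(data / "counts.tsv", "counts")
    sheet = pd.read_csv(data / "samples_rna.tsv", sep="\t")
    genes = read_gtf(data / "genes.gtf")
    truth = json.loads((data / "truth.json").read_text())
    coding = {g.gene_id for g in genes if g.biotype == "coding"}

    expressed = expression.filter_expressed(counts)
    print(f"expressed genes (CPM row sum > 1): {len(expressed)} of {len(counts)}")
    counts = counts.loc[expressed]

    params = expression.DEParams(fdr=args.fdr, lfc=args.lfc)
    results = {}
    for cmp_name in ("ES", "ED"):
        res = expression.de_test(counts, sheet, cmp_name, params)
        res.to_csv(out / f"de_{cmp_name}.tsv", sep="\t", float_format="%.6g")
        results[cmp_name] = res
        n_c = int((res.de & res.index.isin(coding)).sum())
        n_nc = int((res.de & ~res.index.isin(coding)).sum())
        print(f"DE {cmp_name}: {n_c} coding, {n_nc} noncoding "
              f"(padj<{args.fdr}, |log2FC|>{args.lfc})")

    de_all = expression.de_union(list(results.values()))
    de_coding = [g for g in de_all if g in coding]
    print(f"unique DE coding genes across comparisons: {len(de_coding)}")

    z, _ = expression.vst_zscore(counts)
    clu = expression.fuzzy_cmeans(z.loc[de_coding], c=4, seed=args.seed)
    tab = clu.membership.copy()
    tab["assigned"] = clu.assigned
    tab.to_csv(out / "clusters.tsv", sep="\t", float_format="%.6g")
    sizes = clu.assigned.value_counts().sort_index()
    print("cluster sizes:", dict(sizes))
    true_k = pd.Series(truth["de_cluster"])
    common = [g for g in de_coding if g in true_k.index]
    ct = pd.crosstab(clu.assigned.loc[common], true_k.loc[common])
    print("cluster vs planted archetype contingency:")
    print(ct.to_string())

    var_frac, scores, _ = expression.pca_samples(z)
    scores.assign(phase=list(sheet["phase"])).to_csv(
        out / "pca_samples.tsv", sep="\t", float_format="%.6g"
    )
    print(f"PCA: PC1 {100 * var_frac[0]:.1f}% of variance, "
          f"PC2 {100 * var_frac[1]:.1f}%")

    # gene sets: planted archetypes plus random decoys
    import numpy as np
    rng = np.random.default_rng(args.seed)
    sets = {f"archetype_{k}": {g for g, kk in truth["de_cluster"].items() if kk == k}
            for k in (1, 2, 3, 4)}
    for i in range(4):
        sets[f"random_{i}"] = set(rng.choice(list(expressed), size=30, replace=False))
    write_gmt(sets, out / "gene_sets.gmt")
    sets = read_gmt(out / "gene_sets.gmt")
    ranked = results["ED"]["stat"]
    gsea = expression.gsea_preranked(ranked, sets, nperm=1000, seed=args.seed)
    gsea.to_csv(out / "gsea_ED.tsv", sep="\t", float_format="%.6g")
    print("GSEA (ED Wald preranked):")
    print(gsea[["size", "ES", "NES", "pvalue", "fdr_q"]].round(3).to_string())

    ora = expression.ora_fisher(set(de_coding), set(expressed), sets)
    ora.to_csv(out / "ora_de_coding.tsv", sep="\t", float_format="%.6g")
    print("over-representation of gene sets among DE coding genes:")
    print(ora.round(4).to_string())


if __name__ == "__main__":
    main()
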