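import numpy as np
import pandas as pd
import pytest
from scipy import stats

from batchreg import chromatin
from batchreg.evaluation import enrichment_correctness
from batchreg.io import FormatError, GeneModel, Interval
from batchreg.simulate import RNA_TO_CHIP


def _segmentation(L=1000):
    return [
        Interval("s", 0, 300, "E2"),
        Interval("s", 300, 500, "E4"),
        Interval("s", 500, 700, "E9"),
        Interval("s", 700, L, "E2"),
    ]


class TestOverlapEnrichment:
    def test_whole_genome_target_fold_one(self):
        enr = chromatin.overlap_enrichment(
            _segmentation(), [Interval("s", 0, 1000)], 1000, scaffold_lengths={"s": 1000}
        )
        assert all(abs(e.fold_enrichment - 1.0) < 1e-9 for e in enr)

    def test_target_equal_to_one_state(self):
        enr = {e.state: e for e in chromatin.overlap_enrichment(
            _segmentation(), [Interval("s", 300, 500)], 1000, scaffold_lengths={"s": 1000}
        )}
        assert enr[4].fold_enrichment == pytest.approx(1000 / 200)
        assert enr[9].fold_enrichment == 0.0
        assert enr[2].fold_enrichment == 0.0

    def test_gappy_segmentation_rejected(self):
        seg = [Interval("s", 0, 10, "E1"), Interval("s", 20, 30, "E2")]
        with pytest.raises(FormatError):
            chromatin.overlap_enrichment(seg, [Interval("s", 0, 5)], 30)

    def test_matches_per_base_bruteforce(self):
        res = enrichment_correctness(123)
        assert res["max_abs_fold_diff"] < 1e-9
        assert res["whole_genome_max_dev"] < 1e-9


def _gene(gid="g", start0=1000, end0=3000, strand="+"):
    return GeneModel(gid, "s", strand, start0 + 1, end0, "coding")


class TestMarkGeneFlags:
    def test_body_state4_with_interior_peak(self):
        g = _gene()
        seg = [Interval("s", 0, 500, "E2"), Interval("s", 500, 4000, "E4"),
               Interval("s", 4000, 5000, "E2")]
        peaks = {"H3K36me3": [Interval("s", 1500, 1600)],
                 "H3K4me3": [], "H3K27ac": []}
        flags = chromatin.mark_gene_flags([g], seg, peaks)
        assert flags.loc["g", "has_k36_e4"] == True  # noqa: E712
        assert flags.loc["g", "has_k4_e910"] == False  # noqa: E712

    def test_promoter_halfopen_boundary(self):
        g = _gene()  # tss0 = 1000; promoter window [500, 1500)
        seg = [Interval("s", 0, 2000, "E9"), Interval("s", 2000, 5000, "E2")]
        # peak exactly at TSS+500..600 -> starts at window end, no overlap
        peaks = {"H3K4me3": [Interval("s", 1500, 1600)],
                 "H3K36me3": [], "H3K27ac": []}
        flags = chromatin.mark_gene_flags([g], seg, peaks)
        assert flags.loc["g", "has_k4_e910"] == False  # noqa: E712
        peaks2 = {"H3K4me3": [Interval("s", 1499, 1600)],
                  "H3K36me3": [], "H3K27ac": []}
        flags2 = chromatin.mark_gene_flags([g], seg, peaks2)
        assert flags2.loc["g", "has_k4_e910"] == True  # noqa: E712

    def test_missing_mark_track_is_na(self):
        g = _gene()
        seg = [Interval("s", 0, 5000, "E4")]
        flags = chromatin.mark_gene_flags([g], seg, {"H3K36me3": []})
        assert flags.loc["g", "has_k4_e910"] is pd.NA

    def test_synthetic_expressed_genes_carry_flags(self, small_dataset):
        from batchreg.chromatin import mark_gene_flags
        truth = small_dataset.truth
        marked = [
            g for g in small_dataset.genes
            if truth.expressed[g.gene_id] and g.gene_id not in set(truth.unmarked_de)
            and g.biotype == "coding"
        ]
        n_ok = 0
        for tp in (1, 9, 18):
            flags = mark_gene_flags(
                marked, small_dataset.segmentations[tp],
                {m: small_dataset.peaks[(m, tp)] for m in ("H3K36me3", "H3K4me3", "H3K27ac")},
            )
            all3 = flags.all(axis=1)
            assert all3.mean() >= 0.95
            n_ok += 1
        assert n_ok == 3


class TestMarkExpressionCorrelation:
    def _z(self, mat, prefix):
        return pd.DataFrame(mat, index=[f"g{i}" for i in range(mat.shape[0])],
                            columns=[f"{prefix}{j}" for j in range(mat.shape[1])])

    def test_identical_signal_r_one(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=(10, 9))
        s = np.zeros((10, 18))
        for k, t in RNA_TO_CHIP.items():
            s[:, t - 1] = e[:, k - 1]
        res = chromatin.mark_expression_correlation(self._z(e, "r"), self._z(s, "c"), RNA_TO_CHIP)
        assert np.allclose(res.r, 1.0)
        res_neg = chromatin.mark_expression_correlation(self._z(e, "r"), self._z(-s, "c"), RNA_TO_CHIP)
        assert np.allclose(res_neg.r, -1.0)

    def test_too_few_timepoints_rejected(self):
        e = self._z(np.ones((2, 9)), "r")
        s = self._z(np.ones((2, 18)), "c")
        with pytest.raises(ValueError):
            chromatin.mark_expression_correlation(e, s, {1: 1, 2: 3})

    def test_null_type1_within_ci(self):
        rng = np.random.default_rng(42)
        n = 4000
        e = rng.normal(size=(n, 9))
        s = rng.normal(size=(n, 18))
        res = chromatin.mark_expression_correlation(self._z(e, "r"), self._z(s, "c"), RNA_TO_CHIP)
        rate = float((res.pvalue < 0.01).mean())
        ci = 2 * np.sqrt(0.01 * 0.99 / n)
        assert 0.01 - 2 * ci <= rate <= 0.01 + 2 * ci


class TestFlagGroups:
    def test_partition_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(40)]
        flags = pd.DataFrame(
            rng.random((40, 3)) < 0.5,
            index=genes, columns=["has_k36_e4", "has_k4_e910", "has_k27ac_e910"],
        )
        de = pd.DataFrame({"log2fc": rng.normal(size=40)}, index=genes)
        group, summary = chromatin.flag_group_fc_distribution(de, flags)
        assert len(group) == 40
        assert int(summary["n"].sum()) == 40

    def test_unmarked_genes_have_largest_fold_changes(self, small_dataset):
        from batchreg import expression
        ds = small_dataset
        expressed = expression.filter_expressed(ds.counts)
        counts = ds.counts.loc[expressed]
        res = expression.de_test(counts, ds.rna_samples, "ED")
        de_coding = [g for g in ds.truth.de_cluster if g in set(expressed)]
        per_tp = [
            chromatin.mark_gene_flags(
                [g for g in ds.genes if g.gene_id in set(de_coding)],
                ds.segmentations[tp],
                {m: ds.peaks[(m, tp)] for m in ("H3K36me3", "H3K4me3", "H3K27ac")},
            )
            for tp in sorted(ds.segmentations)
        ]
        agg = chromatin.aggregate_flags(per_tp)
        group, summary = chromatin.flag_group_fc_distribution(res.loc[de_coding], agg)
        if {"none", "all_three"} <= set(summary.index):
            assert (
                summary.loc["none", "median_abs_log2fc"]
                > summary.loc["all_three", "median_abs_log2fc"]
            )
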