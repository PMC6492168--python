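import numpy as np
import pandas as pd
import pytest
from scipy import stats

from batchreg import expression
from batchreg.io import make_sample_sheet
from batchreg.simulate import RNA_HOURS, RNA_PHASES, RNA_TP_LABELS


def sheet():
    return make_sample_sheet("rna", RNA_TP_LABELS, RNA_HOURS, RNA_PHASES)


COLS = [f"rna_{t}" for t in RNA_TP_LABELS]


class TestFilterExpressed:
    def test_all_zero_removed(self):
        df = pd.DataFrame({"a": [0, 5], "b": [0, 5]}, index=["g0", "g1"])
        assert list(expression.filter_expressed(df)) == ["g1"]

    def test_cpm_boundary_strict(self):
        # one count of 1 in a library of 1e6 -> CPM row sum exactly 1 -> removed
        df = pd.DataFrame(
            {"a": [1, 10**6 - 1], "b": [0, 10**6]}, index=["g_border", "g_big"]
        )
        kept = expression.filter_expressed(df)
        assert "g_border" not in kept
        # two counts of 1 in two libraries of 1e6 -> row sum 2 -> kept
        df2 = pd.DataFrame(
            {"a": [1, 10**6 - 1], "b": [1, 10**6 - 1]}, index=["g2", "g_big"]
        )
        assert "g2" in expression.filter_expressed(df2)

    def test_zero_library_errors(self):
        df = pd.DataFrame({"a": [0], "b": [1]})
        with pytest.raises(ValueError):
            expression.filter_expressed(df)


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(expression.size_factors(df), 1.0)

    def test_doubled_sample_ratio_two(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = expression.size_factors(df)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_three_gene_worked_example(self):
        df = pd.DataFrame({"a": [2, 8, 50], "b": [4, 16, 200]})
        sf = expression.size_factors(df).to_numpy()
        # brute-force median of ratios against per-gene geometric means
        mat = df.to_numpy(dtype=float)
        geo = np.exp(np.mean(np.log(mat), axis=1))
        expected = np.median(mat / geo[:, None], axis=0)
        assert np.allclose(sf, expected)


class TestDETest:
    def _counts(self, rows, index=None):
        return pd.DataFrame(
            rows, index=index or [f"g{i}" for i in range(len(rows))], columns=COLS
        )

    def test_identical_phases_not_de(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 500, size=60)
        counts = self._counts(np.repeat(base[:, None], 9, axis=1))
        res = expression.de_test(counts, sheet(), "ED")
        assert np.allclose(res.log2fc, 0.0)
        assert not res.de.any()

    def test_de_requires_both_thresholds(self):
        rng = np.random.default_rng(1)
        n = 200
        base = rng.integers(200, 400, size=n).astype(float)
        lam = np.repeat(base[:, None], 9, axis=1)
        # one strong shift below the lfc threshold, one far above
        lam[0, 6:] = base[0] * 1.35  # |lfc| ~ 0.43 < 1, tiny p expected
        lam[1, 6:] = base[1] * 8.0
        counts = self._counts(rng.poisson(lam))
        res = expression.de_test(counts, sheet(), "ED")
        assert res.iloc[0].padj < 0.01 and not res.iloc[0].de
        assert res.iloc[1].de

    def test_padj_never_below_p(self):
        rng = np.random.default_rng(2)
        counts = self._counts(rng.poisson(100, size=(80, 9)))
        res = expression.de_test(counts, sheet(), "ES")
        assert (res.padj >= res.pvalue - 1e-12).all()
        s = res.sort_values("pvalue")
        assert (np.diff(s.padj.to_numpy()) >= -1e-12).all()

    def test_single_sample_phase_rejected(self):
        sh = sheet().iloc[[0, 1, 2, 3, 4]]  # only one stationary sample
        counts = self._counts(np.ones((3, 9), dtype=int))
        with pytest.raises(ValueError):
            expression.de_test(counts[sh.sample_id], sh, "ES")

    def test_unknown_comparison(self):
        with pytest.raises(ValueError):
            expression.de_test(self._counts(np.ones((3, 9), int)), sheet(), "SD")


class TestVstZscore:
    def test_rows_standardized(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(100, (30, 9)), columns=COLS)
        z, flags = expression.vst_zscore(counts)
        nz = z[~flags]
        assert np.allclose(nz.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(nz.std(axis=1, ddof=0), 1, atol=1e-9)

    def test_constant_row_flagged_zero(self):
        counts = pd.DataFrame(
            np.vstack([np.full(9, 7), np.arange(1, 10)]), columns=COLS
        )
        z, flags = expression.vst_zscore(counts, sf=pd.Series(1.0, index=COLS))
        assert flags.iloc[0] and not flags.iloc[1]
        assert (z.iloc[0] == 0).all()

    def test_monotone_counts_monotone_z(self):
        counts = pd.DataFrame([[1, 2, 4, 8, 16, 32, 64, 128, 256]], columns=COLS)
        z, _ = expression.vst_zscore(counts, sf=pd.Series(1.0, index=COLS))
        assert (np.diff(z.to_numpy()[0]) > 0).all()


class TestFuzzyCMeans:
    def _orthogonal_data(self):
        arch = np.eye(4).repeat(3, axis=1) * 4  # 4 orthogonal archetypes, 12 tps
        z = np.repeat(arch, 2, axis=0)  # two copies of each
        z = (z - z.mean(1, keepdims=True)) / z.std(1, keepdims=True)
        return pd.DataFrame(z, index=[f"g{i}" for i in range(8)])

    def test_planted_orthogonal_archetypes(self):
        res = expression.fuzzy_cmeans(self._orthogonal_data(), c=4, seed=3)
        top = res.membership.to_numpy().max(axis=1)
        assert (top > 0.9).all()
        # centers match archetypes up to permutation
        arch = self._orthogonal_data().to_numpy()[::2]
        cz = (res.centers - res.centers.mean(1, keepdims=True)) / res.centers.std(1, keepdims=True)
        corr = cz @ arch.T / arch.shape[1]
        assert sorted(corr.max(axis=1).round(2)) == [1.0] * 4

    def test_memberships_sum_to_one(self):
        res = expression.fuzzy_cmeans(self._orthogonal_data(), c=3, seed=0)
        assert np.allclose(res.membership.sum(axis=1), 1.0)

    def test_deterministic_under_seed(self):
        a = expression.fuzzy_cmeans(self._orthogonal_data(), c=4, seed=5)
        b = expression.fuzzy_cmeans(self._orthogonal_data(), c=4, seed=5)
        assert np.array_equal(a.membership.to_numpy(), b.membership.to_numpy())

    def test_objective_monotone(self):
        res = expression.fuzzy_cmeans(self._orthogonal_data(), c=4, seed=1)
        tr = res.objective_trace
        assert all(b <= a + 1e-9 for a, b in zip(tr, tr[1:]))

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            expression.fuzzy_cmeans(self._orthogonal_data(), c=9)


class TestPCA:
    def test_variance_fractions_nonincreasing(self):
        rng = np.random.default_rng(0)
        z = pd.DataFrame(rng.normal(size=(50, 9)), columns=COLS)
        vf, scores, degenerate = expression.pca_samples(z)
        assert not degenerate
        assert (np.diff(vf) <= 1e-12).all()
        assert vf.sum() == pytest.approx(1.0)

    def test_identical_samples_degenerate_flag(self):
        z = pd.DataFrame(np.ones((20, 9)), columns=COLS)
        vf, scores, degenerate = expression.pca_samples(z)
        assert degenerate and np.allclose(vf, 0)


class TestGSEA:
    def _ranked(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        stats_ = np.sort(rng.normal(size=n))[::-1]
        return pd.Series(stats_, index=[f"g{i:03d}" for i in range(n)])

    def test_top_set_positive_es(self):
        ranked = self._ranked()
        res = expression.gsea_preranked(ranked, {"top": set(ranked.index[:5])}, nperm=200, seed=1)
        assert res.loc["top", "ES"] > 0
        assert res.loc["top", "pvalue"] < 0.05

    def test_es_bounded(self):
        rng = np.random.default_rng(3)
        ranked = self._ranked(seed=3)
        sets = {f"s{i}": set(rng.choice(ranked.index, size=10, replace=False))
                for i in range(20)}
        res = expression.gsea_preranked(ranked, sets, nperm=100, seed=2)
        assert ((res.ES >= -1) & (res.ES <= 1)).all()

    def test_null_sets_type1_within_ci(self):
        rng = np.random.default_rng(7)
        ranked = self._ranked(seed=7)
        sets = {f"null{i}": set(rng.choice(ranked.index, size=10, replace=False))
                for i in range(200)}
        res = expression.gsea_preranked(ranked, sets, nperm=250, seed=4)
        rate = float((res.pvalue < 0.05).mean())
        # binomial CI around 0.05 over 200 sets (doubled for permutation noise)
        assert rate < 0.05 + 2 * 2 * np.sqrt(0.05 * 0.95 / 200)

    def test_small_sets_skipped(self):
        ranked = self._ranked()
        res = expression.gsea_preranked(ranked, {"tiny": {"g000", "g001"}}, nperm=50)
        assert "tiny" not in res.index


class TestORA:
    def test_hypergeometric_tail_equality(self):
        # 2x2 table (10,5,90,895): p equals the hypergeometric upper tail
        hits = {f"h{i}" for i in range(15)}
        universe = set(hits) | {f"u{i}" for i in range(985)}
        inset = {f"h{i}" for i in range(10)} | {f"u{i}" for i in range(90)}
        res = expression.ora_fisher(hits, universe, {"s": inset})
        expected = stats.hypergeom.sf(9, 1000, 100, 15)
        assert res.loc["s", "pvalue"] == pytest.approx(expected, rel=1e-9)

    def test_hits_equal_set_extreme(self):
        universe = {f"g{i}" for i in range(1000)}
        inset = {f"g{i}" for i in range(10)}
        res = expression.ora_fisher(inset, universe, {"s": inset})
        assert res.loc["s", "pvalue"] < 1e-15

    def test_empty_hits_p_one(self):
        universe = {f"g{i}" for i in range(100)}
        res = expression.ora_fisher(set(), universe, {"s": {f"g{i}" for i in range(10)}})
        assert res.loc["s", "pvalue"] == pytest.approx(1.0)

    def test_disjoint_set_skipped(self):
        res = expression.ora_fisher({"g1"}, {"g1", "g2"}, {"s": {"x", "y"}})
        assert len(res) == 0
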