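import numpy as np
import pandas as pd
import pytest

from batchreg import pairs as pairmod
from batchreg.io import GeneModel
from batchreg.pairs import PairRecord


def _gene(gid, start0, end0, scaf="s", biotype="coding", strand="+"):
    return GeneModel(gid, scaf, strand, start0 + 1, end0, biotype)


class TestNeighborPairs:
    def test_gap_distance(self):
        coding = [_gene("g", 10_000, 20_000)]
        lnc = [_gene("l", 9_000, 9_900, biotype="lncRNA")]
        (p,) = pairmod.neighbor_pairs(coding, lnc)
        assert p.distance == 100

    def test_boundary_inclusive_1500(self):
        coding = [_gene("g", 10_000, 20_000)]
        at = [_gene("l", 7_000, 8_500, biotype="lncRNA")]  # gap exactly 1500
        beyond = [_gene("l2", 7_000, 8_499, biotype="lncRNA")]  # gap 1501
        assert len(pairmod.neighbor_pairs(coding, at)) == 1
        assert len(pairmod.neighbor_pairs(coding, beyond)) == 0

    def test_overlap_distance_zero(self):
        coding = [_gene("g", 10_000, 20_000)]
        lnc = [_gene("l", 19_000, 21_000, biotype="lncRNA")]
        (p,) = pairmod.neighbor_pairs(coding, lnc)
        assert p.distance == 0

    def test_different_scaffolds_never_paired(self):
        coding = [_gene("g", 10_000, 20_000, scaf="s1")]
        lnc = [_gene("l", 10_000, 11_000, scaf="s2", biotype="lncRNA")]
        assert pairmod.neighbor_pairs(coding, lnc) == []


COLS = [f"tp{i}" for i in range(9)]


class TestPairCorrelation:
    def _expr(self, rows, index):
        return pd.DataFrame(rows, index=index, columns=COLS)

    def test_identical_and_mirrored(self):
        traj = np.arange(9.0)
        expr = self._expr([traj, traj, -traj], ["l1", "g1", "g2"])
        pairs = [PairRecord("l1", "g1", "neighbor"), PairRecord("l1", "g2", "neighbor")]
        kept, _ = pairmod.pair_correlation(expr, pairs)
        assert kept[0].r == pytest.approx(1.0)
        assert kept[1].r == pytest.approx(-1.0)

    def test_unexpressed_member_dropped(self):
        expr = self._expr(np.ones((2, 9)), ["l1", "g1"])
        pairs = [PairRecord("l1", "g1", "neighbor")]
        kept, dropped = pairmod.pair_correlation(expr, pairs, expressed={"l1"})
        assert kept == [] and len(dropped) == 1

    def test_constant_series_flagged(self):
        expr = self._expr([np.ones(9), np.arange(9.0)], ["l1", "g1"])
        kept, _ = pairmod.pair_correlation(expr, [PairRecord("l1", "g1", "triplex")])
        assert kept[0].r is None

    def test_planted_positive_pairs_recovered(self, small_dataset):
        from batchreg import expression, triplex
        ds = small_dataset
        fpm = expression.cpm(ds.counts)
        planted = [p for p in ds.truth.planted_pairs if p.coupled and p.sign > 0]
        pairs = [PairRecord(p.lnc_id, p.gene_id, "triplex") for p in planted]
        kept, _ = pairmod.pair_correlation(fpm, pairs)
        rs = [p.r for p in kept if p.r is not None]
        assert len(rs) >= 1
        assert np.mean([r > 0 for r in rs]) >= 0.9


class TestCorrelationCompare:
    def _pairs(self, rs, tag="x"):
        return [PairRecord(f"l{i}{tag}", f"g{i}{tag}", "triplex", r=float(r))
                for i, r in enumerate(rs)]

    def test_identical_sets(self):
        rng = np.random.default_rng(0)
        pairs = self._pairs(rng.uniform(-1, 1, 100))
        res = pairmod.correlation_distribution_compare(pairs, pairs)
        assert res["ks_pvalue"] > 0.99
        assert res["frac_high_all"] == res["frac_high_de_lnc"]

    def test_uniform_vs_spikes(self):
        rng = np.random.default_rng(1)
        a = self._pairs(rng.uniform(-1, 1, 300), "a")
        b = self._pairs(np.where(rng.random(300) < 0.5, 0.95, -0.95), "b")
        res = pairmod.correlation_distribution_compare(a, b)
        assert res["frac_high_de_lnc"] > 0.95
        assert res["ks_pvalue"] < 0.01

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            pairmod.correlation_distribution_compare(self._pairs([0.1] * 10), self._pairs([0.2] * 10))


class TestCoverageCompare:
    def _de(self, lfcs, de_flags):
        return pd.DataFrame(
            {"log2fc": lfcs, "de": de_flags},
            index=[f"g{i}" for i in range(len(lfcs))],
        )

    def test_identical_coverage_no_signal(self):
        rng = np.random.default_rng(0)
        n = 60
        de = self._de(rng.normal(0, 2, n), rng.random(n) < 0.5)
        cov = {f"g{i}": 1.0 for i in range(n)}
        res = pairmod.coverage_group_compare(de, cov, n=20)
        assert res["mwu_pvalue"] > 0.4

    def test_planted_high_fc_coverage_detected(self):
        rng = np.random.default_rng(1)
        n = 200
        de_flags = np.array([True] * 60 + [False] * 140)
        lfcs = np.where(de_flags, rng.normal(3, 0.3, n), rng.normal(0, 0.2, n))
        cov = {f"g{i}": (3.0 + rng.random() if de_flags[i] else 0.0) for i in range(n)}
        res = pairmod.coverage_group_compare(self._de(lfcs, de_flags), cov, n=50)
        assert res["mwu_pvalue"] < 0.01
        assert res["mean_high"] > res["mean_low"]

    def test_groups_disjoint_and_truncated(self):
        de = self._de([2.0, -2.5, 0.1, 0.2], [True, True, False, False])
        res = pairmod.coverage_group_compare(de, {}, n=500)
        assert res["n_high_fc"] == 2 and res["n_low_fc"] == 2
        assert set(res["high_fc_genes"]).isdisjoint(res["low_fc_genes"])


class TestTrendMatrix:
    def test_shape_and_z_normalisation(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.poisson(100, (2, 9)).astype(float),
                            index=["l1", "g1"], columns=COLS)
        pairs = [PairRecord("l1", "g1", "both", r=0.5)]
        tab = pairmod.paired_trend_matrix(pairs, expr)
        assert len(tab) == 18
        for member in ("lnc", "gene"):
            z = tab[tab.member == member].z.to_numpy()
            assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9

    def test_ordering_stable(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.poisson(100, (6, 9)).astype(float),
                            index=["l1", "l2", "l3", "g1", "g2", "g3"], columns=COLS)
        pairs = [PairRecord(f"l{i}", f"g{i}", "triplex", r=rng.uniform(-1, 1))
                 for i in (1, 2, 3)]
        a = pairmod.paired_trend_matrix(pairs, expr, {"l1": 2, "l2": 1, "l3": 1})
        b = pairmod.paired_trend_matrix(pairs, expr, {"l1": 2, "l2": 1, "l3": 1})
        assert a.equals(b)
        assert list(a.lnc_cluster)[0] == 1  # sorted by cluster first
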