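import numpy as np
import pytest

from batchreg import triplex
from batchreg.io import GeneModel, GenomeScaffold, Interval
from batchreg.triplex import (
    GeneWindowSpace,
    TriplexParams,
    find_triplexes,
    intersect_sorted,
    map_tts_to_genes,
    merge_intervals,
    revcomp,
    total_length,
    tts_coverage_pct,
    tts_state_localization,
    validate_hit,
)
from batchreg.triplex_oracle import brute_force_hits
from batchreg.evaluation import random_triplex_instance


def hit_keys(hits):
    return {(h.rna_start, h.rna_end, h.tts_start, h.tts_end, h.dna_strand) for h in hits}


class TestFindTriplexes:
    def test_perfect_homopolymer(self):
        hits = find_triplexes("G" * 20, "T" * 10 + "G" * 20 + "T" * 10)
        assert hit_keys(hits) == {(0, 20, 10, 30, "+")}
        (h,) = hits
        assert h.n_errors == 0 and h.guanine_frac == 1.0 and h.length == 20

    def test_guanine_fraction_boundary(self):
        # GA x10: exactly 50% G passes (>= threshold); target = reverse on plus
        rna = "GA" * 10
        dna = "T" * 8 + rna[::-1] + "T" * 8
        hits = find_triplexes(rna, dna)
        assert any(h.rna_start == 0 and h.rna_end == 20 and h.guanine_frac == 0.5
                   for h in hits)

    def test_minus_strand_target(self):
        rna = "G" * 24
        dna = "T" * 9 + "C" * 24 + "A" * 9  # purine strand is the minus strand
        hits = find_triplexes(rna, dna)
        assert hits and all(h.dna_strand == "-" for h in hits)
        assert all(9 <= h.tts_start and h.tts_end <= 33 for h in hits)
        # the full-length alignment is among the maximal hits
        assert (0, 24, 9, 33, "-") in hit_keys(hits)
        assert hit_keys(hits) == brute_force_hits(rna, dna)

    def test_alphabet_violation(self):
        with pytest.raises(ValueError):
            find_triplexes("G" * 20, "GX" * 20)
        with pytest.raises(ValueError):
            find_triplexes("GZ" * 10, "G" * 40)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            TriplexParams(min_length=0)
        with pytest.raises(ValueError):
            TriplexParams(max_error_rate=1.5)
        with pytest.raises(ValueError):
            TriplexParams(motif="pyrimidine")


class TestOracleEquivalence:
    """The seeded engine must equal exhaustive enumeration everywhere."""

    def test_fuzz_engine_equals_bruteforce(self):
        rng = np.random.default_rng(2024)
        params = TriplexParams()
        checked_hits = 0
        for _ in range(200):
            rna, dna = random_triplex_instance(rng)
            eng = hit_keys(find_triplexes(rna, dna, params))
            orc = brute_force_hits(rna, dna, params)
            assert eng == orc, (rna, dna)
            checked_hits += len(orc)
        assert checked_hits > 100  # the instance generator must produce hits

    def test_fuzz_nondefault_params(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            rna, dna = random_triplex_instance(rng)
            params = TriplexParams(
                min_length=int(rng.choice([20, 23])),
                max_error_rate=float(rng.choice([0.1, 0.2])),
                max_consecutive_errors=int(rng.choice([1, 2])),
                min_guanine_frac=float(rng.choice([0.4, 0.5])),
            )
            assert hit_keys(find_triplexes(rna, dna, params)) == brute_force_hits(rna, dna, params)

    def test_every_hit_revalidates(self):
        rng = np.random.default_rng(5)
        params = TriplexParams()
        n_checked = 0
        for _ in range(40):
            rna, dna = random_triplex_instance(rng)
            for h in find_triplexes(rna, dna, params):
                assert validate_hit(h, rna, dna, params)
                n_checked += 1
        assert n_checked > 10

    def test_strand_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            rna, dna = random_triplex_instance(rng)
            fwd = hit_keys(find_triplexes(rna, dna))
            rev = hit_keys(find_triplexes(rna, revcomp(dna)))
            M = len(dna)
            flipped = {
                (rs, re, M - te, M - ts, "+" if st == "-" else "-")
                for rs, re, ts, te, st in rev
            }
            assert fwd == flipped


class TestIntervals:
    def test_merge_overlap(self):
        assert merge_intervals([(0, 10), (5, 15)]) == [(0, 15)]

    def test_merge_touching(self):
        assert merge_intervals([(0, 10), (10, 20)]) == [(0, 20)]

    def test_merge_idempotent_and_bitmap_oracle(self):
        rng = np.random.default_rng(3)
        ivs = [(int(a), int(a + rng.integers(1, 50))) for a in rng.integers(0, 2000, 1000)]
        merged = merge_intervals(ivs)
        assert merge_intervals(merged) == merged
        bitmap = np.zeros(3000, bool)
        for s, e in ivs:
            bitmap[s:e] = True
        assert total_length(merged) == int(bitmap.sum())

    def test_intersect(self):
        assert intersect_sorted([(0, 10), (20, 30)], [(5, 25)]) == [(5, 10), (20, 25)]


def _gene(gid="g1", scaf="s", start0=5000, end0=10000, strand="+", biotype="coding"):
    return GeneModel(gid, scaf, strand, start0 + 1, end0, biotype)


class TestMapping:
    def test_tts_inside_body_pairs(self):
        g = _gene()
        h = triplex.TriplexHit("l1", "s", 0, 20, 6000, 6020, "+", 0, 0.6)
        pairs = map_tts_to_genes([h], [g])
        assert [(p.lnc_id, p.gene_id) for p in pairs] == [("l1", "g1")]

    def test_halfopen_touch_is_no_overlap(self):
        g = _gene()  # window [3500, 11500)
        h = triplex.TriplexHit("l1", "s", 0, 20, 3480, 3500, "+", 0, 0.6)
        assert map_tts_to_genes([h], [g]) == []
        h2 = triplex.TriplexHit("l1", "s", 0, 20, 3480, 3501, "+", 0, 0.6)
        assert len(map_tts_to_genes([h2], [g])) == 1

    def test_self_pairing_excluded(self):
        g = GeneModel("l1", "s", "+", 5001, 10000, "coding")
        h = triplex.TriplexHit("l1", "s", 0, 20, 6000, 6020, "+", 0, 0.6)
        assert map_tts_to_genes([h], [g]) == []

    def test_coverage_pct(self):
        g = _gene(start0=2000, end0=4000)  # window [500, 5500) -> 5 kb
        assert tts_coverage_pct(g, [(1000, 1500)]) == pytest.approx(10.0)
        assert tts_coverage_pct(g, []) == 0.0
        assert tts_coverage_pct(g, [(0, 10000)]) == pytest.approx(100.0)

    def test_coverage_invariant_under_premerge(self):
        g = _gene(start0=2000, end0=4000)
        raw = [(1000, 1300), (1200, 1500), (1500, 1600)]
        assert tts_coverage_pct(g, raw) == tts_coverage_pct(g, merge_intervals(raw))


class TestStateLocalization:
    def test_promoter_only(self):
        seg = [
            Interval("s", 0, 100, "E9"),
            Interval("s", 100, 500, "E2"),
            Interval("s", 500, 600, "E4"),
        ]
        loc = tts_state_localization(
            {"s": [(0, 100)]}, seg, {"s": [(0, 600)]}
        )
        assert loc["promoter"]["freq"] == pytest.approx(1.0)
        assert loc["quiescent"]["freq"] == 0.0
        assert np.isnan(loc["enhancer"]["freq"])  # absent group flagged


class TestGeneWindowSpace:
    def test_lift_roundtrip(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=20000))
        motif = "G" * 25
        # plant target in the promoter region of a synthetic gene
        seq = seq[:6000] + motif[::-1] + seq[6025:]
        scaf = GenomeScaffold("s", seq)
        gene = _gene(start0=6500, end0=9000)
        space = GeneWindowSpace([scaf], [gene], flank=1500)
        searcher = triplex.TriplexSearcher([space.scaffold])
        hits = space.lift(searcher.search(motif, "l1"))
        direct = find_triplexes(motif, scaf, lnc_id="l1")
        in_window = [h for h in direct if h.tts_start < 10500 and h.tts_end > 5000]
        assert hit_keys(hits) == hit_keys(in_window)
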