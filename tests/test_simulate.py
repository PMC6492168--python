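import json

import numpy as np
import pytest

from batchreg import expression, triplex
from batchreg.io import read_fasta, read_gtf, read_table, validate_segmentation
from batchreg.simulate import (
    RNA_TO_CHIP,
    ConfigError,
    SimConfig,
    archetype_profile,
    generate_genome,
    simulate_dataset,
    write_dataset,
)
from tests.conftest import SMALL_CONFIG


class TestConfig:
    def test_tfo_below_minimum_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(planted_tfo_len=19)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(frac_de_coding=0.0)

    def test_genes_must_fit(self):
        with pytest.raises(ConfigError):
            generate_genome(SimConfig(n_scaffolds=1, scaffold_len=50_000))


class TestGenome:
    def test_counts_and_no_overlaps(self, small_dataset):
        genes = small_dataset.genes
        assert sum(g.biotype == "coding" for g in genes) == SMALL_CONFIG["n_coding"]
        assert sum(g.biotype != "coding" for g in genes) == SMALL_CONFIG["n_lnc"]
        by_scaf = {}
        for g in genes:
            by_scaf.setdefault(g.scaffold, []).append(g)
        for gs in by_scaf.values():
            gs.sort(key=lambda g: g.start0)
            for a, b in zip(gs, gs[1:]):
                assert a.end0 <= b.start0

    def test_background_homopurine_runs_capped(self, small_dataset):
        """Direct scan: outside planted motifs there is no purine run >= 20."""
        motif_mask = {s.id: np.zeros(len(s.sequence), bool) for s in small_dataset.scaffolds}
        for scaf, s, e in small_dataset.truth.motif_regions:
            motif_mask[scaf][s:e] = True
        for scaf in small_dataset.scaffolds:
            run = best = 0
            mask = motif_mask[scaf.id]
            for i, ch in enumerate(scaf.sequence):
                if ch in "AG" and not mask[i]:
                    run += 1
                    best = max(best, run)
                else:
                    run = 0
            assert best < 20

    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=5, **SMALL_CONFIG)
        d1 = write_dataset(simulate_dataset(cfg), tmp_path / "a")
        d2 = write_dataset(simulate_dataset(cfg), tmp_path / "b")
        for name in d1:
            b1 = open(d1[name], "rb").read()
            b2 = open(d2[name], "rb").read()
            assert b1 == b2, name

    def test_written_formats_readable(self, tmp_path, small_dataset):
        paths = write_dataset(small_dataset, tmp_path / "ds")
        scafs = read_fasta(paths["genome.fa"])
        assert len(scafs) == SMALL_CONFIG["n_scaffolds"]
        genes = read_gtf(paths["genes.gtf"], known_scaffolds={s.id for s in scafs})
        assert len(genes) == len(small_dataset.genes)
        assert all(g.known_scaffold for g in genes)
        counts = read_table(paths["counts.tsv"], "counts")
        assert counts.shape == small_dataset.counts.shape
        meth = read_table(paths["methylation.tsv"], "methylation")
        assert len(meth) == len(small_dataset.methylation)
        truth = json.loads(open(paths["truth.json"]).read())
        assert len(truth["planted_pairs"]) == SMALL_CONFIG["n_planted_pairs"]


class TestExpression:
    def test_non_de_gene_phase_means_flat(self, small_dataset):
        mu = small_dataset.mu
        truth = small_dataset.truth
        flat = [g for g in mu.index
                if truth.expressed[g] and g not in truth.de_cluster
                and g not in truth.lnc_de_cluster
                and g not in {p.lnc_id for p in truth.planted_pairs}]
        sub = mu.loc[flat].to_numpy()
        ratios = sub[:, :4].mean(axis=1) / sub[:, 6:].mean(axis=1)
        assert np.allclose(ratios, 1.0)

    def test_cluster1_effect_fourfold(self, small_dataset):
        """Archetype 1 with effect 2: decline-phase mean = exponential / 4."""
        mu = small_dataset.mu
        truth = small_dataset.truth
        c1 = [g for g, k in truth.de_cluster.items() if k == 1 and g not in truth.unmarked_de]
        sub = mu.loc[c1].to_numpy()
        ratios = sub[:, :4].mean(axis=1) / sub[:, 6:].mean(axis=1)
        assert np.allclose(ratios, 4.0, rtol=1e-6)

    def test_archetype_peak_to_trough_equals_effect(self):
        for k in (1, 2, 3, 4):
            prof = archetype_profile(k, 2.0)
            assert prof.max() - prof.min() == pytest.approx(2.0)

    def test_counts_reproducible(self):
        cfg = SimConfig(seed=9, **SMALL_CONFIG)
        a = simulate_dataset(cfg, include_epigenome=False).counts
        b = simulate_dataset(cfg, include_epigenome=False).counts
        assert (a == b).all().all()


class TestPlanting:
    def test_oracle_finds_every_planted_site(self, small_dataset):
        """Brute-force-equivalent search spans each planted TTS (mismatches=0)."""
        seqs = {s.id: s.sequence for s in small_dataset.scaffolds}
        genes = {g.gene_id: g for g in small_dataset.genes}
        for p in small_dataset.truth.planted_pairs:
            lnc = genes[p.lnc_id]
            rna = triplex.transcript_sequence(lnc, seqs[lnc.scaffold])
            region = seqs[p.scaffold][max(0, p.tts_start - 40): p.tts_end + 40]
            hits = triplex.find_triplexes(rna, region)
            off = max(0, p.tts_start - 40)
            assert any(
                h.tts_start + off <= p.tts_start and h.tts_end + off >= p.tts_end
                for h in hits
            ), p

    def test_intended_sign_on_expected_values(self, small_dataset):
        mu = small_dataset.mu
        genes = small_dataset.truth.planted_pairs
        for p in genes:
            a = np.log2(mu.loc[p.lnc_id].to_numpy() + 1e-9)
            b = np.log2(mu.loc[p.gene_id].to_numpy() + 1e-9)
            r = np.corrcoef(a, b)[0, 1]
            assert np.sign(r) == p.sign, p
            if p.coupled:
                assert abs(r) >= small_dataset.config.coupling_r


class TestEpigenome:
    def test_segmentations_partition_scaffolds(self, small_dataset):
        lengths = small_dataset.scaffold_lengths
        for tp, ivs in small_dataset.segmentations.items():
            validate_segmentation(ivs, lengths)

    def test_promoter_methylation_bimodal(self, small_dataset):
        truth = small_dataset.truth
        genes = {g.gene_id: g for g in small_dataset.genes}
        by_scaf = {}
        for r in small_dataset.methylation:
            by_scaf.setdefault(r.scaffold, []).append(r)
        on, off = [], []
        for gid, g in genes.items():
            recs = [r for r in by_scaf.get(g.scaffold, [])
                    if abs(r.pos0 - g.tss0) <= 500]
            vals = [r.meth_fraction for r in recs]
            if not vals:
                continue
            (on if truth.expressed[gid] else off).append(np.mean(vals))
        assert np.mean(on) < 0.2
        assert np.mean(off) > 0.8

    def test_coupled_signal_correlates_with_expression(self, small_dataset):
        from batchreg import chromatin
        z, _ = expression.vst_zscore(
            small_dataset.counts.loc[expression.filter_expressed(small_dataset.counts)]
        )
        corr = chromatin.mark_expression_correlation(
            z, chromatin.zscore_rows(small_dataset.signal["H3K4me3"]), RNA_TO_CHIP
        )
        coupled = [g for g in small_dataset.truth.coupled_genes if g in corr.index]
        r = corr.loc[coupled, "r"].dropna()
        assert (r > 0).mean() >= 0.9
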