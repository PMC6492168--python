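"""End-to-end orchestration: simulate (or load) -> normalise -> DE -> cluster
-> methylation profiles -> chromatin enrichment/flags/correlation -> triplex
search -> pair statistics, with a JSON manifest of output hashes.

Each stage derives its own child seed from (global seed, stage name), so
inserting a stage never shifts another stage's random stream, and reruns
with the same config and seed reproduce every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import chromatin, expression, methylation, pairs as pairmod, triplex
from .io import write_bed, Interval
from .simulate import (
    RNA_TO_CHIP,
    SimConfig,
    SyntheticDataset,
    simulate_dataset,
    write_dataset,
)


class PipelineConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "results/pipeline"
    simulate: dict[str, Any] = dataclasses.field(default_factory=dict)
    fdr: float = 0.01
    lfc: float = 1.0
    flank: int = 1500
    min_cov: int = 10
    loess_span: float = 0.75
    n_clusters: int = 4
    coverage_n: int = 500
    triplex: dict[str, Any] = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def _stage_seed(seed: int, stage: str) -> int:
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage on the (simulated) dataset; returns the manifest."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}, "outputs": {}}

    def _record(stage: str, paths: dict[str, Path], t_start: float, **params):
        manifest["stages"][stage] = {
            "params": params,
            "seconds": round(time.time() - t_start, 3),
        }
        for name, p in paths.items():
            manifest["outputs"][name] = _sha(Path(p))

    try:
        # --- simulate -------------------------------------------------------
        ts = time.time()
        sim_kwargs = dict(config.simulate)
        sim_kwargs["seed"] = _stage_seed(config.seed, "simulate")
        ds = simulate_dataset(SimConfig(**sim_kwargs))
        data_dir = out / "data"
        paths = write_dataset(ds, data_dir)
        _record("simulate", {k: Path(v) for k, v in paths.items()}, ts,
                **{k: v for k, v in sim_kwargs.items()})

        # --- expression -----------------------------------------------------
        ts = time.time()
        expressed = expression.filter_expressed(ds.counts)
        counts = ds.counts.loc[expressed]
        zmat, _flags = expression.vst_zscore(counts)
        de_params = expression.DEParams(fdr=config.fdr, lfc=config.lfc)
        res = {
            cmp_name: expression.de_test(counts, ds.rna_samples, cmp_name, de_params)
            for cmp_name in ("ES", "ED")
        }
        de_tables = {}
        for cmp_name, df in res.items():
            p = out / f"de_{cmp_name}.tsv"
            df.to_csv(p, sep="\t", float_format="%.6g")
            de_tables[f"de_{cmp_name}"] = p
        coding = {g.gene_id for g in ds.genes if g.biotype == "coding"}
        de_coding = [
            g for g in expression.de_union(list(res.values())) if g in coding
        ]
        clu = None
        if len(de_coding) >= config.n_clusters:
            clu = expression.fuzzy_cmeans(
                zmat.loc[de_coding], c=config.n_clusters,
                seed=_stage_seed(config.seed, "cluster"),
            )
            p = out / "clusters.tsv"
            tab = clu.membership.copy()
            tab["assigned"] = clu.assigned
            tab.to_csv(p, sep="\t", float_format="%.6g")
            de_tables["clusters"] = p
        var_frac, scores, degenerate = expression.pca_samples(zmat)
        p = out / "pca_samples.tsv"
        scores.assign(phase=list(ds.rna_samples["phase"])).to_csv(
            p, sep="\t", float_format="%.6g"
        )
        de_tables["pca_samples"] = p
        _record("expression", de_tables, ts, fdr=config.fdr, lfc=config.lfc,
                n_expressed=len(expressed), n_de_coding=len(de_coding),
                pc1_var=float(var_frac[0]) if not degenerate else None)

        # --- methylation ----------------------------------------------------
        ts = time.time()
        expr_set = set(expressed)
        meth_tables = {}
        for label, window, group_genes in (
            ("coding_expressed", 3000,
             [g for g in ds.genes if g.biotype == "coding" and g.gene_id in expr_set]),
            ("coding_silent", 3000,
             [g for g in ds.genes if g.biotype == "coding" and g.gene_id not in expr_set]),
            ("noncoding_expressed", 1500,
             [g for g in ds.genes if g.biotype != "coding" and g.gene_id in expr_set]),
            ("noncoding_silent", 1500,
             [g for g in ds.genes if g.biotype != "coding" and g.gene_id not in expr_set]),
        ):
            prof = methylation.tss_profile(
                ds.methylation, group_genes, window=window,
                min_cov=config.min_cov, group=label, span=config.loess_span,
            )
            p = out / f"methprofile_{label}.tsv"
            prof.table.to_csv(p, sep="\t", index=False, float_format="%.6g")
            meth_tables[f"methprofile_{label}"] = p
        _record("methylation", meth_tables, ts, min_cov=config.min_cov,
                span=config.loess_span)

        # --- chromatin ------------------------------------------------------
        ts = time.time()
        mid_tp = len(ds.segmentations) // 4 or 1  # near mid-exponential
        seg = ds.segmentations[mid_tp]
        expr_coding_ivs = [
            Interval(g.scaffold, g.start0, g.end0, g.gene_id)
            for g in ds.genes if g.biotype == "coding" and g.gene_id in expr_set
        ]
        enr = chromatin.overlap_enrichment(
            seg, expr_coding_ivs, sum(ds.scaffold_lengths.values()),
            target_name="expressed_coding", scaffold_lengths=ds.scaffold_lengths,
        )
        chrom_tables = {}
        p = out / "state_enrichment.tsv"
        pd.DataFrame([dataclasses.asdict(e) for e in enr]).to_csv(
            p, sep="\t", index=False, float_format="%.6g"
        )
        chrom_tables["state_enrichment"] = p
        per_tp_flags = [
            chromatin.mark_gene_flags(
                ds.genes, ds.segmentations[tp],
                {m: ds.peaks[(m, tp)] for m in ("H3K36me3", "H3K4me3", "H3K27ac")},
            )
            for tp in sorted(ds.segmentations)
        ]
        agg = chromatin.aggregate_flags(per_tp_flags)
        p = out / "mark_flags.tsv"
        agg.to_csv(p, sep="\t")
        chrom_tables["mark_flags"] = p
        markcorr = {}
        for mark, sig in ds.signal.items():
            markcorr[mark] = chromatin.mark_expression_correlation(
                zmat, chromatin.zscore_rows(sig), RNA_TO_CHIP
            )
            p = out / f"markcorr_{mark}.tsv"
            markcorr[mark].to_csv(p, sep="\t", float_format="%.6g")
            chrom_tables[f"markcorr_{mark}"] = p
        group, fc_summary = chromatin.flag_group_fc_distribution(
            res["ED"].loc[[g for g in de_coding]], agg
        )
        p = out / "fc_by_mark_group.tsv"
        fc_summary.to_csv(p, sep="\t", float_format="%.6g")
        chrom_tables["fc_by_mark_group"] = p
        _record("chromatin", chrom_tables, ts, mid_tp=mid_tp)

        # --- triplex --------------------------------------------------------
        ts = time.time()
        params = triplex.TriplexParams(**config.triplex)
        lnc_ids = [
            g.gene_id for g in ds.genes
            if g.biotype != "coding" and g.gene_id in expr_set
        ]
        hits = triplex.search_lnc_targets(
            ds.scaffolds, ds.genes, lnc_ids, params, flank=config.flank
        )
        tri_pairs = triplex.map_tts_to_genes(
            hits, ds.genes, flank=config.flank, scaffold_lengths=ds.scaffold_lengths
        )
        tri_tables = {}
        p = out / "triplex_hits.bed"
        write_bed(
            [Interval(h.scaffold, h.tts_start, h.tts_end, h.lnc_id, float(h.n_errors))
             for h in hits], p,
        )
        tri_tables["triplex_hits"] = p
        p = out / "triplex_pairs.tsv"
        pd.DataFrame(
            [{"lnc_id": q.lnc_id, "gene_id": q.gene_id, "n_hits": q.n_hits,
              "tts_bases": triplex.total_length(q.merged_tts)} for q in tri_pairs]
        ).to_csv(p, sep="\t", index=False)
        tri_tables["triplex_pairs"] = p
        _record("triplex", tri_tables, ts, n_hits=len(hits), n_pairs=len(tri_pairs),
                **dataclasses.asdict(params))

        # --- interaction dynamics -------------------------------------------
        ts = time.time()
        coding_models = [g for g in ds.genes if g.biotype == "coding"]
        lnc_models = [g for g in ds.genes if g.biotype != "coding"]
        nbr = pairmod.neighbor_pairs(coding_models, lnc_models, max_dist=config.flank)
        all_pairs = pairmod.combine_pairs(nbr, tri_pairs)
        fpm = expression.cpm(ds.counts)
        kept, _dropped = pairmod.pair_correlation(fpm, all_pairs, expressed=expr_set)
        de_lnc = {
            g for g in expressed
            if g not in coding and (
                res["ES"].loc[g, "de"] or res["ED"].loc[g, "de"]
            )
        }
        for p_rec in kept:
            p_rec.lnc_de = p_rec.lnc_id in de_lnc
        pair_tables = {}
        p = out / "pairs.tsv"
        pd.DataFrame([dataclasses.asdict(q) for q in kept]).to_csv(
            p, sep="\t", index=False, float_format="%.6g"
        )
        pair_tables["pairs"] = p
        summary: dict[str, Any] = {}
        de_lnc_pairs = [q for q in kept if q.lnc_de]
        if sum(q.r is not None for q in kept) >= 50 and sum(
            q.r is not None for q in de_lnc_pairs
        ) >= 50:
            comp = pairmod.correlation_distribution_compare(kept, de_lnc_pairs)
            summary["correlation_compare"] = {
                k: v for k, v in comp.items() if not isinstance(v, np.ndarray)
            }
        cov = {}
        merged_by_gene: dict[str, list[tuple[int, int]]] = {}
        for q in tri_pairs:
            merged_by_gene.setdefault(q.gene_id, []).extend(q.merged_tts)
        for g in coding_models:
            if g.gene_id in expr_set:
                cov[g.gene_id] = triplex.tts_coverage_pct(
                    g, merged_by_gene.get(g.gene_id, []), flank=config.flank,
                    scaffold_len=ds.scaffold_lengths[g.scaffold],
                )
        ed_coding = res["ED"].loc[[g for g in expressed if g in coding]]
        summary["coverage_compare"] = {
            k: v for k, v in pairmod.coverage_group_compare(
                ed_coding, cov, n=config.coverage_n
            ).items() if not isinstance(v, list)
        }
        merged_by_scaf: dict[str, list[tuple[int, int]]] = {}
        for h in hits:
            merged_by_scaf.setdefault(h.scaffold, []).append((h.tts_start, h.tts_end))
        windows_by_scaf: dict[str, list[tuple[int, int]]] = {}
        for g in coding_models:
            windows_by_scaf.setdefault(g.scaffold, []).append(
                g.window0(config.flank, ds.scaffold_lengths[g.scaffold])
            )
        loc_rows = []
        for tp in sorted(ds.segmentations):
            loc = triplex.tts_state_localization(
                merged_by_scaf, ds.segmentations[tp], windows_by_scaf
            )
            for gname, d in loc.items():
                loc_rows.append({"tp": tp, "group": gname, **d})
        p = out / "tts_state_localization.tsv"
        pd.DataFrame(loc_rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
        pair_tables["tts_state_localization"] = p
        p = out / "summary.json"
        p.write_text(json.dumps(summary, indent=1, sort_keys=True, default=float))
        pair_tables["summary"] = p
        _record("pairs", pair_tables, ts, n_pairs=len(kept))

    except Exception as exc:  # partial manifest with the failure recorded
        manifest["failure"] = {"stage": "unknown", "error": f"{type(exc).__name__}: {exc}"}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise

    manifest["wall_seconds"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
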