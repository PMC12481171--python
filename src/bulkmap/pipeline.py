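"""Sequential orchestration of the full synthetic-study pipeline.

Stages: simulate -> bsa -> annotate -> de -> triage -> promoter.  Each
stage writes its outputs under ``out_dir/<stage>/`` and records parameters
and content hashes in a JSON manifest; a rerun with the same config and
seed is byte-identical.  Plain sequential execution — this is desk-scale
analysis, not a workflow engine.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import bsa, de, io, simulate, triage as triage_mod
from .config import DEFAULT_ROLES, RunConfig, stage_rng
from .promoter import diff_motifs, global_align, load_catalog

__all__ = ["run_pipeline", "PipelineError", "ConfigError", "DependencyError"]


class PipelineError(RuntimeError):
    exit_code = 1


class ConfigError(PipelineError):
    exit_code = 2


class DependencyError(PipelineError):
    exit_code = 3


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage {needed_by!r} needs {path.name} from stage {stage!r}; "
            f"run that stage first (missing: {path})"
        )
    return path


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the enabled stages in dependency order; return the manifest."""
    valid = {"simulate", "bsa", "annotate", "de", "triage", "promoter"}
    unknown = set(cfg.stages) - valid
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = cfg.sim_config()
    manifest: dict = {"seed": cfg.seed, "stages": {}}

    def record(stage: str, params: dict, files: list) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {
                str(p.relative_to(out)): _sha256(p) for p in sorted(files)
            },
        }

    sim_dir = out / "simulate"
    if "simulate" in cfg.stages:
        sim_dir.mkdir(exist_ok=True)
        reference = (
            simulate.simulate_reference(sim_cfg.chrom_lengths, seed=sim_cfg.seed)
            if cfg.write_reference
            else None
        )
        pop = simulate.simulate_population(sim_cfg)
        low, high = simulate.select_bulks(pop, sim_cfg.bulk_size)
        vmap = simulate.make_variant_map(sim_cfg, reference=reference)
        reads = simulate.simulate_pool_reads(low, high, vmap, sim_cfg)
        io.write_vcf(reads, sim_dir / "variants.vcf", chrom_lengths=sim_cfg.chrom_lengths)
        genes = simulate.simulate_gene_models(sim_cfg)
        io.write_gff3(genes, sim_dir / "genes.gff3")
        counts, lengths, truth, conditions = simulate.simulate_expression(
            sim_cfg, gene_ids=[g.gene_id for g in genes]
        )
        io.write_counts(counts, lengths, sim_dir / "counts.tsv")
        io.write_conditions(conditions, sim_dir / "conditions.yaml")
        truth.to_csv(sim_dir / "truth_expression.tsv", sep="\t")
        pair, ptruth = simulate.simulate_promoter_pair(sim_cfg)
        io.write_fasta({"allele_A": pair[1], "allele_B": pair[2]}, sim_dir / "promoter_pair.fasta")
        ptruth.to_csv(sim_dir / "truth_promoter.tsv", sep="\t", index=False)
        pd.DataFrame(sim_cfg.qtls, columns=["chrom", "pos", "effect"]).to_csv(
            sim_dir / "truth_qtls.tsv", sep="\t", index=False
        )
        files = [
            sim_dir / f
            for f in (
                "variants.vcf", "genes.gff3", "counts.tsv", "conditions.yaml",
                "truth_expression.tsv", "truth_promoter.tsv", "truth_qtls.tsv",
                "promoter_pair.fasta",
            )
        ]
        if reference is not None:
            io.write_fasta(reference, sim_dir / "reference.fasta")
            files.append(sim_dir / "reference.fasta")
        record("simulate", {"sim": sim_cfg.__dict__ | {"qtls": list(map(list, sim_cfg.qtls))}}, files)

    bsa_dir = out / "bsa"
    if "bsa" in cfg.stages:
        vcf_path = _require(sim_dir / "variants.vcf", "simulate", "bsa")
        bsa_dir.mkdir(exist_ok=True)
        sites = bsa.assign_roles(io.read_vcf(vcf_path), DEFAULT_ROLES)
        sites = bsa.filter_informative_sites(sites)
        points = bsa.compute_index(sites)
        points.to_csv(bsa_dir / "index_points.tsv", sep="\t", index=False)
        tracks = {}
        for vclass in ("SNP", "Indel"):
            sub = points[points["vclass"] == vclass]
            win = bsa.sliding_windows(
                sub,
                window_bp=cfg.window_bp,
                step_bp=cfg.step_bp,
                min_sites=cfg.min_sites,
                chrom_lengths=sim_cfg.chrom_lengths,
            )
            win = bsa.loess_fit(win, span=cfg.loess_span)
            depths = win["mean_depth"].dropna()
            if len(depths):
                lo, hi = int(np.floor(depths.min())), int(np.ceil(depths.max()))
                grid = sorted(set(np.linspace(lo, hi, 6).round().astype(int)))
            else:
                grid = [int(sim_cfg.depth_aa)]
            ci = bsa.null_ci(
                grid,
                sim_cfg.bulk_size,
                n_sims=cfg.n_null_sims,
                conf=cfg.conf,
                seed=cfg.seed,
            )
            win = bsa.attach_ci(win, ci)
            win.to_csv(bsa_dir / f"windows_{vclass.lower()}.tsv", sep="\t", index=False)
            tracks[vclass] = win
        called = bsa.call_regions(tracks["SNP"], tracks["Indel"], step_bp=cfg.step_bp)
        io.write_bed(called["snp"], bsa_dir / "regions_snp.bed")
        io.write_bed(called["indel"], bsa_dir / "regions_indel.bed")
        io.write_bed(called["candidates"], bsa_dir / "regions_candidates.bed")
        record(
            "bsa",
            {
                "window_bp": cfg.window_bp,
                "step_bp": cfg.step_bp,
                "min_sites": cfg.min_sites,
                "conf": cfg.conf,
                "loess_span": cfg.loess_span,
                "n_null_sims": cfg.n_null_sims,
                "roles": DEFAULT_ROLES,
            },
            [
                bsa_dir / f
                for f in (
                    "index_points.tsv", "windows_snp.tsv", "windows_indel.tsv",
                    "regions_snp.bed", "regions_indel.bed", "regions_candidates.bed",
                )
            ],
        )

    ann_dir = out / "annotate"
    if "annotate" in cfg.stages:
        from .effects import annotate_table

        vcf_path = _require(sim_dir / "variants.vcf", "simulate", "annotate")
        gff_path = _require(sim_dir / "genes.gff3", "simulate", "annotate")
        fasta_path = sim_dir / "reference.fasta"
        ref = io.read_fasta(fasta_path) if fasta_path.exists() else None
        ann_dir.mkdir(exist_ok=True)
        sites = bsa.assign_roles(io.read_vcf(vcf_path), DEFAULT_ROLES)
        sites = bsa.filter_informative_sites(sites)
        genes = io.read_gff3(gff_path)
        effects = annotate_table(
            sites[["chrom", "pos", "ref", "alt"]], genes, ref, cfg.upstream_bp
        )
        effects.to_csv(ann_dir / "effects.tsv", sep="\t", index=False)
        record("annotate", {"upstream_bp": cfg.upstream_bp}, [ann_dir / "effects.tsv"])

    de_dir = out / "de"
    if "de" in cfg.stages:
        counts_path = _require(sim_dir / "counts.tsv", "simulate", "de")
        cond_path = _require(sim_dir / "conditions.yaml", "simulate", "de")
        de_dir.mkdir(exist_ok=True)
        counts, lengths = io.read_counts(counts_path)
        conditions = io.read_conditions(cond_path)
        res = de.nb_de_test(
            counts, lengths, conditions, fdr_threshold=cfg.fdr, lfc_threshold=cfg.lfc
        )
        res.to_csv(de_dir / "de_results.tsv", sep="\t")
        record(
            "de",
            {"fdr": cfg.fdr, "lfc": cfg.lfc, "direction": res.attrs["direction"]},
            [de_dir / "de_results.tsv"],
        )

    tri_dir = out / "triage"
    if "triage" in cfg.stages:
        regions_path = _require(bsa_dir / "regions_candidates.bed", "bsa", "triage")
        gff_path = _require(sim_dir / "genes.gff3", "simulate", "triage")
        de_path = _require(de_dir / "de_results.tsv", "de", "triage")
        eff_path = _require(ann_dir / "effects.tsv", "annotate", "triage")
        tri_dir.mkdir(exist_ok=True)
        regions = io.read_bed(regions_path)
        genes = io.read_gff3(gff_path)
        de_res = pd.read_csv(de_path, sep="\t", index_col="gene_id")
        effects = pd.read_csv(eff_path, sep="\t")
        report = triage_mod.triage(regions, genes, de_res, effects)
        ranked = triage_mod.rank_candidates(report)
        ranked.to_csv(tri_dir / "candidates.tsv", sep="\t", index=False)
        with open(tri_dir / "summary.json", "w") as fh:
            json.dump(report.counts, fh, indent=2, sort_keys=True)
            fh.write("\n")
        record(
            "triage",
            {"qualifying": sorted(triage_mod.QUALIFYING_EFFECTS)},
            [tri_dir / "candidates.tsv", tri_dir / "summary.json"],
        )

    prom_dir = out / "promoter"
    if "promoter" in cfg.stages:
        pair_path = _require(sim_dir / "promoter_pair.fasta", "simulate", "promoter")
        prom_dir.mkdir(exist_ok=True)
        seqs = io.read_fasta(pair_path)
        if len(seqs) != 2:
            raise ConfigError("promoter FASTA must contain exactly 2 records")
        (name_a, seq_a), (name_b, seq_b) = list(seqs.items())
        catalog = load_catalog()
        aln = global_align(seq_a, seq_b)
        diff = diff_motifs(f"{name_a}|{name_b}", seq_a, seq_b, catalog, alignment=aln)
        diff.variants.to_csv(prom_dir / "promoter_variants.tsv", sep="\t", index=False)
        pd.concat(
            [diff.losses.assign(change="loss"), diff.gains.assign(change="gain")],
            ignore_index=True,
        ).to_csv(prom_dir / "motif_diff.tsv", sep="\t", index=False)
        io.write_fasta(
            {f"{name_a}_aligned": aln[1], f"{name_b}_aligned": aln[2]},
            prom_dir / "aligned.fasta",
        )
        record(
            "promoter",
            {"score": aln[0]},
            [
                prom_dir / "promoter_variants.tsv",
                prom_dir / "motif_diff.tsv",
                prom_dir / "aligned.fasta",
            ],
        )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
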