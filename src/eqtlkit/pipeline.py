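"""End-to-end orchestration: simulate -> preprocess -> scan -> blocks/leads
-> clusters -> artifact flags -> LD pruning, with a manifest recording
seeds, thresholds and per-stage row counts.
"""
from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import artifacts as art
from . import association as assoc
from . import blocks as blk
from . import clusters as clu
from . import enrichment as enr
from . import ioutils as io
from . import preprocess as pre
from .config import PipelineConfig
from .core import Annotation, CovariateTable, GenotypeMatrix
from .simulate import SimConfig, simulate_all

log = logging.getLogger(__name__)


def scan_covariates(covars: CovariateTable) -> np.ndarray:
    """Sex and age columns entering the per-pair model alongside factors."""
    return covars.data[["sex", "age"]].to_numpy(dtype=float)


def _strip_top_genetic(
    adj: "pre.AdjustedExpression",
    table: pd.DataFrame,
    genotypes: GenotypeMatrix,
):
    """Residuals with each transcript's strongest retained dosage effect
    regressed out (one SNP per transcript).

    Used between factor-estimation passes so broad genuine trans signatures
    (hotspots) are not absorbed into the confounder factors.
    """
    from .core import AdjustedExpression

    cleaned = adj.residuals.copy()
    # strongest retained SNP per (transcript, chromosome): removes cis and
    # distant signals simultaneously
    top = table.sort_values(["p", "snp_id"], kind="mergesort").drop_duplicates(
        ["transcript_cluster_id", "chrom"]
    )
    idx = genotypes.snp_index()
    for tc, grp in top.groupby("transcript_cluster_id", sort=False):
        D = np.column_stack(
            [genotypes.dosages[:, idx[s]] for s in grp["snp_id"]]
        )
        D = D - D.mean(axis=0)
        y = cleaned[tc].to_numpy()
        yc = y - y.mean()
        coef, *_ = np.linalg.lstsq(D, yc, rcond=None)
        cleaned[tc] = y - D @ coef
    return AdjustedExpression(cleaned, provenance=adj.provenance
                              + ["strip_top_genetic"], design=adj.design)


def analyze(
    genotypes: GenotypeMatrix,
    annotation: Annotation,
    gene_expr: pd.DataFrame,
    exon_expr: pd.DataFrame | None,
    covars: CovariateTable,
    config: PipelineConfig,
) -> dict:
    """Run the full analysis in memory; returns a dict of result tables.

    Stages: residualize biological covariates, latent factors (two passes:
    factors are re-estimated after stripping each transcript's strongest
    genetic effect, so genuine broad trans signatures are not swallowed as
    confounders), gene-level scan, provisional blocks for cis/trans
    labelling, stratified FDR, significant blocks and stepwise leads, trans
    hotspot clusters, exon-level scan and polymorphism-in-probe flags, LD
    pruning.
    """
    res: dict = {}
    n = len(gene_expr)
    adj0 = pre.residualize(gene_expr, covars)
    k = min(config.n_factors, n - 2, gene_expr.shape[1] - 1)
    C = scan_covariates(covars)
    if k >= 1:
        adj = pre.latent_factors(adj0, k=k)
        tab1, _ = assoc.scan(
            genotypes, adj, annotation,
            retention_p=config.retention_p, covariates=C,
            lambda_snps=1, seed=config.seed,
        )
        cleaned = _strip_top_genetic(adj0, tab1, genotypes)
        factors = pre.latent_factors(cleaned, k=k).factors
        adj = pre.AdjustedExpression(
            adj0.residuals, factors=factors,
            provenance=adj0.provenance + [f"latent_factors(k={k}, 2-pass)"],
            design=adj0.design,
        )
    else:
        adj = adj0

    table, diag = assoc.scan(
        genotypes, adj, annotation,
        retention_p=config.retention_p,
        covariates=C,
        lambda_snps=config.lambda_snps,
        seed=config.seed,
    )
    # provisional blocks from all retained records assign cis/trans labels
    blocks0 = blk.build_blocks(table, annotation, config.block_gap_bp)
    table = blk.label_records(table, blocks0, annotation, config.cis_window_bp)
    table = assoc.stratified_fdr(table, diag.n_tests_cis, diag.n_tests_trans)
    res["associations"] = table
    res["diagnostics"] = diag

    sig = table[table["q"] < config.fdr]
    res["significant"] = sig
    blocks = blk.build_blocks(sig, annotation, config.block_gap_bp)
    for b in blocks:
        blk.classify_cis_trans(b, annotation, config.cis_window_bp)
    res["blocks"] = blocks

    lead_sets = [
        blk.stepwise_leads(
            b, genotypes, adj, C, sig,
            ld_max_r2=config.lead_ld_r2, p_add=config.lead_p_add,
        )
        for b in blocks
    ]
    lead_sets = [ls for ls in lead_sets if ls.leads]
    res["lead_sets"] = lead_sets
    res["leads"] = blk.lead_table(lead_sets, sig)

    # trans hotspot clusters
    gene_chrom = annotation.gene_chrom()
    trans = sig[sig["label"] == "trans"].copy()
    trans["target_chrom"] = trans["transcript_cluster_id"].map(gene_chrom)
    eligible = clu.eligible_snps(trans, config.cluster_min_targets)
    clusters = clu.grow_clusters(eligible, config.cluster_d_max)
    res["eligible_trans"] = eligible
    res["clusters"] = clusters
    res["cluster_table"], res["cluster_singletons"] = clu.cluster_tables(
        clusters, eligible
    )

    # exon-level scan and artifact flags
    if exon_expr is not None:
        adj_e = pre.residualize(exon_expr, covars)
        adj_e.factors = adj.factors  # same confounder estimates
        exon_table, _ = assoc.scan(
            genotypes, adj_e, annotation,
            retention_p=config.retention_p,
            covariates=C,
            lambda_snps=1,
            seed=config.seed,
        )
        res["exon_associations"] = exon_table
        overlaps = art.probe_snp_overlap(annotation.probes, genotypes.snps)
        res["probe_overlaps"] = overlaps
        gene_cis = table[table["label"] == "cis"]
        ps_gene = annotation.probesets.set_index("probeset_id")["gene_id"]
        e = exon_table.copy()
        e["gene_chrom"] = e["transcript_cluster_id"].map(ps_gene).map(gene_chrom)
        exon_cis = e[e["chrom"] == e["gene_chrom"]]
        flags = art.flag_artifacts(
            overlaps, gene_cis, exon_cis, annotation.probesets,
            gene_frac=config.pip_gene_frac, exon_frac=config.pip_exon_frac,
        )
        res["artifact_flags"] = flags
        res["associations"] = art.apply_flags(table, flags)
        res["leads"] = art.apply_flags(res["leads"], flags)

    # LD pruning for enrichment frames
    min_p = table.groupby("snp_id")["p"].min()
    snp_min_p = genotypes.snps[["snp_id"]].copy()
    snp_min_p["min_p"] = snp_min_p["snp_id"].map(min_p)
    res["pruned"] = enr.ld_prune(snp_min_p, genotypes, config.prune_ld)
    return res


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    sim_config: SimConfig | None = None,
    inputs: dict | None = None,
) -> dict:
    """Execute the pipeline and write all artifacts under ``outdir``.

    Either ``sim_config`` (generate the inputs) or ``inputs`` (a dict with
    genotypes/annotation/gene_expr/exon_expr/covars) must be given. Returns
    the manifest. Reruns with an identical config reproduce identical
    outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if sim_config is not None:
            sim_config.seed = sim_config.seed or config.seed
            genotypes, annotation, gene_expr, exon_expr, truth, covars = (
                simulate_all(sim_config)
            )
        elif inputs is not None:
            genotypes = inputs["genotypes"]
            annotation = inputs["annotation"]
            gene_expr = inputs["gene_expr"]
            exon_expr = inputs.get("exon_expr")
            covars = inputs["covars"]
            truth = None
        else:
            raise ValueError("either sim_config or inputs is required")
        stage = "analyze"
        res = analyze(genotypes, annotation, gene_expr, exon_expr, covars,
                      config)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    io.write_table(res["associations"], outdir / "associations.tsv")
    io.write_table(res["leads"], outdir / "leads.tsv")
    io.write_table(res["cluster_table"], outdir / "clusters.tsv")
    io.write_table(res["cluster_singletons"], outdir / "clusters_singletons.tsv")
    blocks_df = pd.DataFrame(
        [
            {
                "transcript_cluster_id": b.transcript_cluster_id,
                "chrom": b.chrom, "start_bp": b.start_bp, "end_bp": b.end_bp,
                "n_members": len(b.member_snps), "label": b.label,
                "contains_tss": b.contains_tss,
            }
            for b in res["blocks"]
        ],
        columns=["transcript_cluster_id", "chrom", "start_bp", "end_bp",
                 "n_members", "label", "contains_tss"],
    )
    io.write_table(blocks_df, outdir / "blocks.tsv")
    if "artifact_flags" in res:
        io.write_table(art.flag_table(res["artifact_flags"]),
                       outdir / "artifact_flags.tsv")
    io.write_table(
        pd.DataFrame({"snp_id": res["pruned"].snp_ids}),
        outdir / "pruned_snps.tsv",
    )

    diag = res["diagnostics"]
    manifest = {
        "config": asdict(config),
        "sim_config": asdict(sim_config) if sim_config is not None else None,
        "counts": {
            "n_samples": len(gene_expr),
            "n_snps": genotypes.n_snps,
            "n_transcript_clusters": gene_expr.shape[1],
            "n_tests": diag.n_tests_cis + diag.n_tests_trans,
            "n_tests_cis": diag.n_tests_cis,
            "n_tests_trans": diag.n_tests_trans,
            "n_retained": int(diag.n_retained),
            "n_significant": int(len(res["significant"])),
            "n_blocks": len(res["blocks"]),
            "n_leads": int(len(res["leads"])),
            "n_clusters_multi": int(len(res["cluster_table"])),
            "n_clusters_singleton": int(len(res["cluster_singletons"])),
            "n_pruned": len(res["pruned"].snp_ids),
        },
        "lambda_gc": float(diag.lambda_gc),
    }
    (outdir / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=False)
    )
    res["manifest"] = manifest
    res["truth"] = truth
    return res
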