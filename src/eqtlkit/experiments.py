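"""Reproducibility experiments: the package's own calibration and
parameter-recovery studies, each run from scratch on freshly simulated
data with known ground truth.

Problem sizes are chosen for a single desktop CPU: null calibration uses
500 SNPs x 50 transcript clusters x 500 samples per seed; recovery studies
use 2000 samples, ~600 SNPs over four chromosomes and 40 transcript
clusters per seed, with planted cis effects of 0.5 expression units per
dosage against probeset noise of 0.5, trans hotspots of 0.4, and
single-probeset artifacts of 1.0.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import association as assoc
from . import preprocess as pre
from .blocks import ld_r2
from .config import PipelineConfig
from .pipeline import analyze, scan_covariates
from .simulate import SimConfig, simulate_all

DESK_FACTORS = 3  # matches the simulated confounder dimension


def _null_config(seed: int) -> SimConfig:
    return SimConfig(
        seed=seed, n_samples=500, n_genes=50, snps_per_chrom=125,
        n_chromosomes=4, cis_fraction=0.0, n_trans_hotspots=0,
        artifact_gene_fraction=0.0,
    )


def null_calibration(seed: int = 1, n_seeds: int = 20,
                     n_lambda_draws: int = 100_000) -> dict:
    """Type-I error and genomic-control factor on fully null simulations.

    Pools the retention count over ``n_seeds`` independent null scans
    (500 SNPs x 50 genes x 500 samples each) and computes lambda from
    ``n_lambda_draws`` pooled null P values.
    """
    all_p = []
    n_ret = n_tests = 0
    for s in range(n_seeds):
        cfg = _null_config(seed + s)
        gm, ann, ge, _, _, cov = simulate_all(cfg)
        adj = pre.latent_factors(pre.residualize(ge, cov), k=DESK_FACTORS)
        _, diag = assoc.scan(
            gm, adj, ann, covariates=scan_covariates(cov),
            lambda_snps=gm.n_snps, seed=seed + s,
        )
        all_p.append(diag.lambda_pvalues)
        n_ret += diag.n_retained
        n_tests += diag.n_tests_cis + diag.n_tests_trans
    draws = np.concatenate(all_p)  # >= n_lambda_draws by construction
    lam = assoc.genomic_lambda(np.clip(draws, 1e-300, 1.0))
    return {
        "n_tests": n_tests,
        "n_retained": n_ret,
        "retention_fraction": n_ret / n_tests,
        "lambda_gc": lam,
        "n_lambda_draws": len(draws),
    }


def _desk_config(seed: int, **overrides) -> SimConfig:
    return replace(SimConfig(seed=seed), **overrides)


def _desk_pipeline_config(seed: int) -> PipelineConfig:
    return PipelineConfig(seed=seed, n_factors=DESK_FACTORS)


def recovery_study(seed: int = 1, n_seeds: int = 20) -> dict:
    """Planted-effect recovery under the default study conditions.

    Per seed: simulate (cis beta 0.5, hotspot beta 0.4, artifacts), run the
    full analysis, and score (a) cis primary-lead recovery — the causal SNP
    or an r²>0.8 proxy leads the gene's cis block at FDR<0.05; (b) hotspot
    recovery — planted cluster count matched and target-set Jaccard >= 0.8;
    (c) artifact flag sensitivity and specificity.
    """
    cis_ok = cis_tot = 0
    jac_ok = jac_tot = count_ok = 0
    sens_n = sens_d = spec_n = spec_d = 0
    for s in range(n_seeds):
        cfg = _desk_config(seed + s)
        gm, ann, ge, ee, truth, cov = simulate_all(cfg)
        res = analyze(gm, ann, ge, ee, cov, _desk_pipeline_config(seed + s))
        idx = gm.snp_index()
        leads = res["leads"]
        prim = leads[(leads["is_primary"]) & (leads["label"] == "cis")]
        for snp, gene, _beta in truth.cis_effects:
            cis_tot += 1
            row = prim[prim["transcript_cluster_id"] == gene]
            if row.empty:
                continue
            ls = row.iloc[0]["snp_id"]
            if ls == snp or ld_r2(
                gm.dosages[:, idx[snp]], gm.dosages[:, idx[ls]]
            ) > 0.8:
                cis_ok += 1
        clus = res["clusters"]
        for _, _, targets in truth.hotspot_loci:
            jac_tot += 1
            best = max(
                (len(c.target_genes & targets) / len(c.target_genes | targets)
                 for c in clus),
                default=0.0,
            )
            jac_ok += best >= 0.8
        count_ok += len(clus) == len(truth.hotspot_loci)
        flagged = {
            f.transcript_cluster_id for f in res["artifact_flags"] if f.flagged
        }
        art_genes = {g for _, g, _ in truth.artifact_pairs}
        cis_genes = {g for _, g, _ in truth.cis_effects}
        sens_d += len(art_genes)
        sens_n += len(art_genes & flagged)
        spec_d += len(cis_genes)
        spec_n += len(cis_genes - flagged)
    return {
        "cis_lead_recovery": cis_ok / cis_tot,
        "hotspot_jaccard_recovery": jac_ok / jac_tot,
        "hotspot_count_match": count_ok / n_seeds,
        "artifact_sensitivity": sens_n / sens_d,
        "artifact_specificity": spec_n / spec_d,
        "n_seeds": n_seeds,
        "n_cis_planted": cis_tot,
        "n_hotspots_planted": jac_tot,
    }


def two_causal_study(seed: int = 1, n_seeds: int = 20,
                     max_pair_ld: float = 0.1) -> dict:
    """Recovery of two independent causal SNPs per gene as separate leads.

    Genes are planted with two cis effects; a gene counts as an eligible
    case when the two causal dosages have LD r² below ``max_pair_ld``. A
    case is recovered when the gene's cis lead set holds >= 2 leads (which
    by construction are pairwise r² < 0.36).
    """
    hits = tot = 0
    for s in range(n_seeds):
        cfg = _desk_config(
            seed + s, cis_per_gene=2, cis_fraction=0.4,
            n_trans_hotspots=0, artifact_gene_fraction=0.0,
        )
        gm, ann, ge, _, truth, cov = simulate_all(cfg)
        res = analyze(gm, ann, ge, None, cov, _desk_pipeline_config(seed + s))
        leads = res["leads"]
        idx = gm.snp_index()
        from collections import defaultdict

        planted = defaultdict(list)
        for snp, gene, _b in truth.cis_effects:
            planted[gene].append(snp)
        for gene, snps in planted.items():
            if len(snps) < 2:
                continue
            if ld_r2(gm.dosages[:, idx[snps[0]]],
                     gm.dosages[:, idx[snps[1]]]) >= max_pair_ld:
                continue
            tot += 1
            gl = leads[
                (leads["transcript_cluster_id"] == gene)
                & (leads["label"] == "cis")
            ]
            if len(gl) >= 2:
                hits += 1
    return {
        "two_lead_recovery": hits / tot if tot else float("nan"),
        "n_eligible_genes": tot,
        "n_seeds": n_seeds,
    }
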