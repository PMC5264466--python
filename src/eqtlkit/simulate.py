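"""Synthetic whole-blood eQTL data with known planted effects.

Generates LD-structured genotype dosages, an exon/transcript-cluster style
annotation, covariates, and gene- plus exon-level expression matrices in
which cis effects, trans hotspots, polymorphism-in-probe artifacts and
confounders are planted and recorded, so that every downstream stage of the
pipeline can be scored against ground truth.

Dosages are sums of two thresholded-Gaussian haplotypes: within an LD block
the latent normals are equicorrelated at ``ld_rho``, which gives r² between
nearby SNPs a population-genetic interpretation rather than being pasted on.
Gene-level expression is exactly the mean of the gene's exon-level
probesets, mirroring how transcript-cluster summaries average probesets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import Annotation, CovariateTable, GenotypeMatrix


@dataclass
class SimConfig:
    """Study-condition parameters for the generator.

    Counts are totals (genes are spread round-robin over chromosomes).
    ``cis_effect_sd`` is the magnitude of planted cis effects in expression
    units per effect-allele dosage (sign random); ``cis_tss_decay_bp`` is
    the exponential length scale for placing the causal SNP around the TSS.
    """

    n_samples: int = 2000
    n_chromosomes: int = 4
    snps_per_chrom: int = 150
    chrom_length_bp: int = 40_000_000
    ld_block_size: int = 5
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 40
    probesets_per_gene: tuple[int, int] = (4, 10)
    cis_fraction: float = 0.5
    cis_per_gene: int = 1
    cis_effect_sd: float = 0.5
    cis_tss_decay_bp: int = 30_000
    n_trans_hotspots: int = 2
    hotspot_targets: int = 8
    hotspot_effect: float = 0.4
    hotspot_mediated: bool = False
    artifact_gene_fraction: float = 0.10
    artifact_effect: float = 1.0
    noise_sd: float = 0.5
    n_latent_factors: int = 3
    latent_effect_sd: float = 0.3
    covariate_effect_sd: float = 0.10
    cell_measured_fraction: float = 1.0
    dosage_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        def bad(name: str, why: str) -> None:
            raise ValueError(f"SimConfig.{name}: {why}")

        for name in (
            "n_samples", "n_chromosomes", "snps_per_chrom", "chrom_length_bp",
            "ld_block_size", "n_genes",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0 or int(v) != v:
                bad(name, f"must be a positive integer, got {v!r}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            bad("maf_range", f"must lie within (0, 0.5], got {self.maf_range}")
        if not (0 <= self.ld_rho < 1):
            bad("ld_rho", f"must be in [0, 1), got {self.ld_rho}")
        if self.n_trans_hotspots > 0 and self.hotspot_targets < 6:
            bad("hotspot_targets", "must be >= 6 so hotspots satisfy the "
                "cluster eligibility rule")
        if not (0 <= self.artifact_gene_fraction <= 1):
            bad("artifact_gene_fraction", "must be a proportion in [0, 1]")
        if not (0 <= self.cis_fraction <= 1):
            bad("cis_fraction", "must be a proportion in [0, 1]")
        if self.noise_sd < 0 or not np.isfinite(self.noise_sd):
            bad("noise_sd", f"must be finite and nonnegative, got {self.noise_sd}")
        if self.n_latent_factors < 0:
            bad("n_latent_factors", "must be >= 0")
        lo_p, hi_p = self.probesets_per_gene
        if lo_p < 1 or hi_p < lo_p:
            bad("probesets_per_gene", f"invalid range {self.probesets_per_gene}")


@dataclass
class SimTruth:
    """Ground truth of everything planted by the generator."""

    cis_effects: list[tuple[str, str, float]] = field(default_factory=list)
    trans_effects: list[tuple[str, str, float]] = field(default_factory=list)
    hotspot_loci: list[tuple[str, int, frozenset]] = field(default_factory=list)
    artifact_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    confounder_loadings: np.ndarray | None = None


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-stage substreams from one integer seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Dosage matrix with block LD structure and per-SNP MAF / imputation R².

    Within each ``ld_block_size`` run of SNPs, two haplotypes per sample are
    formed by thresholding equicorrelated standard normals at the allele
    frequency quantile; the dosage is their sum, so all dosages are in
    {0,1,2} (optionally jittered into [0,2] when ``dosage_noise_sd`` > 0).
    """
    config.validate()
    rng_pos, rng_maf, rng_hap, rng_dn = _rngs(config.seed, 4)[:4]

    rows = []
    n = config.n_samples
    dos_cols: list[np.ndarray] = []
    for ci, chrom in enumerate(_chrom_names(config.n_chromosomes)):
        m = config.snps_per_chrom
        pos = np.sort(
            rng_pos.choice(config.chrom_length_bp, size=m, replace=False)
        )
        mafs = rng_maf.uniform(*config.maf_range, size=m)
        impq = rng_maf.uniform(0.3, 1.0, size=m)
        for j in range(m):
            rows.append(
                {
                    "snp_id": f"{chrom}:snp{j}",
                    "chrom": chrom,
                    "pos": int(pos[j]),
                    "maf": mafs[j],
                    "imp_r2": impq[j],
                    "effect_allele": "A",
                }
            )
        # block-wise correlated haplotypes
        rho = config.ld_rho
        for b0 in range(0, m, config.ld_block_size):
            b1 = min(b0 + config.ld_block_size, m)
            width = b1 - b0
            haps = []
            for _hap in range(2):
                shared = rng_hap.standard_normal((n, 1))
                indiv = rng_hap.standard_normal((n, width))
                z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * indiv
                thresh = stats.norm.ppf(mafs[b0:b1])
                haps.append((z < thresh).astype(float))
            dos_cols.append(haps[0] + haps[1])
    dosages = np.concatenate(dos_cols, axis=1)
    if config.dosage_noise_sd > 0:
        dosages = np.clip(
            dosages + rng_dn.normal(0, config.dosage_noise_sd, dosages.shape),
            0.0,
            2.0,
        )
    sample_ids = [f"s{i:05d}" for i in range(n)]
    return GenotypeMatrix(dosages, sample_ids, pd.DataFrame(rows))


def simulate_annotation(config: SimConfig) -> Annotation:
    """Non-overlapping genes with exon and 25 bp probe intervals.

    Each gene carries between ``probesets_per_gene`` probesets, one probe
    per probeset, every probe inside its exon and every exon inside the
    gene body. Strand alternates; on '-', the TSS is the larger coordinate.
    """
    config.validate()
    rng = _rngs(config.seed, 6)[4]
    chroms = _chrom_names(config.n_chromosomes)
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    genes, exons, probesets, probes = [], [], [], []
    gi = 0
    for chrom, ngc in zip(chroms, per_chrom):
        if ngc == 0:
            continue
        slot = config.chrom_length_bp // ngc
        if slot < 200_000:
            raise ValueError(
                f"chromosome {chrom} too short to place {ngc} genes"
            )
        for k in range(ngc):
            gene_id = f"g{gi:04d}"
            length = int(rng.integers(20_000, 100_000))
            start = k * slot + int(rng.integers(0, slot - length))
            end = start + length
            strand = "+" if gi % 2 == 0 else "-"
            tss, tes = (start, end) if strand == "+" else (end, start)
            genes.append(
                {
                    "gene_id": gene_id, "chrom": chrom, "start": start,
                    "end": end, "strand": strand, "tss": tss, "tes": tes,
                }
            )
            nps = int(rng.integers(config.probesets_per_gene[0],
                                   config.probesets_per_gene[1] + 1))
            # equal-width exons spread over the gene body
            exon_w = max(length // (2 * nps), 100)
            gap = (length - nps * exon_w) // max(nps, 1)
            for e in range(nps):
                es = start + e * (exon_w + gap)
                ee = es + exon_w
                exons.append(
                    {"gene_id": gene_id, "exon_rank": e, "chrom": chrom,
                     "start": es, "end": ee}
                )
                ps_id = f"{gene_id}_ps{e}"
                probesets.append(
                    {"probeset_id": ps_id, "gene_id": gene_id, "exon_rank": e}
                )
                p_start = es + int(rng.integers(0, max(exon_w - 25, 1)))
                probes.append(
                    {"probe_id": f"{ps_id}_pr0", "probeset_id": ps_id,
                     "gene_id": gene_id, "chrom": chrom,
                     "start": p_start, "end": p_start + 25}
                )
            gi += 1
    return Annotation(
        pd.DataFrame(genes), pd.DataFrame(exons),
        pd.DataFrame(probesets), pd.DataFrame(probes),
    )


def _pick_cis_snp(rng, snps: pd.DataFrame, chrom: str, tss: int,
                  decay: float, exclude: set[int]) -> int | None:
    """Index of a same-chromosome SNP, chosen with exp(-dist/decay) weight."""
    cand = snps.index[(snps["chrom"] == chrom)
                      & (~snps.index.isin(list(exclude)))]
    if len(cand) == 0:
        return None
    dist = np.abs(snps.loc[cand, "pos"].to_numpy() - tss)
    w = np.exp(-dist / decay)
    if w.sum() <= 0:
        w = np.ones_like(w)
    return int(rng.choice(cand, p=w / w.sum()))


def simulate_expression(
    genotypes: GenotypeMatrix,
    annotation: Annotation,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth, CovariateTable]:
    """Gene- and exon-level expression with planted effects and covariates.

    Exon value = gene baseline + genetic effects + covariate and
    cell-proportion effects + latent-factor contribution + probeset noise;
    gene value = mean over the gene's probesets. Trans hotspots either add
    beta*dosage directly to each target or, when ``hotspot_mediated``,
    shift a latent platelet-proportion variable that the targets load on.
    Artifact pairs add ``artifact_effect``*dosage to exactly one probeset.
    """
    config.validate()
    rngs = np.random.SeedSequence(config.seed).spawn(8)
    rng_cov = np.random.default_rng(rngs[5])
    rng_fx = np.random.default_rng(rngs[6])
    rng_noise = np.random.default_rng(rngs[7])

    n = genotypes.n_samples
    genes = annotation.genes
    truth = SimTruth()

    # ---- covariates -------------------------------------------------------
    sex = rng_cov.integers(0, 2, size=n).astype(float)
    age = rng_cov.uniform(30, 70, size=n)
    platelet_latent = rng_cov.standard_normal(n)  # mediator for hotspots
    cov = pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "wbc_count": np.maximum(rng_cov.normal(6.0, 1.4, n), 1.0),
            "lymphocyte_pct": np.clip(rng_cov.normal(28, 7, n), 2, 60),
            "monocyte_pct": np.clip(rng_cov.normal(9, 2, n), 1, 25),
            "eosinophil_pct": np.clip(rng_cov.normal(3, 1.6, n), 0, 15),
            "basophil_pct": np.clip(rng_cov.normal(0.8, 0.25, n), 0, 4),
        },
        index=genotypes.sample_ids,
    )
    cov["neutrophil_pct"] = np.clip(
        100 - cov[["lymphocyte_pct", "monocyte_pct", "eosinophil_pct",
                   "basophil_pct"]].sum(axis=1),
        10, 95,
    )

    # ---- genetic effects --------------------------------------------------
    snps = genotypes.snps
    used_snps: set[int] = set()
    gene_ids = list(genes["gene_id"])
    n_cis_genes = int(round(config.cis_fraction * len(gene_ids)))
    cis_genes = list(rng_fx.choice(gene_ids, size=n_cis_genes, replace=False))
    genetic = {g: np.zeros(n) for g in gene_ids}  # gene-wide component
    for g in cis_genes:
        row = genes.loc[genes["gene_id"] == g].iloc[0]
        for _ in range(config.cis_per_gene):
            si = _pick_cis_snp(rng_fx, snps, row["chrom"], row["tss"],
                               config.cis_tss_decay_bp, used_snps)
            if si is None:
                continue
            used_snps.add(si)
            beta = config.cis_effect_sd * (1 if rng_fx.random() < 0.5 else -1)
            genetic[g] = genetic[g] + beta * genotypes.dosages[:, si]
            truth.cis_effects.append((snps.loc[si, "snp_id"], g, beta))

    # ---- trans hotspots ---------------------------------------------------
    hot_gamma = 1.0
    hotspot_used_targets: set[str] = set()
    for _h in range(config.n_trans_hotspots):
        free = snps.index[~snps.index.isin(list(used_snps))]
        si = int(rng_fx.choice(free))
        used_snps.add(si)
        h_chrom = snps.loc[si, "chrom"]
        # target sets are disjoint across hotspots so each planted locus is
        # an identifiable cluster under the set-distance rule
        others = genes.loc[
            (genes["chrom"] != h_chrom)
            & (~genes["gene_id"].isin(hotspot_used_targets)),
            "gene_id",
        ].to_numpy()
        if len(others) < config.hotspot_targets:
            raise ValueError(
                "hotspot_targets exceeds the number of genes on other "
                "chromosomes"
            )
        targets = rng_fx.choice(others, size=config.hotspot_targets,
                                replace=False)
        hotspot_used_targets.update(map(str, targets))
        dosage = genotypes.dosages[:, si]
        if config.hotspot_mediated:
            platelet_latent = platelet_latent + hot_gamma * dosage
        for g in targets:
            beta = config.hotspot_effect * (1 if rng_fx.random() < 0.5 else -1)
            if config.hotspot_mediated:
                # target loads on the shifted mediator; effective dosage
                # slope is beta, plus mediator noise shared across targets
                genetic[g] = genetic[g] + (beta / hot_gamma) * platelet_latent
            else:
                genetic[g] = genetic[g] + beta * dosage
            truth.trans_effects.append((snps.loc[si, "snp_id"], str(g), beta))
        truth.hotspot_loci.append(
            (h_chrom, int(snps.loc[si, "pos"]), frozenset(map(str, targets)))
        )

    cov["platelet_count"] = np.maximum(
        250 + 40 * platelet_latent + rng_cov.normal(0, 5, n), 20.0
    )

    # ---- artifacts: SNP relocated under one probe of the gene -------------
    n_art = int(round(config.artifact_gene_fraction * len(gene_ids)))
    art_pool = [g for g in gene_ids if g not in cis_genes]
    art_genes = list(rng_fx.choice(art_pool, size=min(n_art, len(art_pool)),
                                   replace=False))
    artifact = {}  # gene -> (probeset_id, effect vector)
    new_cols, new_rows = [], []
    for ai, g in enumerate(art_genes):
        row = genes.loc[genes["gene_id"] == g].iloc[0]
        g_probes = annotation.probes.loc[annotation.probes["gene_id"] == g]
        probe = g_probes.iloc[int(rng_fx.integers(0, len(g_probes)))]
        # a fresh, unlinked variant placed inside the probe interval
        maf = rng_fx.uniform(*config.maf_range)
        dosage = (
            (rng_fx.random(n) < maf).astype(float)
            + (rng_fx.random(n) < maf)
        )
        snp_id = f"{row['chrom']}:artsnp{ai}"
        new_rows.append(
            {
                "snp_id": snp_id,
                "chrom": row["chrom"],
                "pos": int(probe["start"]) + int(rng_fx.integers(0, 25)),
                "maf": maf,
                "imp_r2": rng_fx.uniform(0.3, 1.0),
                "effect_allele": "A",
            }
        )
        new_cols.append(dosage)
        beta = config.artifact_effect * (1 if rng_fx.random() < 0.5 else -1)
        artifact[g] = (probe["probeset_id"], beta * dosage)
        truth.artifact_pairs.append((snp_id, g, probe["probeset_id"]))
    if new_rows:
        genotypes.dosages = np.column_stack([genotypes.dosages] + new_cols)
        genotypes.snps = pd.concat(
            [genotypes.snps, pd.DataFrame(new_rows)], ignore_index=True
        )
    genotypes.snps.sort_values(["chrom", "pos"], inplace=True,
                               kind="stable", ignore_index=False)
    order = genotypes.snps.index.to_numpy()
    genotypes.dosages = genotypes.dosages[:, order]
    genotypes.snps.reset_index(drop=True, inplace=True)

    # ---- latent confounders ----------------------------------------------
    K = config.n_latent_factors
    if K > 0:
        loadings = rng_fx.standard_normal((n, K))
        truth.confounder_loadings = loadings
    else:
        loadings = np.zeros((n, 0))
        truth.confounder_loadings = loadings

    # ---- assemble exon matrix --------------------------------------------
    ps = annotation.probesets
    base = {g: rng_fx.normal(7.0, 1.0) for g in gene_ids}
    cov_cols = ["sex", "age", "platelet_count", "wbc_count",
                "lymphocyte_pct", "monocyte_pct", "eosinophil_pct",
                "basophil_pct"]
    cov_std = (cov[cov_cols] - cov[cov_cols].mean()) / cov[cov_cols].std()
    exon_cols = {}
    for g in gene_ids:
        g_ps = ps.loc[ps["gene_id"] == g, "probeset_id"]
        cov_beta = rng_fx.normal(0, config.covariate_effect_sd, len(cov_cols))
        gene_load = rng_fx.normal(0, config.latent_effect_sd, K)
        shared = (
            base[g]
            + genetic[g]
            + cov_std.to_numpy() @ cov_beta
            + loadings @ gene_load
        )
        for ps_id in g_ps:
            v = shared + rng_noise.normal(0, config.noise_sd, n)
            if g in artifact and artifact[g][0] == ps_id:
                v = v + artifact[g][1]
            exon_cols[ps_id] = v
    exon = pd.DataFrame(exon_cols, index=genotypes.sample_ids)
    gene_expr = pd.DataFrame(
        {
            g: exon[ps.loc[ps["gene_id"] == g, "probeset_id"]].mean(axis=1)
            for g in gene_ids
        },
        index=genotypes.sample_ids,
    )

    # measured flags for cell counts
    for f in CovariateTable.CELL_FIELDS:
        flag = np.ones(n, dtype=bool)
        if config.cell_measured_fraction < 1.0:
            flag = rng_cov.random(n) < config.cell_measured_fraction
        cov[f + "_measured"] = flag
    covars = CovariateTable(cov)
    return gene_expr, exon, truth, covars


def simulate_all(config: SimConfig):
    """Convenience wrapper: genotypes, annotation, expression, truth."""
    genotypes = simulate_genotypes(config)
    annotation = simulate_annotation(config)
    gene_expr, exon_expr, truth, covars = simulate_expression(
        genotypes, annotation, config
    )
    return genotypes, annotation, gene_expr, exon_expr, truth, covars
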