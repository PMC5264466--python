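"""Readers and writers for the pipeline's on-disk formats.

TSV is the canonical tabular dialect (tab-separated, header row, UTF-8,
'.' decimal, no quoting). Genotypes travel as a dosage TSV (SNPs x
samples) with a metadata sidecar, or as VCF with a per-sample DS FORMAT
field. Annotation is a GFF3-style gene/exon TSV (1-based inclusive on
disk) plus a probe BED (0-based half-open, as BED requires). Expression
matrices are written features x samples.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Annotation, CovariateTable, GenotypeMatrix

log = logging.getLogger(__name__)

_TSV = dict(sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, **_TSV)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------- genotypes

def write_genotypes_tsv(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """<prefix>.dosage.tsv (SNPs x samples) + <prefix>.snps.tsv metadata."""
    prefix = Path(prefix)
    dos = pd.DataFrame(
        gm.dosages.T, index=gm.snps["snp_id"], columns=gm.sample_ids
    )
    dos.index.name = "snp_id"
    dos.to_csv(prefix.with_suffix(".dosage.tsv"), sep="\t")
    meta = gm.snps.copy()
    meta["pos"] = meta["pos"] + 1  # 1-based on disk
    meta.to_csv(prefix.with_suffix(".snps.tsv"), **_TSV)


def read_genotypes(
    path: str | Path,
    maf_min: float = 0.01,
    impqual_min: float = 0.3,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Load dosages (TSV prefix or VCF), filter by MAF and imputation R².

    Returns the filtered matrix and per-criterion exclusion counts; the
    counts plus the retained count always sum to the input SNP total.
    """
    path = Path(path)
    if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz"):
        gm = read_genotypes_vcf(path)
    else:
        prefix = Path(str(path).replace(".dosage.tsv", ""))
        dos = pd.read_csv(prefix.with_suffix(".dosage.tsv"), sep="\t",
                          index_col="snp_id")
        meta = pd.read_csv(prefix.with_suffix(".snps.tsv"), sep="\t")
        if not (set(meta["snp_id"]) == set(dos.index)):
            raise ValueError("metadata sidecar does not match dosage rows")
        meta = meta.set_index("snp_id").loc[dos.index].reset_index()
        meta["pos"] = meta["pos"] - 1  # back to 0-based
        gm = GenotypeMatrix(dos.to_numpy().T, list(dos.columns), meta)
    bad = (gm.dosages < -1e-6) | (gm.dosages > 2 + 1e-6)
    if bad.any():
        i = int(np.argwhere(bad.any(axis=0)).ravel()[0])
        raise ValueError(
            f"dosage outside [0,2] at {gm.snps.loc[i, 'snp_id']}"
        )
    counts: dict[str, int] = {"total": gm.n_snps}
    maf_bad = gm.snps["maf"].to_numpy() < maf_min
    counts["excluded_maf"] = int(maf_bad.sum())
    imp_bad = (gm.snps["imp_r2"].to_numpy() < impqual_min) & ~maf_bad
    counts["excluded_imputation_quality"] = int(imp_bad.sum())
    keep = ~(maf_bad | imp_bad)
    counts["retained"] = int(keep.sum())
    return gm.subset_snps(keep), counts


def filter_accounting(total: int, exclusions: dict[str, int]) -> int:
    """Retained count from a total and per-criterion exclusion counts.

    The per-criterion counts must be disjoint; retained = total - sum.
    """
    excl = sum(int(v) for v in exclusions.values())
    if excl > total:
        raise ValueError("exclusions exceed the total")
    return int(total) - excl


def write_genotypes_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with a per-sample DS (dosage) FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="MAF">\n')
        fh.write('##INFO=<ID=IMPQ,Number=1,Type=Float,'
                 'Description="Imputation quality R2">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j, row in gm.snps.iterrows():
            ds = "\t".join(f"{v:.3f}" for v in gm.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos'] + 1}\t{row['snp_id']}\tG\t"
                f"{row['effect_allele']}\t.\t.\t"
                f"MAF={row['maf']:.4f};IMPQ={row['imp_r2']:.4f}\tDS\t{ds}\n"
            )


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise ValueError(f"missing DS dosage field at {var.ID}")
        cols.append(np.asarray(ds, float).ravel())
        rows.append(
            {
                "snp_id": var.ID,
                "chrom": var.CHROM,
                "pos": var.POS - 1,
                "maf": float(var.INFO.get("MAF", np.nan)),
                "imp_r2": float(var.INFO.get("IMPQ", np.nan)),
                "effect_allele": var.ALT[0] if var.ALT else ".",
            }
        )
    return GenotypeMatrix(np.array(cols).T, samples, pd.DataFrame(rows))


# --------------------------------------------------------------- expression

def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    """Features x samples on disk (transposed from the in-memory layout)."""
    out = expr.T.rename_axis("feature_id")  # no mutation of the input
    out.to_csv(path, sep="\t")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id").T


# --------------------------------------------------------------- annotation

def write_annotation(ann: Annotation, prefix: str | Path) -> None:
    prefix = Path(prefix)
    genes = ann.genes.copy()
    for c in ("start", "tss", "tes"):
        genes[c] = genes[c] + 1  # 1-based inclusive on disk
    genes.to_csv(prefix.with_suffix(".genes.tsv"), **_TSV)
    exons = ann.exons.copy()
    exons["start"] = exons["start"] + 1
    exons.to_csv(prefix.with_suffix(".exons.tsv"), **_TSV)
    ann.probesets.to_csv(prefix.with_suffix(".probesets.tsv"), **_TSV)
    bed = ann.probes[["chrom", "start", "end"]].copy()
    bed["name"] = (
        ann.probes["probe_id"] + ";" + ann.probes["probeset_id"] + ";"
        + ann.probes["gene_id"]
    )
    bed.to_csv(prefix.with_suffix(".probes.bed"), sep="\t", index=False,
               header=False)


def read_annotation(prefix: str | Path) -> Annotation:
    prefix = Path(prefix)
    genes = pd.read_csv(prefix.with_suffix(".genes.tsv"), sep="\t")
    for c in ("start", "tss", "tes"):
        genes[c] = genes[c] - 1
    exons = pd.read_csv(prefix.with_suffix(".exons.tsv"), sep="\t")
    exons["start"] = exons["start"] - 1
    probesets = pd.read_csv(prefix.with_suffix(".probesets.tsv"), sep="\t")
    bed = pd.read_csv(
        prefix.with_suffix(".probes.bed"), sep="\t",
        names=["chrom", "start", "end", "name"],
    )
    parts = bed["name"].str.split(";", expand=True)
    probes = pd.DataFrame(
        {
            "probe_id": parts[0], "probeset_id": parts[1], "gene_id": parts[2],
            "chrom": bed["chrom"], "start": bed["start"], "end": bed["end"],
        }
    )
    return Annotation(genes, exons, probesets, probes)


# --------------------------------------------------------------- covariates

def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    out = cov.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_covariates(path: str | Path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path, sep="\t", index_col="sample_id"))


def read_kinship(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("kinship row/column sample IDs differ")
    return df.to_numpy(dtype=float)
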