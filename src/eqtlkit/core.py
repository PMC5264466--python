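"""Core in-memory containers shared across the pipeline.

Coordinates are 0-based, half-open internally; file readers/writers convert
to and from the 1-based inclusive convention of VCF/GFF.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "maf", "imp_r2", "effect_allele"]


@dataclass
class GenotypeMatrix:
    """Per-sample effect-allele dosages in [0, 2] plus per-SNP metadata.

    dosages: samples x SNPs array; snps: metadata frame with one row per
    SNP (snp_id, chrom, pos, maf, imp_r2, effect_allele), aligned to the
    dosage columns.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match dosage rows")
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError("snps metadata does not match dosage columns")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])

    def snp_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.snps["snp_id"])}

    def dosage_of(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_index()[snp_id]]

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.dosages[:, mask],
            list(self.sample_ids),
            self.snps.loc[mask].reset_index(drop=True),
        )

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[idx, :],
            [self.sample_ids[i] for i in idx],
            self.snps.copy(),
        )


@dataclass
class Annotation:
    """Gene / exon / probe structure tables.

    genes:     gene_id, chrom, start, end, strand, tss, tes
    exons:     gene_id, exon_rank, chrom, start, end
    probesets: probeset_id, gene_id, exon_rank
    probes:    probe_id, probeset_id, gene_id, chrom, start, end
    TSS/TES are strand aware: on '-', tss == end coordinate.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    probesets: pd.DataFrame
    probes: pd.DataFrame

    def tss_of(self) -> pd.Series:
        return self.genes.set_index("gene_id")["tss"]

    def gene_chrom(self) -> pd.Series:
        return self.genes.set_index("gene_id")["chrom"]


@dataclass
class CovariateTable:
    """Sample covariates: sex/age, blood cell counts, technical columns.

    data is indexed by sample_id. measured columns carry a boolean
    '<field>_measured' companion when cell counts are partially imputed.
    """

    data: pd.DataFrame

    CELL_FIELDS = [
        "platelet_count",
        "wbc_count",
        "lymphocyte_pct",
        "monocyte_pct",
        "eosinophil_pct",
        "basophil_pct",
        "neutrophil_pct",
    ]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample_ids in covariate table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class AdjustedExpression:
    """Residualized expression plus latent factors.

    residuals: samples x transcript clusters; factors: samples x K
    (unit variance); provenance lists adjustment steps applied in order.
    """

    residuals: pd.DataFrame
    factors: np.ndarray | None = None
    variance_explained: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)
    design: np.ndarray | None = None  # pre-phase design; df bookkeeping

    @property
    def n_factors(self) -> int:
        return 0 if self.factors is None else self.factors.shape[1]


def check_sample_alignment(*id_lists: list[str]) -> None:
    """Raise if the sample id sequences are not identical."""
    first = list(id_lists[0])
    for other in id_lists[1:]:
        if list(other) != first:
            missing = sorted(set(first) ^ set(other))
            raise ValueError(
                f"sample sets are not aligned; offenders: {missing[:10]}"
            )
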