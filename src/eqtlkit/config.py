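"""Pipeline configuration with the study's default thresholds."""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with their standard defaults.

    retention_p: per-pair P threshold for storing a record.
    fdr / fdr_strict: nominal and strict BH cutoffs.
    cis_window_bp / block_gap_bp: cis TSS window and block merge gap.
    lead_ld_r2 / lead_p_add: stepwise lead eligibility and admission.
    cluster_min_targets / cluster_d_max: hotspot eligibility and growth.
    pip_gene_frac / pip_exon_frac: polymorphism-in-probe R² fractions.
    prune_ld / proxy_ld_r2: LD pruning and proxy-match thresholds.
    maf_min / impqual_min: SNP inclusion filters.
    n_factors: latent confounding factors.
    """

    retention_p: float = 1e-4
    fdr: float = 0.05
    fdr_strict: float = 0.0005
    cis_window_bp: int = 1_000_000
    block_gap_bp: int = 1_000_000
    lead_ld_r2: float = 0.36
    lead_p_add: float = 1e-4
    cluster_min_targets: int = 6
    cluster_d_max: float = 0.7
    pip_gene_frac: float = 0.90
    pip_exon_frac: float = 0.95
    prune_ld: float = 0.3
    proxy_ld_r2: float = 0.8
    maf_min: float = 0.01
    impqual_min: float = 0.3
    n_factors: int = 20
    lambda_snps: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        defaults = cls()
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in raw.items():
            if v != getattr(defaults, k):
                log.info("config override: %s = %r (default %r)", k, v,
                         getattr(defaults, k))
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )
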