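import numpy as np
import pandas as pd
import pytest

from eqtlkit.config import PipelineConfig
from eqtlkit.pipeline import analyze
from eqtlkit.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """Light simulation (n=500) for structural and IO tests."""
    cfg = SimConfig(seed=7, n_samples=500, n_genes=24, snps_per_chrom=60,
                    n_chromosomes=3, n_trans_hotspots=1, hotspot_targets=6)
    return cfg, simulate_all(cfg)


@pytest.fixture(scope="session")
def study_run():
    """One full analysis under the default study conditions (n=2000)."""
    cfg = SimConfig(seed=11)
    gm, ann, ge, ee, truth, cov = simulate_all(cfg)
    res = analyze(gm, ann, ge, ee, cov, PipelineConfig(seed=11, n_factors=3))
    return dict(sim_config=cfg, genotypes=gm, annotation=ann, gene_expr=ge,
                exon_expr=ee, truth=truth, covars=cov, res=res)


@pytest.fixture()
def toy_annotation():
    """Two genes on one chromosome, one on another; plus exons/probes."""
    genes = pd.DataFrame(
        [
            {"gene_id": "gA", "chrom": "chr1", "start": 5_000_000,
             "end": 5_060_000, "strand": "+", "tss": 5_000_000,
             "tes": 5_060_000},
            {"gene_id": "gB", "chrom": "chr1", "start": 20_000_000,
             "end": 20_040_000, "strand": "-", "tss": 20_040_000,
             "tes": 20_000_000},
            {"gene_id": "gC", "chrom": "chr2", "start": 1_000_000,
             "end": 1_030_000, "strand": "+", "tss": 1_000_000,
             "tes": 1_030_000},
        ]
    )
    exons = pd.DataFrame(
        [
            {"gene_id": "gA", "exon_rank": 0, "chrom": "chr1",
             "start": 5_000_000, "end": 5_005_000},
            {"gene_id": "gA", "exon_rank": 1, "chrom": "chr1",
             "start": 5_050_000, "end": 5_060_000},
        ]
    )
    probesets = pd.DataFrame(
        [
            {"probeset_id": "gA_ps0", "gene_id": "gA", "exon_rank": 0},
            {"probeset_id": "gA_ps1", "gene_id": "gA", "exon_rank": 1},
        ]
    )
    probes = pd.DataFrame(
        [
            {"probe_id": "p0", "probeset_id": "gA_ps0", "gene_id": "gA",
             "chrom": "chr1", "start": 5_001_000, "end": 5_001_025},
        ]
    )
    from eqtlkit.core import Annotation

    return Annotation(genes, exons, probesets, probes)


def brute_force_block_merge(positions, gap_bp):
    """All-pairs interval merge oracle for the gap rule."""
    pos = sorted(positions)
    groups = [[pos[0]]] if pos else []
    for p in pos[1:]:
        placed = False
        for g in groups:
            if any(abs(p - q) <= gap_bp for q in g):
                g.append(p)
                placed = True
                break
        if not placed:
            groups.append([p])
    # transitive closure by repeated merging
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(
                    abs(a - b) <= gap_bp for a in groups[i] for b in groups[j]
                ):
                    groups[i] += groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(sorted(g)) for g in groups)
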