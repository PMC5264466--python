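import numpy as np
import pandas as pd
import pytest

import eqtlkit.blocks as blk
from conftest import brute_force_block_merge


def _records(rows):
    return pd.DataFrame(
        rows, columns=["transcript_cluster_id", "snp_id", "chrom", "pos", "p",
                       "beta", "t_stat", "r2"]
    )


def _ann(genes):
    from eqtlkit.core import Annotation

    empty = pd.DataFrame()
    return Annotation(pd.DataFrame(genes), empty, empty, empty)


MB = 1_000_000


def test_gap_rule_splits_blocks():
    rec = _records([
        ("g1", "a", "chr1", int(1.0 * MB), 1e-9, 1, 1, 0.1),
        ("g1", "b", "chr1", int(1.5 * MB), 1e-8, 1, 1, 0.1),
        ("g1", "c", "chr1", int(3.0 * MB), 1e-7, 1, 1, 0.1),
    ])
    ann = _ann([{"gene_id": "g1", "chrom": "chr1", "start": 0, "end": 10,
                 "strand": "+", "tss": 0, "tes": 10}])
    blocks = blk.build_blocks(rec, ann)
    members = sorted(tuple(b.member_snps) for b in blocks)
    assert members == [("a", "b"), ("c",)]


def test_singleton_block():
    rec = _records([("g1", "a", "chr1", 100, 1e-9, 1, 1, 0.1)])
    ann = _ann([{"gene_id": "g1", "chrom": "chr1", "start": 0, "end": 10,
                 "strand": "+", "tss": 0, "tes": 10}])
    blocks = blk.build_blocks(rec, ann)
    assert len(blocks) == 1 and blocks[0].member_snps == ["a"]
    assert blocks[0].start_bp == blocks[0].end_bp == 100


def test_unknown_chromosome_rejected():
    rec = _records([("g1", "a", "chrUn", 100, 1e-9, 1, 1, 0.1)])
    ann = _ann([{"gene_id": "g1", "chrom": "chr1", "start": 0, "end": 10,
                 "strand": "+", "tss": 0, "tes": 10}])
    blocks = blk.build_blocks(rec, ann)  # unknown chroms allowed for records
    assert blocks  # grouping still proceeds on the record's own chromosome


def test_block_partition_matches_brute_force_merge():
    rng = np.random.default_rng(0)
    ann = _ann([{"gene_id": "g1", "chrom": "chr1", "start": 0, "end": 10,
                 "strand": "+", "tss": 0, "tes": 10}])
    for trial in range(300):
        npos = int(rng.integers(1, 25))
        pos = rng.choice(50 * MB, size=npos, replace=False)
        rec = _records([
            ("g1", f"s{i}", "chr1", int(p), 1e-9, 1, 1, 0.1)
            for i, p in enumerate(pos)
        ])
        blocks = blk.build_blocks(rec, ann)
        got = sorted(
            tuple(sorted(int(rec.loc[rec.snp_id == s, "pos"].iloc[0])
                         for s in b.member_snps))
            for b in blocks
        )
        assert got == brute_force_block_merge(pos, MB)


def test_block_partition_invariant_to_record_order():
    rng = np.random.default_rng(1)
    pos = rng.choice(20 * MB, size=15, replace=False)
    ann = _ann([{"gene_id": "g1", "chrom": "chr1", "start": 0, "end": 10,
                 "strand": "+", "tss": 0, "tes": 10}])
    rec = _records([
        ("g1", f"s{i}", "chr1", int(p), 1e-9, 1, 1, 0.1)
        for i, p in enumerate(pos)
    ])
    b1 = blk.build_blocks(rec, ann)
    b2 = blk.build_blocks(rec.sample(frac=1, random_state=3), ann)
    key = lambda bs: sorted(tuple(sorted(b.member_snps)) for b in bs)
    assert key(b1) == key(b2)


# --- cis/trans classification: 12 hand-built cases ------------------------

GENE = {"gene_id": "gX", "chrom": "chr1", "start": 10 * MB,
        "end": int(10.1 * MB), "strand": "+", "tss": 10 * MB,
        "tes": int(10.1 * MB)}


CIS_TRANS_CASES = [
        ("snp 0.5 Mb upstream of TSS", "chr1", [int(9.5 * MB)], "cis"),
        ("snp exactly at TSS", "chr1", [10 * MB], "cis"),
        ("snp exactly 1 Mb away", "chr1", [11 * MB], "cis"),
        ("snp just beyond 1 Mb, isolated", "chr1", [int(11.000001 * MB)],
         "trans"),
        ("snp on another chromosome", "chr2", [10 * MB], "trans"),
        ("block spanning the TSS", "chr1", [int(9.8 * MB), int(10.2 * MB)],
         "cis"),
        ("long-range block, nearest member 0.8 Mb, farthest 2.5 Mb",
         "chr1", [int(10.8 * MB), int(11.6 * MB), int(12.5 * MB)], "cis"),
        ("long-range block >1 Mb wide wholly inside window edge",
         "chr1", [int(10.9 * MB), int(11.8 * MB), int(12.7 * MB),
                  int(13.6 * MB)], "cis"),
        ("distant block on same chromosome, all members > 1 Mb",
         "chr1", [13 * MB, int(13.5 * MB)], "trans"),
        ("downstream block within window", "chr1", [int(10.6 * MB)], "cis"),
        ("far upstream isolated", "chr1", [5 * MB], "trans"),
        ("two distant members forming their own block", "chr1",
         [20 * MB, int(20.9 * MB)], "trans"),
]


@pytest.mark.parametrize("desc,chrom,positions,expected", CIS_TRANS_CASES)
def test_cis_trans_classification_cases(desc, chrom, positions, expected):
    ann = _ann([GENE])
    rec = _records([
        ("gX", f"s{i}", chrom, p, 1e-9, 1, 1, 0.1)
        for i, p in enumerate(positions)
    ])
    blocks = blk.build_blocks(rec, ann)
    assert len(blocks) == 1, desc
    assert blk.classify_cis_trans(blocks[0], ann) == expected, desc


def test_minus_strand_tss_used_for_cis_window():
    gene = dict(GENE, strand="-", tss=int(10.1 * MB), tes=10 * MB)
    ann = _ann([gene])
    rec = _records([("gX", "s0", "chr1", int(11.05 * MB), 1e-9, 1, 1, 0.1)])
    b = blk.build_blocks(rec, ann)[0]
    assert blk.classify_cis_trans(b, ann) == "cis"  # 0.95 Mb from '-' TSS


def test_primary_lead_argmin_and_tiebreak():
    ann = _ann([GENE])
    rec = _records([
        ("gX", "sA", "chr1", 10 * MB + 500, 1e-8, 1, 1, 0.1),
        ("gX", "sB", "chr1", 10 * MB + 100, 1e-9, 1, 1, 0.1),
        ("gX", "sC", "chr1", 10 * MB + 300, 1e-9, 1, 1, 0.1),
    ])
    b = blk.build_blocks(rec, ann)[0]
    # tie at 1e-9 between sB (pos 100) and sC (pos 300): smaller pos wins
    assert blk.primary_lead(b, rec) == "sB"
    for seed in range(5):
        shuffled = rec.sample(frac=1, random_state=seed)
        assert blk.primary_lead(b, shuffled) == "sB"


def test_ld_r2_basic():
    rng = np.random.default_rng(2)
    a = rng.integers(0, 3, 100).astype(float)
    assert blk.ld_r2(a, a) == pytest.approx(1.0)
    b = a - a.mean()
    c = rng.standard_normal(100)
    c -= (c @ b) / (b @ b) * b  # exactly orthogonal
    assert blk.ld_r2(a, c + 5) == pytest.approx(0.0, abs=1e-20)
    with pytest.raises(ValueError):
        blk.ld_r2(a, np.ones(100))


def test_ld_r2_matches_haplotype_frequency_oracle():
    """Dosage r² in a simulated block tracks the haplotype-based
    correlation implied by the shared latent Gaussian."""
    from eqtlkit.simulate import SimConfig, simulate_genotypes
    from scipy import stats as st

    cfg = SimConfig(seed=13, n_samples=4000, snps_per_chrom=50,
                    n_chromosomes=1, ld_block_size=5, ld_rho=0.8,
                    maf_range=(0.3, 0.3))
    gm = simulate_genotypes(cfg)
    obs = [
        blk.ld_r2(gm.dosages[:, j], gm.dosages[:, j + 1])
        for j in range(0, 49)
        if (j % 5) != 4
    ]
    # oracle: P(both alleles) from the bivariate normal orthant probability
    thr = st.norm.ppf(0.3)
    p11 = st.multivariate_normal(cov=[[1, 0.8], [0.8, 1]]).cdf([thr, thr])
    r_hap = (p11 - 0.09) / 0.21  # cov / var of Bernoulli(0.3)
    assert abs(np.mean(obs) - r_hap**2) < 0.05


def _stepwise_fixture(rng, betas, ld_shared=0.0, n=1500):
    """One gene, five block SNPs; returns everything stepwise needs."""
    from eqtlkit.core import AdjustedExpression, Annotation, GenotypeMatrix

    base = rng.integers(0, 3, (n, 5)).astype(float)
    if ld_shared > 0:
        for j in range(1, 5):
            mask = rng.random(n) < ld_shared
            base[mask, j] = base[mask, 0]
    samples = [f"s{i}" for i in range(n)]
    snps = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(5)], "chrom": "chr1",
        "pos": np.arange(5) * 10_000 + 10 * MB, "maf": 0.3,
        "imp_r2": 1.0, "effect_allele": "A",
    })
    gm = GenotypeMatrix(base, samples, snps)
    y = base @ np.asarray(betas) + 0.5 * rng.standard_normal(n)
    Y = pd.DataFrame({"gX": y}, index=samples)
    ann = _ann([GENE])
    rec = _records([
        ("gX", f"s{j}", "chr1", 10 * MB + j * 10_000, 1e-9, 1, 1, 0.1)
        for j in range(5)
    ])
    block = blk.build_blocks(rec, ann)[0]
    # true per-SNP p-values for lead ordering
    import eqtlkit.association as assoc

    rows = []
    for j in range(5):
        r = assoc.fit_pair(y, base[:, j])
        rows.append(("gX", f"s{j}", "chr1", 10 * MB + j * 10_000, r.p,
                     r.beta, r.t_stat, r.r2))
    return gm, AdjustedExpression(Y), block, _records(rows)


def test_stepwise_recovers_two_independent_causal_snps():
    rng = np.random.default_rng(3)
    gm, adj, block, rec = _stepwise_fixture(rng, [0.5, 0, 0.5, 0, 0])
    ls = blk.stepwise_leads(block, gm, adj, None, rec)
    assert set(ls.leads) >= {"s0", "s2"}
    # every admitted pair in low LD
    k = len(ls.leads)
    for i in range(k):
        for j in range(i + 1, k):
            assert ls.pairwise_ld_r2[i, j] < 0.36


def test_stepwise_high_ld_proxies_yield_single_lead():
    rng = np.random.default_rng(4)
    gm, adj, block, rec = _stepwise_fixture(
        rng, [0.5, 0, 0, 0, 0], ld_shared=0.95
    )
    ls = blk.stepwise_leads(block, gm, adj, None, rec)
    assert len(ls.leads) == 1


def test_stepwise_empty_records_no_error():
    rng = np.random.default_rng(5)
    gm, adj, block, rec = _stepwise_fixture(rng, [0.5, 0, 0, 0, 0])
    empty = rec.iloc[0:0]
    ls = blk.stepwise_leads(block, gm, adj, None, empty)
    assert ls.leads == []


def test_leads_per_egene_grow_with_sample_size():
    """With two modest causal SNPs per gene, the number of independent
    leads per detected eGene rises on nested subsamples: secondary signals
    only clear the conditional admission threshold at larger n."""
    import eqtlkit.pipeline as pl
    from eqtlkit.config import PipelineConfig
    from eqtlkit.core import CovariateTable
    from eqtlkit.simulate import SimConfig, simulate_all

    cfg = SimConfig(seed=11, cis_per_gene=2, cis_effect_sd=0.25,
                    n_trans_hotspots=0, artifact_gene_fraction=0.0)
    gm, ann, ge, _, _, cov = simulate_all(cfg)
    ratios = {}
    for nn in (500, 2000):
        idx = np.arange(nn)
        leads = pl.analyze(
            gm.subset_samples(idx), ann, ge.iloc[idx], None,
            CovariateTable(cov.data.iloc[idx]),
            PipelineConfig(seed=11, n_factors=3),
        )["leads"]
        s = leads[leads.label == "cis"]
        ratios[nn] = len(s) / max(1, s.transcript_cluster_id.nunique())
    assert ratios[2000] >= ratios[500]
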