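import numpy as np
import pandas as pd
import pytest
from scipy import stats

import eqtlkit.enrichment as enr
from eqtlkit.blocks import ld_r2
from eqtlkit.core import GenotypeMatrix


def _gm(dosages, chrom=None, pos=None):
    n, m = dosages.shape
    snps = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["chr1"] * m,
        "pos": pos if pos is not None else np.arange(m) * 1000,
        "maf": 0.3, "imp_r2": 1.0, "effect_allele": "A",
    })
    return GenotypeMatrix(dosages, [f"i{k}" for k in range(n)], snps)


def _min_p(gm, values):
    return pd.DataFrame({"snp_id": gm.snps["snp_id"], "min_p": values})


def test_prune_independent_snps_all_retained():
    rng = np.random.default_rng(0)
    gm = _gm(rng.integers(0, 3, (400, 10)).astype(float))
    out = enr.ld_prune(_min_p(gm, np.linspace(1e-8, 1e-2, 10)), gm,
                       threshold=0.3)
    assert sorted(out.snp_ids) == sorted(gm.snp_ids)


def test_prune_drops_perfect_proxy_with_larger_p():
    rng = np.random.default_rng(1)
    d = rng.integers(0, 3, (300, 1)).astype(float)
    gm = _gm(np.hstack([d, d]))
    out = enr.ld_prune(_min_p(gm, [1e-8, 1e-4]), gm, threshold=0.3)
    assert out.snp_ids == ["s0"]


def _greedy_oracle(ids, min_p, dos, threshold):
    order = sorted(range(len(ids)), key=lambda i: (min_p[i], ids[i]))
    kept, dropped = [], set()
    for i in order:
        if i in dropped:
            continue
        kept.append(ids[i])
        for j in order:
            if j == i or j in dropped:
                continue
            if ld_r2(dos[:, i], dos[:, j]) > threshold:
                dropped.add(j)
    return kept


def test_prune_matches_greedy_oracle_on_fuzzed_sets():
    rng = np.random.default_rng(2)
    for _ in range(30):
        m = int(rng.integers(5, 25))
        base = rng.integers(0, 3, (200, m)).astype(float)
        # plant some LD by copying columns with noise flips
        for j in range(1, m, 3):
            mask = rng.random(200) < 0.8
            base[mask, j] = base[mask, j - 1]
        gm = _gm(base)
        min_p = rng.uniform(1e-9, 1.0, m)
        out = enr.ld_prune(_min_p(gm, min_p), gm, threshold=0.3)
        assert out.snp_ids == _greedy_oracle(gm.snp_ids, min_p, base, 0.3)


def test_pruned_set_passes_exhaustive_pairwise_check(study_run):
    gm = study_run["genotypes"]
    pruned = study_run["res"]["pruned"]
    idx = gm.snp_index()
    meta = gm.snps.set_index("snp_id")
    kept = pruned.snp_ids
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            a, b = kept[i], kept[j]
            if meta.loc[a, "chrom"] != meta.loc[b, "chrom"]:
                continue
            if abs(meta.loc[a, "pos"] - meta.loc[b, "pos"]) > 1_000_000:
                continue
            assert ld_r2(gm.dosages[:, idx[a]], gm.dosages[:, idx[b]]) <= 0.3


def test_catalog_overlap_trivial_extremes():
    rng = np.random.default_rng(3)
    gm = _gm(rng.integers(0, 3, (300, 20)).astype(float))
    pruned = enr.ld_prune(_min_p(gm, np.full(20, np.nan)), gm, 0.3)
    leads = {"s1", "s2", "s3"}
    catalog = pd.DataFrame({"snp_id": ["s1", "s2", "s3"]})
    res = enr.catalog_overlap(leads, catalog, gm, pruned)
    assert res.observed == 3
    empty_hits = enr.catalog_overlap({"s19"}, pd.DataFrame(
        {"snp_id": ["s5", "s6"]}), gm, pruned)
    assert empty_hits.observed == 0
    with pytest.raises(ValueError):
        enr.catalog_overlap(leads, pd.DataFrame({"snp_id": []}), gm, pruned)


def test_catalog_overlap_counts_proxies():
    rng = np.random.default_rng(4)
    d = rng.integers(0, 3, (500, 1)).astype(float)
    dos = np.hstack([d, d, rng.integers(0, 3, (500, 1)).astype(float)])
    gm = _gm(dos, pos=[0, 100, 200])
    pruned = enr.PrunedSnpSet(["s0", "s2"], 0.3)
    # catalog SNP s1 is a perfect proxy of eQTL s0
    res = enr.catalog_overlap({"s0"}, pd.DataFrame({"snp_id": ["s1"]}),
                              gm, pruned, proxy_r2=0.8)
    assert res.observed == 1


def test_geneset_fisher_matches_hypergeometric_oracle():
    universe = 266
    targets = set(range(100))
    gene_set = set(range(90, 100)) | set(ap for ap in range(200, 356))
    # |targets|=100, |set|=166, overlap=10
    res = enr.geneset_fisher(targets, gene_set, universe + 200)
    M, nn, N, k = 466, 166, 100, 10
    oracle = stats.hypergeom.sf(k - 1, M, nn, N)
    assert res.p_value == pytest.approx(oracle, abs=1e-10)


def test_geneset_fisher_min_overlap_rule_and_extreme():
    out = enr.geneset_fisher({"a", "b"}, {"a", "b", "c"}, 100)
    assert out is None  # overlap below 6
    targets = set(range(10))
    res = enr.geneset_fisher(targets, targets, 40, min_overlap=6)
    assert res.p_value < 1e-6
    with pytest.raises(ValueError):
        enr.geneset_fisher(set(range(10)), set(range(5)), 8)


def test_geneset_fisher_null_calibration():
    rng = np.random.default_rng(5)
    universe = 200
    ps = []
    for _ in range(300)[:300]:
        t = set(rng.choice(universe, 60, replace=False).tolist())
        g = set(rng.choice(universe, 60, replace=False).tolist())
        r = enr.geneset_fisher(t, g, universe, min_overlap=0)
        ps.append(r.p_value)
    # one-sided null P values should not pile up near zero
    assert np.mean(np.array(ps) < 0.05) < 0.12


def _results(rows):
    return pd.DataFrame(
        rows, columns=["transcript_cluster_id", "snp_id", "label", "q",
                       "beta"]
    )


def test_internal_replication_identical_tables():
    t = _results([
        ("g1", "s1", "cis", 0.001, 0.5),
        ("g2", "s2", "trans", 0.01, -0.3),
    ])
    out = enr.internal_replication(t, t.copy())
    assert out["cis"]["rate"] == 1.0
    assert out["trans"]["rate"] == 1.0
    assert out["cis"]["sign_concordance"] == 1.0


def test_internal_replication_disjoint_spaces_and_empty_strata():
    t = _results([("g1", "s1", "cis", 0.001, 0.5)])
    other = _results([("g9", "s9", "cis", 0.001, 0.5)])
    with pytest.raises(ValueError, match="disjoint"):
        enr.internal_replication(t, other)
    out = enr.internal_replication(t, t)
    assert np.isnan(out["trans"]["rate"])  # no trans discoveries


def test_split_half_replication_cis_exceeds_trans(study_run):
    """Split-half internal replication: strong cis signals replicate more
    often than weaker trans signals."""
    import eqtlkit.pipeline as pl
    from eqtlkit.config import PipelineConfig
    from eqtlkit.core import CovariateTable

    gm = study_run["genotypes"]
    ge = study_run["gene_expr"]
    cov = study_run["covars"]
    ann = study_run["annotation"]
    n = len(ge)
    halves = []
    for idx in (np.arange(n // 2), np.arange(n // 2, n)):
        r = pl.analyze(gm.subset_samples(idx), ann, ge.iloc[idx], None,
                       CovariateTable(cov.data.iloc[idx]),
                       PipelineConfig(seed=11, n_factors=3))
        halves.append(r["associations"])
    rep = enr.internal_replication(halves[0], halves[1])
    assert rep["cis"]["rate"] > 0.5
    assert rep["cis"]["sign_concordance"] > 0.95


def test_external_validation_verbatim_and_masks():
    rng = np.random.default_rng(6)
    gm = _gm(rng.integers(0, 3, (200, 5)).astype(float))
    leads = pd.DataFrame({
        "transcript_cluster_id": ["g1", "g2"],
        "snp_id": ["s0", "s1"],
        "beta": [0.5, -0.2],
    })
    external = leads.copy()
    out = enr.external_validation(
        leads, external, gm,
        eligible_snps={"s0", "s1"}, eligible_transcripts={"g1", "g2"},
    )
    assert out["rate"] == 1.0
    assert out["sign_concordance"] == 1.0
    with pytest.raises(ValueError):
        enr.external_validation(leads, external, gm, None, None)


def test_external_validation_respects_eligibility():
    rng = np.random.default_rng(7)
    gm = _gm(rng.integers(0, 3, (200, 5)).astype(float))
    leads = pd.DataFrame({
        "transcript_cluster_id": ["g1", "g2"],
        "snp_id": ["s0", "s1"],
        "beta": [0.5, -0.2],
    })
    out = enr.external_validation(
        leads, leads.copy(), gm,
        eligible_snps={"s0"}, eligible_transcripts={"g1"},
    )
    assert out["n_eligible"] == 1 and out["rate"] == 1.0


# --- positional enrichment ------------------------------------------------

def test_region_classification_conventions(toy_annotation):
    genes = toy_annotation.genes.set_index("gene_id")
    gA = genes.loc["gA"]
    gA = gA.copy()
    gA["gene_id"] = "gA"
    ex = toy_annotation.exons
    # at the TSS: transcribed side, 5'UTR proxy region of first exon
    assert enr.classify_region(5_000_000, gA, ex) == "5utr"
    assert enr.classify_region(5_002_000, gA, ex) == "first_exon"
    assert enr.classify_region(5_030_000, gA, ex) == "first_intron"
    assert enr.classify_region(5_059_900, gA, ex) == "3utr"
    assert enr.classify_region(4_900_000, gA, ex) == "upstream_intergenic"
    assert enr.classify_region(5_200_000, gA, ex) == "downstream_intergenic"
    assert enr.classify_region(5_000_000 + 2_000_000, gA, ex) == "outside"


def test_positional_enrichment_planted_first_exon_leads(toy_annotation):
    leads = pd.DataFrame({
        "transcript_cluster_id": ["gA"] * 4,
        "snp_id": [f"s{i}" for i in range(4)],
        "pos": [5_002_000, 5_002_500, 5_003_000, 5_004_000],
    })
    rng = np.random.default_rng(8)
    bg = pd.DataFrame({
        "snp_id": [f"b{i}" for i in range(300)],
        "chrom": "chr1",
        "pos": rng.integers(4_200_000, 5_800_000, 300),
    })
    out = enr.positional_enrichment(leads, toy_annotation, bg)
    out = out.set_index("region")
    finite = out["fold"].replace([np.inf], np.nan).dropna()
    assert out.loc["first_exon", "fold"] == finite.max()
    assert (out.attrs["lead_tss_distances"] >= 0).all()


def test_positional_enrichment_null_folds_near_one(toy_annotation):
    rng = np.random.default_rng(9)
    pos = rng.integers(4_000_001, 6_000_000, 400)
    leads = pd.DataFrame({
        "transcript_cluster_id": ["gA"] * 400,
        "snp_id": [f"s{i}" for i in range(400)],
        "pos": pos,
    })
    bg = pd.DataFrame({
        "snp_id": [f"b{i}" for i in range(4000)],
        "chrom": "chr1",
        "pos": rng.integers(4_000_001, 6_000_000, 4000),
    })
    out = enr.positional_enrichment(leads, toy_annotation, bg)
    big = out[out["n_background"] >= 200]
    assert ((big["fold"] > 0.5) & (big["fold"] < 1.5)).all()
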