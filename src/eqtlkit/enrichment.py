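"""LD-pruned enrichment statistics and replication / validation scoring.

Enrichment (GWAS-catalog overlap, positional enrichment relative to gene
structure, gene-set enrichment of hotspot targets) is computed against an
LD-pruned set of near-independent SNPs so that 2x2 contingency counts come
from approximately independent observations. Replication requires
significance in both halves of a split; validation matches our lead eQTLs
to an external study directly or through an LD proxy (r² > 0.8).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import ld_r2
from .core import Annotation, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class PrunedSnpSet:
    snp_ids: list[str]
    prune_threshold: float
    provenance: str = "min-P order, greedy r2 prune"


@dataclass
class EnrichmentResult:
    observed: float
    expected: float
    fold: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]] | None = None
    extra: dict = field(default_factory=dict)


def ld_prune(
    snps: pd.DataFrame,
    genotypes: GenotypeMatrix,
    threshold: float = 0.3,
    window_bp: int = 1_000_000,
) -> PrunedSnpSet:
    """Greedy sweep: order SNPs by min-P (insignificant ones last), keep the
    head of the list, prune everything later with LD r² > threshold to it,
    then advance to the next survivor.

    ``snps`` needs snp_id and a min_p column (NaN for SNPs never significant
    for any gene). LD is only evaluated within ``window_bp`` on the same
    chromosome; farther pairs are treated as unlinked.
    """
    idx = genotypes.snp_index()
    meta = genotypes.snps.set_index("snp_id")
    df = snps.copy()
    df["_order_p"] = df["min_p"].fillna(np.inf)
    df = df.sort_values(["_order_p", "snp_id"], kind="mergesort")
    ids = list(df["snp_id"])
    alive = dict.fromkeys(ids, True)
    kept: list[str] = []
    for s in ids:
        if not alive[s]:
            continue
        kept.append(s)
        ci, pi = meta.loc[s, "chrom"], meta.loc[s, "pos"]
        ds = genotypes.dosages[:, idx[s]]
        for t in ids:
            if t == s or not alive[t]:
                continue
            if meta.loc[t, "chrom"] != ci or abs(meta.loc[t, "pos"] - pi) > window_bp:
                continue
            if np.ptp(genotypes.dosages[:, idx[t]]) == 0:
                continue
            if np.ptp(ds) == 0:
                continue
            if ld_r2(ds, genotypes.dosages[:, idx[t]]) > threshold:
                alive[t] = False
        alive[s] = False
    return PrunedSnpSet(kept, threshold)


def _fisher(table: np.ndarray, alternative: str = "two-sided") -> float:
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def catalog_overlap(
    eqtl_snps: set[str],
    catalog: pd.DataFrame,
    genotypes: GenotypeMatrix,
    pruned: PrunedSnpSet,
    proxy_r2: float = 0.8,
    window_bp: int = 1_000_000,
) -> EnrichmentResult:
    """Count catalog SNPs that are eQTLs directly or via an LD proxy, and
    test enrichment against the pruned independent frame.

    Catalog SNPs absent from the genotype panel are counted and logged but
    cannot be proxy-matched.
    """
    if catalog is None or catalog.empty:
        raise ValueError("empty GWAS catalog")
    idx = genotypes.snp_index()
    meta = genotypes.snps.set_index("snp_id")
    cat_ids = list(dict.fromkeys(catalog["snp_id"]))
    unmapped = [s for s in cat_ids if s not in idx]
    if unmapped:
        log.info("%d catalog SNPs not in genotype panel", len(unmapped))
    mapped = [s for s in cat_ids if s in idx]

    def is_hit(s: str) -> bool:
        if s in eqtl_snps:
            return True
        ci, pi = meta.loc[s, "chrom"], meta.loc[s, "pos"]
        ds = genotypes.dosages[:, idx[s]]
        if np.ptp(ds) == 0:
            return False
        for e in eqtl_snps:
            if e not in idx:
                continue
            if meta.loc[e, "chrom"] != ci or abs(meta.loc[e, "pos"] - pi) > window_bp:
                continue
            de = genotypes.dosages[:, idx[e]]
            if np.ptp(de) == 0:
                continue
            if ld_r2(ds, de) > proxy_r2:
                return True
        return False

    observed = sum(is_hit(s) for s in mapped)
    # sampling frame: the pruned independent set
    frame = set(pruned.snp_ids)
    frame_hits = sum(1 for s in frame if is_hit(s))
    n_frame = len(frame)
    rate = frame_hits / n_frame if n_frame else 0.0
    expected = rate * len(mapped)
    a = observed
    b = len(mapped) - observed
    c = frame_hits
    d = n_frame - frame_hits
    tab = np.array([[a, b], [c, d]])
    p = _fisher(tab, "greater")
    fold = observed / expected if expected > 0 else float("inf")
    return EnrichmentResult(
        observed=observed, expected=expected, fold=fold, p_value=p,
        table=((a, b), (c, d)),
        extra={"n_unmapped": len(unmapped), "frame_rate": rate},
    )


REGION_CLASSES = [
    "upstream_intergenic", "5utr", "first_exon", "other_exon", "3utr",
    "first_intron", "other_intron", "downstream_intergenic", "outside",
]


def classify_region(
    pos: int, gene_row: pd.Series, exons: pd.DataFrame,
    window_bp: int = 1_000_000,
    utr_bp: int = 300,
) -> str:
    """Assign one position to a disjoint region class of one gene.

    The gene body is split into exons/introns in transcription order; the
    first ``utr_bp`` of the first exon and last ``utr_bp`` of the last exon
    act as 5'/3' UTR proxies and take precedence over the exon classes.
    Positions beyond the 2 Mb TSS-centered window fall in 'outside'.
    """
    tss, tes = int(gene_row["tss"]), int(gene_row["tes"])
    strand = gene_row["strand"]
    if abs(pos - tss) > window_bp:
        return "outside"
    start, end = int(gene_row["start"]), int(gene_row["end"])
    if not (start <= pos < end):
        before_tss = pos < tss if strand == "+" else pos > tss
        return "upstream_intergenic" if before_tss else "downstream_intergenic"
    ex = exons[exons["gene_id"] == gene_row["gene_id"]].sort_values("start")
    ex = ex.reset_index(drop=True)
    if strand == "-":
        ex = ex.iloc[::-1].reset_index(drop=True)  # transcription order
    n_ex = len(ex)
    for rank in range(n_ex):
        es, ee = int(ex.loc[rank, "start"]), int(ex.loc[rank, "end"])
        if es <= pos < ee:
            if rank == 0:
                five_prime_edge = (
                    pos < es + utr_bp if strand == "+" else pos >= ee - utr_bp
                )
                if five_prime_edge:
                    return "5utr"
                return "first_exon"
            if rank == n_ex - 1:
                three_prime_edge = (
                    pos >= ee - utr_bp if strand == "+" else pos < es + utr_bp
                )
                if three_prime_edge:
                    return "3utr"
            return "other_exon"
    # intronic: which intron (in transcription order)?
    bounds = sorted(
        (int(ex.loc[r, "start"]), int(ex.loc[r, "end"])) for r in range(n_ex)
    )
    for i in range(len(bounds) - 1):
        if bounds[i][1] <= pos < bounds[i + 1][0]:
            genomic_rank = i
            tx_rank = genomic_rank if strand == "+" else (len(bounds) - 2 - i)
            return "first_intron" if tx_rank == 0 else "other_intron"
    return "other_intron"


def positional_enrichment(
    leads: pd.DataFrame,
    annotation: Annotation,
    background_snps: pd.DataFrame,
    flagged_clusters: set[str] | None = None,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Fold enrichment of lead-eQTL region classes versus a pruned background.

    ``leads`` needs transcript_cluster_id, snp_id, pos (cis leads);
    ``background_snps`` needs snp_id, chrom, pos and is classified against
    every gene's window. Artifact-flagged transcript clusters are excluded.
    Returns a per-class table with counts, fractions, fold, Fisher P, plus
    lead-TSS / lead-TES distances in an attrs entry.
    """
    flagged_clusters = flagged_clusters or set()
    genes = annotation.genes
    by_id = {r["gene_id"]: r for _, r in genes.iterrows()}
    lead_cls, d_tss, d_tes = [], [], []
    for _, row in leads.iterrows():
        tc = row["transcript_cluster_id"]
        if tc in flagged_clusters or tc not in by_id:
            continue
        g = by_id[tc]
        lead_cls.append(
            classify_region(int(row["pos"]), g, annotation.exons, window_bp)
        )
        d_tss.append(abs(int(row["pos"]) - int(g["tss"])))
        d_tes.append(abs(int(row["pos"]) - int(g["tes"])))
    bg_cls = []
    bg = background_snps
    for _, g in genes.iterrows():
        sub = bg[(bg["chrom"] == g["chrom"])
                 & (np.abs(bg["pos"] - g["tss"]) <= window_bp)]
        for p in sub["pos"]:
            bg_cls.append(classify_region(int(p), g, annotation.exons,
                                          window_bp))
    lead_counts = pd.Series(lead_cls).value_counts()
    bg_counts = pd.Series(bg_cls).value_counts()
    n_lead, n_bg = max(len(lead_cls), 1), max(len(bg_cls), 1)
    rows = []
    for cls in REGION_CLASSES:
        lo = int(lead_counts.get(cls, 0))
        bo = int(bg_counts.get(cls, 0))
        f_lead, f_bg = lo / n_lead, bo / n_bg
        fold = f_lead / f_bg if f_bg > 0 else float("inf") if f_lead else np.nan
        tab = np.array([[lo, n_lead - lo], [bo, n_bg - bo]])
        rows.append(
            {
                "region": cls, "n_leads": lo, "n_background": bo,
                "frac_leads": f_lead, "frac_background": f_bg,
                "fold": fold, "p_value": _fisher(tab),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["lead_tss_distances"] = np.array(d_tss)
    out.attrs["lead_tes_distances"] = np.array(d_tes)
    return out


def geneset_fisher(
    target_genes: set[str], gene_set: set[str], universe: int,
    min_overlap: int = 6,
) -> EnrichmentResult | None:
    """One-sided (greater) Fisher exact test for target/gene-set overlap.

    Applied only when the intersection has at least ``min_overlap`` genes;
    returns None otherwise.
    """
    inter = len(set(target_genes) & set(gene_set))
    if universe < len(set(target_genes) | set(gene_set)):
        raise ValueError("universe smaller than the union of the sets")
    if inter < min_overlap:
        return None
    a = inter
    b = len(target_genes) - inter
    c = len(gene_set) - inter
    d = universe - a - b - c
    p = _fisher(np.array([[a, b], [c, d]]), "greater")
    expected = len(target_genes) * len(gene_set) / universe
    return EnrichmentResult(
        observed=a, expected=expected,
        fold=a / expected if expected > 0 else float("inf"),
        p_value=p, table=((a, b), (c, d)),
    )


def internal_replication(
    results_a: pd.DataFrame, results_b: pd.DataFrame, fdr: float = 0.05
) -> dict:
    """Replication between a discovery and a replication scan.

    A pair replicates when it is FDR-significant in both tables; rates are
    reported per cis/trans label along with sign concordance of beta among
    replicated pairs. Empty discovery strata report NaN rates.
    """
    key = ["transcript_cluster_id", "snp_id"]
    if not (set(results_a["snp_id"]) & set(results_b["snp_id"])) and len(
        results_a
    ) and len(results_b):
        raise ValueError("disjoint SNP identifier spaces")
    out: dict = {}
    for label in ("cis", "trans"):
        da = results_a[(results_a["label"] == label) & (results_a["q"] < fdr)]
        db = results_b[(results_b["label"] == label) & (results_b["q"] < fdr)]
        merged = da.merge(db, on=key, suffixes=("_a", "_b"))
        n_disc = len(da)
        rate = len(merged) / n_disc if n_disc else float("nan")
        if len(merged):
            conc = float(
                (np.sign(merged["beta_a"]) == np.sign(merged["beta_b"])).mean()
            )
        else:
            conc = float("nan")
        out[label] = {
            "n_discovery": n_disc,
            "n_replicated": len(merged),
            "rate": rate,
            "sign_concordance": conc,
        }
    return out


def external_validation(
    our_leads: pd.DataFrame,
    external_pairs: pd.DataFrame,
    genotypes: GenotypeMatrix,
    eligible_snps: set[str],
    eligible_transcripts: set[str],
    proxy_r2: float = 0.8,
    window_bp: int = 1_000_000,
    external_detect_rate: float | None = None,
) -> dict:
    """Validation of our lead pairs against an external study.

    A lead pair validates when the external study reports the same
    transcript with the same SNP or one in LD r² > ``proxy_r2``. Only pairs
    whose SNP and transcript the external study could have seen (the
    eligibility masks) enter the denominator. The expected count is the
    external study's eligible detection rate times our eligible pair count.
    Direction-of-effect concordance is computed when the external table
    carries a beta column, else skipped with a logged note.
    """
    if eligible_snps is None or eligible_transcripts is None:
        raise ValueError("eligibility masks are required")
    idx = genotypes.snp_index()
    meta = genotypes.snps.set_index("snp_id")
    ext_by_tc: dict[str, pd.DataFrame] = {
        tc: grp for tc, grp in external_pairs.groupby("transcript_cluster_id")
    }
    eligible = our_leads[
        our_leads["snp_id"].isin(eligible_snps)
        & our_leads["transcript_cluster_id"].isin(eligible_transcripts)
    ]
    n_eligible = len(eligible)
    validated = 0
    signs: list[bool] = []
    has_beta = "beta" in external_pairs.columns
    if not has_beta:
        log.info("external table has no beta column; direction check skipped")
    for _, row in eligible.iterrows():
        ext = ext_by_tc.get(row["transcript_cluster_id"])
        if ext is None:
            continue
        hit = None
        if (ext["snp_id"] == row["snp_id"]).any():
            hit = ext[ext["snp_id"] == row["snp_id"]].iloc[0]
        else:
            s = row["snp_id"]
            if s in idx and np.ptp(genotypes.dosages[:, idx[s]]) > 0:
                ci, pi = meta.loc[s, "chrom"], meta.loc[s, "pos"]
                for _, erow in ext.iterrows():
                    e = erow["snp_id"]
                    if e not in idx:
                        continue
                    if meta.loc[e, "chrom"] != ci or abs(
                        meta.loc[e, "pos"] - pi
                    ) > window_bp:
                        continue
                    if np.ptp(genotypes.dosages[:, idx[e]]) == 0:
                        continue
                    if ld_r2(
                        genotypes.dosages[:, idx[s]],
                        genotypes.dosages[:, idx[e]],
                    ) > proxy_r2:
                        hit = erow
                        break
        if hit is not None:
            validated += 1
            if has_beta and np.isfinite(hit.get("beta", np.nan)):
                signs.append(np.sign(hit["beta"]) == np.sign(row["beta"]))
    rate = validated / n_eligible if n_eligible else float("nan")
    if external_detect_rate is None:
        # fall back: external detections over external eligible pair space
        n_space = max(len(eligible_snps) * len(eligible_transcripts), 1)
        external_detect_rate = len(external_pairs) / n_space
    expected = external_detect_rate * n_eligible
    a, b = validated, n_eligible - validated
    exp_hits = min(int(round(expected)), n_eligible)
    tab = np.array([[a, b], [exp_hits, n_eligible - exp_hits]])
    p = _fisher(tab, "greater") if n_eligible else float("nan")
    return {
        "n_eligible": n_eligible,
        "n_validated": validated,
        "rate": rate,
        "expected": expected,
        "expected_rate": external_detect_rate,
        "p_value": p,
        "sign_concordance": float(np.mean(signs)) if signs else float("nan"),
    }
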