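"""Contiguous eQTL blocks, cis/trans classification, and stepwise selection
of independent lead eQTLs.

A block is a maximal run of significant SNPs for one transcript on one
chromosome with no internal gap above 1 Mb. A block is cis when it lies on
the transcript's chromosome and either contains the TSS or has a member
within 1 Mb of it; everything else is trans. Within a block the primary
lead is the smallest-P member; secondary leads are admitted by forward
stepwise regression among members in low LD (r² < 0.36) with every current
lead, with all lead effects re-estimated jointly at each step and admission
requiring conditional P < 1e-4.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AdjustedExpression, Annotation, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class EqtlBlock:
    transcript_cluster_id: str
    chrom: str
    start_bp: int
    end_bp: int
    member_snps: list[str]
    contains_tss: bool = False
    label: str = "unassigned"


@dataclass
class LeadSet:
    block: EqtlBlock
    leads: list[str] = field(default_factory=list)
    conditional_p: list[float] = field(default_factory=list)
    pairwise_ld_r2: np.ndarray | None = None


def build_blocks(
    sig_records: pd.DataFrame,
    annotation: Annotation,
    gap_bp: int = 1_000_000,
) -> list[EqtlBlock]:
    """Single-linkage merge of significant SNP positions per transcript and
    chromosome: sort positions and cut wherever the gap exceeds ``gap_bp``."""
    known = set(annotation.genes["chrom"]).union(sig_records["chrom"])
    bad = set(sig_records["chrom"]) - known
    if bad:
        raise ValueError(f"records on unknown chromosomes: {sorted(bad)}")
    blocks: list[EqtlBlock] = []
    cols = ["snp_id", "pos"]
    for (tc, chrom), grp in sig_records.groupby(
        ["transcript_cluster_id", "chrom"], sort=True
    ):
        grp = grp[cols].drop_duplicates("snp_id").sort_values(
            ["pos", "snp_id"], kind="mergesort"
        )
        pos = grp["pos"].to_numpy()
        ids = grp["snp_id"].to_numpy()
        cuts = np.where(np.diff(pos) > gap_bp)[0] + 1
        for seg_ids, seg_pos in zip(
            np.split(ids, cuts), np.split(pos, cuts)
        ):
            blocks.append(
                EqtlBlock(
                    transcript_cluster_id=str(tc),
                    chrom=str(chrom),
                    start_bp=int(seg_pos[0]),
                    end_bp=int(seg_pos[-1]),
                    member_snps=list(seg_ids),
                )
            )
    return blocks


def classify_cis_trans(
    block: EqtlBlock, annotation: Annotation, cis_window_bp: int = 1_000_000
) -> str:
    """cis iff the block is on the gene's chromosome and either spans the
    TSS or has a member within the cis window of it; else trans."""
    g = annotation.genes.loc[
        annotation.genes["gene_id"] == block.transcript_cluster_id
    ]
    if g.empty:
        raise ValueError(f"unknown transcript {block.transcript_cluster_id}")
    row = g.iloc[0]
    if block.chrom != row["chrom"]:
        block.label = "trans"
        return "trans"
    tss = int(row["tss"])
    spans = block.start_bp <= tss <= block.end_bp
    near = (
        min(abs(block.start_bp - tss), abs(block.end_bp - tss)) <= cis_window_bp
        or spans
    )
    block.contains_tss = bool(spans)
    block.label = "cis" if near else "trans"
    return block.label


def label_records(
    table: pd.DataFrame, blocks: list[EqtlBlock], annotation: Annotation,
    cis_window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Assign each retained record the label of its (transcript, SNP) block."""
    lab: dict[tuple[str, str], str] = {}
    for b in blocks:
        if b.label == "unassigned":
            classify_cis_trans(b, annotation, cis_window_bp)
        for s in b.member_snps:
            lab[(b.transcript_cluster_id, s)] = b.label
    out = table.copy()
    out["label"] = [
        lab.get((tc, s), "unassigned")
        for tc, s in zip(out["transcript_cluster_id"], out["snp_id"])
    ]
    return out


def primary_lead(block: EqtlBlock, records: pd.DataFrame) -> str:
    """Block member with the smallest P; ties broken by smaller genomic
    position then lexicographic snp_id."""
    if not block.member_snps:
        raise ValueError("empty block")
    sub = records[
        (records["transcript_cluster_id"] == block.transcript_cluster_id)
        & records["snp_id"].isin(block.member_snps)
    ]
    sub = sub.sort_values(["p", "pos", "snp_id"], kind="mergesort")
    return str(sub.iloc[0]["snp_id"])


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors."""
    a = np.asarray(dosage_a, float)
    b = np.asarray(dosage_b, float)
    if len(a) != len(b):
        raise ValueError("length mismatch")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _joint_fit_pvals(
    y: np.ndarray, X_cov: np.ndarray, dosages: np.ndarray
) -> np.ndarray:
    """Two-sided t-test P for each dosage coefficient in the joint model."""
    X = np.column_stack([X_cov, dosages])
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise np.linalg.LinAlgError("saturated design")
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        raise np.linalg.LinAlgError("rank-deficient design")
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (X.T @ y)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / df
    k = dosages.shape[1]
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv)[-k:], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef[-k:] / se, np.inf)
    return 2.0 * stats.t.sf(np.abs(t), df)


def stepwise_leads(
    block: EqtlBlock,
    genotypes: GenotypeMatrix,
    adjusted: AdjustedExpression,
    covariates: np.ndarray | None,
    records: pd.DataFrame,
    ld_max_r2: float = 0.36,
    p_add: float = 1e-4,
) -> LeadSet:
    """Forward stepwise conditional selection of independent leads.

    Candidates are block members in LD r² < ``ld_max_r2`` with *every*
    current lead. Each step fits the joint model (covariates + all current
    leads + candidate) for each candidate, admits the candidate with the
    smallest conditional P if below ``p_add``, and stops otherwise.
    """
    sub = records[
        (records["transcript_cluster_id"] == block.transcript_cluster_id)
        & records["snp_id"].isin(block.member_snps)
    ]
    if sub.empty:
        return LeadSet(block)
    y = adjusted.residuals[block.transcript_cluster_id].to_numpy()
    n = len(y)
    cov_cols = [np.ones(n)]
    if covariates is not None and covariates.size:
        cov_cols.append(np.asarray(covariates, float))
    if adjusted.factors is not None and adjusted.n_factors:
        cov_cols.append(adjusted.factors)
    X_cov = np.column_stack(cov_cols)

    idx = genotypes.snp_index()
    members = sorted(
        set(sub["snp_id"]),
        key=lambda s: (int(genotypes.snps.loc[idx[s], "pos"]), s),
    )
    dos = {s: genotypes.dosages[:, idx[s]] for s in members}

    lead0 = primary_lead(block, records)
    leads = [lead0]
    cond_p = [float(sub.loc[sub["snp_id"] == lead0, "p"].iloc[0])]
    while True:
        cands = [
            s for s in members
            if s not in leads
            and all(ld_r2(dos[s], dos[l]) < ld_max_r2 for l in leads)
        ]
        if not cands:
            break
        best, best_p = None, np.inf
        lead_mat = np.column_stack([dos[l] for l in leads])
        for s in cands:
            try:
                pv = _joint_fit_pvals(
                    y, X_cov, np.column_stack([lead_mat, dos[s]])
                )[-1]
            except np.linalg.LinAlgError:
                log.warning("candidate %s skipped: rank-deficient design", s)
                continue
            if pv < best_p:
                best, best_p = s, pv
        if best is None or best_p >= p_add:
            break
        leads.append(best)
        cond_p.append(float(best_p))

    k = len(leads)
    ld_mat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ld_mat[i, j] = ld_mat[j, i] = ld_r2(dos[leads[i]], dos[leads[j]])
    return LeadSet(block, leads=leads, conditional_p=cond_p,
                   pairwise_ld_r2=ld_mat)


def lead_table(lead_sets: list[LeadSet], records: pd.DataFrame) -> pd.DataFrame:
    """Flatten LeadSets into a per-lead table mirroring the scan columns."""
    rows = []
    rec_idx = records.set_index(["transcript_cluster_id", "snp_id"])
    for ls in lead_sets:
        for rank, (snp, cp) in enumerate(zip(ls.leads, ls.conditional_p)):
            key = (ls.block.transcript_cluster_id, snp)
            r = rec_idx.loc[key]
            if isinstance(r, pd.DataFrame):
                r = r.iloc[0]
            rows.append(
                {
                    "transcript_cluster_id": ls.block.transcript_cluster_id,
                    "snp_id": snp,
                    "chrom": ls.block.chrom,
                    "pos": int(r["pos"]),
                    "lead_rank": rank,
                    "is_primary": rank == 0,
                    "beta": float(r["beta"]),
                    "t_stat": float(r["t_stat"]),
                    "r2": float(r["r2"]),
                    "p": float(r["p"]),
                    "conditional_p": cp,
                    "label": ls.block.label,
                    "block_start": ls.block.start_bp,
                    "block_end": ls.block.end_bp,
                }
            )
    cols = ["transcript_cluster_id", "snp_id", "chrom", "pos", "lead_rank",
            "is_primary", "beta", "t_stat", "r2", "p", "conditional_p",
            "label", "block_start", "block_end"]
    return pd.DataFrame(rows, columns=cols)
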