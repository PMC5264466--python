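"""Trans-eQTL hotspot clustering by seeded, set-distance growth.

Eligible SNPs are trans-eQTLs with at least six extrachromosomal target
transcripts. On each chromosome the unclustered eligible SNP with the
smallest min-P seeds a cluster; neighbouring eligible SNPs are scanned
outward by position and join while the set distance

    d(A, B) = 1 - |A ∩ B| / min(|A|, |B|)

between the union A of current member target sets and the candidate's
target set B stays below 0.7. Expansion on a side stops at the first
failing candidate; the procedure restarts with the next unclustered SNP
until every eligible SNP is assigned.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class TransCluster:
    chrom: str
    member_snps: list[str]
    target_genes: set[str]
    start_bp: int
    end_bp: int

    @property
    def width_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def n_members(self) -> int:
        return len(self.member_snps)


@dataclass
class ClusterSummary:
    chrom: str
    start_bp: int
    end_bp: int
    width_bp: int
    n_members: int
    n_gwas: int
    n_targets: int
    max_targets_single_snp: int
    member_snps: list[str] = field(default_factory=list)


def eligible_snps(
    assoc: pd.DataFrame, min_targets: int = 6
) -> pd.DataFrame:
    """Per-SNP extrachromosomal target sets for significant trans records.

    Input must already be restricted to FDR-significant trans records with
    columns snp_id, chrom, pos, transcript_cluster_id, p and a
    target_chrom column (chromosome of the target gene). Returns one row
    per retained SNP: snp_id, chrom, pos, min_p, targets (frozenset).
    """
    ex = assoc[assoc["target_chrom"] != assoc["chrom"]]
    rows = []
    for snp, grp in ex.groupby("snp_id", sort=True):
        targets = frozenset(grp["transcript_cluster_id"])
        if len(targets) < min_targets:
            continue
        rows.append(
            {
                "snp_id": snp,
                "chrom": grp["chrom"].iloc[0],
                "pos": int(grp["pos"].iloc[0]),
                "min_p": float(grp["p"].min()),
                "targets": targets,
            }
        )
    return pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "min_p", "targets"]
    )


def set_distance(A: set, B: set) -> float:
    """d = 1 - |A∩B| / min(|A|, |B|), in [0, 1]."""
    if not A or not B:
        raise ValueError("set_distance requires nonempty sets")
    return 1.0 - len(set(A) & set(B)) / min(len(A), len(B))


def grow_clusters(
    eligible: pd.DataFrame, d_max: float = 0.7
) -> list[TransCluster]:
    """Seeded outward growth of clusters per chromosome (see module doc)."""
    clusters: list[TransCluster] = []
    for chrom, grp in eligible.groupby("chrom", sort=True):
        grp = grp.sort_values(["pos", "snp_id"], kind="mergesort").reset_index(
            drop=True
        )
        unassigned = set(range(len(grp)))
        while unassigned:
            # seed: smallest min-P among unclustered, ties by position
            seed = min(
                unassigned,
                key=lambda i: (grp.loc[i, "min_p"], grp.loc[i, "pos"]),
            )
            members = [seed]
            targets = set(grp.loc[seed, "targets"])
            # outward sweep; a side stops at its first failing candidate
            for step in (1, -1):
                j = seed + step
                while 0 <= j < len(grp):
                    if j not in unassigned or j in members:
                        break
                    cand = set(grp.loc[j, "targets"])
                    if set_distance(targets, cand) < d_max:
                        members.append(j)
                        targets |= cand
                        j += step
                    else:
                        break
            positions = sorted(int(grp.loc[i, "pos"]) for i in members)
            clusters.append(
                TransCluster(
                    chrom=str(chrom),
                    member_snps=[
                        grp.loc[i, "snp_id"]
                        for i in sorted(members, key=lambda i: grp.loc[i, "pos"])
                    ],
                    target_genes=targets,
                    start_bp=positions[0],
                    end_bp=positions[-1],
                )
            )
            unassigned -= set(members)
    return clusters


def summarize(
    cluster: TransCluster,
    eligible: pd.DataFrame,
    gwas_catalog: pd.DataFrame | None = None,
) -> ClusterSummary:
    """Table-5 style summary: address, width, N, Ng, Tr, Tr-max."""
    by_snp = eligible.set_index("snp_id")["targets"]
    tr_max = max(len(by_snp[s]) for s in cluster.member_snps)
    n_gwas = 0
    if gwas_catalog is not None and len(gwas_catalog):
        n_gwas = int(
            pd.Series(cluster.member_snps).isin(gwas_catalog["snp_id"]).sum()
        )
    return ClusterSummary(
        chrom=cluster.chrom,
        start_bp=cluster.start_bp,
        end_bp=cluster.end_bp,
        width_bp=cluster.width_bp,
        n_members=cluster.n_members,
        n_gwas=n_gwas,
        n_targets=len(cluster.target_genes),
        max_targets_single_snp=tr_max,
        member_snps=list(cluster.member_snps),
    )


def cluster_tables(
    clusters: list[TransCluster],
    eligible: pd.DataFrame,
    gwas_catalog: pd.DataFrame | None = None,
    min_report_members: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Headline multi-SNP cluster table plus a singleton accounting table."""
    rows, single = [], []
    for ci, c in enumerate(clusters):
        s = summarize(c, eligible, gwas_catalog)
        row = {
            "cluster_id": ci,
            "address": f"{s.chrom}:{s.start_bp}-{s.end_bp}",
            "chrom": s.chrom,
            "start_bp": s.start_bp,
            "end_bp": s.end_bp,
            "width_bp": s.width_bp,
            "n_members": s.n_members,
            "n_gwas": s.n_gwas,
            "n_targets": s.n_targets,
            "max_targets_single_snp": s.max_targets_single_snp,
            "member_snps": ",".join(s.member_snps),
            "target_genes": ",".join(sorted(c.target_genes)),
        }
        (rows if s.n_members >= min_report_members else single).append(row)
    cols = list(rows[0]) if rows else (list(single[0]) if single else [])
    return pd.DataFrame(rows, columns=cols), pd.DataFrame(single, columns=cols)
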