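"""Polymorphism-in-probe artifact detection.

A variant sitting under a 25 bp hybridization probe can change binding
affinity and masquerade as an expression effect. Such a SNP is flagged
when (1) its gene-level association R² exceeds 90% of the maximal R²
achieved by the transcript cluster's lead eQTL, and (2) its exon-level R²
for the overlapped probeset exceeds 95% of the maximal R² achieved by any
cis-SNP for any probeset of that cluster. A triggered flag marks every
eQTL record of the transcript cluster, since most are in LD with the lead.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ProbeOverlap:
    snp_id: str
    probe_id: str
    probeset_id: str
    transcript_cluster_id: str
    offset_in_probe: int


@dataclass
class ArtifactFlag:
    transcript_cluster_id: str
    trigger_snp_id: str | None
    gene_level_r2_frac: float
    exon_level_r2_frac: float
    flagged: bool
    decidable: bool = True


def probe_snp_overlap(
    probes: pd.DataFrame, snps: pd.DataFrame
) -> list[ProbeOverlap]:
    """All (SNP, probe) incidences by half-open interval search.

    ``probes`` needs probe_id, probeset_id, gene_id, chrom, start, end
    (0-based half-open); ``snps`` needs snp_id, chrom, pos. A SNP at the
    probe start overlaps; one at the end coordinate does not.
    """
    if (probes["end"] <= probes["start"]).any():
        bad = probes.loc[probes["end"] <= probes["start"], "probe_id"]
        raise ValueError(f"malformed probe intervals: {list(bad)[:5]}")
    out: list[ProbeOverlap] = []
    for chrom, pgrp in probes.groupby("chrom", sort=True):
        sgrp = snps[snps["chrom"] == chrom]
        if sgrp.empty:
            continue
        pos = np.sort(sgrp["pos"].to_numpy())
        order = np.argsort(sgrp["pos"].to_numpy(), kind="mergesort")
        ids = sgrp["snp_id"].to_numpy()[order]
        lo = np.searchsorted(pos, pgrp["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, pgrp["end"].to_numpy() - 1, side="right")
        for (_, prow), a, b in zip(pgrp.iterrows(), lo, hi):
            for k in range(a, b):
                out.append(
                    ProbeOverlap(
                        snp_id=str(ids[k]),
                        probe_id=str(prow["probe_id"]),
                        probeset_id=str(prow["probeset_id"]),
                        transcript_cluster_id=str(prow["gene_id"]),
                        offset_in_probe=int(pos[k] - prow["start"]),
                    )
                )
    out.sort(key=lambda o: (o.snp_id, o.probe_id))
    return out


def flag_artifacts(
    overlaps: list[ProbeOverlap],
    gene_assoc: pd.DataFrame,
    exon_assoc: pd.DataFrame,
    probesets: pd.DataFrame,
    gene_frac: float = 0.90,
    exon_frac: float = 0.95,
) -> list[ArtifactFlag]:
    """Apply the two-threshold gene/exon R² rule per overlapping SNP.

    ``gene_assoc`` is the gene-level cis association table (columns snp_id,
    transcript_cluster_id, r2); ``exon_assoc`` the exon-level table keyed
    by probeset (transcript_cluster_id column holds the probeset_id).
    Records absent from the retained tables contribute R² = 0, which is
    conservative for the maxima. A cluster with overlaps but no exon-level
    records at all is reported undecidable rather than silently unflagged.
    """
    ps_to_gene = probesets.set_index("probeset_id")["gene_id"]
    g_r2 = gene_assoc.set_index(["transcript_cluster_id", "snp_id"])["r2"]
    g_max = gene_assoc.groupby("transcript_cluster_id")["r2"].max()
    e_tab = exon_assoc.copy()
    e_tab["gene_id"] = e_tab["transcript_cluster_id"].map(ps_to_gene)
    e_r2 = e_tab.set_index(["transcript_cluster_id", "snp_id"])["r2"]
    e_max = e_tab.groupby("gene_id")["r2"].max()

    flags: dict[str, ArtifactFlag] = {}
    for ov in overlaps:
        tc = ov.transcript_cluster_id
        if tc not in g_max.index:
            continue  # no retained gene-level eQTL: nothing to inflate
        if tc not in e_max.index:
            flags.setdefault(
                tc,
                ArtifactFlag(tc, None, float("nan"), float("nan"),
                             flagged=False, decidable=False),
            )
            continue
        gr = float(g_r2.get((tc, ov.snp_id), 0.0)) / float(g_max[tc])
        er = float(e_r2.get((ov.probeset_id, ov.snp_id), 0.0)) / float(e_max[tc])
        hit = gr > gene_frac and er > exon_frac
        prev = flags.get(tc)
        if prev is None or (hit and not prev.flagged) or (
            prev.decidable and not prev.flagged and gr > prev.gene_level_r2_frac
        ):
            flags[tc] = ArtifactFlag(tc, ov.snp_id, gr, er, flagged=hit)
    return sorted(flags.values(), key=lambda f: f.transcript_cluster_id)


def flag_table(flags: list[ArtifactFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_cluster_id": f.transcript_cluster_id,
                "trigger_snp_id": f.trigger_snp_id,
                "gene_level_r2_frac": f.gene_level_r2_frac,
                "exon_level_r2_frac": f.exon_level_r2_frac,
                "flagged": f.flagged,
                "decidable": f.decidable,
            }
            for f in flags
        ],
        columns=["transcript_cluster_id", "trigger_snp_id",
                 "gene_level_r2_frac", "exon_level_r2_frac", "flagged",
                 "decidable"],
    )


def apply_flags(table: pd.DataFrame, flags: list[ArtifactFlag]) -> pd.DataFrame:
    """Propagate a boolean artifact column onto any per-record table."""
    flagged = {f.transcript_cluster_id for f in flags if f.flagged}
    out = table.copy()
    out["artifact_flag"] = out["transcript_cluster_id"].isin(flagged)
    return out
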