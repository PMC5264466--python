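"""Genome-wide per-pair additive-dosage association scan.

Each SNP x transcript-cluster pair is fit with ordinary least squares,

    expression = mean + covariates + latent factors + dosage,

and the dosage coefficient's beta, t, partial R², and two-sided P (t
distribution, df = n - p) are collected for pairs passing the retention
threshold (default P < 1e-4). Benjamini-Hochberg FDR is computed separately
for cis and trans strata against the *total* number of evaluated tests in
each stratum, not just the stored subset. A genomic-control factor is
estimated from the full P-value distribution of a random SNP subsample.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .core import AdjustedExpression, Annotation, GenotypeMatrix, check_sample_alignment

log = logging.getLogger(__name__)

ASSOC_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "transcript_cluster_id",
    "beta", "t_stat", "r2", "p", "log10_p", "q", "label",
]


@dataclass
class AssociationRecord:
    snp_id: str
    transcript_cluster_id: str
    beta: float
    t_stat: float
    r2: float
    p: float
    df: int
    q: float = float("nan")
    label: str = "unassigned"
    effect_allele: str = "A"

    @property
    def log10_p(self) -> float:
        return float(np.log10(self.p)) if self.p > 0 else -np.inf


@dataclass
class ScanDiagnostics:
    lambda_gc: float
    n_tests_cis: int
    n_tests_trans: int
    retention_p: float
    subsample_size: int
    n_retained: int = 0
    lambda_pvalues: np.ndarray | None = None


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), covariates])


def fit_pair(
    y: np.ndarray,
    dosage: np.ndarray,
    covars: np.ndarray | None = None,
) -> AssociationRecord | None:
    """OLS fit of one expression vector on one dosage plus covariates.

    Returns None (with a logged reason) for zero-variance dosage. The
    partial R² of the dosage term is t²/(t²+df).
    """
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if len(y) != len(dosage):
        raise ValueError("y and dosage lengths differ")
    if np.ptp(dosage) == 0:
        log.warning("zero-variance dosage; pair skipped")
        return None
    X = np.column_stack([_design(covars, len(y)), dosage])
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} <= parameters={p}")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - p
    rss = float(resid @ resid)
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(max(rss / df, 0.0) * xtx_inv[-1, -1])
    beta = float(coef[-1])
    if se == 0:
        t = np.inf if beta > 0 else (-np.inf if beta < 0 else 0.0)
        pval = 0.0 if beta != 0 else 1.0
        r2 = 1.0 if beta != 0 else 0.0
    else:
        t = beta / se
        pval = 2.0 * stats.t.sf(abs(t), df)
        r2 = t * t / (t * t + df)
    return AssociationRecord(
        snp_id="", transcript_cluster_id="", beta=beta, t_stat=float(t),
        r2=float(r2), p=float(pval), df=df,
    )


def cis_test_mask(
    snps: pd.DataFrame, annotation: Annotation, window_bp: int = 1_000_000
) -> np.ndarray:
    """Boolean SNP x gene matrix: pair lies within the cis TSS window.

    Used for stratified FDR denominators; the final cis/trans label of a
    retained record may still be upgraded to cis by block construction.
    """
    genes = annotation.genes
    same_chrom = (
        snps["chrom"].to_numpy()[:, None] == genes["chrom"].to_numpy()[None, :]
    )
    dist = np.abs(
        snps["pos"].to_numpy()[:, None] - genes["tss"].to_numpy()[None, :]
    )
    return same_chrom & (dist <= window_bp)


def scan(
    genotypes: GenotypeMatrix,
    adjusted: AdjustedExpression,
    annotation: Annotation,
    retention_p: float = 1e-4,
    covariates: np.ndarray | None = None,
    lambda_snps: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, ScanDiagnostics]:
    """Evaluate every SNP x transcript pair; keep P < retention_p.

    The scan is a vectorized equivalent of :func:`fit_pair`: expression and
    dosages are residualized on the covariate design once, and the per-pair
    slope, t, and P follow from cross-products. ``lambda_snps`` SNPs are
    drawn at random and their full P-value set retained for the
    genomic-control factor.
    """
    check_sample_alignment(genotypes.sample_ids, list(adjusted.residuals.index))
    Y = adjusted.residuals.to_numpy()
    G = genotypes.dosages
    n, n_genes = Y.shape
    n_snps = G.shape[1]
    if n_snps == 0:
        diag = ScanDiagnostics(float("nan"), 0, 0, retention_p, 0)
        return pd.DataFrame(columns=ASSOC_COLUMNS), diag

    cov_cols = []
    if covariates is not None and covariates.size:
        cov_cols.append(np.asarray(covariates, dtype=float))
    if adjusted.factors is not None and adjusted.n_factors:
        cov_cols.append(adjusted.factors)
    C = np.column_stack(cov_cols) if cov_cols else np.zeros((n, 0))
    X = np.column_stack([np.ones(n), C])
    # the pre-phase residualization design also consumed dimensions: project
    # both expression and dosage on the combined span and count its rank,
    # so the per-pair t is exactly t(df) under the null
    if adjusted.design is not None:
        combined = np.column_stack([X, adjusted.design])
    else:
        combined = X
    Q = linalg.orth(combined)
    rank = Q.shape[1]
    df = n - rank - 1  # - dosage
    if df <= 0:
        raise ValueError("more parameters than samples")
    Yr = Y - Q @ (Q.T @ Y)
    Gr = G - Q @ (Q.T @ G)
    gg = (Gr ** 2).sum(axis=0)
    ok = gg > 1e-12
    if not ok.all():
        log.warning("%d zero-variance dosage columns skipped", (~ok).sum())
    yy = (Yr ** 2).sum(axis=0)

    gy = Gr.T @ Yr                        # snps x genes
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg[:, None]
        rss = yy[None, :] - beta ** 2 * gg[:, None]
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg[:, None])
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals[~ok, :] = np.nan

    cis_mask = cis_test_mask(genotypes.snps, annotation)
    n_tests = int(ok.sum()) * n_genes
    n_tests_cis = int(cis_mask[ok].sum())
    n_tests_trans = n_tests - n_tests_cis

    si, gi = np.where(pvals < retention_p)
    snps = genotypes.snps
    gene_ids = np.asarray(adjusted.residuals.columns)
    r2 = t ** 2 / (t ** 2 + df)
    table = pd.DataFrame(
        {
            "snp_id": snps["snp_id"].to_numpy()[si],
            "chrom": snps["chrom"].to_numpy()[si],
            "pos": snps["pos"].to_numpy()[si],
            "effect_allele": snps["effect_allele"].to_numpy()[si],
            "transcript_cluster_id": gene_ids[gi],
            "beta": beta[si, gi],
            "t_stat": t[si, gi],
            "r2": r2[si, gi],
            "p": pvals[si, gi],
        }
    )
    with np.errstate(divide="ignore"):
        table["log10_p"] = np.where(
            table["p"] > 0, np.log10(table["p"]), -np.inf
        )
    table["q"] = np.nan
    table["label"] = "unassigned"
    # deterministic order and tie-breaking: p, then position, transcript
    table = table.sort_values(
        ["p", "chrom", "pos", "transcript_cluster_id"], kind="mergesort"
    ).reset_index(drop=True)

    rng = np.random.default_rng(seed)
    sub = rng.choice(np.where(ok)[0], size=min(lambda_snps, int(ok.sum())),
                     replace=False)
    lam_p = pvals[sub, :].ravel()
    lam_p = lam_p[np.isfinite(lam_p)]
    lam = genomic_lambda(np.clip(lam_p, 1e-300, 1.0))
    diag = ScanDiagnostics(
        lambda_gc=lam,
        n_tests_cis=n_tests_cis,
        n_tests_trans=n_tests_trans,
        retention_p=retention_p,
        subsample_size=len(sub),
        n_retained=len(table),
        lambda_pvalues=lam_p,
    )
    diag.df = df
    return table, diag


def bh_fdr(p: np.ndarray, m: int) -> np.ndarray:
    """Benjamini-Hochberg q-values for the stored smallest-P subset.

    The stored values occupy the smallest global ranks among the ``m``
    evaluated tests, so q_i = min_{j>=i} m * p_(j) / j over stored ranks.
    """
    p = np.asarray(p, dtype=float)
    k = len(p)
    if m < k:
        raise ValueError(f"m={m} is smaller than the stored count {k}")
    if k == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(k)
    q[order] = q_sorted
    return q


def genomic_lambda(p: np.ndarray) -> float:
    """Genomic-control factor: ratio of chi²(1) upper-tail quantiles at the
    median P and at 0.5."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty P vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P values must lie in (0, 1]")
    med = float(np.median(p))
    return float(stats.chi2.isf(med, 1) / stats.chi2.isf(0.5, 1))


def gc_adjust(table: pd.DataFrame, lambda_gc: float) -> pd.DataFrame:
    """Divide each test's chi²(1) statistic by lambda and recompute P.

    After adjustment the genomic-control factor of the adjusted statistics
    is 1 by construction. q-values must be recomputed by the caller (they
    depend on the stratum denominators).
    """
    if not (lambda_gc > 0):
        raise ValueError("lambda_gc must be positive")
    out = table.copy()
    chi2 = stats.chi2.isf(np.clip(out["p"].to_numpy(), 1e-300, 1.0), 1)
    newp = stats.chi2.sf(chi2 / lambda_gc, 1)
    out["p"] = newp
    with np.errstate(divide="ignore"):
        out["log10_p"] = np.where(newp > 0, np.log10(newp), -np.inf)
    return out


def stratified_fdr(
    table: pd.DataFrame, n_tests_cis: int, n_tests_trans: int
) -> pd.DataFrame:
    """BH q-values computed separately for cis- and trans-labelled records,
    each ranked against its stratum's total test count."""
    out = table.copy()
    for label, m in (("cis", n_tests_cis), ("trans", n_tests_trans)):
        mask = out["label"] == label
        if mask.any():
            out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy(), m)
    return out
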