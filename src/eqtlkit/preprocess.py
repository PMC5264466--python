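"""Two-phase expression adjustment: technical covariates, cell-count
imputation, biological-covariate residualization, and latent confounding
factors.

The latent-factor step is an iterated-PCA (truncated SVD) factor model on
the residualized expression, standing in for a Bayesian factor engine; the
interface accepts any callable producing sample-space factors.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .core import AdjustedExpression, CovariateTable

log = logging.getLogger(__name__)

BIO_COVARIATES = [
    "sex", "age", "platelet_count", "wbc_count",
    "lymphocyte_pct", "monocyte_pct", "eosinophil_pct", "basophil_pct",
]


def _residualize_matrix(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of every column of Y on the design X (with intercept)."""
    X1 = np.column_stack([np.ones(len(Y)), X]) if X.size else np.ones((len(Y), 1))
    coef, *_ = linalg.lstsq(X1, Y)
    return Y - X1 @ coef


def _first_pc(Y: np.ndarray) -> np.ndarray:
    """First principal component of the centered, unscaled matrix (scores)."""
    Yc = Y - Y.mean(axis=0)
    u, s, _ = np.linalg.svd(Yc, full_matrices=False)
    return u[:, 0] * s[0]


def adjust_technical(
    expression: pd.DataFrame, tech: CovariateTable,
    tech_columns: list[str] | None = None,
    batch_column: str = "batch",
    remove_pc1: bool = True,
) -> pd.DataFrame:
    """Remove batch, technical covariates, and (optionally) expression PC1.

    Fits each feature on batch indicator columns, the named technical
    covariates, and PC1 of the centered unscaled expression matrix, and
    returns the residuals (plus the original feature means so values stay
    on the expression scale). The covariate projection is idempotent; PC1
    removal is not (each pass would strip the next component), hence the
    ``remove_pc1`` switch. Constant covariate columns are dropped with a
    warning; a rank-deficient design raises naming the collinear columns.
    """
    data = tech.data.loc[expression.index]
    cols: list[np.ndarray] = []
    names: list[str] = []
    if batch_column in data:
        batches = pd.get_dummies(data[batch_column], drop_first=True)
        for c in batches:
            cols.append(batches[c].to_numpy(dtype=float))
            names.append(f"batch[{c}]")
    for c in tech_columns or []:
        v = data[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            log.warning("technical covariate %r is constant; dropped", c)
            continue
        cols.append(v)
        names.append(c)
    if remove_pc1:
        cols.append(_first_pc(expression.to_numpy()))
        names.append("PC1")
    if not cols:
        return expression.copy()
    X = np.column_stack(cols)
    X1 = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(X1)
    if rank < X1.shape[1]:
        raise ValueError(
            f"rank-deficient technical design; collinear among: {names}"
        )
    means = expression.mean(axis=0)
    resid = _residualize_matrix(expression.to_numpy(), X)
    return pd.DataFrame(resid + means.to_numpy(), index=expression.index,
                        columns=expression.columns)


def impute_cell_counts(
    expression: pd.DataFrame, covars: CovariateTable,
    n_components: int = 10,
) -> tuple[CovariateTable, dict[str, float]]:
    """Fill unmeasured cell-count fields by PLS regression on expression.

    Fits a partial-least-squares regression of each cell-count field on the
    expression matrix over samples whose ``<field>_measured`` flag is true,
    predicts the missing samples, and reports a cross-validated R² per
    field. Measured values are never overwritten.
    """
    data = covars.data.copy()
    Y = expression.loc[data.index].to_numpy()
    cv_r2: dict[str, float] = {}
    for f in CovariateTable.CELL_FIELDS:
        if f not in data:
            continue
        flag_col = f + "_measured"
        measured = (
            data[flag_col].to_numpy(dtype=bool)
            if flag_col in data
            else np.ones(len(data), dtype=bool)
        )
        n_meas = int(measured.sum())
        if n_meas == 0:
            raise ValueError(f"no measured samples for {f}")
        if n_meas <= n_components:
            raise ValueError(
                f"{f}: {n_meas} measured samples <= {n_components} components"
            )
        y = data[f].to_numpy(dtype=float)
        Xm, ym = Y[measured], y[measured]
        # cross-validated R^2 over measured samples
        kf = KFold(n_splits=min(5, n_meas), shuffle=False)
        press, tss = 0.0, float(((ym - ym.mean()) ** 2).sum())
        for tr, te in kf.split(Xm):
            pls = PLSRegression(n_components=n_components, scale=False)
            pls.fit(Xm[tr], ym[tr])
            press += float(((ym[te] - pls.predict(Xm[te]).ravel()) ** 2).sum())
        cv_r2[f] = 1.0 - press / tss if tss > 0 else float("nan")
        if measured.all():
            continue
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(Xm, ym)
        pred = pls.predict(Y[~measured]).ravel()
        y[~measured] = pred
        data[f] = y
        data[flag_col] = measured  # imputed entries keep flag False
    return CovariateTable(data), cv_r2


def _gls_residuals(y: np.ndarray, X1: np.ndarray, kinship: np.ndarray,
                   thetas: np.ndarray) -> np.ndarray:
    """Per-feature GLS residuals with covariance sigma^2 (I + theta K).

    theta is chosen per feature by profile maximum likelihood on a grid.
    """
    n = len(y)
    eigval, eigvec = np.linalg.eigh(kinship)
    yt = eigvec.T @ y
    Xt = eigvec.T @ X1
    best = (None, -np.inf)
    for th in thetas:
        w = 1.0 + th * eigval
        if np.any(w <= 0):
            continue
        Xw = Xt / w[:, None]
        coef, *_ = linalg.lstsq(Xt.T @ Xw, Xw.T @ yt)
        r = yt - Xt @ coef
        sigma2 = float((r ** 2 / w).sum() / n)
        ll = -0.5 * (n * np.log(sigma2) + np.log(w).sum())
        if ll > best[1]:
            best = (coef, ll)
    return y - X1 @ best[0]


def residualize(
    expression: pd.DataFrame, covars: CovariateTable,
    kinship: np.ndarray | None = None,
    covariate_columns: list[str] | None = None,
) -> AdjustedExpression:
    """Residuals of each feature on sex, age and blood-count covariates.

    With a kinship matrix, per-feature generalized least squares with
    covariance sigma^2 (I + theta * kinship) is used (theta by grid ML);
    otherwise ordinary least squares. Residual columns are numerically
    orthogonal to every adjusted covariate.
    """
    cols = covariate_columns or [
        c for c in BIO_COVARIATES if c in covars.data.columns
    ]
    data = covars.data.loc[expression.index, cols]
    if data.isna().any().any():
        bad = list(data.columns[data.isna().any()])
        raise ValueError(f"missing covariate values in columns {bad}")
    X = data.to_numpy(dtype=float)
    keep = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0]
    X = X[:, keep]
    Y = expression.to_numpy()
    if kinship is None:
        resid = _residualize_matrix(Y, X)
    else:
        kinship = np.asarray(kinship, dtype=float)
        if kinship.shape != (len(Y), len(Y)) or not np.allclose(
            kinship, kinship.T, atol=1e-10
        ):
            raise ValueError("kinship must be a symmetric sample x sample matrix")
        if np.linalg.eigvalsh(kinship).min() < -1e-8:
            raise ValueError("kinship must be positive semidefinite")
        X1 = np.column_stack([np.ones(len(Y)), X])
        thetas = np.concatenate([[0.0], np.logspace(-3, 1, 9)])
        resid = np.column_stack(
            [_gls_residuals(Y[:, j], X1, kinship, thetas)
             for j in range(Y.shape[1])]
        )
    out = pd.DataFrame(resid, index=expression.index,
                       columns=expression.columns)
    design = np.column_stack([np.ones(len(Y)), X])
    return AdjustedExpression(out, provenance=[f"residualize({cols})"],
                              design=design)


def latent_factors(adjusted: AdjustedExpression, k: int = 20) -> AdjustedExpression:
    """Top-k sample-space variance factors of the residual matrix.

    Factors are left singular vectors of the centered residuals, scaled to
    unit variance; the proportion of residual variance captured by each is
    recorded. They are pairwise orthogonal by construction.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    Y = adjusted.residuals.to_numpy()
    n, p = Y.shape
    if k >= min(n, p):
        raise ValueError(f"k={k} must be < min(n_samples, n_features)={min(n, p)}")
    Yc = Y - Y.mean(axis=0)
    u, s, _ = np.linalg.svd(Yc, full_matrices=False)
    factors = u[:, :k]
    factors = factors / factors.std(axis=0, ddof=0)
    var_explained = (s[:k] ** 2) / (s ** 2).sum()
    return AdjustedExpression(
        adjusted.residuals,
        factors=factors,
        variance_explained=var_explained,
        provenance=adjusted.provenance + [f"latent_factors(k={k})"],
        design=adjusted.design,
    )
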