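"""Single-SNP linear mixed-model association with a genomic
relationship matrix.

Model per SNP:  y = W alpha + x beta + u + e,  u ~ N(0, Vg K),
e ~ N(0, Ve I), with K the GRM from (LD-pruned) SNPs.  The variance
ratio delta = Ve/Vg is profiled once on the covariate-only model by
REML — eigendecompose K, rotate, scan delta on a log grid and refine by
bounded scalar optimization — and then held fixed while each SNP is
tested by generalized least squares in the rotated coordinates
(the EMMAX approximation).  Significance is the Wald chi-square
(beta/se)^2 against chi2 with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import GenotypeMatrix
from .structure import grm_matrix


def grm(gm: GenotypeMatrix, snp_set: np.ndarray | None = None) -> np.ndarray:
    """Kinship for the mixed model: the GRM restricted to ``snp_set``
    (typically LD-pruned), symmetrized and clipped to PSD."""
    K = grm_matrix(gm, snp_set)
    K = 0.5 * (K + K.T)
    w, v = np.linalg.eigh(K)
    if w.min() < -1e-8:
        K = (v * np.clip(w, 0, None)) @ v.T
    return K


def _reml_neg_loglik(log_delta: float, s: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    """Negative restricted log-likelihood at delta = exp(log_delta),
    in K's eigenbasis (s eigenvalues, yr/Xr rotated response/design)."""
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    n, p = Xr.shape
    XtWX = (Xr * w[:, None]).T @ Xr
    XtWy = (Xr * w[:, None]).T @ yr
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yr - Xr @ beta
    rss = float((w * resid**2).sum())
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    _, logdet_xx = np.linalg.slogdet(Xr.T @ Xr)
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi * rss / (n - p))
        + (n - p)
        + np.sum(np.log(s + delta))
        + logdet_xwx
        - logdet_xx
    )
    return -ll


@dataclass
class LMMResult:
    """Association scan output plus fitted variance components."""

    table: pd.DataFrame  # snp, chrom, bp, beta, se, chi2, p
    vg: float
    ve: float
    delta: float
    alpha: np.ndarray  # covariate coefficients under the null model
    reml_loglik: float


def lmm_assoc(
    gm: GenotypeMatrix,
    pheno: pd.DataFrame,
    K: np.ndarray,
    covariates: pd.DataFrame | None = None,
    trait: str = "trait",
    snp_set: np.ndarray | None = None,
) -> LMMResult:
    """Test each SNP for association with ``trait``.

    ``pheno`` needs columns id and ``trait``; ``covariates`` (optional)
    an id column plus numeric columns, to which an intercept is always
    appended.  Individuals are aligned on id; rows missing a phenotype
    are dropped.  Missing dosages are mean-imputed per SNP for this
    stage only.
    """
    ids = gm.individuals["id"]
    ph = pheno.set_index("id").reindex(ids)
    keep = ph[trait].notna().to_numpy()
    if keep.sum() < 3:
        raise ValueError("too few phenotyped individuals")
    y = ph.loc[keep, trait].to_numpy(dtype=float)
    n = int(keep.sum())

    W = np.ones((n, 1))
    if covariates is not None:
        cv = covariates.set_index("id").reindex(ids).loc[keep]
        W = np.column_stack([W, cv.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("covariate matrix is singular")
    if n <= W.shape[1] + 1:
        raise ValueError("need n > rank(W) + 1")

    Ks = K[np.ix_(np.flatnonzero(keep), np.flatnonzero(keep))]
    s, U = np.linalg.eigh(0.5 * (Ks + Ks.T))
    if s.min() < -1e-8:
        raise ValueError("kinship is not positive semidefinite")
    s = np.clip(s, 0.0, None)
    yr = U.T @ y
    Wr = U.T @ W

    # profile REML over delta = Ve/Vg: coarse log grid, then refinement
    grid = np.linspace(np.log(1e-4), np.log(1e4), 61)
    vals = [_reml_neg_loglik(g, s, yr, Wr) for g in grid]
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(s, yr, Wr), method="bounded"
    )
    delta = float(np.exp(res.x))
    w = 1.0 / (s + delta)

    # null-model components
    XtWX = (Wr * w[:, None]).T @ Wr
    alpha = np.linalg.solve(XtWX, (Wr * w[:, None]).T @ yr)
    resid = yr - Wr @ alpha
    vg = float((w * resid**2).sum() / (n - W.shape[1]))
    ve = vg * delta

    x_all = gm.dosages_float()[keep]
    if snp_set is not None:
        snp_idx = np.asarray(snp_set)
    else:
        snp_idx = np.arange(gm.n_snp)
    rows = []
    for k in snp_idx:
        xk = x_all[:, k]
        mask = np.isnan(xk)
        if mask.all():
            continue
        xk = np.where(mask, np.nanmean(xk), xk)
        if np.ptp(xk) == 0:
            continue
        xr = U.T @ xk
        X = np.column_stack([Wr, xr])
        XtWX = (X * w[:, None]).T @ X
        XtWy = (X * w[:, None]).T @ yr
        try:
            coef = np.linalg.solve(XtWX, XtWy)
            cov_un = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            continue
        r = yr - X @ coef
        sigma2 = float((w * r**2).sum() / (n - X.shape[1]))
        se = float(np.sqrt(sigma2 * cov_un[-1, -1]))
        beta = float(coef[-1])
        chi2 = (beta / se) ** 2 if se > 0 else np.inf
        rows.append(
            (int(k), gm.snps["chrom"].iloc[k], int(gm.snps["bp"].iloc[k]),
             beta, se, chi2, float(stats.chi2.sf(chi2, df=1)))
        )
    table = pd.DataFrame(
        rows, columns=["snp", "chrom", "bp", "beta", "se", "chi2", "p"]
    )
    return LMMResult(
        table=table, vg=vg, ve=ve, delta=delta, alpha=alpha,
        reml_loglik=-float(res.fun),
    )
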