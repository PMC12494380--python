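"""Shared numerical kernels: vectorized OLS, two-group MANOVA, Fisher z.

The per-feature linear models are solved with one shared design factored
once and applied to every feature row (the strategy limma popularized),
which is what makes thousand-feature x thousand-permutation scans
tractable.  Coefficients, standard errors and p-values are identical to
per-feature OLS; the test suite cross-checks against statsmodels.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats


def drop_collinear_columns(X: np.ndarray, names: list, protect: int) -> tuple:
    """Drop trailing columns that make X rank-deficient.

    The first ``protect`` columns (the primary design) are never
    dropped; later columns (surrogate variables) are removed greedily
    until X has full column rank.
    """
    keep = list(range(X.shape[1]))
    while np.linalg.matrix_rank(X[:, keep]) < len(keep):
        droppable = [j for j in keep[protect:]]
        if not droppable:
            raise np.linalg.LinAlgError("primary design matrix is rank-deficient")
        j = droppable[-1]
        keep.remove(j)
        warnings.warn(f"dropping collinear covariate {names[j]!r}")
    return X[:, keep], [names[j] for j in keep]


def vectorized_ols(Y: np.ndarray, X: np.ndarray) -> dict:
    """OLS of every row of ``Y`` (features x samples) on design ``X``.

    Returns coefficients, standard errors, t statistics and two-sided
    p-values, each features x predictors, plus the residual dof.
    """
    n, p = X.shape
    if Y.shape[1] != n:
        raise ValueError("Y columns must match design rows")
    if n <= p:
        raise ValueError("more predictors than samples")
    xtx_inv = np.linalg.inv(X.T @ X)
    proj = X @ xtx_inv  # n x p
    beta = Y @ proj  # features x p
    resid = Y - beta @ X.T
    dof = n - p
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    pvals = np.where(np.isfinite(t) | (beta == 0), pvals, 0.0)
    pvals = np.where((se == 0) & (beta == 0), 1.0, pvals)
    return {"beta": beta, "se": se, "t": t, "p": pvals, "dof": dof, "resid": resid}


def two_group_pillai(a: np.ndarray, b: np.ndarray) -> tuple:
    """Two-sample MANOVA via Hotelling's T^2; returns (Pillai V, F, p).

    For two groups every MANOVA statistic is a monotone function of
    T^2 and the F test is exact:  F = T^2 (n - 1 - p) / ((n - 2) p)
    with (p, n - 1 - p) degrees of freedom, and Pillai's trace equals
    T^2 / (T^2 + n - 2).
    """
    na, nb = len(a), len(b)
    p = a.shape[1]
    n = na + nb
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 samples per group")
    if n - 1 - p <= 0:
        raise ValueError("too few samples for the dimensionality")
    d = a.mean(axis=0) - b.mean(axis=0)
    sa = np.cov(a, rowvar=False)
    sb = np.cov(b, rowvar=False)
    pooled = ((na - 1) * np.atleast_2d(sa) + (nb - 1) * np.atleast_2d(sb)) / (n - 2)
    try:
        sol = np.linalg.solve(pooled, d)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(pooled) @ d
    t2 = (na * nb / n) * float(d @ sol)
    t2 = max(t2, 0.0)
    f = t2 * (n - 1 - p) / ((n - 2) * p)
    pval = float(stats.f.sf(f, p, n - 1 - p))
    pillai = t2 / (t2 + n - 2)
    return pillai, f, pval


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple:
    """Compare two independent correlations via Fisher's z transform."""
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 per correlation")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
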