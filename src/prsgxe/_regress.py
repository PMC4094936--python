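"""Closed-form least-squares helpers for vectorized per-SNP scans.

These implement ordinary least squares via the Frisch-Waugh-Lovell
decomposition: shared covariate columns are projected out once with a QR
basis, after which each SNP needs only a one- or two-regressor solve.
Used by the GWAS and the SNP x environment scans, where 10^3-10^6 small
regressions make per-model overhead prohibitive; model class and inference
are standard OLS with conventional standard errors.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: smallest positive normal double; p-values are floored here so that
#: -log10(p) stays finite for score weighting
P_FLOOR = float(np.finfo(np.float64).tiny)


def qr_basis(columns: np.ndarray) -> np.ndarray:
    """Orthonormal basis (n x k) of the column space of ``columns``."""
    q, _ = np.linalg.qr(np.asarray(columns, dtype=float))
    return q


def residualize(a: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Residuals of the columns of ``a`` after projection onto basis ``q``."""
    return a - q @ (q.T @ a)


def t_pvalue(t: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p from the t distribution, floored at P_FLOOR."""
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.maximum(p, P_FLOOR)


def single_regressor_scan(y_til: np.ndarray, g_til: np.ndarray, df: int):
    """Per-column slope stats of y on each column of ``g_til``.

    Both inputs must already be residualized on the shared covariates
    (including the intercept); ``df`` is the residual degrees of freedom of
    the full model. Returns (beta, se, t, p) arrays; columns with zero
    variance yield NaN and should be filtered by the caller.
    """
    gg = np.einsum("ij,ij->j", g_til, g_til)
    gy = g_til.T @ y_til
    yy = float(y_til @ y_til)
    # a residualized column that is numerically zero is monomorphic
    bad = gg <= 1e-10 * max(len(y_til), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = np.maximum(yy - beta * gy, 0.0)
        rss = np.where(rss < 1e-12 * yy, 0.0, rss)   # exact fit up to rounding
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        t = beta / se
    # perfect fit: zero residual variance with a real slope -> p at the floor
    t = np.where((se == 0) & (beta != 0), np.sign(beta) * np.inf, t)
    p = t_pvalue(t, df)
    for arr in (beta, se, t, p):
        arr[bad] = np.nan
    return beta, se, t, p


def two_regressor_scan(y_til: np.ndarray, g_til: np.ndarray, w_til: np.ndarray,
                       df: int):
    """Joint two-regressor fit per column pair (g_til[:, j], w_til[:, j]).

    Returns stats for the *second* regressor (the interaction term):
    (beta_w, se_w, t_w, p_w) plus beta_g for completeness. Inputs must be
    residualized on the shared covariates.
    """
    a = np.einsum("ij,ij->j", g_til, g_til)
    b = np.einsum("ij,ij->j", g_til, w_til)
    c = np.einsum("ij,ij->j", w_til, w_til)
    u = g_til.T @ y_til
    v = w_til.T @ y_til
    yy = float(y_til @ y_til)
    det = a * c - b * b
    bad = ~(det > 1e-10 * np.maximum(a * c, 1e-30))   # collinear or monomorphic
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_g = (c * u - b * v) / det
        beta_w = (a * v - b * u) / det
        rss = np.maximum(yy - (beta_g * u + beta_w * v), 0.0)
        rss = np.where(rss < 1e-12 * yy, 0.0, rss)
        sigma2 = rss / df
        se_w = np.sqrt(sigma2 * a / det)
        t_w = beta_w / se_w
    t_w = np.where((se_w == 0) & (beta_w != 0), np.sign(beta_w) * np.inf, t_w)
    p_w = t_pvalue(t_w, df)
    for arr in (beta_g, beta_w, se_w, t_w, p_w):
        arr[bad] = np.nan
    return beta_g, beta_w, se_w, t_w, p_w
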