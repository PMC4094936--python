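"""Discovery-stage GWAS: per-SNP OLS of a continuous phenotype on dosage.

Each SNP is tested with ordinary least squares of the phenotype on
[intercept, dosage, covariates]; the reported beta/se/t/p belong to the
dosage term, with a two-sided p from the t distribution at n - k residual
degrees of freedom. Sex enters as a covariate in the standard pipeline.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._regress import qr_basis, residualize, single_regressor_scan
from .datatypes import GenotypeMatrix

logger = logging.getLogger(__name__)


def _covariate_matrix(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != n:
        raise ValueError(f"covariates have {c.shape[0]} rows, expected {n}")
    return np.column_stack([np.ones(n), c])


def run_gwas(genotypes: GenotypeMatrix, phenotype, covariates=None) -> pd.DataFrame:
    """Per-SNP association scan; returns a SummaryStats table.

    Parameters
    ----------
    genotypes
        Effect-allele dosages; NaN entries are handled by per-SNP listwise
        deletion, with the per-SNP sample size reported as ``n_used``.
    phenotype
        Continuous outcome aligned with ``genotypes.individual_ids``.
    covariates
        Optional n x k matrix (e.g. sex); an intercept is always included.

    Monomorphic SNPs (zero dosage variance after deletion) are excluded
    from the output with a logged reason. p-values are floored at the
    smallest positive normal double so -log10(p) stays finite.
    """
    y = np.asarray(phenotype, dtype=float)
    n = genotypes.n_individuals
    if y.shape[0] != n:
        raise ValueError(f"phenotype has {y.shape[0]} rows, expected {n}")
    cov = _covariate_matrix(covariates, n)
    if np.isnan(y).any() or np.isnan(cov).any():
        keep = ~(np.isnan(y) | np.isnan(cov).any(axis=1))
        y, cov = y[keep], cov[keep]
        dosage = genotypes.dosage[keep]
    else:
        dosage = genotypes.dosage
    n_eff = len(y)
    k = cov.shape[1]           # intercept + covariates
    df = n_eff - (k + 1)
    if df <= 0:
        raise ValueError("not enough observations for the requested model")

    q = qr_basis(cov)
    y_til = residualize(y[:, None], q)[:, 0]

    has_nan = np.isnan(dosage).any(axis=0)
    beta = np.full(genotypes.n_snps, np.nan)
    se = np.full_like(beta, np.nan)
    t = np.full_like(beta, np.nan)
    p = np.full_like(beta, np.nan)
    n_used = np.full(genotypes.n_snps, n_eff)

    complete = ~has_nan
    if complete.any():
        g_til = residualize(dosage[:, complete], q)
        beta[complete], se[complete], t[complete], p[complete] = (
            single_regressor_scan(y_til, g_til, df))

    for j in np.flatnonzero(has_nan):
        ok = ~np.isnan(dosage[:, j])
        nj = int(ok.sum())
        dfj = nj - (k + 1)
        n_used[j] = nj
        if dfj <= 0:
            continue
        qj = qr_basis(cov[ok])
        yj = residualize(y[ok, None], qj)[:, 0]
        gj = residualize(dosage[ok, j][:, None], qj)
        bj, sj, tj, pj = single_regressor_scan(yj, gj, dfj)
        beta[j], se[j], t[j], p[j] = bj[0], sj[0], tj[0], pj[0]

    out = pd.DataFrame({
        "snp_id": genotypes.snps["snp_id"].to_numpy(),
        "effect_allele": genotypes.snps["effect_allele"].to_numpy(),
        "other_allele": genotypes.snps["other_allele"].to_numpy(),
        "beta": beta,
        "se": se,
        "t_stat": t,
        "p_value": p,
        "n_used": n_used,
    })
    mono = out["beta"].isna()
    if mono.any():
        logger.info("excluding %d monomorphic/degenerate SNP(s): %s",
                    int(mono.sum()), out.loc[mono, "snp_id"].head().tolist())
        out = out[~mono].reset_index(drop=True)
    return out
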