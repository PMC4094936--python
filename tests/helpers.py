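"""Shared test fixtures-in-code: random genotype tables and a brute-force OLS oracle."""

import numpy as np
import pandas as pd

import prsgxe as P


def random_genotypes(rng, n=50, m=20, missing=0):
    """Unstructured genotype fixture with uniform dosages in [0, 2]."""
    dosage = rng.uniform(0, 2, size=(n, m))
    if missing:
        mask = rng.random((n, m)) < missing
        dosage[mask] = np.nan
    snps = pd.DataFrame({
        "snp_id": [f"snp{j}" for j in range(m)],
        "effect_allele": ["A"] * m,
        "other_allele": ["G"] * m,
    })
    ids = np.array([f"I{i}" for i in range(n)], dtype=object)
    return P.GenotypeMatrix(individual_ids=ids, snps=snps, dosage=dosage)


def ols_oracle(y, x):
    """Brute-force normal-equations OLS via pseudo-inverse.

    Returns (beta, se, t, p) for all columns of x (including intercept).
    Independent of the package's QR/FWL code path.
    """
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, k = x.shape
    xtx_inv = np.linalg.pinv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = n - np.linalg.matrix_rank(x)
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p
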