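"""Set-based permutation test for SNP-level G x E enrichment.

Pipeline: select the top discovery SNPs (default p <= 1e-4), LD-prune them
in an independent-individuals subset of the target cohort (greedy scan in
ascending discovery-p order, keep iff squared dosage correlation with every
kept SNP stays below r2_max = 0.50), fit a per-SNP interaction model

    y ~ 1 + sex + dosage_c + env_c + dosage_c * env_c

and summarize the set by the sum of |t| over SNPs whose interaction is
significant at alpha = 0.05. The null distribution comes from jointly
permuting the phenotype/covariate rows (alcohol problems, sex, environment
move together) while genotype rows stay fixed, so all SNP-SNP LD is
preserved exactly and only genotype-phenotype links are broken. The
empirical p-value is (R + 1)/(N + 1), with exceedance counted strictly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._regress import qr_basis, residualize, two_regressor_scan
from .datatypes import EnrichmentResult, GenotypeMatrix

logger = logging.getLogger(__name__)


def select_top_snps(sumstats: pd.DataFrame, cutoff: float = 1e-4) -> list[str]:
    """Discovery SNPs with p <= cutoff, ordered by ascending p."""
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in (0, 1], got {cutoff}")
    hits = sumstats[sumstats["p_value"] <= cutoff]
    if hits.empty:
        raise ValueError(f"no SNPs reach p <= {cutoff}")
    return hits.sort_values(["p_value", "snp_id"], kind="stable")["snp_id"].tolist()


def ld_prune(genotypes: GenotypeMatrix, snp_ids: list[str],
             r2_max: float = 0.50, individual_ids=None) -> list[str]:
    """Greedy LD pruning: keep a SNP iff r^2 < r2_max with every kept SNP.

    ``snp_ids`` must already be in the desired priority order (ascending
    discovery p from :func:`select_top_snps`); the first SNP is always
    kept. ``individual_ids`` restricts the correlation estimate to an
    independent subset (one member per family), as LD should not be
    estimated on relatives.
    """
    geno = genotypes
    if individual_ids is not None:
        geno = genotypes.subset_individuals(individual_ids)
    cols = geno.snp_indices(snp_ids)
    d = geno.dosage[:, cols]
    d = np.where(np.isnan(d), np.nanmean(d, axis=0, keepdims=True), d)
    sd = d.std(axis=0)
    keep_mask = sd > 0
    z = np.zeros_like(d)
    z[:, keep_mask] = (d[:, keep_mask] - d[:, keep_mask].mean(0)) / sd[keep_mask]
    n = len(z)

    kept: list[int] = []
    for j in range(len(snp_ids)):
        if not keep_mask[j]:
            continue
        if kept:
            r = z[:, kept].T @ z[:, j] / n
            if np.any(r * r >= r2_max):
                continue
        kept.append(j)
    logger.info("LD pruning: %d -> %d SNPs at r^2 < %.2f",
                len(snp_ids), len(kept), r2_max)
    return [snp_ids[j] for j in kept]


def _gxe_scan(y, sex, env, dosage):
    """Vectorized per-SNP interaction stats; returns (t, p, valid_mask)."""
    n = len(y)
    df = n - 5
    if df <= 0:
        raise ValueError("too few individuals for the interaction model")
    env_c = env - env.mean()
    q = qr_basis(np.column_stack([np.ones(n), sex, env_c]))
    g_c = dosage - dosage.mean(axis=0)
    w = g_c * env_c[:, None]
    y_til = residualize(y[:, None], q)[:, 0]
    g_til = residualize(g_c, q)
    w_til = residualize(w, q)
    _, _, _, t, p = two_regressor_scan(y_til, g_til, w_til, df)
    valid = ~np.isnan(t)
    return t, p, valid


def snp_gxe_tstats(genotypes: GenotypeMatrix, cohort: pd.DataFrame,
                   environment: str, snp_ids: list[str],
                   outcome: str = "alcohol_problems") -> pd.DataFrame:
    """Interaction t and two-sided p per SNP, mirroring the score-level model.

    Dosage and environment are centered before the product is formed.
    Monomorphic SNPs are excluded from the output with a logged count.
    """
    geno = genotypes.subset_individuals(cohort["individual_id"].to_numpy())
    cols = geno.snp_indices(snp_ids)
    d = geno.dosage[:, cols]
    d = np.where(np.isnan(d), np.nanmean(d, axis=0, keepdims=True), d)
    y = cohort[outcome].to_numpy(dtype=float)
    sex = cohort["sex"].to_numpy(dtype=float)
    env = cohort[environment].to_numpy(dtype=float)
    t, p, valid = _gxe_scan(y, sex, env, d)
    if not valid.all():
        logger.info("excluding %d monomorphic/degenerate SNP(s) from G x E scan",
                    int((~valid).sum()))
    return pd.DataFrame({
        "snp_id": np.asarray(snp_ids, dtype=object)[valid],
        "t_stat": t[valid],
        "p_value": p[valid],
    })


def observed_statistic(tstats: pd.DataFrame, alpha: float = 0.05) -> float:
    """Sum of |t| over SNPs whose interaction p is below alpha (0 if none)."""
    sig = tstats["p_value"] < alpha
    return float(np.abs(tstats.loc[sig, "t_stat"]).sum())


def permutation_test(genotypes: GenotypeMatrix, cohort: pd.DataFrame,
                     environment: str, snp_ids: list[str],
                     n_perm: int = 100_000, seed: int = 0,
                     alpha: float = 0.05,
                     outcome: str = "alcohol_problems",
                     n_top_snps_discovery: int | None = None,
                     n_available_target: int | None = None,
                     null_stream=None) -> EnrichmentResult:
    """Permutation null for the significant-|t| sum statistic.

    Each of the ``n_perm`` permutations applies one shared random row
    permutation to the [outcome, sex, environment] block while leaving the
    genotype rows untouched, then recomputes the statistic. R counts
    permuted statistics strictly greater than the observed one;
    empirical p = (R + 1)/(N + 1). If ``null_stream`` is a writable text
    handle, one permuted statistic is written per line.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    geno = genotypes.subset_individuals(cohort["individual_id"].to_numpy())
    cols = geno.snp_indices(snp_ids)
    d = geno.dosage[:, cols]
    d = np.where(np.isnan(d), np.nanmean(d, axis=0, keepdims=True), d)
    valid = d.std(axis=0) > 0
    d = d[:, valid]
    y = cohort[outcome].to_numpy(dtype=float)
    sex = cohort["sex"].to_numpy(dtype=float)
    env = cohort[environment].to_numpy(dtype=float)
    n = len(y)

    t, p, ok = _gxe_scan(y, sex, env, d)
    observed = float(np.abs(t[ok & (p < alpha)]).sum())

    rng = np.random.default_rng(seed)
    r_exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        t, p, ok = _gxe_scan(y[perm], sex[perm], env[perm], d)
        stat = float(np.abs(t[ok & (p < alpha)]).sum())
        if null_stream is not None:
            null_stream.write(f"{stat:.10g}\n")
        if stat > observed:
            r_exceed += 1

    n_pruned = int(valid.sum())
    return EnrichmentResult(
        environment=environment,
        observed_stat=observed,
        r_exceed=r_exceed,
        n_perm=n_perm,
        n_top_snps_discovery=(n_top_snps_discovery
                              if n_top_snps_discovery is not None else n_pruned),
        n_available_target=(n_available_target
                            if n_available_target is not None else n_pruned),
        n_after_pruning=n_pruned,
        n_individuals=n,
    )
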