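"""Threshold polygenic scores with sign x (-log10 p) weights.

Each SNP passing a discovery p-value threshold contributes its
effect-allele dosage weighted by sign(beta) * (-log10 p). Scores default
to the average-per-allele normalization (sum of weighted dosages divided
by twice the number of non-missing scored SNPs), the convention of the
standard --score procedure; a plain sum mode is available. Thresholds are
inclusive (p <= threshold), so SNP sets are nested across the series.
"""

from __future__ import annotations

import logging
from numbers import Real

import numpy as np
import pandas as pd

from .config import DEFAULT_THRESHOLDS
from .datatypes import GenotypeMatrix, ScoreSet

logger = logging.getLogger(__name__)


def snp_weight(beta: float, p: float) -> float:
    """Score weight of one SNP: sign(beta) * (-log10 p).

    The sign keeps the direction of the discovery effect; the magnitude
    grows with association strength. ``p`` must lie in (0, 1]; p = 1 gives
    weight 0 and sign(0) is defined as 0.
    """
    if not isinstance(p, Real) or not (0.0 < p <= 1.0):
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return float(np.sign(beta) * (-np.log10(p)))


def align_alleles(target_snps: pd.DataFrame, sumstats: pd.DataFrame) -> pd.DataFrame:
    """Match target SNPs to discovery summary statistics by id and alleles.

    Returns the sumstats rows for SNPs present in both tables, with an
    added boolean ``flip`` column: True where the target's effect allele is
    the discovery's other allele, in which case the target dosage must be
    reflected (2 - dosage) before weighting. SNPs whose allele pair cannot
    be reconciled are dropped with a logged count.
    """
    for name, tab in (("target_snps", target_snps), ("sumstats", sumstats)):
        if tab["snp_id"].duplicated().any():
            dups = tab["snp_id"][tab["snp_id"].duplicated()].unique().tolist()
            raise ValueError(f"{name} contains duplicated snp_id(s): {dups[:5]}")
    merged = sumstats.merge(
        target_snps[["snp_id", "effect_allele", "other_allele"]],
        on="snp_id", suffixes=("", "_target"),
    )
    # a target table parsed from bare .raw carries no other-allele info ("N");
    # fall back to matching on the effect-allele column alone
    unknown = merged["other_allele_target"] == "N"
    same = ((merged["effect_allele"] == merged["effect_allele_target"])
            & ((merged["other_allele"] == merged["other_allele_target"]) | unknown))
    flipped = ((merged["other_allele"] == merged["effect_allele_target"])
               & ((merged["effect_allele"] == merged["other_allele_target"]) | unknown))
    unresolved = ~(same | flipped)
    if unresolved.any():
        logger.info("dropping %d SNP(s) with irreconcilable allele codings",
                    int(unresolved.sum()))
    out = merged[~unresolved].copy()
    out["flip"] = flipped[~unresolved].to_numpy()
    return out.drop(columns=["effect_allele_target", "other_allele_target"])


def build_scores(genotypes: GenotypeMatrix, sumstats: pd.DataFrame,
                 thresholds=DEFAULT_THRESHOLDS, mode: str = "avg") -> list[ScoreSet]:
    """Polygenic scores in a target cohort across a p-value threshold series.

    For each threshold, score_i = sum_j w_j d_ij / (2 * |S_i|) with
    ``mode="avg"`` (|S_i| = SNPs non-missing for individual i) or the plain
    weighted sum with ``mode="sum"``. Missing dosages are excluded from
    numerator and denominator. Raises if a threshold selects no usable SNP.
    """
    if mode not in ("avg", "sum"):
        raise ValueError(f"mode must be 'avg' or 'sum', got {mode!r}")
    thresholds = sorted(float(t) for t in thresholds)
    if any(not (0.0 < t <= 1.0) for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")

    aligned = align_alleles(genotypes.snps, sumstats)
    aligned = aligned.sort_values("snp_id", kind="stable").reset_index(drop=True)
    cols = genotypes.snp_indices(aligned["snp_id"])
    dosage = genotypes.dosage[:, cols]
    dosage = np.where(aligned["flip"].to_numpy()[None, :], 2.0 - dosage, dosage)
    weights = np.sign(aligned["beta"].to_numpy()) * (-np.log10(aligned["p_value"].to_numpy()))

    out: list[ScoreSet] = []
    for thr in thresholds:
        in_thr_discovery = int((sumstats["p_value"] <= thr).sum())
        sel = (aligned["p_value"] <= thr).to_numpy()
        if not sel.any():
            raise ValueError(f"no scored SNPs at threshold p <= {thr}")
        d = dosage[:, sel]
        w = weights[sel]
        missing = np.isnan(d)
        num = np.where(missing, 0.0, d) @ w
        if mode == "avg":
            denom = 2.0 * (~missing).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.where(denom > 0, num / denom, np.nan)
        else:
            vals = num
        out.append(ScoreSet(
            threshold=thr,
            scores=pd.Series(vals, index=pd.Index(genotypes.individual_ids,
                                                  name="individual_id")),
            n_snps_in_threshold=in_thr_discovery,
            n_snps_used=int(sel.sum()),
        ))
    return out
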