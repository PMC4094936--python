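"""Polygenic association, gene-environment correlation, twin heritability.

Association between score and outcome is tested with Pearson partial
correlations controlling for sex (double residualization). rGE is the
plain Pearson correlation of the score with each environment scale. The
Falconer heuristic 2 * (rMZ - rDZ) converts MZ/DZ twin correlations into
an additive-heritability estimate. A drop-one-per-family utility supports
the non-independence sensitivity re-run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._regress import qr_basis, residualize
from .datatypes import ScoreSet


def partial_correlation(x, y, covariates=None):
    """Pearson correlation of x and y after removing covariates from both.

    Returns (r, p, n). Both variables are residualized on
    [intercept, covariates] by OLS; p is two-sided from
    t = r * sqrt((n - k - 2) / (1 - r^2)) with k covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-d vectors")
    n = len(x)
    if covariates is None:
        c = np.empty((n, 0))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
    k = c.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations (n={n}, k={k})")
    q = qr_basis(np.column_stack([np.ones(n), c]))
    rx = residualize(x[:, None], q)[:, 0]
    ry = residualize(y[:, None], q)[:, 0]
    xx, yy = float(rx @ rx), float(ry @ ry)
    # residual variance numerically zero relative to the raw variable
    if (xx <= 1e-20 * max(np.var(x) * n, 1e-30)
            or yy <= 1e-20 * max(np.var(y) * n, 1e-30)):
        raise ValueError("zero residual variance; partial correlation undefined")
    # xx * yy is symmetric in x and y, so r is exactly symmetric too
    r = float((rx @ ry) / np.sqrt(xx * yy))
    r = max(-1.0, min(1.0, r))
    df = n - k - 2
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p, n


def associate_scores(scores: list[ScoreSet], cohort: pd.DataFrame,
                     outcome: str = "alcohol_problems",
                     covariates: tuple[str, ...] = ("sex",)) -> pd.DataFrame:
    """Partial-correlation association of each threshold score with the outcome.

    Returns a tidy table (threshold, partial_r, p_value, variance_explained,
    n); the mean variance explained across thresholds is stored in
    ``result.attrs["mean_variance_explained"]``.
    """
    rows = []
    ids = cohort["individual_id"].to_numpy()
    for ss in scores:
        missing = [i for i in ids if i not in ss.scores.index]
        if missing:
            raise ValueError(f"score set {ss.threshold} lacks individual(s) "
                             f"{missing[:5]}")
        x = ss.scores.loc[ids].to_numpy()
        y = cohort[outcome].to_numpy(dtype=float)
        cov = cohort[list(covariates)].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(cov).any(axis=1))
        r, p, n = partial_correlation(x[ok], y[ok], cov[ok])
        rows.append({"threshold": ss.threshold, "partial_r": r, "p_value": p,
                     "variance_explained": r * r, "n": n})
    out = pd.DataFrame(rows)
    out.attrs["mean_variance_explained"] = float(out["variance_explained"].mean())
    return out


def rge_correlations(score: ScoreSet, cohort: pd.DataFrame,
                     environments: tuple[str, ...] = ("parental_knowledge",
                                                      "peer_deviance")) -> pd.DataFrame:
    """Gene-environment correlation: Pearson r of score with each environment."""
    ids = cohort["individual_id"].to_numpy()
    x = score.scores.loc[ids].to_numpy()
    rows = []
    for env in environments:
        e = cohort[env].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(e))
        if np.std(e[ok]) == 0:
            raise ValueError(f"environment {env!r} is constant")
        r, p = stats.pearsonr(x[ok], e[ok])
        rows.append({"environment": env, "r": float(r), "p_value": float(p),
                     "n": int(ok.sum())})
    return pd.DataFrame(rows)


def falconer_h2(r_mz: float, r_dz: float) -> float:
    """Falconer heritability heuristic 2 * (rMZ - rDZ), clipped to [0, 1].

    MZ co-twins share all, DZ co-twins half of their additive genetic
    variation, so twice the correlation difference estimates the additive
    genetic variance fraction under equal shared environments.
    """
    for name, r in (("r_mz", r_mz), ("r_dz", r_dz)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [-1, 1], got {r}")
    h2 = 2.0 * (r_mz - r_dz)
    if not 0.0 <= h2 <= 1.0:
        warnings.warn(f"Falconer estimate {h2:.3f} outside [0, 1]; clipping",
                      stacklevel=2)
        h2 = max(0.0, min(1.0, h2))
    return h2


def twin_correlations(cohort: pd.DataFrame,
                      value: str = "alcohol_problems") -> dict[str, float]:
    """Double-entry MZ and DZ co-twin Pearson correlations of ``value``.

    Each complete pair contributes both orderings (the intraclass
    convention of the twin literature). Returns {"MZ": r, "DZ": r, ...}
    with pair counts under "n_MZ"/"n_DZ".
    """
    out: dict[str, float] = {}
    for zyg in ("MZ", "DZ"):
        sub = cohort[cohort["zygosity"] == zyg]
        sizes = sub.groupby("family_id")["individual_id"].size()
        fams = sizes[sizes == 2].index
        pairs = sub[sub["family_id"].isin(fams)].sort_values(
            ["family_id", "individual_id"])
        a = pairs.groupby("family_id")[value].nth(0).to_numpy(dtype=float)
        b = pairs.groupby("family_id")[value].nth(1).to_numpy(dtype=float)
        if len(a) < 3:
            raise ValueError(f"too few complete {zyg} pairs ({len(a)})")
        x = np.concatenate([a, b])
        y = np.concatenate([b, a])
        out[zyg] = float(np.corrcoef(x, y)[0, 1])
        out[f"n_{zyg}"] = len(a)
    return out


def drop_one_per_family(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Retain one randomly chosen member of each two-member family.

    Singletons are kept as-is. Used to verify that association and
    moderation results are not driven by the non-independence of twins.
    """
    rng = np.random.default_rng(seed)
    keep = []
    for _, group in cohort.groupby("family_id", sort=True):
        idx = group.index.to_numpy()
        if len(idx) == 1:
            keep.append(idx[0])
        else:
            keep.append(idx[rng.integers(0, len(idx))])
    return cohort.loc[sorted(keep)].reset_index(drop=True)
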