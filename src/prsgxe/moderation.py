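"""Moderated multiple regression: does the environment moderate polygenic risk?

The core model regresses alcohol problems on sex, the (centered) polygenic
score, the (centered) environment, and their product:

    y = b0 + b1*sex + b2*score_c + b3*env_c + b4*(score_c * env_c) + e

Centering the score and environment before forming the product reduces
collinearity without changing the interaction estimate. Hierarchical
delta-R^2 follows the fixed entry order sex -> score -> environment ->
interaction. Sensitivity utilities cover the rGE residualization control
and the log10(y + 1) scale check; predicted values on a +/-1 SD grid
support interaction plots, with negative predictions clamped to the
scale floor of zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import ModerationResult, ScoreSet

TERMS = ("intercept", "sex", "score", "environment", "score_x_environment")


def center(v) -> np.ndarray:
    """Subtract the mean; result has mean zero to machine precision."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("cannot center an empty vector")
    return v - v.mean()


def _score_vector(score, cohort: pd.DataFrame) -> np.ndarray:
    if isinstance(score, ScoreSet):
        return score.scores.loc[cohort["individual_id"].to_numpy()].to_numpy()
    s = np.asarray(score, dtype=float)
    if s.shape[0] != len(cohort):
        raise ValueError("score vector does not align with cohort rows")
    return s


def fit_moderation(cohort: pd.DataFrame, score, environment: str,
                   outcome: str = "alcohol_problems",
                   outcome_transform=None) -> ModerationResult:
    """Fit the moderated regression for one environment.

    ``score`` may be a ScoreSet (aligned by individual_id) or a raw
    vector. Score and environment are centered on the analysis sample
    before the product term is formed; sex stays on its raw 0/1 coding.
    Listwise deletion is applied, and the listwise-complete n is used for
    all inference. delta-R^2 comes from explicitly refit nested models.
    """
    if environment not in cohort.columns:
        raise KeyError(f"environment column {environment!r} not in cohort")
    s = _score_vector(score, cohort)
    y = cohort[outcome].to_numpy(dtype=float)
    e = cohort[environment].to_numpy(dtype=float)
    sex = cohort["sex"].to_numpy(dtype=float)
    ok = ~(np.isnan(s) | np.isnan(y) | np.isnan(e) | np.isnan(sex))
    s, y, e, sex = s[ok], y[ok], e[ok], sex[ok]
    if outcome_transform is not None:
        y = np.asarray(outcome_transform(y), dtype=float)
    n = len(y)

    s_c = center(s)
    e_c = center(e)
    x_full = np.column_stack([np.ones(n), sex, s_c, e_c, s_c * e_c])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        # name the offending columns via near-zero diagonal of R in QR
        r = np.linalg.qr(x_full, mode="r")
        scale = np.abs(np.diag(r))
        bad = [TERMS[i] for i in np.flatnonzero(scale < 1e-10 * max(scale.max(), 1.0))]
        raise ValueError(f"design matrix is rank deficient; collinear term(s): {bad}")

    fits = []
    for ncol in (1, 2, 3, 4, 5):
        fits.append(sm.OLS(y, x_full[:, :ncol]).fit())
    full = fits[-1]

    coef = pd.DataFrame({
        "b": full.params,
        "se": full.bse,
        "t": full.tvalues,
        "p": full.pvalues,
    }, index=pd.Index(TERMS, name="term"))
    r2 = [f.rsquared for f in fits]
    delta = pd.Series(np.diff(r2), index=pd.Index(TERMS[1:], name="term"))

    return ModerationResult(
        environment=environment,
        coefficients=coef,
        delta_r2=delta,
        total_r2=float(full.rsquared),
        n=n,
        score_mean=float(s.mean()),
        score_sd=float(s.std(ddof=1)),
        env_mean=float(e.mean()),
        env_sd=float(e.std(ddof=1)),
        sex_mean=float(sex.mean()),
        resid_sd=float(full.resid.std(ddof=0)),
        outcome=outcome,
    )


def residualize_pair(score, environment):
    """Mutually residualize a score/environment pair to remove rGE.

    Returns (score_resid, env_resid): the residuals of score ~ [1, env]
    and environment ~ [1, score]. Each residual is exactly uncorrelated
    with the other raw variable, which statistically eliminates
    gene-environment correlation from a subsequent moderation model.
    """
    s = np.asarray(score, dtype=float)
    e = np.asarray(environment, dtype=float)
    if s.shape != e.shape:
        raise ValueError("score and environment must be aligned")
    if np.std(s) == 0 or np.std(e) == 0:
        raise ValueError("constant input; residualization undefined")
    s_c, e_c = center(s), center(e)
    s_resid = s_c - (s_c @ e_c) / (e_c @ e_c) * e_c
    e_resid = e_c - (e_c @ s_c) / (s_c @ s_c) * s_c
    return s_resid, e_resid


def fit_moderation_residualized(cohort: pd.DataFrame, score, environment: str,
                                outcome: str = "alcohol_problems") -> ModerationResult:
    """rGE control: refit the moderation with mutually residualized variables."""
    s = _score_vector(score, cohort)
    e = cohort[environment].to_numpy(dtype=float)
    y = cohort[outcome].to_numpy(dtype=float)
    sex = cohort["sex"].to_numpy(dtype=float)
    ok = ~(np.isnan(s) | np.isnan(e) | np.isnan(y) | np.isnan(sex))
    sub = cohort.loc[ok].copy()
    s_resid, e_resid = residualize_pair(s[ok], e[ok])
    sub = sub.assign(**{environment: e_resid})
    return fit_moderation(sub, s_resid, environment, outcome=outcome)


def log_sensitivity(cohort: pd.DataFrame, score, environment: str,
                    outcome: str = "alcohol_problems") -> ModerationResult:
    """Scale-sensitivity check: refit with outcome log10(y + 1)."""
    return fit_moderation(cohort, score, environment, outcome=outcome,
                          outcome_transform=lambda y: np.log10(y + 1.0))


def predicted_values(result: ModerationResult, sd_multiple: float = 1.0) -> pd.DataFrame:
    """Model-implied outcome at low/high (+/- 1 SD) score and environment.

    Predictions are formed from the fitted equation with sex at its sample
    mean; negative predictions are clamped to zero, the floor of the
    outcome scale, with the ``clamped`` flag set. The ``error_bar`` column
    is SD(model residuals) / sqrt(n).
    """
    b = result.coefficients["b"]
    rows = []
    err = result.resid_sd / np.sqrt(result.n)
    for s_label, s_mult in (("low", -sd_multiple), ("high", sd_multiple)):
        for e_label, e_mult in (("low", -sd_multiple), ("high", sd_multiple)):
            s_c = s_mult * result.score_sd
            e_c = e_mult * result.env_sd
            pred = (b["intercept"] + b["sex"] * result.sex_mean
                    + b["score"] * s_c + b["environment"] * e_c
                    + b["score_x_environment"] * s_c * e_c)
            clamped = pred < 0
            rows.append({
                "score_level": s_label,
                "env_level": e_label,
                "score_value": result.score_mean + s_c,
                "env_value": result.env_mean + e_c,
                "predicted": max(pred, 0.0),
                "unclamped": float(pred),
                "clamped": bool(clamped),
                "error_bar": err,
            })
    return pd.DataFrame(rows)
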