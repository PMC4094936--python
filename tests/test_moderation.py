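"""Moderated regression: oracle equivalence, centering invariance, sensitivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import prsgxe as P
from helpers import ols_oracle


def toy_cohort(rng, n=150, gamma=0.0):
    sex = rng.integers(0, 2, n).astype(float)
    score = rng.standard_normal(n) * 0.02 - 0.07
    env = rng.integers(4, 17, n).astype(float)
    s_c, e_c = score - score.mean(), env - env.mean()
    lam = np.exp(-1.5 + 0.2 * sex + 3.0 * s_c + 0.1 * e_c + gamma * s_c * e_c)
    y = rng.poisson(np.clip(lam, 0, 20))
    cohort = pd.DataFrame({
        "individual_id": [f"I{i}" for i in range(n)],
        "family_id": [f"F{i}" for i in range(n)],
        "zygosity": "DZ",
        "sex": sex.astype(int),
        "alcohol_problems": np.minimum(y, 30),
        "parental_knowledge": env.astype(int),
        "peer_deviance": rng.integers(4, 17, n),
    })
    return cohort, score


def test_center():
    assert np.allclose(P.center([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])
    assert np.allclose(P.center([5.0, 5.0, 5.0]), 0.0)
    v = np.array([-1.0, 0.5, 0.5])
    assert np.allclose(P.center(v), v)
    with pytest.raises(ValueError):
        P.center([])


def test_matches_nested_refit_oracle(rng):
    cohort, score = toy_cohort(rng, gamma=0.5)
    res = P.fit_moderation(cohort, score, "parental_knowledge")
    n = len(cohort)
    sex = cohort["sex"].to_numpy(float)
    y = cohort["alcohol_problems"].to_numpy(float)
    s_c = score - score.mean()
    e = cohort["parental_knowledge"].to_numpy(float)
    e_c = e - e.mean()
    x = np.column_stack([np.ones(n), sex, s_c, e_c, s_c * e_c])
    beta, se, t, p = ols_oracle(y, x)
    assert np.allclose(res.coefficients["b"], beta, atol=1e-8)
    assert np.allclose(res.coefficients["se"], se, atol=1e-8)
    assert np.allclose(res.coefficients["t"], t, atol=1e-8)
    assert np.allclose(res.coefficients["p"], p, atol=1e-10)

    # delta R^2 from explicitly refit nested models
    def r2(xx):
        b = np.linalg.pinv(xx.T @ xx) @ xx.T @ y
        resid = y - xx @ b
        return 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

    r2s = [r2(x[:, :k]) for k in range(1, 6)]
    assert np.allclose(res.delta_r2, np.diff(r2s), atol=1e-10)
    assert res.delta_r2.sum() == pytest.approx(res.total_r2, abs=1e-10)
    assert (res.delta_r2 >= -1e-12).all()


def test_interaction_invariant_to_centering(rng):
    cohort, score = toy_cohort(rng, gamma=0.4)
    res_centered = P.fit_moderation(cohort, score, "parental_knowledge")
    # refit with raw (uncentered) score and environment, by hand
    n = len(cohort)
    y = cohort["alcohol_problems"].to_numpy(float)
    e = cohort["parental_knowledge"].to_numpy(float)
    x_raw = np.column_stack([np.ones(n), cohort["sex"], score, e, score * e])
    beta, se, t, p = ols_oracle(y, x_raw)
    inter = res_centered.interaction
    assert inter["b"] == pytest.approx(beta[4], abs=1e-8)
    assert inter["p"] == pytest.approx(p[4], abs=1e-8)


def test_rank_deficiency_names_collinear_terms(rng):
    cohort, score = toy_cohort(rng)
    cohort["parental_knowledge"] = 8            # constant environment
    with pytest.raises(ValueError, match="environment"):
        P.fit_moderation(cohort, score, "parental_knowledge")


def test_residualize_pair_properties(rng):
    s = rng.standard_normal(100)
    e = 0.3 * s + rng.standard_normal(100)
    s_r, e_r = P.residualize_pair(s, e)
    assert abs(np.corrcoef(s_r, e)[0, 1]) < 1e-10
    assert abs(np.corrcoef(e_r, s)[0, 1]) < 1e-10
    # uncorrelated pair: residuals equal the centered inputs
    e_ind = rng.standard_normal(100)
    e_ind = e_ind - e_ind.mean()
    basis = (s - s.mean()) / np.linalg.norm(s - s.mean())
    e_ind = e_ind - basis * (basis @ e_ind)     # exactly orthogonal to s
    s_r2, e_r2 = P.residualize_pair(s, e_ind + 7.0)
    assert np.allclose(s_r2, s - s.mean(), atol=1e-10)
    assert np.allclose(e_r2, e_ind, atol=1e-10)
    # perfectly correlated pair: residuals vanish
    s_r3, e_r3 = P.residualize_pair(s, 2 * s + 1)
    assert np.allclose(s_r3, 0.0, atol=1e-10)
    assert np.allclose(e_r3, 0.0, atol=1e-10)
    with pytest.raises(ValueError, match="constant"):
        P.residualize_pair(np.ones(10), np.arange(10.0))


def test_residualized_refit_matches_projection_oracle(rng):
    cohort, score = toy_cohort(rng, gamma=0.5)
    env = "parental_knowledge"
    res = P.fit_moderation_residualized(cohort, score, env)
    n = len(cohort)
    e = cohort[env].to_numpy(float)
    y = cohort["alcohol_problems"].to_numpy(float)

    def project_out(v, u):
        u = np.column_stack([np.ones(n), u])
        proj = u @ np.linalg.pinv(u.T @ u) @ u.T    # explicit projection matrix
        return v - proj @ v

    s_r = project_out(score, e)
    e_r = project_out(e, score)
    x = np.column_stack([np.ones(n), cohort["sex"],
                         s_r - s_r.mean(), e_r - e_r.mean(),
                         (s_r - s_r.mean()) * (e_r - e_r.mean())])
    beta, se, t, p = ols_oracle(y, x)
    assert np.allclose(res.coefficients["b"], beta, atol=1e-8)
    assert np.allclose(res.coefficients["p"], p, atol=1e-8)


def test_log_transform_arithmetic(rng):
    cohort, score = toy_cohort(rng)
    cohort["alcohol_problems"] = 0
    res = P.log_sensitivity(cohort, score, "peer_deviance")
    # log10(0 + 1) = 0 everywhere: R^2 undefined but coefficients all zero
    assert np.allclose(res.coefficients["b"].iloc[1:], 0.0, atol=1e-12)
    vals = np.array([0, 9, 99] * 50)
    assert np.allclose(np.log10(vals + 1.0), np.array([0, 1, 2] * 50))


def test_log_scale_attenuates_multiplicative_interaction():
    """On a multiplicative-noise outcome the log scale weakens the raw-scale interaction."""
    raw_t, log_t = [], []
    for rep in range(200):
        rng = np.random.default_rng(3000 + rep)
        cohort, score = toy_cohort(rng, n=400, gamma=0.6)
        raw = P.fit_moderation(cohort, score, "parental_knowledge")
        logged = P.log_sensitivity(cohort, score, "parental_knowledge")
        raw_t.append(abs(raw.interaction["t"]))
        log_t.append(abs(logged.interaction["t"]))
    assert np.mean(raw_t) > np.mean(log_t)


def test_predicted_values_match_hand_grid():
    res = P.ModerationResult(
        environment="parental_knowledge",
        coefficients=pd.DataFrame(
            {"b": [0.16, 0.23, 3.10, 0.14, 1.54],
             "se": np.nan, "t": np.nan, "p": np.nan},
            index=pd.Index(["intercept", "sex", "score", "environment",
                            "score_x_environment"], name="term")),
        delta_r2=pd.Series([0.006, 0.006, 0.088, 0.003],
                           index=["sex", "score", "environment",
                                  "score_x_environment"]),
        total_r2=0.103, n=1115, score_mean=-0.07, score_sd=0.02,
        env_mean=6.62, env_sd=2.08, sex_mean=0.53, resid_sd=0.91)
    grid = P.predicted_values(res).set_index(["score_level", "env_level"])
    for s_m, s_lab in ((-0.02, "low"), (0.02, "high")):
        for e_m, e_lab in ((-2.08, "low"), (2.08, "high")):
            hand = (0.16 + 0.23 * 0.53 + 3.10 * s_m + 0.14 * e_m
                    + 1.54 * s_m * e_m)
            row = grid.loc[(s_lab, e_lab)]
            assert row["unclamped"] == pytest.approx(hand, abs=1e-12)
            assert row["predicted"] == pytest.approx(max(hand, 0.0), abs=1e-12)
            assert row["clamped"] == (hand < 0)
            assert row["error_bar"] == pytest.approx(0.91 / np.sqrt(1115))


def test_predicted_values_interaction_geometry(rng):
    cohort, score = toy_cohort(rng, n=400, gamma=0.0)
    res = P.fit_moderation(cohort, score, "parental_knowledge")
    res.coefficients.loc["score_x_environment", "b"] = 0.0
    grid = P.predicted_values(res).set_index(["score_level", "env_level"])
    gap_low = (grid.loc[("high", "low"), "unclamped"]
               - grid.loc[("low", "low"), "unclamped"])
    gap_high = (grid.loc[("high", "high"), "unclamped"]
                - grid.loc[("low", "high"), "unclamped"])
    assert gap_low == pytest.approx(gap_high, abs=1e-10)  # parallel lines

    res.coefficients.loc["score_x_environment", "b"] = 0.8
    grid = P.predicted_values(res).set_index(["score_level", "env_level"])
    gap_low = (grid.loc[("high", "low"), "unclamped"]
               - grid.loc[("low", "low"), "unclamped"])
    gap_high = (grid.loc[("high", "high"), "unclamped"]
                - grid.loc[("low", "high"), "unclamped"])
    assert gap_high > gap_low   # genetic effect larger in the risky environment


@given(shift=st.floats(-5, 5), scale=st.floats(0.2, 3))
def test_center_is_idempotent_and_affine(shift, scale):
    rng = np.random.default_rng(8)
    v = rng.standard_normal(25)
    c = P.center(scale * v + shift)
    assert abs(c.mean()) < 1e-10
    assert np.allclose(c, scale * P.center(v), atol=1e-9)
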