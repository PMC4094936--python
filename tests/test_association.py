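"""Partial correlations, rGE, Falconer heritability, drop-one utility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import prsgxe as P


def test_orthogonal_covariate_equals_plain_pearson(rng):
    n = 200
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    z = rng.standard_normal(n)
    # orthogonalize z against both x and y (and the intercept)
    basis = np.linalg.qr(np.column_stack([np.ones(n), x, y]))[0]
    z = z - basis @ (basis.T @ z)
    r, p, _ = P.partial_correlation(x, y, z)
    plain = stats.pearsonr(x, y)
    assert r == pytest.approx(plain.statistic, abs=1e-10)


def test_identical_vectors_give_r_one(rng):
    x = rng.standard_normal(50)
    r, p, n = P.partial_correlation(x, x.copy(), rng.standard_normal(50))
    assert r == pytest.approx(1.0, abs=1e-12)
    assert p == 0.0


def test_first_order_partial_matches_closed_form(rng):
    """r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))"""
    n = 40
    z = rng.standard_normal(n)
    x = 0.5 * z + rng.standard_normal(n)
    y = -0.3 * z + rng.standard_normal(n)
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    closed = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r, p, nn = P.partial_correlation(x, y, z)
    assert r == pytest.approx(closed, abs=1e-10)
    t = closed * np.sqrt((n - 3) / (1 - closed**2))
    assert p == pytest.approx(2 * stats.t.sf(abs(t), n - 3), rel=1e-9)


@given(seed=st.integers(0, 500))
def test_partial_correlation_symmetric_in_x_y(seed):
    rng = np.random.default_rng(seed)
    x, y, z = rng.standard_normal((3, 30))
    r1, p1, _ = P.partial_correlation(x, y, z)
    r2, p2, _ = P.partial_correlation(y, x, z)
    assert r1 == r2 and p1 == p2


def test_partial_r_invariant_to_affine_sex_recoding(rng):
    x, y = rng.standard_normal((2, 100))
    sex = rng.integers(0, 2, 100).astype(float)
    r1, p1, _ = P.partial_correlation(x, y, sex)
    r2, p2, _ = P.partial_correlation(x, y, 2 * sex - 5)
    assert r1 == pytest.approx(r2, abs=1e-12)
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_zero_residual_variance_rejected(rng):
    z = rng.standard_normal(30)
    with pytest.raises(ValueError, match="residual variance"):
        P.partial_correlation(2 * z + 1, rng.standard_normal(30), z)


def _toy_cohort_and_scores(rng, n=120):
    cohort = pd.DataFrame({
        "individual_id": [f"I{i}" for i in range(n)],
        "family_id": [f"F{i // 2}" for i in range(n)],
        "zygosity": "DZ",
        "sex": rng.integers(0, 2, n),
        "alcohol_problems": rng.poisson(0.4, n),
        "parental_knowledge": rng.integers(4, 17, n),
        "peer_deviance": rng.integers(4, 17, n),
    })
    scores = [P.ScoreSet(threshold=t,
                         scores=pd.Series(rng.standard_normal(n),
                                          index=cohort["individual_id"]),
                         n_snps_in_threshold=50, n_snps_used=40)
              for t in (0.05, 0.5)]
    return cohort, scores


def test_associate_scores_composes_partial_correlation(rng):
    cohort, scores = _toy_cohort_and_scores(rng)
    res = P.associate_scores(scores, cohort)
    for row, ss in zip(res.itertuples(), scores):
        r, p, n = P.partial_correlation(
            ss.scores.loc[cohort["individual_id"]].to_numpy(),
            cohort["alcohol_problems"].to_numpy(dtype=float),
            cohort["sex"].to_numpy(dtype=float))
        assert row.partial_r == pytest.approx(r, abs=1e-12)
        assert row.p_value == pytest.approx(p, abs=1e-12)
        assert row.variance_explained == pytest.approx(r * r, abs=1e-12)
    assert res.attrs["mean_variance_explained"] == pytest.approx(
        res["variance_explained"].mean())


def test_shuffled_scores_are_null(rng):
    pvals = []
    for rep in range(200):
        local = np.random.default_rng(rep)
        cohort, scores = _toy_cohort_and_scores(local)
        res = P.associate_scores(scores[:1], cohort)
        pvals.append(res["p_value"].iloc[0])
    assert np.mean(np.array(pvals) < 0.05) == pytest.approx(0.05, abs=0.05)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_rge_correlation_matches_hand_computation():
    table = pd.DataFrame({
        "individual_id": [f"I{i}" for i in range(10)],
        "parental_knowledge": [4, 6, 8, 5, 7, 9, 10, 6, 5, 8],
        "peer_deviance": [7, 7, 8, 4, 5, 6, 9, 10, 4, 5],
    })
    score = P.ScoreSet(threshold=0.05,
                       scores=pd.Series([0.1, -0.2, 0.3, 0.0, 0.2, 0.5, 0.4,
                                         -0.1, -0.3, 0.25],
                                        index=table["individual_id"]),
                       n_snps_in_threshold=5, n_snps_used=5)
    res = P.rge_correlations(score, table).set_index("environment")
    for env in ("parental_knowledge", "peer_deviance"):
        hand = np.corrcoef(score.scores, table[env])[0, 1]
        assert res.loc[env, "r"] == pytest.approx(hand, abs=1e-12)


def test_rge_null_and_positive_direction():
    null_rs, pos_rs = [], []
    for rep in range(100):
        cfg = P.SimulationConfig(n_discovery=10, n_target_pairs=250, n_snps=80,
                                 n_causal=20, gxe_coef=0.0, seed=5000 + rep,
                                 rge_corr={"parental_knowledge": 0.0,
                                           "peer_deviance": 0.25})
        geno = P.simulate_genotypes(cfg, "target")
        cohort = P.simulate_phenotypes(geno, cfg)
        g = cohort.latent["genetic_std"].to_numpy()
        null_rs.append(np.corrcoef(g, cohort.table["parental_knowledge"])[0, 1])
        pos_rs.append(np.corrcoef(g, cohort.table["peer_deviance"])[0, 1])
    n = 500
    assert abs(np.mean(null_rs)) < 3 / np.sqrt(n * 100)
    assert np.mean(np.array(pos_rs) > 0) > 0.95  # sign test


@pytest.mark.parametrize("r_mz,r_dz,expected", [
    (0.53, 0.36, 0.34),       # the twin-correlation worked example
    (0.4, 0.4, 0.0),
    (1.0, 0.5, 1.0),
])
def test_falconer_formula(r_mz, r_dz, expected):
    assert P.falconer_h2(r_mz, r_dz) == pytest.approx(expected, abs=1e-12)


def test_falconer_clips_with_warning():
    with pytest.warns(UserWarning, match="clipping"):
        assert P.falconer_h2(0.9, 0.1) == 1.0
    with pytest.warns(UserWarning, match="clipping"):
        assert P.falconer_h2(0.1, 0.3) == 0.0
    with pytest.raises(ValueError):
        P.falconer_h2(1.2, 0.3)


def test_twin_correlations_double_entry(small_study):
    _, _, _, targ = small_study
    tc = P.twin_correlations(targ.table)
    assert -1 <= tc["DZ"] <= tc["MZ"] <= 1
    assert tc["n_MZ"] + tc["n_DZ"] == 120


def test_drop_one_per_family_count_and_determinism(rng):
    cohort, _ = _toy_cohort_and_scores(rng, n=1000)  # 500 two-member families
    sub1 = P.drop_one_per_family(cohort, seed=11)
    sub2 = P.drop_one_per_family(cohort, seed=11)
    assert len(sub1) == 500
    assert sub1["family_id"].is_unique
    pd.testing.assert_frame_equal(sub1, sub2)


def test_drop_one_choice_frequencies_binomial(rng):
    cohort, _ = _toy_cohort_and_scores(rng, n=40)  # 20 families
    first_kept = np.zeros(20)
    n_seeds = 1000
    for seed in range(n_seeds):
        sub = P.drop_one_per_family(cohort, seed=seed)
        kept_first = sub["individual_id"].str[1:].astype(int) % 2 == 0
        first_kept += kept_first.to_numpy()
    freq = first_kept / n_seeds
    assert np.all(np.abs(freq - 0.5) < 4 * np.sqrt(0.25 / n_seeds))
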