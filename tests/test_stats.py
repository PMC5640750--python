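import numpy as np
import pandas as pd
import pytest

from stopchange import (bonferroni_pairwise, coordinate_ttest, fit_ic_model,
                        quadratic_trend, rm_anova)
from stopchange.simulate import simulate_score_cohort


def _wide(Y):
    """(n, 6) latency array -> the bird x trial DataFrame rm_anova eats."""
    return pd.DataFrame(Y, columns=[1, 2, 3, 4, 5, 6],
                        index=[f"b{i}" for i in range(len(Y))])


def _random_wide(n=20, seed=0, block_effect=0.0, sd=1.0):
    rng = np.random.default_rng(seed)
    base = 8.0 + rng.standard_normal((n, 1)) * 2.0
    Y = base + sd * rng.standard_normal((n, 6))
    Y[:, 3:] -= block_effect
    return _wide(Y)


# --- repeated-measures ANOVA --------------------------------------------

def test_constant_latencies_give_zero_F():
    res = rm_anova(_wide(np.full((8, 6), 7.0)))
    assert (res.table["F"] == 0).all()
    assert (res.table["p"] == 1).all()


def test_incomplete_layout_rejected():
    w = _random_wide(6)
    w.iloc[2, 4] = np.nan
    with pytest.raises(ValueError, match="b2"):
        rm_anova(w)
    with pytest.raises(ValueError, match="missing trial"):
        rm_anova(w.drop(columns=[5]))


def test_sums_of_squares_decomposition():
    res = rm_anova(_random_wide(25, seed=3))
    ss = res.ss
    parts = (ss["subjects"] + ss["Block"] + ss["TrialType"]
             + ss["Block:TrialType"] + ss["Block:subj"]
             + ss["TrialType:subj"] + ss["residual"])
    assert parts == pytest.approx(ss["total"], abs=1e-9)


def test_matches_statsmodels_anova_rm():
    from statsmodels.stats.anova import AnovaRM

    w = _random_wide(15, seed=7, block_effect=1.5)
    res = rm_anova(w)
    long = w.stack().rename("lat").reset_index()
    long.columns = ["bird", "trial", "lat"]
    long["blk"] = np.where(long["trial"] <= 3, 1, 2)
    long["pos"] = (long["trial"] - 1) % 3
    sm = AnovaRM(long, "lat", "bird", within=["blk", "pos"]).fit()
    tab = sm.anova_table
    ours = res.table.set_index("effect")
    for theirs, mine in (("blk", "Block"), ("pos", "TrialType"),
                         ("blk:pos", "Block:TrialType")):
        assert ours.loc[mine, "F"] == pytest.approx(
            tab.loc[theirs, "F Value"], rel=1e-9)
        assert ours.loc[mine, "p"] == pytest.approx(
            tab.loc[theirs, "Pr > F"], rel=1e-9)


def test_anova_invariant_to_bird_order():
    w = _random_wide(12, seed=5)
    r1 = rm_anova(w)
    r2 = rm_anova(w.iloc[::-1])
    pd.testing.assert_frame_equal(r1.table, r2.table)


# --- trend and post hocs -------------------------------------------------

def test_quadratic_contrast_on_block_means():
    res = quadratic_trend(np.array([[13.3, 8.5, 8.8]] * 5)
                          + np.random.default_rng(0).normal(0, 1e-9, (5, 3)))
    assert res["contrast"] == pytest.approx(13.3 - 2 * 8.5 + 8.8, abs=1e-6)
    assert res["contrast"] == pytest.approx(5.1, abs=1e-6)


def test_linear_ramp_annihilated():
    res = quadratic_trend(np.array([[2.0, 4.0, 6.0]] * 6))
    assert res["contrast"] == pytest.approx(0.0)
    assert res["F"] == 0.0


def test_v_shape_power_grows_with_n():
    rng = np.random.default_rng(2)
    ps = []
    for n in (6, 24, 96):
        V = np.array([6.0, 3.0, 6.0]) + rng.normal(0, 1.5, (n, 3))
        ps.append(quadratic_trend(V)["p"])
    assert ps[0] > ps[2]
    assert quadratic_trend(np.array([[6.0, 3.0, 6.0]] * 8
                                    + np.random.default_rng(1)
                                    .normal(0, .5, (8, 3))))["contrast"] > 0


def test_quadratic_trend_needs_two_birds():
    with pytest.raises(ValueError):
        quadratic_trend(np.array([[1.0, 2.0, 3.0]]))


def test_bonferroni_identical_trials():
    tab = bonferroni_pairwise(np.full((10, 3), 4.0), block=1)
    assert (tab["p_bonferroni"] == 1.0).all()


def test_bonferroni_never_below_raw():
    rng = np.random.default_rng(8)
    tab = bonferroni_pairwise(rng.normal(5, 2, (12, 3)))
    assert (tab["p_bonferroni"] >= tab["p_raw"] - 1e-15).all()
    assert (tab["p_bonferroni"] <= 1.0).all()


def test_paired_t_matches_textbook_formula():
    rng = np.random.default_rng(4)
    V = rng.normal(5, 2, (5, 3))
    tab = bonferroni_pairwise(V, block=2).set_index("pair")
    d = V[:, 0] - V[:, 1]
    t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    from scipy.stats import t as tdist
    p = 2 * tdist.sf(abs(t), len(d) - 1)
    row = tab.loc["first_go vs second_go"]
    assert row["t"] == pytest.approx(t, abs=1e-9)
    assert row["p_raw"] == pytest.approx(p, abs=1e-9)
    assert row["p_bonferroni"] == pytest.approx(min(1, 3 * p), abs=1e-9)


# --- coordinate tests ----------------------------------------------------

def test_symmetric_coordinates_give_t_zero():
    res = coordinate_ttest(np.array([-0.3, 0.3, -0.1, 0.1]))
    assert res["t"] == pytest.approx(0.0, abs=1e-12)
    assert res["p"] == pytest.approx(1.0)


def test_shifted_coordinates_match_closed_form():
    rng = np.random.default_rng(6)
    v = rng.normal(0, 0.2, 30) + 0.15
    res = coordinate_ttest(v)
    t = v.mean() / (v.std(ddof=1) / np.sqrt(len(v)))
    assert res["t"] == pytest.approx(t, abs=1e-12)
    assert res["df"] == 29


def test_single_value_rejected():
    with pytest.raises(ValueError):
        coordinate_ttest(np.array([0.4]))


# --- mixed model ---------------------------------------------------------

def test_null_simulation_estimates_near_zero():
    df = simulate_score_cohort(400, {}, seed=0)
    res = fit_ic_model(df)
    assert res.method == "mixedlm"
    tab = res.table.set_index("term")
    for term in ("sex_m", "body_size", "bwa", "to", "trial4_rt"):
        assert abs(tab.loc[term, "b"]) < 3 * tab.loc[term, "SE"] + 0.05
    assert not res.interaction_included


def test_injected_size_effect_recovered():
    df = simulate_score_cohort(300, {"body_size": -0.5}, seed=1,
                               noise_sd=0.5)
    res = fit_ic_model(df)
    tab = res.table.set_index("term")
    assert tab.loc["body_size", "b"] == pytest.approx(-0.5, abs=0.15)
    assert tab.loc["body_size", "p"] < 0.01


def test_sex_coding_reference_female():
    df = simulate_score_cohort(200, {"sex_m": 1.0}, seed=2, noise_sd=0.3)
    res = fit_ic_model(df)
    b_m = res.table.set_index("term").loc["sex_m", "b"]
    flipped = df.copy()
    flipped["sex"] = np.where(df["sex"] == "M", "F", "M")
    b_f = fit_ic_model(flipped).table.set_index("term").loc["sex_m", "b"]
    assert b_m == pytest.approx(-b_f, abs=1e-6)
    assert b_m == pytest.approx(1.0, abs=0.2)


def test_single_enclosure_falls_back_to_ols():
    df = simulate_score_cohort(120, {}, seed=3, n_enclosures=1)
    res = fit_ic_model(df)
    assert res.method == "ols-fallback"
    assert res.random_intercept_var == 0.0


def test_rank_deficient_design_rejected():
    df = simulate_score_cohort(100, {}, seed=4)
    df["to"] = df["bwa"] * 2.0
    with pytest.raises(ValueError, match="aliased|rank"):
        fit_ic_model(df)


def test_significant_interaction_is_kept():
    df = simulate_score_cohort(400, {"body_size": 0.2}, seed=5,
                               noise_sd=0.3)
    strong = df.copy()
    strong["ic_score"] += 1.5 * (strong["sex"] == "M") * strong["body_size"]
    res = fit_ic_model(strong)
    assert res.interaction_included
    assert "sex_m:body_size" in set(res.table["term"])
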