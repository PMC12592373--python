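"""Linear models on scores and regions, BH-FDR, matching, and ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskpls import (
    ModelSpec,
    anova_group_scores,
    bh_fdr,
    fit_linear_model,
    nearest_neighbor_match,
    regionwise_interaction,
)


def brute_force_bh(p, q):
    """Step-up rule straight from its definition: reject the i smallest
    p-values where p_(i) <= i*q/m for the largest such i."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


# ------------------------------------------------------------------ BH-FDR

def test_bh_fdr_hand_examples():
    _, rej = bh_fdr([0.01, 0.02, 0.04, 0.5], 0.05)
    assert rej.tolist() == [True, True, False, False]
    _, rej = bh_fdr([1.0, 1.0, 1.0], 0.05)
    assert not rej.any()
    _, rej = bh_fdr([0.04], 0.05)
    assert rej.all()  # m=1 reduces to the plain level


def test_bh_fdr_validates_inputs():
    with pytest.raises(ValueError):
        bh_fdr([0.1], q_level=0.0)
    with pytest.raises(ValueError):
        bh_fdr([1.5], q_level=0.05)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    p=st.lists(st.floats(0, 1), min_size=1, max_size=20),
    q=st.sampled_from([0.01, 0.05, 0.1, 0.2]),
)
def test_bh_fdr_matches_brute_force_step_up(p, q):
    adjusted, reject = bh_fdr(p, q)
    np.testing.assert_array_equal(reject, brute_force_bh(p, q))
    assert np.all(adjusted >= np.asarray(p) - 1e-12)  # q >= p elementwise


# ------------------------------------------------------------ linear models

def _cohort(n=300, seed=0, interaction=0.0):
    rng = np.random.default_rng(seed)
    age = rng.uniform(44, 82, n)
    sex = rng.random(n) < 0.5
    z_age = (age - age.mean()) / age.std(ddof=1)
    y = 0.3 * z_age - 0.2 * sex + interaction * z_age * sex + rng.standard_normal(n)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "age": age,
            "sex": np.where(sex, "female", "male"),
            "score": y,
        }
    )


def test_perfect_linear_outcome_gives_unit_standardized_beta():
    d = _cohort(n=50, seed=1)
    d["score"] = 2.0 * d["age"] + 3.0
    res = fit_linear_model(d, ModelSpec("score", ["age"]))
    assert res.term("age")["beta"] == pytest.approx(1.0)
    assert res.r_squared == pytest.approx(1.0)


def test_standardized_betas_invariant_to_affine_rescaling():
    d = _cohort(n=200, seed=2, interaction=0.3)
    spec = ModelSpec("score", ["age", "sex", "age:sex"])
    a = fit_linear_model(d, spec)
    d2 = d.copy()
    d2["age"] = d2["age"] * 12.0 + 7.0  # months with an offset
    b = fit_linear_model(d2, spec)
    np.testing.assert_allclose(a.table["beta"], b.table["beta"], atol=1e-10)


def test_planted_interaction_recovered_within_three_se():
    hits = 0
    for seed in range(10):
        d = _cohort(n=400, seed=seed, interaction=0.25)
        res = fit_linear_model(d, ModelSpec("score", ["age", "sex", "age:sex"]))
        row = res.table[res.table["term"].str.contains("age:")].iloc[0]
        # outcome z-scoring rescales betas by 1/sd(score), and the fitted
        # contrast may be the complementary sex indicator: compare magnitudes
        d_sd = d["score"].std(ddof=1)
        hits += abs(abs(row["beta"]) - 0.25 / d_sd) <= 3 * row["se"]
    assert hits >= 9


def test_rank_deficient_design_raises_with_aliased_terms():
    d = _cohort(n=100, seed=3)
    d["age2"] = d["age"]  # perfect alias
    with pytest.raises(ValueError, match="aliased"):
        fit_linear_model(d, ModelSpec("score", ["age", "age2"]))


def test_interaction_without_main_effect_violates_hierarchy():
    with pytest.raises(ValueError, match="hierarchy"):
        ModelSpec("score", ["age", "age:sex"]).validate()


# --------------------------------------------------------------- regionwise

def _regionwise_data(n=500, seed=0, slope=0.0, n_regions=20, planted=5):
    rng = np.random.default_rng(seed)
    age = rng.uniform(44, 82, n)
    sex = rng.random(n) < 0.5
    z_age = (age - age.mean()) / age.std(ddof=1)
    thick = rng.standard_normal((n, n_regions))
    thick[:, :planted] += slope * (z_age * sex)[:, None]
    thickness = pd.DataFrame(thick, columns=[f"thk{j:02d}" for j in range(n_regions)])
    cov = pd.DataFrame({"age": age, "sex": np.where(sex, "female", "male")})
    return thickness, cov


def test_regionwise_detects_planted_interactions_and_reports_all_regions():
    thickness, cov = _regionwise_data(n=800, seed=4, slope=0.4, planted=5)
    res = regionwise_interaction(
        thickness, cov, ModelSpec("t", ["age", "sex", "age:sex"]), "age:sex", 0.05
    )
    assert len(res.table) == 20  # one row per region
    assert res.table["significant"].head(5).sum() >= 4
    assert (res.table["q"] >= res.table["p"] - 1e-12).all()


def test_regionwise_null_rarely_rejects_and_skips_constant_regions():
    thickness, cov = _regionwise_data(n=200, seed=5, slope=0.0)
    thickness["thk_flat"] = 1.0
    with pytest.warns(UserWarning, match="constant"):
        res = regionwise_interaction(
            thickness, cov, ModelSpec("t", ["age", "sex", "age:sex"]), "age:sex", 0.05
        )
    flat = res.table[res.table["region"] == "thk_flat"]
    assert np.isnan(flat["p"].iloc[0]) and not flat["significant"].iloc[0]


# ----------------------------------------------------------------- matching

def test_two_pair_matching_agrees_with_exhaustive_best_assignment():
    d = pd.DataFrame(
        {
            "subject_id": ["a1", "a2", "b1", "b2"],
            "group": ["A", "A", "B", "B"],
            "age": [50.0, 60.0, 50.5, 61.0],
        }
    )
    res = nearest_neighbor_match(d, "group", "age")
    pairs = {
        (r["template_id"], r["matched_id"])
        for _, r in res.pair_age_differences.iterrows()
    }
    assert pairs == {("a1", "b1"), ("a2", "b2")}


def test_identical_age_lists_match_with_zero_gaps_and_no_reuse():
    d = pd.DataFrame(
        {
            "subject_id": [f"x{i}" for i in range(6)],
            "group": ["A"] * 3 + ["B"] * 3,
            "age": [50.0, 55.0, 60.0] * 2,
        }
    )
    res = nearest_neighbor_match(d, "group", "age")
    assert (res.pair_age_differences["age_difference"] == 0).all()
    used = [i for ids in res.matched_ids.values() for i in ids]
    assert len(used) == len(set(used)) == 6


def test_matched_groups_have_template_size_and_close_mean_ages():
    rng = np.random.default_rng(6)
    d = pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(260)],
            "group": ["PRE"] * 30 + ["POST"] * 180 + ["SURG"] * 50,
            "age": np.r_[
                rng.normal(52, 3, 30), rng.normal(62, 6, 180), rng.normal(55, 4, 50)
            ],
        }
    )
    res = nearest_neighbor_match(d, "group", "age")
    assert all(len(ids) == 30 for ids in res.matched_ids.values())
    stats = res.group_stats.set_index("group")
    spread = stats["mean_age"].max() - stats["mean_age"].min()
    assert spread < stats["sd_age"].max()


def test_matching_requires_enough_candidates():
    d = pd.DataFrame(
        {
            "subject_id": ["a", "b", "c", "d", "e"],
            "group": ["A", "A", "A", "B", "B"],
            "age": [50.0, 51.0, 52.0, 53.0, 54.0],
        }
    )
    with pytest.raises(ValueError, match="too small"):
        nearest_neighbor_match(d, "group", "age", ratio=3)


# -------------------------------------------------------------------- ANOVA

def test_anova_equal_group_means_give_near_zero_f():
    scores = np.r_[np.zeros(10), np.zeros(10)] + np.tile([1.0, -1.0], 10)
    groups = np.r_[["a"] * 10, ["b"] * 10]
    f, df, p = anova_group_scores(scores, groups)
    assert f == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)
    assert df == (1, 18)


def test_two_group_anova_equals_squared_t():
    from scipy import stats

    rng = np.random.default_rng(7)
    a, b = rng.standard_normal(30), rng.standard_normal(25) + 0.4
    f, _, p_f = anova_group_scores(np.r_[a, b], np.r_[["a"] * 30, ["b"] * 25])
    t, p_t = stats.ttest_ind(a, b)
    assert f == pytest.approx(t**2)
    assert p_f == pytest.approx(p_t)


def test_anova_power_for_one_sd_group_shift():
    rng = np.random.default_rng(8)
    detected = 0
    for _ in range(20):
        a = rng.standard_normal(50)
        b = rng.standard_normal(50) + 1.0
        _, _, p = anova_group_scores(np.r_[a, b], np.r_[["a"] * 50, ["b"] * 50])
        detected += p < 0.05
    assert detected >= 19


def test_anova_rejects_degenerate_groups():
    with pytest.raises(ValueError, match="2 groups"):
        anova_group_scores([1.0, 2.0], ["a", "a"])
    with pytest.raises(ValueError, match="fewer than 2"):
        anova_group_scores([1.0, 2.0, 3.0], ["a", "a", "b"])
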