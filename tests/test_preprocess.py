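"""Screening, backfilling, imputation, coding, menopause derivation and
standardization rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskpls import (
    backfill_from_prior_visits,
    derive_menopause_status,
    dummy_code,
    impute_missing,
    screen_low_variance,
    screen_participants,
    screen_variables,
    zscore_columns,
)


def _table(n=100, values=None, **extra):
    base = {
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "age": np.linspace(45, 80, n),
        "sex": (["female", "male"] * n)[:n],
    }
    base.update(extra)
    if values is not None:
        base.update(values)
    return pd.DataFrame(base)


# ---------------------------------------------------------------- screening

def test_variable_missing_in_11_of_100_rows_is_dropped():
    v = np.ones(100)
    v[:11] = np.nan
    table = _table(values={"rf_a": v, "rf_b": np.arange(100.0)})
    out, report = screen_variables(table, columns=["rf_a", "rf_b"])
    assert "rf_a" not in out.columns
    assert report.dropped_variables == {"rf_a": pytest.approx(0.11)}


def test_variable_missing_in_exactly_10pct_is_retained():
    v = np.ones(100)
    v[:10] = np.nan
    table = _table(values={"rf_a": v})
    out, report = screen_variables(table, columns=["rf_a"])
    assert "rf_a" in out.columns and not report.dropped_variables


def test_fully_observed_table_keeps_all_variables_and_is_idempotent():
    table = _table(values={"rf_a": np.arange(100.0), "rf_b": np.ones(100)})
    once, r1 = screen_variables(table, columns=["rf_a", "rf_b"])
    twice, r2 = screen_variables(once, columns=["rf_a", "rf_b"])
    pd.testing.assert_frame_equal(once, twice)
    assert not r1.dropped_variables and not r2.dropped_variables


@pytest.mark.parametrize("n_missing,kept", [(11, False), (10, True), (0, True)])
def test_participant_screening_boundary(n_missing, kept):
    cols = {f"rf{j:02d}": np.ones(20) for j in range(12)}
    table = _table(n=20, values=cols)
    for j in range(n_missing):
        table.loc[0, f"rf{j:02d}"] = np.nan
    out, report = screen_participants(table, columns=list(cols))
    assert ("S0000" in set(out["subject_id"])) == kept
    assert (report.dropped_subjects == {"S0000": n_missing}) != kept


def test_low_variance_screen_drops_single_category_variables():
    skewed = np.zeros(100)
    skewed[:4] = 1  # modal category holds 96%
    ok = np.r_[np.zeros(50), np.ones(50)]
    table = _table(values={"rf_skew": skewed, "rf_ok": ok})
    out, report = screen_low_variance(table, columns=["rf_skew", "rf_ok"])
    assert "rf_skew" not in out.columns and "rf_ok" in out.columns
    assert report.dropped_variables["rf_skew"] == pytest.approx(0.96)


# -------------------------------------------------------------- backfilling

def test_backfill_fills_only_missing_cells_and_prefers_imaging_visit():
    current = _table(n=3, values={"rf_a": [np.nan, 2.0, np.nan]})
    prior = _table(n=3, values={"rf_a": [3.0, 5.0, np.nan]})
    prior = prior.iloc[:2]  # third subject absent from prior visit
    out = backfill_from_prior_visits(current, prior, columns=["rf_a"])
    assert out["rf_a"].tolist()[:2] == [3.0, 2.0]  # filled; never overwritten
    assert np.isnan(out["rf_a"].iloc[2])  # absent from prior -> unchanged


def test_backfill_rejects_schema_mismatch():
    current = _table(n=3, values={"rf_a": [1.0, 2.0, 3.0]})
    prior = _table(n=3)
    with pytest.raises(ValueError, match="schema"):
        backfill_from_prior_visits(current, prior, columns=["rf_a"])


# ---------------------------------------------------------------- imputation

def _correlated_table(n=200, seed=0, missing=0.0):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    cont1 = z + 0.3 * rng.standard_normal(n)
    cont2 = -z + 0.3 * rng.standard_normal(n)
    cat = (z > 0).astype(float)
    table = _table(n=n, values={"rf_c1": cont1, "rf_c2": cont2, "rf_cat": cat})
    mask = rng.random(n) < missing
    table.loc[mask, "rf_c1"] = np.nan
    return table, cont1, mask


def test_impute_identity_when_nothing_missing_and_deterministic():
    table, _, _ = _correlated_table(missing=0.0)
    out = impute_missing(table, seed=1, columns=["rf_c1", "rf_c2", "rf_cat"])
    pd.testing.assert_frame_equal(out, table)
    table, _, _ = _correlated_table(missing=0.1, seed=5)
    a = impute_missing(table, seed=7, columns=["rf_c1", "rf_c2", "rf_cat"])
    b = impute_missing(table, seed=7, columns=["rf_c1", "rf_c2", "rf_cat"])
    pd.testing.assert_frame_equal(a, b)
    assert not a["rf_c1"].isna().any()


def test_impute_beats_column_mean_on_correlated_data():
    table, truth, mask = _correlated_table(n=300, seed=3, missing=0.05)
    out = impute_missing(table, seed=2, columns=["rf_c1", "rf_c2", "rf_cat"],
                         n_trees=50)
    rf_rmse = np.sqrt(np.mean((out.loc[mask, "rf_c1"] - truth[mask]) ** 2))
    mean_fill = table["rf_c1"].mean()
    mean_rmse = np.sqrt(np.mean((mean_fill - truth[mask]) ** 2))
    assert rf_rmse < mean_rmse
    # observed cells untouched; categorical cells keep legal codes
    pd.testing.assert_series_equal(out.loc[~mask, "rf_c1"], table.loc[~mask, "rf_c1"])
    assert set(out["rf_cat"].unique()) <= {0.0, 1.0}


def test_impute_rejects_variable_with_no_observed_values():
    table = _table(n=20, values={"rf_a": [np.nan] * 20, "rf_b": np.arange(20.0)})
    with pytest.raises(ValueError, match="zero observed"):
        impute_missing(table, seed=0, columns=["rf_a", "rf_b"])


def test_backfill_with_no_prior_data_then_impute_equals_impute_alone():
    table, _, _ = _correlated_table(n=100, seed=8, missing=0.1)
    prior = table.head(0)  # no prior-visit rows at all
    cols = ["rf_c1", "rf_c2", "rf_cat"]
    via_backfill = impute_missing(
        backfill_from_prior_visits(table, prior, columns=cols), seed=4, columns=cols
    )
    direct = impute_missing(table, seed=4, columns=cols)
    pd.testing.assert_frame_equal(via_backfill, direct)


# ------------------------------------------------------------------- coding

def test_dummy_code_ordered_levels_and_binary():
    table = _table(
        n=4,
        values={
            "income": ["<18k", "18-31k", "31-52k", "52-100k"],
            "chronotype": ["morning", "evening", "morning", "evening"],
            "smoker": ["yes", "no", "no", "yes"],
            "already": [1.0, 2.0, 3.0, 4.0],
        },
    )
    coding = {
        "income": {"<18k": 1, "18-31k": 2, "31-52k": 3, "52-100k": 4, ">100k": 5},
        "chronotype": {"morning": 1, "evening": 2},
        "smoker": {"yes": 1, "no": 0},
        "already": {},
    }
    out = dummy_code(table, coding)
    assert out["income"].tolist() == [1, 2, 3, 4]
    assert out["chronotype"].tolist() == [1, 2, 1, 2]
    assert out["smoker"].tolist() == [1, 0, 0, 1]
    assert out["already"].tolist() == [1.0, 2.0, 3.0, 4.0]  # unchanged


def test_dummy_code_unseen_level_names_variable_and_level():
    table = _table(n=2, values={"income": ["<18k", "mystery"]})
    with pytest.raises(ValueError) as err:
        dummy_code(table, {"income": {"<18k": 1}})
    assert "income" in str(err.value) and "mystery" in str(err.value)


# ------------------------------------------------------- menopause derivation

def _repro(**kw):
    base = {
        "reported_menopause": "no",
        "age_at_menopause": None,
        "bilateral_oophorectomy": "no",
        "age_at_oophorectomy": None,
        "hysterectomy_only": "no",
    }
    base.update(kw)
    return base


@pytest.mark.parametrize(
    "repro,age,expected",
    [
        (_repro(), 55, "PRE"),
        (_repro(), 72, "POST_NATURAL"),  # over-70 rule overrides a "no"
        (_repro(), 70, "PRE"),  # strictly over 70
        (_repro(reported_menopause="yes", age_at_menopause=50), 60, "POST_NATURAL"),
        (_repro(age_at_menopause=50), 60, "POST_NATURAL"),  # reported age suffices
        (
            _repro(
                reported_menopause="yes",
                age_at_menopause=45,
                bilateral_oophorectomy="yes",
                age_at_oophorectomy=45,
            ),
            60,
            "POST_SURGICAL",  # oophorectomy at menopause: "at or prior"
        ),
        (
            _repro(
                reported_menopause="yes",
                age_at_menopause=45,
                bilateral_oophorectomy="yes",
                age_at_oophorectomy=50,
            ),
            60,
            "POST_NATURAL",  # oophorectomy after menopause does not qualify
        ),
        (_repro(hysterectomy_only="yes"), 55, "EXCLUDED"),
        (_repro(reported_menopause="unsure"), 55, "EXCLUDED"),
    ],
)
def test_menopause_status_rules(repro, age, expected):
    assert derive_menopause_status(repro, age) == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    reported=st.sampled_from(["yes", "no", "unsure", ""]),
    age_meno=st.one_of(st.none(), st.floats(30, 62)),
    oophor=st.sampled_from(["yes", "no"]),
    age_oo=st.one_of(st.none(), st.floats(30, 62)),
    hyst=st.sampled_from(["yes", "no"]),
    age=st.floats(44, 82),
)
def test_menopause_status_is_a_pure_total_function(
    reported, age_meno, oophor, age_oo, hyst, age
):
    repro = {
        "reported_menopause": reported,
        "age_at_menopause": age_meno,
        "bilateral_oophorectomy": oophor,
        "age_at_oophorectomy": age_oo,
        "hysterectomy_only": hyst,
    }
    first = derive_menopause_status(repro, age)
    assert first in {"PRE", "POST_NATURAL", "POST_SURGICAL", "EXCLUDED"}
    assert derive_menopause_status(repro, age) == first


# ------------------------------------------------------------ standardization

def test_zscore_simple_column_and_moments():
    out = zscore_columns(np.array([[1.0], [2.0], [3.0]]))
    np.testing.assert_allclose(out[:, 0], [-1.0, 0.0, 1.0])
    rng = np.random.default_rng(0)
    M = zscore_columns(rng.standard_normal((50, 4)) * 7 + 3)
    np.testing.assert_allclose(M.mean(axis=0), 0, atol=1e-8)
    np.testing.assert_allclose(M.std(axis=0, ddof=1), 1, atol=1e-8)


def test_zscore_rejects_constant_column_by_name():
    M = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
    with pytest.raises(ValueError, match="flat"):
        zscore_columns(M)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_zscore_is_idempotent(seed):
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((20, 3)) * rng.uniform(0.5, 5, size=3)
    once = zscore_columns(M)
    np.testing.assert_allclose(zscore_columns(once), once, atol=1e-8)
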