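"""Cohort screening, backfilling, imputation, coding and standardization.

The rules here turn a raw mixed-type cohort table into the pair of
complete, column-standardized matrices the PLS decomposition consumes:

* variables with more than 10% missing data are dropped;
* participants missing more than 10 risk-factor variables are dropped;
* remaining gaps are backfilled from earlier assessment visits (the
  imaging visit always takes precedence) and then imputed with an
  iterative random-forest sweep;
* categorical answers are coded as ordered integers;
* female menopause status (PRE / natural POST / surgical POST) is derived
  from reproductive self-report with an over-70 override;
* every retained column is z-scored to mean 0, SD 1 (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreeningReport",
    "PairedMatrices",
    "screen_variables",
    "screen_participants",
    "screen_low_variance",
    "backfill_from_prior_visits",
    "impute_missing",
    "dummy_code",
    "derive_menopause_status",
    "add_menopause_status",
    "menopause_indicator_columns",
    "zscore_columns",
    "build_paired_matrices",
    "riskfactor_columns",
    "thickness_columns",
]

REPRO_FIELDS = (
    "reported_menopause",
    "age_at_menopause",
    "bilateral_oophorectomy",
    "age_at_oophorectomy",
    "hysterectomy_only",
)

_NON_ANALYSIS = {"subject_id", "visit", "age", "sex", "prs", "menopause_status"}


def riskfactor_columns(table: pd.DataFrame) -> list[str]:
    """Columns holding risk-factor codes (everything that is not id,
    demographic, reproductive, or thickness)."""
    skip = _NON_ANALYSIS | set(REPRO_FIELDS)
    return [
        c for c in table.columns if c not in skip and not c.startswith("thk")
    ]


def thickness_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("thk")]


@dataclass
class ScreeningReport:
    dropped_variables: dict[str, float] = field(default_factory=dict)
    dropped_subjects: dict[str, int] = field(default_factory=dict)
    retained_shape: tuple[int, int] = (0, 0)


@dataclass
class PairedMatrices:
    """Row-aligned z-scored brain (X) and behavior (Y) matrices."""

    X: np.ndarray
    Y: np.ndarray
    row_ids: list[str]
    x_names: list[str]
    y_names: list[str]


def screen_variables(
    table: pd.DataFrame,
    columns: Sequence[str] | None = None,
    max_missing_frac: float = 0.10,
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Drop variables whose missing fraction strictly exceeds the threshold.

    The boundary is retained: a variable missing in exactly 10% of rows
    stays in ("more than 10%" read literally).
    """
    if table.empty:
        raise ValueError("empty table")
    cols = list(columns) if columns is not None else riskfactor_columns(table)
    fracs = table[cols].isna().mean()
    dropped = {c: float(fracs[c]) for c in cols if fracs[c] > max_missing_frac}
    if len(dropped) == len(cols):
        raise ValueError("all variables exceed the missingness threshold")
    out = table.drop(columns=list(dropped))
    report = ScreeningReport(
        dropped_variables=dropped,
        retained_shape=(len(out), len(cols) - len(dropped)),
    )
    return out, report


def screen_participants(
    table: pd.DataFrame,
    columns: Sequence[str] | None = None,
    max_missing_vars: int = 10,
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Drop participants missing strictly more than ``max_missing_vars``
    of the risk-factor variables (boundary retained)."""
    if table.empty:
        raise ValueError("empty table")
    cols = list(columns) if columns is not None else riskfactor_columns(table)
    counts = table[cols].isna().sum(axis=1)
    bad = counts > max_missing_vars
    dropped = {
        str(table.loc[i, "subject_id"]): int(counts[i])
        for i in table.index[bad]
    }
    out = table.loc[~bad].reset_index(drop=True)
    report = ScreeningReport(
        dropped_subjects=dropped, retained_shape=(len(out), len(cols))
    )
    return out, report


def screen_low_variance(
    table: pd.DataFrame,
    columns: Sequence[str] | None = None,
    max_modal_frac: float = 0.95,
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Drop coded variables whose modal response holds more than
    ``max_modal_frac`` of the observed answers.

    A reproducible stand-in for by-eye screening of heavily skewed
    single-category distributions that contribute no usable variance.
    """
    cols = list(columns) if columns is not None else riskfactor_columns(table)
    dropped: dict[str, float] = {}
    for c in cols:
        observed = table[c].dropna()
        if observed.empty:
            dropped[c] = 1.0
            continue
        top = observed.value_counts(normalize=True).iloc[0]
        if top > max_modal_frac:
            dropped[c] = float(top)
    out = table.drop(columns=list(dropped))
    report = ScreeningReport(
        dropped_variables=dropped,
        retained_shape=(len(out), len(cols) - len(dropped)),
    )
    return out, report


def backfill_from_prior_visits(
    current: pd.DataFrame,
    prior: pd.DataFrame,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fill cells missing at the imaging visit from an earlier visit.

    Values present at the imaging visit are never overwritten — the most
    recent (imaging-visit) answer always takes precedence.
    """
    cols = list(columns) if columns is not None else riskfactor_columns(current)
    missing_cols = [c for c in cols if c not in prior.columns]
    if missing_cols or "subject_id" not in prior.columns:
        raise ValueError(f"prior visit schema mismatch: missing {missing_cols or ['subject_id']}")
    out = current.copy()
    prior_idx = prior.set_index("subject_id")
    if prior_idx.index.has_duplicates:
        prior_idx = prior_idx[~prior_idx.index.duplicated(keep="last")]
    lookup = prior_idx.reindex(out["subject_id"])[cols].to_numpy()
    for j, c in enumerate(cols):
        vals = out[c].to_numpy(dtype=float, copy=True)
        mask = np.isnan(vals) & ~pd.isna(lookup[:, j])
        vals[mask] = lookup[mask, j].astype(float)
        out[c] = vals
    return out


def _is_categorical(col: pd.Series, max_levels: int = 10) -> bool:
    vals = col.dropna().to_numpy()
    if len(vals) == 0:
        return False
    return (
        np.all(np.equal(np.mod(vals, 1), 0)) and len(np.unique(vals)) <= max_levels
    )


def impute_missing(
    table: pd.DataFrame,
    seed: int,
    columns: Sequence[str] | None = None,
    categorical: Sequence[str] | None = None,
    max_iter: int = 10,
    n_trees: int = 100,
) -> pd.DataFrame:
    """Iterative random-forest imputation of mixed-type variables.

    Each incomplete variable is regressed on all the others with a random
    forest (regression for continuous, classification for integer-coded
    categoricals), sweeping variables in ascending order of missingness and
    iterating until the change in the imputed cells stops decreasing (the
    previous iterate is then returned) or ``max_iter`` is reached.
    Observed cells are never altered; imputed categorical cells take only
    codes seen in the data.
    """
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    cols = list(columns) if columns is not None else riskfactor_columns(table)
    sub = table[cols].astype(float)
    n_miss = sub.isna().sum()
    if (n_miss == len(sub)).any():
        empty = list(n_miss.index[n_miss == len(sub)])
        raise ValueError(f"variables with zero observed values: {empty}")
    targets = [c for c in cols if n_miss[c] > 0]
    if not targets:
        return table.copy()
    if len(cols) - len(targets) < 0:
        pass  # all incomplete is fine; predictors use current fill
    if categorical is None:
        categorical = [c for c in cols if _is_categorical(sub[c])]
    cat = set(categorical)

    # initial fill: column mean / mode
    filled = sub.copy()
    for c in cols:
        obs = sub[c].dropna()
        fill = obs.mode().iloc[0] if c in cat else obs.mean()
        filled[c] = sub[c].fillna(fill)

    masks = {c: sub[c].isna().to_numpy() for c in targets}
    order = sorted(targets, key=lambda c: n_miss[c])
    prev = filled.copy()
    prev_score = np.inf
    rng = np.random.default_rng(seed)
    for _ in range(max_iter):
        new = filled.copy()
        for c in order:
            mask = masks[c]
            others = [x for x in cols if x != c]
            X_obs = new.loc[~mask, others].to_numpy()
            y_obs = new.loc[~mask, c].to_numpy()
            X_mis = new.loc[mask, others].to_numpy()
            rs = int(rng.integers(2**31))
            if c in cat:
                model = RandomForestClassifier(
                    n_estimators=n_trees, random_state=rs, n_jobs=1
                )
                model.fit(X_obs, y_obs.astype(int))
                pred = model.predict(X_mis).astype(float)
            else:
                model = RandomForestRegressor(
                    n_estimators=n_trees, random_state=rs, n_jobs=1
                )
                model.fit(X_obs, y_obs)
                pred = model.predict(X_mis)
            new.loc[mask, c] = pred
        # combined change score: squared change in continuous imputed cells
        # plus disagreement count in categorical imputed cells
        score = 0.0
        for c in targets:
            delta = new.loc[masks[c], c].to_numpy() - filled.loc[masks[c], c].to_numpy()
            if c in cat:
                score += float(np.sum(delta != 0))
            else:
                denom = float(np.sum(new.loc[masks[c], c].to_numpy() ** 2)) or 1.0
                score += float(np.sum(delta**2)) / denom
        prev = filled
        filled = new
        if score >= prev_score:
            filled = prev  # change stopped decreasing: keep previous sweep
            break
        prev_score = score

    out = table.copy()
    for c in cols:
        out[c] = filled[c]
    return out


def dummy_code(
    table: pd.DataFrame, coding_map: Mapping[str, Mapping[object, int]]
) -> pd.DataFrame:
    """Replace categorical answers with their ordered integer codes.

    ``coding_map`` gives, per variable, the level -> integer assignment
    (e.g. income brackets 1..5 with higher = higher income, chronotype
    morning -> 1 / evening -> 2, yes/no -> 1/0).  Columns not named in the
    map are left untouched.
    """
    out = table.copy()
    for var, levels in coding_map.items():
        if var not in out.columns:
            raise KeyError(f"variable '{var}' not in table")
        if not levels:  # already-numeric column: nothing to recode
            continue
        col = out[var]
        coded = np.full(len(col), np.nan)
        for i, v in enumerate(col):
            if pd.isna(v):
                continue
            if v in levels:
                coded[i] = levels[v]
            elif isinstance(v, (int, float, np.integer, np.floating)) and v in set(
                levels.values()
            ):
                coded[i] = v  # already coded
            else:
                raise ValueError(f"unseen level {v!r} for variable '{var}'")
        out[var] = coded
    return out


def derive_menopause_status(repro: Mapping[str, object], age: float) -> str:
    """Classify a female participant's menopause status from self-report.

    Returns ``PRE``, ``POST_NATURAL``, ``POST_SURGICAL`` or ``EXCLUDED``:

    * hysterectomy without bilateral oophorectomy -> EXCLUDED;
    * a reported age at menopause, a "yes" answer, or age strictly over
      70 years -> postmenopausal; surgical when a bilateral oophorectomy
      at or prior to the reported age at menopause is on record,
      natural otherwise;
    * an explicit "no" with no overriding rule -> PRE;
    * anything unresolvable (unsure / missing report) -> EXCLUDED.
    """
    if age is None or (isinstance(age, float) and np.isnan(age)):
        raise ValueError("age is required to derive menopause status")

    def _yes(key: str) -> bool:
        return str(repro.get(key, "")).strip().lower() == "yes"

    reported = str(repro.get("reported_menopause", "")).strip().lower()
    age_meno = repro.get("age_at_menopause")
    age_meno = float(age_meno) if age_meno is not None and not pd.isna(age_meno) else None
    age_oo = repro.get("age_at_oophorectomy")
    age_oo = float(age_oo) if age_oo is not None and not pd.isna(age_oo) else None

    if _yes("hysterectomy_only") and not _yes("bilateral_oophorectomy"):
        return "EXCLUDED"
    post = reported == "yes" or age_meno is not None or age > 70
    if post:
        if (
            _yes("bilateral_oophorectomy")
            and age_oo is not None
            and age_meno is not None
            and age_oo <= age_meno
        ):
            return "POST_SURGICAL"
        return "POST_NATURAL"
    if reported == "no":
        return "PRE"
    return "EXCLUDED"


def add_menopause_status(table: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``menopause_status`` column (females only; males get NA)."""
    out = table.copy()
    status = []
    for _, row in out.iterrows():
        if row.get("sex") != "female":
            status.append(pd.NA)
        else:
            status.append(
                derive_menopause_status(
                    {k: row.get(k) for k in REPRO_FIELDS}, float(row["age"])
                )
            )
    out["menopause_status"] = status
    return out


def menopause_indicator_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Binary menopause variables for the menopause-augmented analysis:
    postmenopausal (either type), natural menopause, surgical menopause."""
    if "menopause_status" not in table.columns:
        table = add_menopause_status(table)
    out = table.copy()
    st = out["menopause_status"]
    out["meno_post"] = st.isin(["POST_NATURAL", "POST_SURGICAL"]).astype(int)
    out["meno_natural"] = (st == "POST_NATURAL").astype(int)
    out["meno_surgical"] = (st == "POST_SURGICAL").astype(int)
    return out


def zscore_columns(
    matrix: np.ndarray | pd.DataFrame,
    names: Sequence[str] | None = None,
) -> np.ndarray:
    """Center and scale every column to mean 0, SD 1 (n-1 denominator).

    Constant columns carry no usable variance and are rejected by name.
    """
    values = np.asarray(
        matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else matrix,
        dtype=float,
    )
    if names is None:
        names = (
            list(matrix.columns)
            if isinstance(matrix, pd.DataFrame)
            else [f"col{j}" for j in range(values.shape[1])]
        )
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    if np.isnan(values).any():
        raise ValueError("missing entries present; impute before standardizing")
    sd = values.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd < 1e-12)
    if bad.size:
        raise ValueError(
            f"constant column(s) with insufficient variance: {[names[j] for j in bad]}"
        )
    return (values - values.mean(axis=0)) / sd


def build_paired_matrices(
    table: pd.DataFrame,
    x_cols: Sequence[str] | None = None,
    y_cols: Sequence[str] | None = None,
) -> PairedMatrices:
    """Assemble the z-scored brain/behavior matrix pair from a cohort table."""
    x_cols = list(x_cols) if x_cols is not None else thickness_columns(table)
    y_cols = list(y_cols) if y_cols is not None else riskfactor_columns(table)
    X = zscore_columns(table[x_cols])
    Y = zscore_columns(table[y_cols])
    return PairedMatrices(
        X=X,
        Y=Y,
        row_ids=[str(s) for s in table["subject_id"]],
        x_names=x_cols,
        y_names=y_cols,
    )
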