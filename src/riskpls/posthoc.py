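"""Post-hoc linear models, FDR correction, age matching and ANOVA.

These are the univariate follow-ups around the PLS decomposition: ordinary
least squares on latent-variable scores or region-wise thickness (with
continuous variables z-scored so the betas are standardized), Benjamini-
Hochberg control of the false discovery rate across regions, greedy 1:1
nearest-neighbor age matching of groups, and one-way ANOVA of scores
between matched groups.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "ModelResult",
    "RegionwiseResult",
    "MatchResult",
    "fit_linear_model",
    "bh_fdr",
    "regionwise_interaction",
    "nearest_neighbor_match",
    "anova_group_scores",
]


@dataclass
class ModelSpec:
    """A linear model: outcome regressed on main effects and interactions.

    ``terms`` use ":" for interactions (e.g. ``["age", "sex", "age:sex"]``);
    every interaction's constituent main effects must be present.  Factors
    get reference-level treatment contrasts via ``reference_levels`` (e.g.
    ``{"menopause_status": "POST_NATURAL"}``); unlisted non-numeric
    variables use their first level alphabetically.
    """

    outcome: str
    terms: list[str]
    reference_levels: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        mains = {t for t in self.terms if ":" not in t}
        for t in self.terms:
            for part in t.split(":"):
                if part not in mains:
                    raise ValueError(
                        f"interaction '{t}' lacks main effect '{part}' (hierarchy)"
                    )


@dataclass
class ModelResult:
    table: pd.DataFrame  # term, beta, se, t, p
    term_tests: pd.DataFrame  # term, F, df, p (joint Wald test per term)
    n: int
    r_squared: float

    def term(self, name: str) -> pd.Series:
        hit = self.table[self.table["term"] == name]
        if hit.empty:
            raise KeyError(f"term '{name}' not in model result")
        return hit.iloc[0]


@dataclass
class RegionwiseResult:
    table: pd.DataFrame  # region, beta, p, q, significant
    focal_term: str
    q_level: float


@dataclass
class MatchResult:
    matched_ids: dict[str, list[str]]  # group -> subject ids
    pair_age_differences: pd.DataFrame  # template id, group, abs age gap
    group_stats: pd.DataFrame  # group, n, mean age, sd age


def _is_continuous(col: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(col) and col.nunique() > 2


_CONTRAST_RE = re.compile(r"C\((\w+)(?:, Treatment\(reference=[^)]*\))?\)")


def _tidy_label(label: str) -> str:
    """'C(sex)[T.male]' -> 'sex[T.male]'; leaves plain labels alone."""
    return _CONTRAST_RE.sub(r"\1", label)


def _fit_ols(table: pd.DataFrame, spec: ModelSpec):
    """Shared fitting path: z-score continuous variables, build the
    reference-coded formula, check rank, fit OLS."""
    import statsmodels.formula.api as smf
    from patsy import dmatrices

    spec.validate()
    variables = {spec.outcome} | {p for t in spec.terms for p in t.split(":")}
    missing = variables - set(table.columns)
    if missing:
        raise KeyError(f"model variables not in table: {sorted(missing)}")
    data = table[sorted(variables)].dropna().copy()
    if data.empty:
        raise ValueError("no complete rows for the model")

    expr: dict[str, str] = {}
    for v in variables:
        if _is_continuous(data[v]):
            sd = data[v].std(ddof=1)
            if sd < 1e-12:
                raise ValueError(f"variable '{v}' is constant")
            data[v] = (data[v] - data[v].mean()) / sd
            expr[v] = v
        elif v in spec.reference_levels:
            expr[v] = f"C({v}, Treatment(reference={spec.reference_levels[v]!r}))"
        elif not pd.api.types.is_numeric_dtype(data[v]):
            expr[v] = f"C({v})"
        else:
            expr[v] = v  # already a 0/1 contrast code
    term_map = {t: ":".join(expr[p] for p in t.split(":")) for t in spec.terms}
    formula = f"{expr.get(spec.outcome, spec.outcome)} ~ {' + '.join(term_map.values())}"

    _, Xd = dmatrices(formula, data, return_type="dataframe")
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        _, R = np.linalg.qr(Xd.to_numpy())
        aliased = [
            _tidy_label(Xd.columns[j])
            for j in range(Xd.shape[1])
            if abs(R[j, j]) < 1e-8
        ]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    res = smf.ols(formula, data=data).fit()
    return res, term_map


def fit_linear_model(table: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """OLS with standardized betas and reference-coded factors.

    Continuous variables (outcome included, when continuous) are z-scored
    before the fit; binary and categorical predictors enter as treatment
    contrasts, so coefficients on continuous terms are standardized slopes.
    ``term_tests`` additionally carries a joint Wald F per model term,
    which is what multi-level factor interactions are judged on.  A
    rank-deficient design raises, naming the aliased columns.
    """
    res, term_map = _fit_ols(table, spec)
    coef = pd.DataFrame(
        {
            "term": [_tidy_label(t) for t in res.params.index],
            "beta": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "t": res.tvalues.to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )
    wald = res.wald_test_terms(scalar=True).table
    tests = pd.DataFrame(
        {
            "term": [
                next((k for k, v in term_map.items() if v == raw), _tidy_label(raw))
                for raw in wald.index
            ],
            "F": wald["statistic"].to_numpy(dtype=float),
            "df": wald["df_constraint"].to_numpy(dtype=int),
            "p": wald["pvalue"].to_numpy(dtype=float),
        }
    )
    return ModelResult(
        table=coef, term_tests=tests, n=int(res.nobs), r_squared=float(res.rsquared)
    )


def bh_fdr(
    p_values: Sequence[float], q_level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and rejection mask.

    Rejects the i smallest p-values where p_(i) <= i*q/m for the largest
    such i; adjusted values use the standard cumulative-minimum form.
    """
    if not 0 < q_level < 1:
        raise ValueError(f"q_level must be in (0, 1), got {q_level}")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, reject


def regionwise_interaction(
    thickness: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: ModelSpec,
    focal_term: str,
    q_level: float = 0.05,
) -> RegionwiseResult:
    """Fit the model independently per region and FDR-correct the focal term.

    ``spec.outcome`` is ignored; each thickness column takes its place.
    The focal term's p-value is its joint Wald F test (identical to the
    coefficient t-test for single-contrast terms); the reported beta is the
    term's first contrast coefficient.  Constant regions are skipped with a
    warning and excluded from the correction.
    """
    if focal_term not in spec.terms:
        raise ValueError(f"focal term '{focal_term}' not among model terms")
    rows = []
    for region in thickness.columns:
        col = thickness[region]
        if col.std(ddof=1) < 1e-12:
            warnings.warn(f"region '{region}' is constant; skipped")
            rows.append({"region": region, "beta": np.nan, "p": np.nan})
            continue
        data = covariates.copy()
        data["thickness_mm"] = col.to_numpy()
        rspec = ModelSpec("thickness_mm", spec.terms, spec.reference_levels)
        result = fit_linear_model(data, rspec)
        p = float(result.term_tests.set_index("term").loc[focal_term, "p"])
        parts = focal_term.split(":")
        is_focal = result.table["term"].apply(
            lambda lbl: [s.split("[")[0] for s in lbl.split(":")] == parts
        )
        beta = float(result.table.loc[is_focal, "beta"].iloc[0])
        rows.append({"region": region, "beta": beta, "p": p})
    out = pd.DataFrame(rows)
    ok = out["p"].notna().to_numpy()
    q = np.full(len(out), np.nan)
    sig = np.zeros(len(out), dtype=bool)
    if ok.any():
        q[ok], sig[ok] = bh_fdr(out.loc[ok, "p"], q_level)
    out["q"] = q
    out["significant"] = sig
    return RegionwiseResult(table=out, focal_term=focal_term, q_level=q_level)


def nearest_neighbor_match(
    table: pd.DataFrame,
    group_col: str,
    covariate: str = "age",
    ratio: int = 1,
) -> MatchResult:
    """Greedy nearest-neighbor matching without replacement on a covariate.

    The smallest group is the template; its subjects are visited in
    ascending id order and, from every other group, the ``ratio`` unused
    candidates with the smallest absolute covariate difference are taken
    (ties broken by ascending id).  Every subject is used at most once.
    """
    if table[covariate].isna().any():
        raise ValueError(f"covariate '{covariate}' has missing values")
    groups = {
        str(g): sub.sort_values("subject_id").reset_index(drop=True)
        for g, sub in table.groupby(group_col, observed=True, dropna=True)
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to match")
    template_name = min(groups, key=lambda g: (len(groups[g]), g))
    template = groups[template_name]
    for g, sub in groups.items():
        if g != template_name and len(sub) < ratio * len(template):
            raise ValueError(
                f"group '{g}' too small to supply {ratio} match(es) per template subject"
            )
    matched: dict[str, list[str]] = {template_name: list(template["subject_id"])}
    pairs = []
    for g, sub in groups.items():
        if g == template_name:
            continue
        available = sub.copy()
        chosen: list[str] = []
        for _, t_row in template.iterrows():
            gaps = (available[covariate] - t_row[covariate]).abs()
            order = available.assign(_gap=gaps).sort_values(
                ["_gap", "subject_id"], kind="mergesort"
            )
            take = order.head(ratio)
            for _, c_row in take.iterrows():
                chosen.append(str(c_row["subject_id"]))
                pairs.append(
                    {
                        "template_id": str(t_row["subject_id"]),
                        "group": g,
                        "matched_id": str(c_row["subject_id"]),
                        "age_difference": float(
                            abs(c_row[covariate] - t_row[covariate])
                        ),
                    }
                )
            available = available.drop(take.index)
        matched[g] = chosen
    stats_rows = []
    indexed = table.set_index("subject_id")
    for g, ids in matched.items():
        ages = indexed.loc[ids, covariate]
        stats_rows.append(
            {
                "group": g,
                "n": len(ids),
                "mean_age": float(ages.mean()),
                "sd_age": float(ages.std(ddof=1)),
            }
        )
    return MatchResult(
        matched_ids=matched,
        pair_age_differences=pd.DataFrame(pairs),
        group_stats=pd.DataFrame(stats_rows),
    )


def anova_group_scores(
    scores: Sequence[float], groups: Sequence[object]
) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA of per-subject scores between groups.

    Returns (F, (df_between, df_within), p).
    """
    from scipy import stats

    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        small = labels[counts < 2]
        raise ValueError(f"groups with fewer than 2 subjects: {list(small)}")
    samples = [scores[groups == g] for g in labels]
    f, p = stats.f_oneway(*samples)
    df = (len(labels) - 1, len(scores) - len(labels))
    return float(f), df, float(p)
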