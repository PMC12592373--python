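"""End-to-end analysis designs: screen -> impute -> PLS -> inference -> post hoc.

Six analysis designs mirror the study structure:

* ``whole_sample`` — everyone, with post-hoc age x sex models on scores and
  region-wise age x sex interaction maps;
* ``male_only`` / ``female_only`` — sex-stratified PLS with age models on
  scores (females additionally get age x menopause models);
* ``female_plus_menopause_vars`` — the female design with three binary
  menopause indicators (post, natural, surgical) added to the behavior block;
* ``age_matched_female`` — the three menopause groups age-matched 1:1 and
  compared by ANOVA on scores;
* ``age_matched_with_males`` — the same with an age-matched male group.

Interpretation is limited to the first two statistically significant
latent variables, or to the significant prefix jointly explaining more
than 95% of the covariance, whichever is larger.  Every run is
deterministic given its seed, and all result tables are written as
comma-separated text with a YAML run log.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import preprocess as pp
from .inference import (
    BootstrapResult,
    PermutationResult,
    SplitHalfResult,
    bootstrap_ratios,
    permutation_test,
    split_half_stability,
)
from .pls import PLSModel, ScoreSet, compute_scores, fit_pls
from .posthoc import ModelSpec, anova_group_scores, fit_linear_model, nearest_neighbor_match, regionwise_interaction
from .simulate import GeneratorConfig, generate_cohort, read_cohort

log = logging.getLogger("riskpls")

DESIGNS = (
    "whole_sample",
    "male_only",
    "female_only",
    "female_plus_menopause_vars",
    "age_matched_female",
    "age_matched_with_males",
)

MENOPAUSE_GROUPS = ("PRE", "POST_NATURAL", "POST_SURGICAL")


@dataclass
class AnalysisConfig:
    design: str = "whole_sample"
    input_path: str | None = None  # cohort table CSV; or use `generator`
    prior_visit_path: str | None = None
    generator: GeneratorConfig | None = None
    n_perm: int = 500
    n_boot: int = 500
    n_splithalf: int = 200
    bsr_threshold: float = 1.95
    alpha: float = 0.05
    fdr_levels: tuple[float, float] = (0.05, 0.20)
    match_ratio: int = 1
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design '{self.design}'; one of {DESIGNS}")
        if self.input_path is None and self.generator is None:
            raise ValueError("either input_path or generator must be provided")
        for name in ("n_perm", "n_boot", "n_splithalf"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class RunReport:
    design: str
    lv_table: pd.DataFrame  # lv, singular value, covexp, perm p, split-half Z
    bsr_table: pd.DataFrame  # variable, domain, lv, bsr, se, significant
    score_table: pd.DataFrame  # subject, lv, brain and behavior scores
    reported_lvs: list[int]  # 1-based indices of interpreted LVs
    posthoc: dict[str, pd.DataFrame] = field(default_factory=dict)
    screening: dict[str, object] = field(default_factory=dict)
    model: PLSModel | None = None
    scores: ScoreSet | None = None
    permutation: PermutationResult | None = None
    bootstrap: BootstrapResult | None = None
    splithalf: SplitHalfResult | None = None
    table: pd.DataFrame | None = None  # the analysis table after subsetting


def select_reported_lvs(
    p_values: Sequence[float], covexp: Sequence[float], alpha: float = 0.05
) -> list[int]:
    """Which latent variables to interpret (1-based indices).

    The first two statistically significant LVs, or the smallest
    significant prefix whose cumulative covariance explained exceeds 95%,
    whichever set is larger.  No significant LV -> empty list with a
    warning.
    """
    p = np.asarray(p_values, dtype=float)
    cov = np.asarray(covexp, dtype=float)
    sig = [i for i in range(len(p)) if p[i] < alpha]
    if not sig:
        warnings.warn("no statistically significant latent variables")
        return []
    first_two = sig[:2]
    cum = np.cumsum(cov[sig])
    above = np.flatnonzero(cum > 0.95)
    prefix = sig[: above[0] + 1] if above.size else sig
    chosen = prefix if len(prefix) > len(first_two) else first_two
    return [i + 1 for i in chosen]


def _split_strata(table: pd.DataFrame) -> np.ndarray:
    """Split-half strata: age deciles x sex x menopause status (present)."""
    age_bins = pd.qcut(table["age"], 10, labels=False, duplicates="drop")
    parts = age_bins.astype(str)
    if table["sex"].nunique() > 1:
        parts = parts + "|" + table["sex"].astype(str)
    if "menopause_status" in table.columns and table["menopause_status"].notna().any():
        parts = parts + "|" + table["menopause_status"].astype("string").fillna("NA")
    return parts.to_numpy()


def _subset_for_design(
    table: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.DataFrame, list[str] | None]:
    """Apply the design's participant subsetting; returns the analysis
    table and any extra behavior columns the design adds."""
    design = config.design
    if design == "whole_sample":
        return table, None
    if design == "male_only":
        return table[table["sex"] == "male"].reset_index(drop=True), None

    females = table[
        (table["sex"] == "female")
        & table["menopause_status"].isin(MENOPAUSE_GROUPS)
    ].reset_index(drop=True)
    if design == "female_only":
        return females, None
    if design == "female_plus_menopause_vars":
        return pp.menopause_indicator_columns(females), [
            "meno_post",
            "meno_natural",
            "meno_surgical",
        ]
    # age-matched designs
    match = nearest_neighbor_match(females, "menopause_status", "age")
    keep = [sid for ids in match.matched_ids.values() for sid in ids]
    matched_f = females[females["subject_id"].isin(keep)].reset_index(drop=True)
    if design == "age_matched_female":
        return matched_f, None
    # add an age-matched male group (config.match_ratio males per female
    # template subject; the template is the smallest menopause group)
    males = table[table["sex"] == "male"].copy()
    males["match_group"] = "male"
    template = matched_f.copy()
    template["match_group"] = "female"
    both = pd.concat([template, males], ignore_index=True)
    m2 = nearest_neighbor_match(both, "match_group", "age", ratio=config.match_ratio)
    keep_m = set(m2.matched_ids["male"])
    matched_m = males[males["subject_id"].isin(keep_m)].drop(columns=["match_group"])
    out = pd.concat([matched_f, matched_m], ignore_index=True)
    return out.reset_index(drop=True), None


def _posthoc_models(
    analysis: pd.DataFrame,
    report: RunReport,
    config: AnalysisConfig,
) -> dict[str, pd.DataFrame]:
    """Design-appropriate linear models on the reported LV scores, plus the
    region-wise interaction maps and group ANOVAs."""
    out: dict[str, pd.DataFrame] = {}
    lvs = report.reported_lvs or [1]
    scores = report.scores
    has_prs = "prs" in analysis.columns and analysis["prs"].notna().all()

    def score_frame(lv: int) -> pd.DataFrame:
        d = analysis.copy()
        d["brain_score"] = scores.brain_scores[:, lv - 1]
        d["behavior_score"] = scores.behavior_scores[:, lv - 1]
        return d

    rows = []
    for lv in lvs:
        d = score_frame(lv)
        for domain in ("brain_score", "behavior_score"):
            if config.design == "whole_sample":
                spec = ModelSpec(domain, ["age", "sex", "age:sex"])
            elif config.design in ("male_only",):
                spec = ModelSpec(domain, ["age"])
            elif config.design in (
                "female_only",
                "female_plus_menopause_vars",
                "age_matched_female",
            ):
                spec = ModelSpec(
                    domain,
                    ["age", "menopause_status", "age:menopause_status"],
                    reference_levels={"menopause_status": "POST_NATURAL"},
                )
            else:  # age_matched_with_males: sexes mixed again
                spec = ModelSpec(domain, ["age", "sex", "age:sex"])
            try:
                res = fit_linear_model(d, spec)
            except ValueError as err:
                log.warning("score model skipped (LV%d %s): %s", lv, domain, err)
                continue
            for _, r in res.table.iterrows():
                rows.append(
                    {"lv": lv, "domain": domain, **r.to_dict(), "n": res.n}
                )
    out["score_models"] = pd.DataFrame(rows)

    if has_prs:
        rows = []
        for lv in lvs:
            d = score_frame(lv)
            for domain in ("brain_score", "behavior_score"):
                if config.design == "whole_sample":
                    terms = ["age", "sex", "prs", "age:sex", "age:prs", "sex:prs", "age:sex:prs"]
                else:
                    terms = ["age", "prs", "age:prs"]
                try:
                    res = fit_linear_model(d, ModelSpec(domain, terms))
                except ValueError as err:
                    log.warning("PRS model skipped (LV%d %s): %s", lv, domain, err)
                    continue
                for _, r in res.table.iterrows():
                    rows.append({"lv": lv, "domain": domain, **r.to_dict(), "n": res.n})
        out["prs_models"] = pd.DataFrame(rows)

    thick_cols = pp.thickness_columns(analysis)
    if config.design == "whole_sample" and analysis["sex"].nunique() > 1:
        rw = regionwise_interaction(
            analysis[thick_cols],
            analysis[["age", "sex"]],
            ModelSpec("thickness_mm", ["age", "sex", "age:sex"]),
            focal_term="age:sex",
            q_level=config.fdr_levels[0],
        )
        out["regionwise_age_by_sex"] = rw.table
    if config.design in (
        "female_only",
        "female_plus_menopause_vars",
        "age_matched_female",
    ):
        rw = regionwise_interaction(
            analysis[thick_cols],
            analysis[["age", "menopause_status"]],
            ModelSpec(
                "thickness_mm",
                ["age", "menopause_status", "age:menopause_status"],
                reference_levels={"menopause_status": "POST_NATURAL"},
            ),
            focal_term="age:menopause_status",
            q_level=config.fdr_levels[1],
        )
        out["regionwise_age_by_menopause"] = rw.table

    if config.design in ("age_matched_female", "age_matched_with_males"):
        group = analysis["menopause_status"].astype("string")
        if config.design == "age_matched_with_males":
            group = group.fillna("MALE")
        rows = []
        for lv in lvs:
            for domain, mat in (
                ("brain_score", scores.brain_scores),
                ("behavior_score", scores.behavior_scores),
            ):
                f, df, p = anova_group_scores(mat[:, lv - 1], group.to_numpy())
                rows.append(
                    {
                        "lv": lv,
                        "domain": domain,
                        "F": f,
                        "df_between": df[0],
                        "df_within": df[1],
                        "p": p,
                    }
                )
        out["score_anova"] = pd.DataFrame(rows)
    return out


def run_pipeline(config: AnalysisConfig) -> RunReport:
    """Execute one analysis design end to end.

    Raises before any computation on a design/data mismatch (e.g. a
    menopause design without reproductive fields).  Deterministic given
    ``config.seed``; all stage seeds derive from it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    stage_seed = {
        name: int(rng.integers(2**31))
        for name in ("generator", "impute", "perm", "boot", "split")
    }

    if config.input_path is not None:
        table = read_cohort(config.input_path)
    else:
        gen = GeneratorConfig(**{**vars(config.generator), "seed": stage_seed["generator"]})
        table, _ = generate_cohort(gen)
    needs_menopause = config.design not in ("whole_sample", "male_only")
    if needs_menopause:
        missing = [c for c in pp.REPRO_FIELDS if c not in table.columns]
        if missing:
            raise ValueError(
                f"design '{config.design}' requires reproductive fields; missing {missing}"
            )

    # --- screening / backfilling / imputation on the risk-factor block ---
    screening: dict[str, object] = {}
    table, rep_v = pp.screen_variables(table)
    screening["dropped_variables"] = rep_v.dropped_variables
    table, rep_lv = pp.screen_low_variance(table)
    screening["dropped_low_variance"] = rep_lv.dropped_variables
    table, rep_s = pp.screen_participants(table)
    screening["dropped_subjects"] = rep_s.dropped_subjects
    if config.prior_visit_path is not None:
        prior = read_cohort(config.prior_visit_path)
        table = pp.backfill_from_prior_visits(table, prior)
    rf_cols = pp.riskfactor_columns(table)
    if table[rf_cols].isna().any().any():
        log.info("imputing %d missing cells", int(table[rf_cols].isna().sum().sum()))
        table = pp.impute_missing(table, seed=stage_seed["impute"])
    table = pp.add_menopause_status(table)

    analysis, extra_y = _subset_for_design(table, config)
    log.info("design %s: %d subjects", config.design, len(analysis))

    y_cols = pp.riskfactor_columns(analysis)
    if extra_y:
        y_cols = [c for c in y_cols if c not in extra_y] + list(extra_y)
    # a column can lose all variance after subsetting; drop it, not the run
    keep = [c for c in y_cols if analysis[c].std(ddof=1) > 1e-12]
    dropped_const = sorted(set(y_cols) - set(keep))
    if dropped_const:
        log.warning("dropping constant columns after subsetting: %s", dropped_const)
        screening["dropped_constant_after_subset"] = dropped_const
    pm = pp.build_paired_matrices(analysis, y_cols=keep)

    model = fit_pls(pm.X, pm.Y, x_names=pm.x_names, y_names=pm.y_names)
    scores = compute_scores(pm.X, pm.Y, model, row_ids=pm.row_ids)
    perm = permutation_test(pm.X, pm.Y, n_perm=config.n_perm, seed=stage_seed["perm"])
    boot = bootstrap_ratios(pm.X, pm.Y, model, n_boot=config.n_boot, seed=stage_seed["boot"])
    split = split_half_stability(
        pm.X, pm.Y, strata=_split_strata(analysis),
        n_iter=config.n_splithalf, seed=stage_seed["split"],
    )
    reported = select_reported_lvs(perm.p_values, model.covexp, alpha=config.alpha)

    k = model.k
    lv_table = pd.DataFrame(
        {
            "lv": np.arange(1, k + 1),
            "singular_value": model.S,
            "covexp_pct": 100 * model.covexp,
            "perm_p": perm.p_values,
            "splithalf_z_brain": split.z_brain,
            "splithalf_z_behavior": split.z_behavior,
            "stable": split.stable,
            "reported": [i + 1 in reported for i in range(k)],
        }
    )
    var_names = list(pm.x_names) + list(pm.y_names)
    domains = ["brain"] * len(pm.x_names) + ["behavior"] * len(pm.y_names)
    bsr_rows = []
    for i in range(k):
        for j, (name, dom) in enumerate(zip(var_names, domains)):
            bsr_rows.append(
                {
                    "variable": name,
                    "domain": dom,
                    "lv": i + 1,
                    "bsr": boot.bsr[j, i],
                    "se": boot.se[j, i],
                    "significant": bool(abs(boot.bsr[j, i]) > config.bsr_threshold),
                }
            )
    bsr_table = pd.DataFrame(bsr_rows)
    score_table = pd.DataFrame({"subject_id": pm.row_ids})
    for i in range(k):
        score_table[f"brain_lv{i + 1}"] = scores.brain_scores[:, i]
        score_table[f"behavior_lv{i + 1}"] = scores.behavior_scores[:, i]

    report = RunReport(
        design=config.design,
        lv_table=lv_table,
        bsr_table=bsr_table,
        score_table=score_table,
        reported_lvs=reported,
        screening=screening,
        model=model,
        scores=scores,
        permutation=perm,
        bootstrap=boot,
        splithalf=split,
        table=analysis,
    )
    report.posthoc = _posthoc_models(analysis, report, config)

    if config.output_dir is not None:
        _write_report(report, config)
    return report


def _write_report(report: RunReport, config: AnalysisConfig) -> None:
    import yaml

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    report.lv_table.to_csv(outdir / "lv_table.csv", index=False, float_format=fmt)
    report.bsr_table.to_csv(outdir / "bsr_table.csv", index=False, float_format=fmt)
    report.score_table.to_csv(outdir / "scores.csv", index=False, float_format=fmt)
    report.table.to_csv(outdir / "analysis_table.csv", index=False, na_rep="NA", float_format=fmt)
    for name, tab in report.posthoc.items():
        tab.to_csv(outdir / f"posthoc_{name}.csv", index=False, float_format=fmt)
    from . import __version__

    run_log = {
        "riskpls_version": __version__,
        "design": config.design,
        "seed": config.seed,
        "n_subjects": len(report.table),
        "n_perm": config.n_perm,
        "n_boot": config.n_boot,
        "n_splithalf": config.n_splithalf,
        "bsr_threshold": config.bsr_threshold,
        "alpha": config.alpha,
        "fdr_levels": list(config.fdr_levels),
        "reported_lvs": report.reported_lvs,
        "screening": {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in report.screening.items()
        },
    }
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(run_log, fh, sort_keys=True)
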