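"""Synthetic cohort generation with planted latent structure.

Emulates a mid-to-late-life imaging cohort: regional mean cortical
thickness (mm) and ordered-integer lifestyle risk-factor codes sharing a
small number of latent components of decaying strength, plus age, sex,
menopause and polygenic-risk covariates with optional interaction effects
on thickness.  The planted ground truth (saliences, strengths, covariate
slopes) is returned alongside the table for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "GeneratorTruth",
    "generate_cohort",
    "inject_missingness",
    "make_prior_visit",
    "write_cohort",
    "read_cohort",
    "write_truth",
]

#: mm; typical regional mean thickness and between-subject SD
THICKNESS_BASELINE = 2.5
THICKNESS_SCALE = 0.1

#: years; centre and width of the logistic menopause-onset curve
MENOPAUSE_AGE_CENTER = 51.0
MENOPAUSE_AGE_WIDTH = 2.5


class ConfigurationError(ValueError):
    """Raised when a generator configuration field is invalid."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    ``component_strengths`` must be strictly decreasing and positive;
    ``interaction_effects`` maps a model term (``"age"``, ``"sex"``,
    ``"age:sex"``, ``"age:menopause_surgical"``, ...) to a pair
    ``(region_indices, standardized_slope)``.  ``categorical_specs`` maps a
    risk-factor column index to its ordered integer codes; ``None`` uses a
    mixed default (binary / 3-level / 5-level / continuous, cycling), an
    empty dict keeps every risk factor continuous.
    """

    n_subjects: int = 1000
    n_regions: int = 64
    n_riskfactors: int = 12
    n_components: int = 2
    component_strengths: Sequence[float] = (3.0, 1.0)
    noise_sd: float = 1.0
    age_range: tuple[float, float] = (44.0, 82.0)
    female_fraction: float = 0.552
    menopause_fractions: tuple[float, float, float] = (0.05, 0.78, 0.12)
    interaction_effects: Mapping[str, tuple[Sequence[int], float]] = field(
        default_factory=dict
    )
    missing_rate: float = 0.0
    categorical_specs: Mapping[int, Sequence[int]] | None = None
    include_prs: bool = True
    seed: int = 0

    def validate(self) -> None:
        s = np.asarray(self.component_strengths, dtype=float)
        if self.n_components != len(s):
            raise ConfigurationError(
                "component_strengths: expected one strength per component "
                f"(k={self.n_components}, got {len(s)})"
            )
        if self.n_components > 0:
            if np.any(s <= 0):
                raise ConfigurationError("component_strengths: must be positive")
            if np.any(np.diff(s) >= 0):
                raise ConfigurationError(
                    "component_strengths: must be strictly decreasing"
                )
        if self.n_components > min(self.n_regions, self.n_riskfactors):
            raise ConfigurationError(
                "n_components: must be <= min(n_regions, n_riskfactors)"
            )
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate: must be in [0, 1)")
        if not 0 <= self.female_fraction <= 1:
            raise ConfigurationError("female_fraction: must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be nonnegative")
        mf = np.asarray(self.menopause_fractions, dtype=float)
        if np.any(mf < 0) or np.any(mf > 1) or mf.sum() > 1:
            raise ConfigurationError(
                "menopause_fractions: fractions must lie in [0,1] and sum to <= 1"
            )
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range: min must be below max")


@dataclass
class GeneratorTruth:
    """Planted parameters: the quantities recovery tests check against."""

    true_brain_saliences: np.ndarray  # p x k, orthonormal columns
    true_behavior_saliences: np.ndarray  # q x k, orthonormal columns
    true_strengths: np.ndarray  # k-vector, strictly decreasing
    true_covariate_betas: dict[str, float]


def _random_orthonormal(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    if k == 0:
        return np.zeros((n, 0))
    q, r = np.linalg.qr(rng.standard_normal((n, k)))
    return q * np.sign(np.diag(r))


def _default_categorical_specs(q: int) -> dict[int, list[int]]:
    # mixed coding as in questionnaire-derived risk factors: binary yes/no,
    # 3-level frequency, 5-level bracket, and a continuous measure, cycling
    cycle: list[list[int] | None] = [[0, 1], [0, 1, 2], [1, 2, 3, 4, 5], None]
    specs: dict[int, list[int]] = {}
    for j in range(q):
        codes = cycle[j % len(cycle)]
        if codes is not None:
            specs[j] = codes
    return specs


def _quantile_bin(x: np.ndarray, codes: Sequence[int]) -> np.ndarray:
    """Bin a continuous vector into ordered integer codes by its quantiles."""
    codes = np.asarray(sorted(codes))
    n_levels = len(codes)
    edges = np.quantile(x, np.linspace(0, 1, n_levels + 1)[1:-1])
    return codes[np.searchsorted(edges, x, side="left")]


def _assign_menopause(
    rng: np.random.Generator,
    age: np.ndarray,
    female: np.ndarray,
    fractions: tuple[float, float, float],
) -> pd.DataFrame:
    """Age-dependent menopause status and the self-report fields behind it.

    Post probability follows a logistic curve in age so premenopausal
    subjects skew younger (the age-menopause confound the analysis has to
    handle); the logistic assignment is thinned so the expected PRE share
    matches the configured fraction, making PRE both the youngest and
    (typically) the smallest group.  Among postmenopausal women the
    natural/surgical split follows the configured fractions, and
    1 - sum(fractions) of females get inconsistent reports (unsure, or
    hysterectomy without oophorectomy).
    """
    n = len(age)
    cols = {
        "reported_menopause": np.full(n, "NA", dtype=object),
        "age_at_menopause": np.full(n, np.nan),
        "bilateral_oophorectomy": np.full(n, "NA", dtype=object),
        "age_at_oophorectomy": np.full(n, np.nan),
        "hysterectomy_only": np.full(n, "NA", dtype=object),
    }
    pre_f, nat_f, surg_f = fractions
    excl_f = max(0.0, 1.0 - (pre_f + nat_f + surg_f))
    post_total = nat_f + surg_f
    surg_given_post = surg_f / post_total if post_total > 0 else 0.0

    from scipy.special import expit

    p_post = expit((age - MENOPAUSE_AGE_CENTER) / MENOPAUSE_AGE_WIDTH)
    # thin the logistic's PRE share down to the configured target fraction
    mu_pre = float(np.mean(1 - p_post[female])) if female.any() else 0.0
    keep_pre = min(1.0, pre_f / mu_pre) if mu_pre > 0 else 0.0

    for i in np.flatnonzero(female):
        if rng.random() < excl_f:
            # uncertain report or hysterectomy-only: excluded downstream
            if rng.random() < 0.5:
                cols["reported_menopause"][i] = "unsure"
                cols["bilateral_oophorectomy"][i] = "no"
                cols["hysterectomy_only"][i] = "no"
            else:
                cols["reported_menopause"][i] = "no"
                cols["bilateral_oophorectomy"][i] = "no"
                cols["hysterectomy_only"][i] = "yes"
            continue
        is_pre = age[i] <= 70 and rng.random() >= p_post[i]
        if is_pre and rng.random() >= keep_pre:
            is_pre = False
        if is_pre:
            cols["reported_menopause"][i] = "no"
            cols["bilateral_oophorectomy"][i] = "no"
            cols["hysterectomy_only"][i] = "no"
        elif rng.random() < surg_given_post:
            m_age = float(np.clip(rng.normal(47.0, 4.0), 35.0, min(age[i], 60.0)))
            cols["reported_menopause"][i] = "yes"
            cols["age_at_menopause"][i] = round(m_age)
            cols["bilateral_oophorectomy"][i] = "yes"
            cols["age_at_oophorectomy"][i] = round(m_age)  # at or prior
            cols["hysterectomy_only"][i] = "no"
        else:
            m_age = float(np.clip(rng.normal(50.5, 3.0), 40.0, min(age[i], 60.0)))
            cols["reported_menopause"][i] = "yes"
            cols["age_at_menopause"][i] = round(m_age)
            cols["bilateral_oophorectomy"][i] = "no"
            cols["hysterectomy_only"][i] = "no"
    return pd.DataFrame(cols)


def _covariate_design(
    term: str, z_age: np.ndarray, female: np.ndarray, surgical: np.ndarray
) -> np.ndarray:
    parts = {
        "age": z_age,
        "sex": female.astype(float),
        "menopause_surgical": surgical.astype(float),
    }
    out = np.ones_like(z_age)
    for factor in term.split(":"):
        if factor not in parts:
            raise ConfigurationError(f"interaction_effects: unknown term '{factor}'")
        out = out * parts[factor]
    return out


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, GeneratorTruth]:
    """Generate a cohort table and its planted ground truth.

    Thickness (mm) = baseline + scale * (covariate effects + latent signal
    + noise); risk factors share the same latent subject scores through the
    planted behavior saliences, then are discretized per
    ``categorical_specs``.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p, q, k = (
        config.n_subjects,
        config.n_regions,
        config.n_riskfactors,
        config.n_components,
    )

    U = _random_orthonormal(rng, p, k)
    V = _random_orthonormal(rng, q, k)
    strengths = np.asarray(config.component_strengths, dtype=float)

    age = rng.uniform(*config.age_range, size=n)
    z_age = (age - age.mean()) / age.std(ddof=1)
    female = rng.random(n) < config.female_fraction
    repro = _assign_menopause(rng, age, female, config.menopause_fractions)
    surgical = (repro["bilateral_oophorectomy"].to_numpy() == "yes") & female

    T = rng.standard_normal((n, k))  # latent subject scores, iid N(0,1)
    latent_x = T @ (strengths[:, None] * U.T) if k else np.zeros((n, p))
    latent_y = T @ (strengths[:, None] * V.T) if k else np.zeros((n, q))

    covar = np.zeros((n, p))
    betas: dict[str, float] = {}
    for term, (regions, slope) in config.interaction_effects.items():
        design = _covariate_design(term, z_age, female, surgical)
        covar[:, np.asarray(regions, dtype=int)] += slope * design[:, None]
        betas[term] = float(slope)

    thick = THICKNESS_BASELINE + THICKNESS_SCALE * (
        covar + latent_x + config.noise_sd * rng.standard_normal((n, p))
    )
    y_cont = latent_y + config.noise_sd * rng.standard_normal((n, q))

    specs = (
        _default_categorical_specs(q)
        if config.categorical_specs is None
        else dict(config.categorical_specs)
    )
    y_cols = {}
    for j in range(q):
        col = y_cont[:, j]
        y_cols[f"rf{j + 1:02d}"] = _quantile_bin(col, specs[j]) if j in specs else col

    table = pd.DataFrame({"subject_id": [f"S{i + 1:06d}" for i in range(n)]})
    table["visit"] = 2  # imaging visit
    table["age"] = np.round(age, 1)
    table["sex"] = np.where(female, "female", "male")
    for c in repro.columns:
        table[c] = repro[c]
    if config.include_prs:
        table["prs"] = rng.standard_normal(n)
    for name, col in y_cols.items():
        table[name] = col
    for j in range(p):
        table[f"thk{j + 1:02d}"] = thick[:, j]

    if config.missing_rate > 0:
        table = inject_missingness(
            table,
            config.missing_rate,
            list(y_cols),
            seed=int(rng.integers(2**31)),
        )

    truth = GeneratorTruth(
        true_brain_saliences=U,
        true_behavior_saliences=V,
        true_strengths=strengths,
        true_covariate_betas=betas,
    )
    return table, truth


def inject_missingness(
    table: pd.DataFrame, rate: float, columns: Sequence[str], seed: int
) -> pd.DataFrame:
    """Set each targeted cell missing independently with probability ``rate``.

    Missing-completely-at-random; cells outside ``columns`` are untouched.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    out = table.copy()
    rng = np.random.default_rng(seed)
    for c in columns:
        mask = rng.random(len(out)) < rate
        col = out[c].astype(float) if out[c].dtype.kind in "iub" else out[c].copy()
        col[mask] = np.nan
        out[c] = col
    return out


def make_prior_visit(
    table: pd.DataFrame,
    columns: Sequence[str],
    seed: int,
    observed_fraction: float = 0.8,
    subset_fraction: float = 0.9,
) -> pd.DataFrame:
    """Build an earlier assessment visit to exercise backfilling.

    Keeps a random subset of subjects, marks ``visit`` 1, and re-observes
    each targeted cell with probability ``observed_fraction`` (values may
    differ from the imaging visit: answers drift between assessments).
    """
    rng = np.random.default_rng(seed)
    keep = rng.random(len(table)) < subset_fraction
    prior = table.loc[keep].copy()
    prior["visit"] = 1
    for c in columns:
        vals = prior[c].to_numpy(dtype=float, copy=True)
        observed = ~np.isnan(vals)
        if observed.any():
            pool = vals[observed]
            redraw = pool[rng.integers(len(pool), size=len(vals))]
            mix = rng.random(len(vals)) < 0.2
            vals = np.where(mix, redraw, vals)
        vals[rng.random(len(vals)) >= observed_fraction] = np.nan
        prior[c] = vals
    return prior


def write_cohort(table: pd.DataFrame, path: str) -> None:
    """Comma-separated, header row, 'NA' for missing."""
    table.to_csv(path, index=False, na_rep="NA")


def read_cohort(path: str) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"], keep_default_na=True)


def write_truth(truth: GeneratorTruth, path: str) -> None:
    """Ground truth as a YAML sidecar next to the cohort table."""
    import yaml

    payload = {
        "true_strengths": truth.true_strengths.tolist(),
        "true_brain_saliences": truth.true_brain_saliences.tolist(),
        "true_behavior_saliences": truth.true_behavior_saliences.tolist(),
        "true_covariate_betas": dict(truth.true_covariate_betas),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)
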