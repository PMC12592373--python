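import numpy as np
import pytest

from riskpls import GeneratorConfig, generate_cohort
from riskpls.preprocess import zscore_columns


def null_pair(seed: int, n: int = 300, p: int = 10, q: int = 8):
    """Independent standard-normal X, Y (z-scored): the global null."""
    rng = np.random.default_rng(seed)
    return (
        zscore_columns(rng.standard_normal((n, p))),
        zscore_columns(rng.standard_normal((n, q))),
    )


def planted_pair(
    seed: int,
    n: int = 500,
    p: int = 10,
    q: int = 8,
    strengths=(5.0,),
    noise_sd: float = 0.5,
):
    """Z-scored matrices with planted shared components, plus the truth."""
    cfg = GeneratorConfig(
        n_subjects=n,
        n_regions=p,
        n_riskfactors=q,
        n_components=len(strengths),
        component_strengths=strengths,
        noise_sd=noise_sd,
        categorical_specs={},
        seed=seed,
    )
    table, truth = generate_cohort(cfg)
    X = zscore_columns(table[[c for c in table if c.startswith("thk")]])
    Y = zscore_columns(table[[c for c in table if c.startswith("rf")]])
    return X, Y, truth


@pytest.fixture
def small_planted():
    return planted_pair(seed=11)
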