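"""Generate a synthetic imaging cohort with planted brain-behavior structure.

The generator plants k latent components of decaying strength that are
shared between regional cortical thickness (mm) and ordered-integer risk
factor codes, plus an age-dependent menopause assignment and
missing-completely-at-random gaps.
"""

import numpy as np

from riskpls import GeneratorConfig, generate_cohort

config = GeneratorConfig(
    n_subjects=1000,
    n_regions=64,
    n_riskfactors=12,
    n_components=2,
    component_strengths=(3.0, 1.0),
    noise_sd=1.0,
    missing_rate=0.02,
    seed=7,
)
table, truth = generate_cohort(config)

females = table[table["sex"] == "female"]
pre = females[females["reported_menopause"] == "no"]
post = females[females["reported_menopause"] == "yes"]
rf_cols = [c for c in table.columns if c.startswith("rf")]

print(f"cohort: {len(table)} subjects, {len(females)} female")
print(f"age range: {table['age'].min():.1f}-{table['age'].max():.1f} years")
print(f"mean age, premenopausal:  {pre['age'].mean():.1f}")
print(f"mean age, postmenopausal: {post['age'].mean():.1f}")
print(f"missing risk-factor cells: {table[rf_cols].isna().mean().mean():.1%}")
print(f"planted strengths: {truth.true_strengths}")
# The pre/post age gap is the planted age-menopause confound; the ~2%
# missingness is what the imputation stage later has to fill.
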