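# Methods

This note documents the statistical model, the synthetic-cohort generator,
the numerical conventions, and the design choices made where the procedure
left room for judgment.

## The PLS correlation model

The analysis assumes two blocks measured on the same n participants: a
brain block X (n × p regional mean cortical thickness, mm) and a behavior
block Y (n × q coded risk factors). Both blocks are z-scored per column
with the n−1 standard deviation, so R = XᵀY/(n−1) holds Pearson
correlations. The SVD R = U diag(s) Vᵀ yields min(p, q) latent variables;
all are computed, and only reporting is truncated. Because any positive
rescaling of R scales the singular values by the same constant and leaves
U, V and the covariance-explained fractions sᵢ²/Σsⱼ² untouched, the choice
of the n−1 denominator is cosmetic — but it is fixed so outputs are
reproducible to the byte.

Sign convention: SVD signs are arbitrary, so each component is flipped so
that the largest-magnitude element of its behavior salience is positive
(ties broken by first index). Subject scores are the projections XU and
YV. Applied write-ups occasionally describe a participant's score as a
singular value of a decomposition of the subject's own data block; that
reading conflicts with standard PLS usage, and this package implements
the standard projection scores, which is also what the common Python PLS
implementations compute.

Degenerate inputs: n < 3 rows, missing entries, or non-finite covariance
entries raise; exactly tied singular values are accepted as returned by
the solver (stability tests avoid exact ties, which have measure zero
under the generator).

## Resampling inference

**Permutation.** Rows of X are shuffled (Y fixed), breaking the pairing
while preserving each block's internal covariance; the k ordered null
singular values are recorded per draw, and pᵢ = (1 + #{null Sᵢ ≥ observed
Sᵢ})/(1 + n_perm). The i-th ordered null value is compared with the i-th
observed value — no Procrustes rotation — and the add-one estimator keeps
p-values in [1/(n_perm+1), 1]. Comparing ordered maxima makes the test
conservative for trailing LVs. Row shuffling leaves column moments intact,
so no re-standardization is needed within permutations.

**Bootstrap ratios.** Subjects are resampled with replacement; each
resample is re-z-scored and refit, and each LV is sign-aligned to the
original by the sign of the combined brain+behavior salience dot product.
The bootstrapped quantity is weight × singular value per variable and LV;
its standard deviation over draws is the SE, and BSR = observed
(weight × S)/SE. The SE belongs to the same product as the numerator — an
alternative (SE of the weight alone) would be inconsistent with that
numerator. |BSR| > 1.95 (strict) flags reliability, analogous to a
two-sided p < 0.05 for an approximately normal quantity. A resample
producing a constant column is redrawn (up to 10 times); a zero SE yields
±inf with a warning and counts as significant (it arises only in
pathological constant resamples).

**Split-half stability.** Subjects are split into two halves balanced
within strata (age deciles × sex × menopause status where present;
singleton strata are assigned at random with a warning); PLS is refit per
half after re-z-scoring, and the absolute Pearson correlation between the
halves' saliences is recorded per LV and domain. Absolute values absorb
the arbitrary sign. Z = mean/SD of each r distribution over iterations
(default 200); |Z| > 1.96 in both domains flags a stable LV. Whether the
original procedure re-standardized within halves is not specifiable from
the outside; this package re-standardizes within every resample, and
`rezscore=False` disables it.

Calibration facts the test suite verifies: the permutation test holds its
level under the global null; pooled null-variable |BSR| > 1.95 rates sit
near 0.05 (slightly below — the ordered-LV construction is mildly
conservative); planted signals are flagged stable in ≥95% of seeds.

## Preprocessing rules

- Variables are dropped when *strictly more than* 10% missing; participants
  when *strictly more than* 10 risk-factor variables are missing. Both
  thresholds are literal readings of "more than"; boundary cases are
  retained.
- Low-variance screening is, in the original workflow, a by-eye judgment of
  heavily skewed single-category distributions. The reproducible proxy here
  drops a coded variable whose modal category holds >95% of observed
  responses (configurable).
- Backfilling fills imaging-visit gaps from earlier visits and never
  overwrites an imaging-visit answer; conflicting reports across visits are
  resolved by imaging-visit precedence uniformly.
- Imputation follows the missForest recipe: initial mean/mode fill,
  variables swept in ascending missingness, each regressed on all others
  with a 100-tree random forest (regression for continuous, classification
  for integer-coded categoricals), iterating until the combined change
  score (normalized squared change in continuous imputed cells plus
  disagreement count in categorical cells) stops decreasing — the previous
  sweep is then returned — or 10 iterations. Observed cells are never
  altered; categorical imputations take only observed codes; everything is
  seeded.
- Menopause derivation: hysterectomy without bilateral oophorectomy →
  EXCLUDED; a reported age at menopause, a "yes", or age strictly over 70
  ("over 70" read literally) → postmenopausal, surgical when a bilateral
  oophorectomy at or prior to the reported age at menopause is on record,
  natural otherwise; an explicit "no" → PRE; unresolvable (unsure/missing)
  → EXCLUDED. The over-70 rule takes precedence over an uncertain or "no"
  report, since age is concrete evidence. The four categories partition
  all female inputs (property-tested).
- z-scoring rejects constant columns by name rather than silently emitting
  NaN.

## Post-hoc models

Score and region-wise models are OLS with continuous variables (outcome
included) z-scored first, so slopes are standardized betas; binary and
categorical predictors enter as treatment contrasts and are not rescaled.
The menopause reference level is natural menopause, so surgical effects
read as contrasts against the postmenopausal norm. Interactions require
their main effects (hierarchy), and the three-way age × sex × PRS model is
expanded hierarchically. Multi-contrast terms are judged by their joint
Wald F. BH-FDR is applied across regions within one term and one model
(whole-map, not per hemisphere, and never pooled across models), at 5% for
the age × sex map and 20% for the smaller age × menopause analysis.

Age matching is greedy 1:1 (configurable k:1 for the male group)
nearest-neighbor without replacement: the smallest group is the template,
visited in ascending id order, ties broken by ascending id — fully
deterministic, mirroring the default "nearest" method of standard matching
software. Group differences in scores are one-way ANOVA.

## The synthetic cohort generator

The generator is the package's study population. Defaults: ages uniform on
44–82 years; 55.2% female; 64 thickness regions around a 2.5 mm baseline
with a 0.1 mm per-unit scale; k latent components with strictly decreasing
strengths shared between blocks through orthonormal salience matrices
(subject scores iid standard normal, components independent — the
orthogonal-component model the SVD assumes); Gaussian noise with
configurable SD on the latent scale; risk factors discretized by quantile
binning into ordered codes (a mixed binary/3-level/5-level/continuous
cycle by default), which preserves monotone association after integer
coding; 2% missing completely at random where enabled. Menopause status
follows an age-logistic curve centered at 51 years (width 2.5), thinned so
the expected premenopausal share matches its configured fraction (default
5%, with 78% natural, 12% surgical, 5% inconsistent reports) — making PRE
the youngest and smallest group, which is exactly the age–menopause
confound the matched designs exist to handle. Covariate effects on
thickness (age, sex, and interaction slopes on chosen region subsets) are
planted in standardized units and returned as ground truth.

What the generator does **not** emulate: real marginal distributions or
units of any biobank field, vertex-level surfaces, systematic (non-MCAR)
missingness, dependence between risk factors beyond the planted
components, or diagnosis-based exclusions. Passing tests therefore
demonstrate that the machinery recovers known structure under its own
assumptions — not that any particular epidemiological finding replicates.

A note on recovery measurement: planted saliences are defined on the
generator's latent (covariance) scale. Z-scoring divides each column by
its own SD, which rescales salience rows, so fitted saliences from
z-scored data align closely but not perfectly with the planted ones even
at low noise; recovery checks against ground truth are made on centered,
unscaled data, where the noiseless case is exact.

## Problem sizes and reproducibility

Default resampling counts follow the reference analysis (5,000
permutations, 5,000 bootstraps, 200 split-half iterations); the pipeline's
test profile and the calibration suite use reduced counts (hundreds) and
desk-scale cohorts (n in the hundreds to low thousands, p ≤ 64, q ≤ 12),
chosen so the full suite runs in about a minute while keeping Monte-Carlo
error well inside the asserted tolerances. Every stochastic stage draws
its own seed from the pipeline seed, and rerunning a design with the same
seed reproduces every output file byte for byte (timestamps go to the
console log only, never into result files).

## Known limitations

- The BSR null calibration is slightly conservative (pooled exceedance
  ~0.035–0.045 rather than 0.050) because bootstrap SEs of ordered-LV
  quantities absorb LV-ordering variability; the reliability threshold is
  therefore mildly strict, never anticonservative.
- Greedy matching is order-dependent by design (determinism was chosen
  over optimality); optimal matching can achieve smaller total age gaps.
- The imputation contract targets the missForest algorithm, not the R
  package byte-for-byte; forests differ across implementations.
- No regression-mode PLS, sparse/penalized variants, jackknife, BCa
  intervals, or rotation-based permutation schemes.
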