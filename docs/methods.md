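# Methods

## Scope and model family

The package implements the analysis battery used in cross-sectional
air-pollution mixture epidemiology where the outcome is a *predicted* risk
score rather than incident events: each participant's 10-year ASCVD risk is
computed from a Cox-score equation, dichotomized at 10%, and the binary
"high predicted risk" indicator is related to constituent-resolved PM2.5
exposure by logistic regression. All effect estimates are odds ratios with
Wald 95% confidence intervals (z = 1.96); profile-likelihood intervals are
out of scope. Analyses are complete-case: rows missing any model variable
are dropped.

## Synthetic cohort generator

The generator exists so that every downstream stage is testable without
access to any cohort's raw data. It emulates three structural features of
speciated-exposure cohort data:

1. **Correlated constituents with mass closure.** The six constituents are
   drawn from a Gaussian copula. Marginals are zero-truncated normals (or
   moment-matched lognormals) with configurable means and SDs; defaults are
   BC 5.190 ± 0.947, NH4 10.694 ± 1.431, NO3 18.016 ± 2.619, OM
   15.659 ± 1.746, SO4 14.624 ± 1.827, SOIL 9.655 ± 1.579 µg/m³. With the
   default means the truncation point lies ≥ 5 SD below the mean, so the
   truncation bias on means is negligible (< 1e-6 µg/m³). The default copula
   correlation is a one-factor structure with loadings
   (0.995, 0.850, 0.995, 0.714, 0.900, 0.714), chosen so the off-diagonal
   correlations span [0.51, 0.99] — the range reported for such data —
   while remaining positive semi-definite by construction. Total mass is
   either the exact constituent sum (`exact_sum`, used by the ISM identity
   tests) or the sum plus an independent truncated-normal unspeciated
   remainder (`residual_mass`, the default; mean 1.400 µg/m³ so the total
   averages 75.238 µg/m³, SD 0.4 µg/m³ as a realistic closure-gap spread).
   Real speciation data close only approximately, which is why
   `residual_mass` is the default and why the ISM identities are asserted
   only under `exact_sum`.

2. **Covariates.** Categorical covariates are sampled from configured
   probability vectors stored as exact count fractions (so they sum to 1 to
   machine precision); the first listed level is the downstream reference
   level. Continuous risk factors are independent normals (age
   55.898 ± 9.782 y, waist 84.232 ± 10.209 cm, SBP 125.566 ± 19.478 mmHg,
   TC 184.676 ± 37.361 mg/dL, HDL-C 51.287 ± 12.891 mg/dL). The
   antihypertensive-treatment prevalence is entered as its cohort-wide
   marginal (4,365/31,162 ≈ 14.0%), since the within-hypertensives
   percentage is not a sampling probability. Region defaults to a constant
   single northern level, reflecting a single-province rural cohort; risk
   tables mean-center their region term so a constant region cancels.
   Covariates are sampled independently of exposures by default: any
   exposure–covariate confounding is a user-supplied configuration, not a
   baked-in assumption, because the true joint structure is unpublished.

3. **Outcome with known ground truth.** The logistic mechanism draws
   Y ~ Bernoulli(expit(α + Σ βⱼxⱼ)) with user-chosen coefficients (the
   recovery-test ground truth) and calibrates α by bisection on [−20, 20] to
   a prevalence tolerance of 1e-4 (default target 28.143%); an unreachable
   target raises rather than clips. The alternative mechanism scores the
   generated risk factors through a coefficient table and thresholds
   predicted risk at 10%.

What passing tests on this generator do **not** show about real data:
exposures here have no spatial structure, no measurement error, no
exposure–covariate confounding under the defaults, and normal (not skewed)
risk-factor marginals. Effect estimates on real cohorts face all four.

## Exposure windows

Long-term exposure is the arithmetic mean of exactly `years` × 12 monthly
values ending with the month *before* the baseline month (the baseline month
itself is excluded), for windows of 3 (primary), 5, 8 and 10 years.
Participants without full coverage are excluded from that window's fit and
counted in the output.

## Risk engine

Risk tables are versioned YAML with sex-specific term lists (name, transform,
coefficient, derivation-cohort mean) and a baseline survival S0 ∈ (0, 1).
Transforms are limited to identity, natural log, equality indicator and
product interaction — sufficient for Cox-score equations of this family.
The package deliberately ships **no published coefficients**: the bundled
table (`data/synthetic_risk_coefficients.yaml`) is synthetic, for tests and
demonstrations; users supply published sex-specific tables in the same
schema. Plausibility ranges (e.g. SBP 60–260 mmHg) warn rather than fail,
and can be disabled.

## Regression core

Fits use maximum likelihood via Newton–Raphson (statsmodels) with tolerance
1e-10 and an explicit post-fit gradient check (max |score| < 1e-6 required
for `converged`). Separation is detected both from fitted probabilities
pinned at 0/1 and from runaway coefficients (|β| > 50) and raised as an
error, never returned silently. Rank-deficient designs are errors; condition
numbers above 1e8 warn but proceed — substitution designs are strongly
collinear by nature, and refusing to fit them would forbid the method. The
small-instance oracle maximizes the same likelihood by Nelder–Mead with a
Powell polish (derivative-free, independent of the Newton path) and is
restricted to ≤ 30 rows × ≤ 4 columns; it exists only for cross-checks.

Dummy encoding uses the first category of each pandas Categorical as the
reference level (for the generator's defaults: female, married, lowest
education/income, never-smoker/drinker, low physical activity, "no" diet
flags). Exposure scaling is exact: dividing the exposure by s multiplies β̂
by s, and ORs are reported per 1 unit of the scaled exposure.

## Constituent methods

Concentration models are fit as separate single-pollutant models — total
PM2.5 in its own model and each constituent alone — because the parallel
rows of the standard results-table layout correspond to separate fits; total
mass co-adjustment is available behind `adjust_total=True`. Proportions are
expressed in percent so "one percentile increase" equals +1 regressor unit,
with total mass always co-adjusted. Residuals are computed by OLS of the
constituent on total mass *within the analysis sample* (no external
calibration sample is involved), guaranteeing zero mean and exact
orthogonality to total mass, so the residual models do not re-enter total
mass.

## Isochronous substitution model

Leave one constituent out, keep total mass and the other five. Because total
mass is held fixed, the coefficient of a retained constituent k in the
leave-j-out model estimates the log-OR of replacing 1 µg/m³ of j with
1 µg/m³ of k. Under exact closure this model is a linear reparameterization
of the all-constituent model without total mass, giving
β̂ₖ^(−j) = β̂ₖ − β̂ⱼ exactly; the suite asserts this, plus reciprocity and
transitivity of the log-ORs, to 1e-6. Under approximate closure the
identities hold only up to the residual-mass share, so they are not asserted
there. Including total mass *and* all six constituents under exact closure
is rank-deficient and raises.

## Splines

Restricted cubic splines use the truncated-power basis normalized by
(t_K − t_1)², K ∈ {3, 4, 5}, default K = 4 at the 5th/35th/65th/95th
percentiles (the standard recommendation; the choice is not data-driven per
fit). The reference exposure defaults to the sample median and the curve is
evaluated on 100 points between the 1st and 99th percentiles to avoid tail
extrapolation. OR(x) = exp(η̂(x) − η̂(x_ref)) with pointwise Wald bands from
the delta method on the spline coefficients; OR(x_ref) = 1 identically.
Nonlinearity is a likelihood-ratio test of the K − 2 nonlinear terms.

## Stratified analysis and interaction

Subgroups are refit independently per stratum with the stratifier removed
from its own adjustment set; strata too small to identify the model are
skipped with a log entry, not an error. Interaction is tested in the pooled
model by LRT on the exposure × stratifier product terms (df = levels − 1);
Wald on the same terms is available and agrees with the LRT in large samples
(verified at n = 20,000). Multi-level stratifiers are tested as factors
(2-df), not as trends. No multiplicity correction is applied across the
stratifier × pollutant grid.

## Numerical and design choices

- Half-up decimal rounding (not banker's) for exported percentages and ORs,
  3 decimals, matching the convention of published tables in this area.
- All randomness flows from explicit integer seeds; `generate_cohort` spawns
  named substreams so stages can be regenerated independently, and the
  pipeline manifest records the seed.
- Calibration suites in the tests use deliberately modest problem sizes —
  Wald-coverage at 500 replicates of n = 2,000, nonlinearity and interaction
  type-I error at 1,000 replicates of n = 400 — sizes at which the asymptotic
  calibration being tested already holds while the whole suite stays fast.
- The acceptance script draws the full reference cohort size (n = 31,162)
  once, which is well within the two-standard-error band it is checked
  against.

## Known limitations

- Reference ORs from large real cohorts (e.g. BC Model 2 ≈ 1.49) are carried
  in tests as documentation of output shape only; they are not reproducible
  from synthetic data and are never asserted numerically.
- The generator does not model spatial exposure assignment, measurement
  error, missing data, or exposure–covariate confounding (configurable but
  off by default).
- The risk engine performs no recalibration; a table derived in one
  population misestimates absolute risk in another, which propagates to the
  high/low classification.
- Substitution ORs inherit the instability of near-collinear designs; the
  recorded condition numbers and wide CIs flag this rather than suppress it.
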