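# Methods

This note documents the statistical model the package implements, the
conventions and numerical choices behind it, what the synthetic-data
generator does and does not emulate, and the known limitations. It is the
package's own account of its science; every number quoted is computed by
the test suite or by `scripts/acceptance.py`.

## The joint abundance index

The analysis fuses three long-running survey programs that observe the
same underlying bird population on incompatible scales: hunter-reported
total harvest (AGTS), mean birds per breeding-season route (BBS), and mean
birds per winter count station (CBC). The fusion is deliberately simple:

1. every survey record is reduced to a county-year observation;
2. the response is transformed (`log1p` by default, since the three
   sources span orders of magnitude and counts are multiplicative) and
   z-scored *within survey type*, using the mean and sample SD over the
   rows of the current restricted dataset;
3. the standardized responses are stacked into one table, with survey
   type retained as a mandatory fixed factor so that residual intercept
   differences between sources are absorbed.

Covariates always enter with a one-year lag: abundance in year *t* is
modelled from conditions in year *t − 1*, because recruitment responds to
the previous season's weather, land use, and predation pressure. Rows
with a missing value in any predictor under consideration are dropped
(complete cases), and the standardization is recomputed on whatever set
survives — each of the three analyses (main, pesticide, crop) therefore
has its own calibration of the index.

Because the z-scoring happens per survey, a fitted slope is in "index SDs
per predictor unit". To compare against a latent-scale effect (or report
one), slopes and SEs are multiplied back by the mean of the per-survey
standardization SDs (`assembly.latent_scale`); with a log response this
recovers effects on the log-abundance scale up to the (small) spread in
per-survey SDs.

## The mixed model

Every candidate is a Gaussian linear mixed model of the standardized
index:

    z ~ survey_type + effects + (1 | region / county)

with random intercepts of county nested within region (county-only in
regional re-analyses). Estimation is by **maximum likelihood, not REML**,
because candidates differ in their fixed effects and are compared by
AICc; REML likelihoods are not comparable across fixed-effect structures.
Fitting is delegated to `statsmodels`' `MixedLM`; boundary fits (a
variance component estimated at zero) are routine and valid, and the
fitter cascades through optimizers (default, L-BFGS, Powell,
Nelder–Mead) because gradient methods often report failure precisely at
such boundaries. A model whose optimization genuinely fails, or whose
log-likelihood is not finite, is excluded from the model set with a
warning.

Design parametrization (fixed across the package, because coefficient
meaning depends on it): main effects enter in original units; calendar
year is centered at the dataset mean; interaction columns are products of
mean-centered components. Only the highest-order coefficient of an
interaction family is invariant to the centering choice — lower-order
terms are interpreted *at the means*. Survey type uses treatment
contrasts with the alphabetically first level (AGTS) as reference.

The parameter count `k` for AICc includes fixed coefficients, variance
components, and the residual variance. The "at most 8 estimated
parameters" constraint of the model-set analysis applies to the *fixed*
count (intercept + 2 survey contrasts + slopes, shared mains counted
once), which is what reproduces a top model with two cropland-by-year
interactions at exactly 8.

## Model-set analysis

Candidate models are all subsets of at most four candidate effects (an
interaction candidate counts as one effect and brings its hierarchy:
mains and lower-order interactions), excluding any model that contains
both members of a correlated predictor pair (|Pearson r| ≥ 0.65,
inclusive; interactions inherit their components' prohibitions) and any
model over the fixed-parameter cap. The cap is lifted in the pesticide
analysis, whose three-way interactions (cropland × pesticide × year)
need 8 slope terms by hierarchy alone.

Ranking uses AICc differences Δᵢ and Akaike weights
wᵢ = exp(−Δᵢ/2) / Σ exp(−Δⱼ/2). A candidate screened in the grouped
variable-reduction stage is carried forward when its single-candidate
model sits at least 2 AICc units below the baseline (survey type only)
**and** below the null (random effects only). The 2-unit rule is applied
inclusively (≤ baseline − 2); the narrative wording it derives from is
ambiguous between "more than" and "at least", and the inclusive reading
is flagged here as an interpretive choice.

### Representation-adjusted importance

Raw per-covariate importance (the sum of weights of models containing the
covariate) is biased when covariates appear in different numbers of
models — inevitable under correlation screening and the parameter cap.
The adjusted probability contrasts mean weights instead: with covariate
*j* in m⁠ⱼ of M models,

    Aⱼ = (Σ_{i: j∈i} wᵢ) / mⱼ,   Bⱼ = (Σ_{i: j∉i} wᵢ) / (M − mⱼ),
    pⱼ = Aⱼ / (Aⱼ + Bⱼ),         adjusted ER = pⱼ / (1 − pⱼ).

This mean-weight-contrast-plus-odds form was reconstructed from the
published importance tables, where every printed (probability, ER) pair
satisfies ER ≈ p/(1−p) at two decimals; it is documented as an inference,
and the raw weight sum is always reported alongside. When pⱼ = 1 the ER
is rendered ">100", the same convention used for any ER above 100. A
covariate in exactly half the models satisfies pⱼ = raw weight sum, so
the adjustment is a strict generalization of the usual weight-sum score.
Ranks sort by descending pⱼ, ties broken by descending raw weight sum,
then name (no convention was stated; this one is deterministic).

## Effect summaries

Predictions hold all other design columns at their data means (which
averages the survey contrasts at their observed proportions) and take
95% intervals from the fixed-effect covariance only — random effects
enter neither the point prediction nor the band. Pesticide slices pin
pesticide at the 10th/90th empirical percentiles (linear-interpolation
quantiles) and year at the midpoint of the early (1991–2000) or late
(2001–2013) era, while both stay continuous in the model.

Percent-change effects divide the slope (in index units per predictor
unit) by a reference index level, by default the mean of the
pre-standardization (transformed) response over the fitted dataset, and
multiply by 100. How a standardized-index coefficient becomes a
percentage is not recoverable from the source analysis; this
back-transform is an explicit reconstruction and the reference is
configurable.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes —
it is the package's test bed, not a calibration to any real dataset:

- a latent log-abundance per county-year,
  log λ = intercept + u_region + u_county + Σ βⱼ xⱼ(t−1) + ε, with
  N(0, σ²) region/county intercepts and year-level process noise ε;
- covariate panels with the study's structural missingness: three survey
  spans that differ by design (defaults 1948–2010 harvest, 1974–2012
  breeding counts, 1914–2013 winter counts), pesticide only from 1990,
  per-crop percentages only from 1980, plus
  missing-completely-at-random coverage within spans;
- county-trended land-use percentages, Dirichlet crop shares bounded by
  harvested cropland, county-mean-centered climate draws, counts of
  corvids/raptors/turkeys with a mild upward trend, and pesticide rates
  that increase on average from their start year;
- observation models per survey: Poisson for route/station counts,
  negative binomial for harvest (heavier tail, as self-reported totals
  warrant), each with its own detectability multiplier q_s.

Structurally missing pesticide is treated as zero *exposure* in the
latent process (the panel cell stays missing): otherwise any latent
pesticide effect would truncate the entire latent series to post-1990.

Not emulated, hence outside what passing tests can show: spatial
autocorrelation between counties, hunter-effort dynamics, route-level
observation structure, and real-world covariate collinearity beyond what
the share construction induces.

## Validation experiments and their conditions

The canned experiments (`jointabund.experiments`) fix their generative
conditions deliberately:

- **Parameter recovery** (4 regions × 8 counties × 40 years × 3 surveys,
  50 replicates): one climate covariate with latent effect β = 0.15,
  process noise σ = 0.05, moderate counts. In this
  observation-noise-dominated regime the Gaussian LMM is approximately
  well-specified and its CIs are close to calibrated (the reproduction
  script reports the mean estimate, relative error, and coverage).
- **Type-I error** (same width, 20 years, all β = 0): the full 32-county
  layout is used because with few counties the county-intercept variance
  is poorly resolved and covariates with between-county mean structure
  become mildly anticonservative.
- **Joint vs. single-survey precision**: three unbiased surveys with
  comparable observation noise. Pooling under a homoscedastic model then
  strictly helps, and the joint fit's SE is below the best single
  survey's.

Known limitations, observed in the misspecified regimes: (i) strong
effects make the log-count observation noise heteroscedastic in the
covariate, and model SEs then understate the sampling variance (coverage
dropped to ~86% at β = 0.3 in exploratory runs); (ii) the three surveys
observe the *same* latent realization, so large process noise induces
residual correlation across surveys within a county-year that the model
ignores — with three near-noiseless surveys the joint SE can be
optimistic, and a single survey that is far cleaner than the others can
beat the pooled fit. Both effects are properties of any analysis of this
form, not of this implementation.

## Numerical conventions

- AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); an error is raised when
  n − k − 1 ≤ 0.
- Conditional R² = (σ²_fixed + σ²_region + σ²_county) / (that + σ²_resid),
  with σ²_fixed the sample variance (ddof 1) of the fixed linear
  predictor; NaN flags the all-zero-variance degenerate case.
- Sample SDs everywhere use ddof 1; a survey whose transformed responses
  have SD below 1e−12 (relative) cannot be standardized and raises.
- Akaike weights are computed from Δ values, so they are invariant to a
  constant shift in AICc at 1e−12.
- Correlation screening treats a constant covariate (undefined r) as
  forbidden with every partner, with a warning.
- Non-PD fixed-effect covariance at a variance boundary yields NaN SEs
  for the affected columns rather than a fabricated number.

## Problem sizes

Default pipeline runs use 4 regions × 6 counties over the full span union
(1914–2013); validation experiments use the sizes listed above. These
sizes resolve all the qualitative behaviour the tests assert while
keeping a full run in seconds and the complete validation sweep in under
a minute.
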