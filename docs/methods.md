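# Methods

## Problem and estimation unit

The package estimates mean daily intake (g/d) of seven animal-source foods
(ASF) for children and adolescents (0–19 completed years), jointly by
country, year and demographic stratum. The stratum — one cell of age group
{<1, 1–2, 3–4, 5–9, 10–14, 15–19} × sex {female, male} × parental education
{low <6 y, medium 6–<12 y, high ≥12 y} × urbanicity {urban, rural}, 72 cells
in all — is the atomic estimation unit. Inputs are per-stratum survey
summaries (mean, SD, sample size) plus survey metadata (assessment method,
national representativeness, individual- vs household-level), per-stratum
population weights, and national per-capita food-availability series.

## Harmonization

Surveys report intakes at heterogeneous energy levels. Intakes are
energy-standardized by multiplicative density scaling,
`mean × (standard kcal / observed mean kcal)`, to age-band standards of
700 (age <1), 1,000 (1–<2), 1,300 (2–5), 1,700 (6–10) and 2,000 (11–19)
kcal/d; the SD scales by the same factor and zeros are preserved. The model
age groups do not nest exactly in the energy bands: 5–9 straddles the
2–5/6–10 boundary at age 5 and 10–14 straddles 6–10/11–19 at age 10. Each
group is assigned the band covering the majority of its completed-year
span (5–9 → 1,700; 10–14 and 15–19 → 2,000; 3–4 → 1,300). The two-year
group 1–2 ties between the 1–<2 and 2–5 bands and is assigned the lower
band (1,000 kcal). This is a declared convention: a per-individual
adjustment would avoid it, but stratum summaries cannot. Records carry an
`energy_adjusted` flag making the operation idempotent; records without a
reported mean energy must be skipped explicitly.

Serving conversions use fixed portion sizes — milk 245 g, cheese 42 g,
yogurt 245 g, eggs 55 g, seafood 100 g, unprocessed red meat 100 g,
processed meat 50 g — applied after aggregation (the conversion is linear,
so the order does not change values; converting once controls rounding).
Display rounding is half-away-from-zero, which is what reproduces printed
values such as 18/50 = 0.36 → 0.4.

## The hierarchical model

Per ASF, on the natural-log scale:

* likelihood `log y_i ~ N(η_i, v_i · φ^{flag_i})` with delta-method
  sampling variance `v_i = (sd_i/mean_i)²/n_i`, floored at 1e-4 (the floor
  binds only for degenerate inputs such as sd = 0);
* `η = β₀ + u_region + u_country + age + sex + education + urbanicity +
  b_method + γ·z`, with reference levels age <1, female, low education,
  rural, 24-hour recall;
* nested exchangeable random effects `u_region ~ N(0, σ_R²)`,
  `u_country ~ N(0, σ_C²)`;
* `z` is the food-availability covariate z-scored within ASF over the full
  covariate table (so fitted and predicted country-years share one scale);
  this slope is the model's time component — intake trends enter through
  the availability series;
* `flag` marks surveys that are not nationally representative or report
  any factor collapsed ("all"); `φ ≥ 1` is a single estimated
  multiplicative variance-inflation factor shared by all flagged
  observations;
* coarse cells enter as observations of the population-weight-averaged
  linear predictor over the collapsed fine strata, which keeps the
  likelihood linear in all location parameters (see Limitations);
* each ASF is fitted independently; no cross-ASF pooling.

Priors are weakly informative and configurable: `β₀ ~ N(0, 10²)`, all
fixed-effect contrasts and the slope `N(0, 1)`, `σ_R, σ_C ~ HalfNormal(0.5)`
and `φ − 1 ~ HalfNormal(1)`.

### Sampler

Given (σ_R, σ_C, φ) the model is linear-Gaussian, so all location
parameters have an exact multivariate-normal full conditional, sampled by
Cholesky factorization of the posterior precision (the Gram matrices of
flagged and unflagged observations are precomputed once, so each sweep
costs O(p³) with p ≈ 14 + #regions + #countries). σ_R, σ_C and φ are
updated by univariate stepping-out slice sampling on log σ and
log(φ − 1). This blocked Gibbs scheme has no step-size tuning and mixes
quickly; 500 warmup sweeps and 4,000 retained draws (the reference
configuration) split across 2 chains complete in seconds at the scale of a
few thousand observation rows. Split-R-hat is computed with `arviz` for
all parameters when ≥2 chains are run; values above 1.05 raise a warning
in the fit report (never silently).

### Prediction

Posterior draws of a stratum's mean intake are `exp(η)` with method bias
at the reference. A country without surveys takes its fitted region effect
plus a country effect drawn per posterior draw from `N(0, σ_C)` — the
predictive distribution — which is how missingness widens its intervals
(a property test asserts unsurveyed-country intervals are wider on
average). Summaries are the 2.5/50/97.5 linear-interpolation percentiles
of the draws.

## Aggregation

All rollups are computed draw-wise: for each retained draw, the
population-weighted average `Σ w_s x_sd / Σ w_s` over in-scope strata, then
percentiles of the aggregate's draw vector. Aggregating summaries instead
would be wrong for skewed posteriors, and a test demonstrates the
difference on a skewed fixture. Subgroup contrasts (e.g. high vs low
education) difference the two levels' rollups within each draw, each level
weighted by its own population; period differences aggregate both years
with the comparison year's weights (2018 by default) so demographic change
is held fixed. Fold differences are exact max/min ratios of group means;
cross-ASF rank correlations use average-rank Spearman, with pairs
involving a constant column reported as undefined rather than silently
NaN.

## Synthetic-data generator

The generator shares the model's parameterization, so recovery is
well-defined. Defaults define the reference study conditions:

* world layout 4 regions × 5 countries × 2 surveys per country, years
  1990 and 2018;
* effect scales σ_region = 0.3, σ_country = 0.2 (log scale); age profile
  rising from 0 (<1 y) to +0.75 (15–19 y); sex contrast +0.02 (near
  parity); education +0.10/+0.30 (medium/high vs low); urban +0.15;
* method biases ffq +0.10, short questionnaire −0.15, household budget
  +0.20 (24-hour recall 0), fixed and known so the model's bias terms are
  identifiable;
* availability covariate: linear-plus-noise country series with a mildly
  positive trend; the truth's time slope (0.15) applies to the z-scored
  series, z-scoring being done identically by generator and model;
* survey heterogeneity: 88% nationally representative, 25% coarse
  (each factor collapsed with probability 1/2, at least one), method mix
  50/30/10/10; per-stratum sample sizes log-normal (median 100, log-SD
  0.6, minimum 10); within-survey log-SD 0.5, so a reported SD encodes the
  CV and the model's delta-method variance recovers the noise scale;
  overdispersion factor 2.0 for flagged surveys;
* intercepts anchored at plausible global mean intakes per ASF
  (e.g. log 100 g/d for milk).

Noise is multiplicative log-normal, matching the model's log-scale
likelihood, because intakes are positive and right-skewed. Coarse cells
report population-weighted averages of fine-stratum true means on the
natural scale. Everything is reproducible bit-for-bit from one seed
(`numpy.random.SeedSequence` spawning per stage).

What the generator does *not* emulate: item-level dietary measurement
error, seasonal and day-to-day variation collapsed into survey means,
non-random survey placement (real surveys are denser in richer countries),
reporting-unit heterogeneity needing real harmonization decisions, and
household-to-individual disaggregation (household-budget records are
treated as pre-disaggregated means, flagged non-individual-level). Passing
recovery and calibration tests on this generator therefore shows the
estimator is correct and calibrated *under the model's own assumptions*,
not that the assumptions hold for any real survey database.

## Cross-validation and screening

Fivefold cross-validation omits ~20% of surveys per fold at the survey
level (all strata of a survey move together, preventing leakage), refits,
and predicts each held-out cell with the held-out survey's method bias
applied. Reported metrics: Pearson and Spearman correlation, mean error
and RMSE on log and natural scales, and empirical coverage of 95%
prediction intervals (which add the observation-level noise, inflated by
the posterior φ for flagged cells). Folds with R-hat warnings are excluded
from pooled metrics with notice. A numeric plausibility screen lists any
stratum summary outside broad per-ASF bounds.

## Validation-test design choices

* Stratum-level interval-coverage indicators are strongly correlated
  within a country (all 72 strata share the country effect), so the
  calibration test pools several independently seeded worlds and sets its
  binomial tolerance from the number of independent country clusters, not
  the raw stratum count.
* Recovery coverage is assessed pooled over monitored parameters ×
  replicates; demanding every parameter jointly in every replicate would
  require super-nominal calibration even from an exact sampler.
* The near-noiseless cross-validation world uses 4 surveys per country so
  that a fold rarely orphans an entire country; predictions for fully
  unobserved countries correctly carry the unknown country effect, which
  is a feature tested separately, not a CV accuracy failure.
* Test problem sizes (20 countries, 1,000 retained draws, 20 recovery
  replicates, 3 calibration worlds) were chosen as the smallest worlds at
  which the monitored frequentist properties stabilize.

## Limitations

* The weight-averaged *linear predictor* for coarse cells is the log of a
  weighted geometric mean, while a coarse survey physically reports an
  arithmetic mean; the Jensen gap (≈ half the variance of η across the
  collapsed strata) slightly inflates coarse observations relative to the
  model. It is second-order at the default effect scales and partially
  absorbed by the overdispersion factor, but grows with the demographic
  spread of the collapsed strata.
* The time component is a single covariate slope shared across countries
  per ASF; country-specific trend deviations load onto the country effect
  and the residual.
* Demographic contrasts are global; an optional region interaction is not
  implemented.
* Observations with zero mean intake cannot enter the log-scale likelihood
  and are dropped with notice; in sparse-food settings (cheese, yogurt in
  some regions) this can bias national means upward.
* One overdispersion factor is shared by all flagged surveys; the
  inflation mechanism in real data is surely more heterogeneous.
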