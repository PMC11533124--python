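# asfintake

Global dietary surveillance of children and adolescents rests on sparse,
heterogeneous survey data: a few hundred national surveys, reported as
per-stratum summaries, with different assessment methods, different
representativeness, and whole countries missing. `asfintake` implements a
reusable pipeline for estimating animal-source food (ASF) intake — milk,
cheese, yogurt, eggs, seafood, unprocessed red meat and processed meat — for
every country-year and each of the 72 joint demographic strata (6 age groups
× 2 sexes × 3 parental-education levels × urban/rural), with full
uncertainty propagation from the model posterior to every reported number.

It is written for quantitative nutrition and global-health researchers who
need small-area intake estimates from stratified survey summaries, and for
methodologists studying calibration of such models: a synthetic-data
generator with known ground truth is a first-class part of the package.

## Model

For one ASF, the observed log mean intake of survey stratum *s* in country
*c* (region *r*), year *t*, assessed by method *m*:

```
log y ~ Normal(η, v · φ^flag)
η = β₀ + u_r + u_c + αᵃᵍᵉ + αˢᵉˣ + αᵉᵈᵘ + αᵘʳᵇ + b_m + γ z_ct
u_r ~ N(0, σ_R²),  u_c ~ N(0, σ_C²)
```

with nested country-in-region random effects, global demographic contrasts,
fixed-reference method biases (24-hour recall = 0), a time component `γ` on
the z-scored national food-availability covariate `z_ct`, delta-method
sampling variance `v = (sd/mean)²/n`, and a shared overdispersion factor
`φ ≥ 1` inflating the variance of surveys that are not nationally
representative or not fully stratified. Coarse survey cells (factors
reported as `"all"`) enter as population-weight-averaged linear predictors
over the collapsed fine strata. Given the variance components the model is
linear-Gaussian, so the posterior is sampled by a blocked Gibbs sampler:
an exact multivariate-normal draw for all location parameters, slice
updates for σ_R, σ_C and φ; 4,000 retained draws by default, split-R-hat
diagnostics via `arviz`.

Every downstream quantity — population-weighted global/regional/national
means, education and urbanicity contrasts, 1990→2018 changes standardized
to 2018 population weights, fold differences, serving conversions — is a
functional of the posterior draws, computed draw-wise and summarized at the
2.5/50/97.5 percentiles.

## Worked example

```python
from asfintake import (AggregationQuery, ModelSpec, SurveyDesign, TruthConfig,
                       build_design, fit, predict_strata, simulate_world,
                       subgroup_difference, weighted_rollup)

world = simulate_world(TruthConfig(asfs=("milk",)), SurveyDesign(), seed=42)
design = build_design(world.surveys, world.covariates,
                      weights=world.weights, asf="milk")
fitted = fit(design, ModelSpec(n_draws=1000, chains=2, warmup=400, seed=0))
draws = predict_strata(fitted, [(c, 2018) for c in world.truth.countries])
print(weighted_rollup(draws, world.weights,
                      AggregationQuery(level="global")).summary())
```

Output of the full example script (40 synthetic surveys in 20 countries):

```
simulated surveys: 40 (2209 stratum rows) in 20 countries
max split-R-hat: 1.019
global mean milk intake 2018: 241 g/d (95% UI 240, 242) = 1.0 servings/day
high-vs-low parental education gap: +1.9 servings/week (95% UI 1.9, 1.9)
true generating education ratio: exp(0.3) = 1.35
```

The first line describes the simulated survey database; the rollup is the
population-weighted average of all 72 stratum posteriors in every country,
aggregated within each of the 1,000 posterior draws (hence the tight
uncertainty interval at this noise level); the education gap is the
draw-wise difference between the high- and low-education subgroup rollups,
converted to servings per week after aggregation. The generating truth for
this world put high-education intake 35% above low-education intake, which
the recovered absolute gap reflects at the world's intake level.

The same stages are available from the shell:

```
asfintake simulate --seed 1 --out-dir sim/
asfintake fit --surveys sim/surveys.csv --covariates sim/covariates.csv \
              --weights sim/weights.csv --asf milk --out draws.csv
asfintake aggregate --draws draws.csv --weights sim/weights.csv \
              --level region --unit servings/day --out regional.csv
asfintake validate --surveys sim/surveys.csv --covariates sim/covariates.csv \
              --weights sim/weights.csv --out cv.csv
asfintake run --config config.yaml --out-dir results/
```

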