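# sagecort

Bayesian models linking feather corticosterone (fCort) in female greater
sage-grouse (*Centrocercus urophasianus*) to non-native grazer pressure,
drought, and subsequent demographic rates.

Feathers integrate circulating glucocorticoids over the weeks they grow,
so fCort (pg of corticosterone per mm of feather) indexes chronic
physiological stress during the feather-growth season.  This package is
for quantitative ecologists who want to fit — or stress-test on synthetic
data — the full analysis chain behind that kind of study:

1. **Covariate construction** — grazing intensity as use-days/km²
   (head count × days present ÷ area, horses counted year-round),
   per-bird averages over relocations, a mass-residual body-condition
   index (mass regressed on PC1 of wing and tarsus), z-standardization
   with stored constants, and grazer × climate interaction terms.
2. **Corticosterone model** — a Bayesian negative-binomial GLM for
   integer fCort: log μ_i = x_i′β with constant shape r
   (Var = μ + μ²/r), normal(0, 10) prior on the intercept and a common
   normal(0, v) shrinkage prior on the nine slope terms, v tuned by
   eightfold cross-validated mean absolute prediction error over
   {0.001, …, 1}.
3. **Demography** — four models of fCort effects on vital rates:
   weekly known-fate survival with seasonal offsets (winter intercept),
   Bernoulli breeding propensity and nest success, and zero-inflated
   Poisson fledged-chick counts.
4. **Diagnostics** — MAPE, seeded k-fold partitions, Moran's I with a
   permutation test on residuals, split-R-hat/ESS convergence reports.
5. **Synthetic populations** — a generator calibrated to the published
   coefficient table (intercept 3.779 log pg/mm, horses × precipitation
   −0.125, …) with the NB shape r\* ≈ 0.142 reconstructed so that 65% of
   birds fall below 10 pg/mm, plus encounter histories and breeding
   outcomes drawn from the demographic models themselves.

Models are scikit-learn-style estimators (`fit`, `predict`,
`get_params`, fitted attributes with trailing underscores) built on an
emcee ensemble-sampler MCMC layer; posterior tables report mean, SD, 95%
credible bounds, and Pr<0 / Pr>0 per coefficient.

## Worked example

```python
import sagecort

# a synthetic population at the default (published-table) calibration
data = sagecort.generate(sagecort.SyntheticConfig(n_birds=2000, seed=101))

model = sagecort.NegativeBinomialRegressionCV(random_state=55)
model.fit(data.design, data.birds.fcort_pg_mm)
print(f"selected slope prior variance: {model.prior_var_}")
print(model.summary_.round(3).to_string(index=False))
```

```
selected slope prior variance: 0.15
                  term  estimate    sd    lci    uci  pr_lt_0  pr_gt_0
             intercept     3.902 0.106  3.698  4.120    0.000    1.000
                  cows    -0.024 0.063 -0.148  0.100    0.648    0.352
                horses    -0.117 0.060 -0.235  0.001    0.974    0.026
        body_condition     0.039 0.058 -0.077  0.154    0.251    0.749
                   age    -0.170 0.123 -0.419  0.068    0.920    0.080
          annual_grass    -0.000 0.056 -0.111  0.110    0.500    0.500
         precipitation    -0.159 0.058 -0.272 -0.042    0.997    0.003
horses_x_precipitation    -0.093 0.059 -0.208  0.020    0.946    0.054
 horses_x_annual_grass     0.059 0.057 -0.050  0.172    0.156    0.844
  cows_x_precipitation    -0.144 0.064 -0.267 -0.020    0.989    0.011
```

Estimates sit within two posterior SDs of the generating values — e.g.
horses × precipitation −0.093 (SD 0.059) against the truth −0.125.
`pr_lt_0`/`pr_gt_0` are the posterior mass below/above zero, the
probability statements this style of analysis reports instead of
p-values.

The demographic side works the same way:

```python
surv = sagecort.fit_survival(data.encounters, data.birds, seed=2)
print(surv.cort_row())           # fCort effect on weekly logit survival
# estimate 0.00122 (sd 0.00036), truth 0.001
print(surv.annual_survival(cort=44, age=1))   # 0.564
```

A `sagecort` command-line tool chains the stages
(`synth → prep → fit-cort → fit-demog → diagnose`, or `run-all`), writing
coefficient tables, posterior draws, the MAPE grid trace, Moran's I, and
convergence reports into one reproducible output directory:

```bash
sagecort run-all --n 280 --seed 1 --out results/demo
```

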