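# linprob

Linear-in-probability modelling of binary outcomes. With outcomes coded
`{-1, +1}` the model is

```
pr(Y = y | x) = (1 + y * beta'x) / 2        so  E(Y | x) = beta'x,
```

valid whenever the linear predictor `delta_i = beta'x_i` lies in `[-1, 1]`
for every row. Compared with the logistic model, the coefficients have a
direct reading in expected counts of individuals, at the price of a bounded
parameter space. The package provides:

- **Estimation** (`linprob.model`): OLS with the variance-corrected
  covariance `(x'x)^-1 - (x'x)^-1 x' D x (x'x)^-1`, `D = diag(delta_i^2)`;
  a one-step WLS variant (flagged when weights are floored — the row
  variance `1 - delta_i^2` is not bounded away from zero); and maximum
  likelihood constrained to `|delta_i| <= 1 - eps`, with an efficiency
  report showing the OLS-vs-ML variance gap is of order
  `max delta^4/(1 - delta^2) / n`. ML is fragile: a single observation
  out of range refutes the parameter under the likelihood, while OLS moves
  by O(1/n).
- **Out-of-range diagnostics** (`linprob.diagnostics`): the observed count
  `R` of fitted values outside `[-1, 1]`, its model-based expectation
  `lambda = sum_i p_i`, and `var(R)` including the pairwise dependence
  terms via bivariate-normal quadrant probabilities (one-dimensional
  quadrature, plus a fast truncated-normal-mean approximation).
- **Interpretation** (`linprob.interpret`): coefficients as expected-count
  changes (`m * beta_j / 2` per unit for continuous covariates; no halving
  for `{-1, +1}` binaries), an internal logistic fit, and the pairwise
  coefficient-ratio comparison between the two models.
- **Missing-value sensitivity** (`linprob.sensitivity`): refit under every
  high/low extreme assignment of the partially missing covariates
  (quartiles for continuous, `+-1` for binaries), full `2^k` factorial or
  a half fraction, with per-coefficient spread and missingness main
  effects.
- **Synthetic data** (`linprob.simulate`): generators honouring the model
  and the feasibility constraint, MCAR missingness, controlled
  out-of-range contamination, and a survey-like five-covariate preset.

## Command line

```sh
# synthetic study with missing values, written as CSV + truth sidecar
linprob simulate --n 2000 --seed 1 --out study.csv --truth-out truth.json

# fit (ols | wls | ml) and a coefficient table
linprob fit --input study.csv --outcome outcome \
    --covariates gender,test_score,log_income,race,lives_with_parent

# out-of-range diagnostic: R, lambda, var(R)
linprob diagnose --input study.csv --outcome outcome --covariates ...

# extreme-assignment sensitivity analysis over missing covariates
linprob sensitivity --input study.csv --outcome outcome --covariates ... \
    --csv-out sensitivity.csv

# linear vs logistic coefficient ratios
linprob compare --input study.csv --outcome outcome --covariates ...

# everything, driven by a YAML config, with JSON + text reports
linprob full --config analysis.yaml --output-dir out/
```

Config keys for `full` mirror `linprob.pipeline.AnalysisConfig`
(`input_path`, `outcome`, `covariates`, `coding`, `fitter`, `fit_ml`,
`sensitivity_levels`, `pair_mode`, `max_pairs`, `output_dir`, `seed`,
`na_tokens`). Flags override file values. Exit codes: 0 success,
2 validation error, 3 computation error.

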