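# natfert

Individual-level modelling of natural fertility with likelihood-free
estimation. The package simulates the monthly reproductive histories of a
cohort of women — lognormal age at marriage, an age-varying conception
hazard expressed in a cubic Bernstein basis with the window endpoints
pinned at zero, a fixed 9-month gestation and a post-partum amenorrhea
period — and estimates the five model parameters

`(mu_m, sigma_m, phi1, phi2, delta)`

from a vector of single-age fertility rates (ASFRs) by ABC rejection
sampling with per-parameter random-forest regression adjustment. A
Gamma-frailty extension (`z ~ Gamma(s, s)`, mean 1, variance `1/s`)
supports heterogeneity-scenario scans, and a cross-validation harness
quantifies parameter recovery via the variance-scaled prediction-error
statistic ERR.

## Layout

| module                | contents |
|-----------------------|----------|
| `natfert.fecundability` | Bernstein conception-hazard curve, peak finder, Gamma frailty |
| `natfert.simulate`      | monthly cohort simulator, ASFR reduction, completed fertility |
| `natfert.abc`           | priors, reference tables, rejection, RF adjustment, posterior predictive, heterogeneity scan |
| `natfert.validation`    | leave-one-out cross-validation, ERR, recovery experiment |
| `natfert.data_io`       | maternity-history CSV schema, intact-marriage filter, observed ASFRs, descriptive estimators, fixture writer |
| `natfert.cli`           | `natfert` command-line entry point |

## CLI

All subcommands take a YAML config, a root `--seed` and an `--out`
directory; every output CSV embeds the package version, seed and config
hash in header comments.

```sh
natfert simulate --config config.yaml --seed 1 --out run/       # histories + ASFRs
natfert observe  --histories run/histories.csv \
                 --cohort-min 1860 --cohort-max 1914 --out obs/  # filter + observed ASFRs
natfert fit      --config config.yaml --obs obs/observed_asfr.csv \
                 --seed 1 --out fit/                             # posterior + envelope
natfert validate --config config.yaml --seed 1 --out val/ \
                 --tier 5000 --replicates 100                    # cross-validation / ERR
natfert het-scan --config config.yaml --obs obs/observed_asfr.csv \
                 --seed 1 --out het/ --sigma2 0 --sigma2 0.02    # frailty scenarios
```

Minimal config:

```yaml
parameters: {mu_m: 22.0, sigma_m: 3.0, phi1: 0.4, phi2: 0.2, delta: 8.0}
n_women: 5000
age_grid: [15, 49]
n_draws: 10000
accept_fraction: 0.05
rf: {n_trees: 500, min_accepted: 50}
priors:
  mu_m: [19, 27]       # years
  sigma_m: [2, 7]      # years
  delta: [6, 18]       # months
  peak_range: [0.12, 0.35]
heterogeneity: {sigma2: 0}   # frailty variance; 0 = homogeneous
```

## Maternity-history schema

`natfert.data_io` defines a canonical CSV layout (one row per woman;
ages in months): `woman_id, cohort, marriage_age_months,
wife_death_age_months, spouse_death_age_months, observed_to_50,
child_birth_ages_months` (the last a `;`-separated list). The
intact-marriage filter keeps women observed to age 50 whose marriage was
not ended by either spouse's death before that age, restricted to a
cohort range. Simulated cohorts export to the same schema
(`write_fixture`), so the observed-data path is fully testable on
synthetic data.

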