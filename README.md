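# mortgap

Bayesian hierarchical modelling and projection of cancer-mortality
disparities across English regions and income-deprivation quintiles.

## The problem

Lung-cancer (LC) and breast-cancer (BC) mortality in England differ
sharply between affluent and deprived communities and between regions, and
those gaps are expected to persist. `mortgap` is a pipeline for analysts
who want to

- fit cause- and sex-specific hierarchical models to stratified death
  counts (5-year age band x calendar year x region x deprivation band),
- project mortality rates to 2036 with credible intervals,
- quantify the relative deprivation gap in age-standardised rates,
- compare registered pandemic-period (2020-2022) deaths with the deaths
  expected under pre-pandemic trends, and
- estimate excess deaths under diagnosis-delay scenarios (1, 3 or
  6 months of later average age-at-diagnosis from 2020 onward, LC only).

The stratified national registry extract such analyses use is access
restricted, so the package ships a first-class synthetic-data generator
with known ground truth; every stage is validated against it.

## The model

Deaths in stratum *i* (age band *x*, year *t*, deprivation quintile *q*,
region *r*) follow a Poisson-lognormal hierarchical model

```
D_i ~ Poisson(E_i exp(eta_i + eps_i)),   eps_i ~ N(0, sigma_eps^2)
eta_i = beta_0 + alpha_x + kappa_t + gamma_q + rho_r
        + beta_AAD (a_rt - a_bar) + beta_NS (p_xt - p_bar) [+ interactions]
```

with person-years exposure `E_i`, sum-to-zero categorical effects, the
year effect `kappa_t` anchored at the baseline year 2018, and centred
continuous covariates: average age-at-diagnosis (AAD, per region-year) and
non-smoker prevalence (NS, per age-year, a smoking proxy).  Posterior
sampling is adaptive Metropolis-within-Gibbs; model comparison uses the
conditional Deviance Information Criterion (DIC).

Projection extrapolates `kappa_t` per posterior draw as a random walk with
drift, holding deprivation and region effects fixed.  Age-standardised
mortality rates (ASMR, per 100,000) use European Standard Population 2013
weights; the relative deprivation gap is `(ASMR_q1 - ASMR_q5)/ASMR_q1`;
excess deaths under a delay scenario are the difference in expected deaths
against the pre-pandemic-trend baseline, draw by draw.

## Worked example

```python
import numpy as np
from mortgap.synthetic import make_fixture
from mortgap.model import ModelSpec, McmcConfig, sample_posterior
from mortgap.projection import estimate_drift, project_year_effects, project_rates
from mortgap.pipeline import baseline_horizon_covariates
from mortgap.stats import asmr, relative_gap
from mortgap.data_io import esp2013_weights

truth, cov, table = make_fixture("tiny", seed=11)   # 72-cell male LC grid
draws = sample_posterior(ModelSpec(cause="LC", sex="M"), table, cov,
                         McmcConfig(chains=2, iterations=2000,
                                    burn_in=1000, thin=2, seed=11))
ba = draws.scalar_draws("aad")
print(f"beta_AAD: {ba.mean():+.3f} "
      f"(95% CI {np.quantile(ba,0.025):+.3f}, {np.quantile(ba,0.975):+.3f})")
delta, sigma_k = estimate_drift(draws.kappa_draws())
print(f"drift delta: {delta.mean():+.4f}")
```

prints

```
beta_AAD: +0.074 (95% CI -0.254, +0.388)
drift delta: -0.0268
```

The AAD coefficient is weakly identified on 72 cells (the generating value
+0.150 sits well inside the wide interval; the full 6,480-cell grid pins it
tightly), while the annual improvement drift -0.0268 recovers the
generating -0.025.  Continuing to the 2036 projection and the
deprivation-gap statistic:

```python
paths = project_year_effects(delta, sigma_k, range(2019, 2037), seed=11)
proj = project_rates(draws, paths, baseline_horizon_covariates(cov, 2018),
                     horizon_years=range(2019, 2037), seed=11)
```

yields, for the most vs least deprived quintile in the north east in 2036,
a relative gap of `0.43 (95% CI 0.36, 0.49)`: standardised LC mortality in
the most deprived fifth is estimated to be 43% higher than what the least
deprived fifth's rate would imply.

The full pipeline — simulate, fit, project, scenarios, statistics, CSV
reports with a provenance manifest — runs from one command:

```sh
mortgap all --preset tiny --seed 5 --out-dir runs/demo
```

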