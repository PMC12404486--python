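# Methods

## Model

Cause- and sex-specific death counts on the stratification grid
(5-year age band x year x region x deprivation quintile) are modelled as

    D_i ~ Poisson(E_i * exp(eta_i + eps_i)),  eps_i ~ Normal(0, sigma_eps^2),

with exposure `E_i` in person-years.  The log rate is additive:

    eta_i = beta_0 + alpha_age + kappa_year + gamma_quintile + rho_region
            + beta_AAD * (AAD - mean AAD) + beta_NS * (NS - mean NS)
            + selected two-way interactions.

Identifiability: `alpha`, `gamma`, `rho` are sum-to-zero; `kappa` is
anchored at the baseline year (`kappa_2018 = 0`, the last fitted year);
continuous covariates enter centred on their fitting-window means, which
decorrelates them from the intercept.  The heterogeneity term `eps` is
indexed by Poisson cell (stratum-year), capturing cohort and
sub-population variation beyond Poisson noise.

Age ranges are cause-specific: lung cancer (LC) 45-54, 55-59, ..., 85-89
(the 45-54 band is a single 10-year band); breast cancer (BC) 35-39, ...,
85-89, women only.  AAD shows no usable regional variability for BC and is
excluded from BC models; diagnosis-delay scenarios are therefore LC-only.

### Priors

The data carry no strong prior information, so priors are weakly
informative and configurable: fixed effects Normal(0, 10^2) on the log
scale; `sigma_eps` half-Normal(0, 1).  A per-effect prior-s.d. override of
zero pins a coefficient exactly (used in degenerate-prior tests).

### Posterior computation

Sampling is adaptive Metropolis-within-Gibbs, reproducible given a seed:

1. **Fixed effects** update jointly by a random-walk proposal whose shape
   is the covariance of a Poisson GLM fitted to the same design
   (statsmodels), scaled adaptively toward 23.4% acceptance.  The GLM fit
   also initialises the chains (with per-chain jitter).
2. **Cell effects `eps`** update as vectorised single-site random walks
   (their conditionals are independent given the fixed effects), with a
   shared adaptive scale targeting 44% acceptance.
3. **`sigma_eps`** updates by a log-scale random walk against its
   half-Normal prior.

Adaptation uses Robbins-Monro steps and is frozen at the end of burn-in,
so retained draws come from a fixed-kernel Markov chain.  Convergence is
summarised by split R-hat and bulk ESS (arviz) across chains; R-hat above
1.05 warns but never errors.  Defaults are 4 chains x 5,000 iterations
(2,500 burn-in, thin 5) at full scale and 2 x 2,000 on the tiny fixture;
the test suite and acceptance script use shorter, explicitly stated
settings that their checks are insensitive to.

### Model comparison

The Deviance Information Criterion is computed in its *conditional* form:
the cell effects count among the likelihood's parameters, `p_D` is mean
deviance minus deviance at the posterior mean of all parameters, and
`DIC = mean deviance + p_D`.  Selection over a candidate list is
DIC-argmin with ties broken toward fewer parameters; Bayes factors are
deliberately out of scope and the selection trace records DIC only.
Candidate interactions are age x year, deprivation x year and
region x deprivation — the minimal pairs able to express a widening gap
over time and region-specific gradients.

## Projection

Year effects are extrapolated per posterior draw as a random walk with
drift: for each draw, `delta` is the mean of successive `kappa`
differences and `sigma_kappa` their sample s.d.; future paths add
`delta` per year plus Normal(0, sigma_kappa^2) innovations.  Because every
draw carries its own `(delta, sigma_kappa)`, parameter uncertainty flows
into the projections (the alternative — projecting from the posterior-mean
path — was rejected as understating uncertainty).

For inference *about* the drift itself, `drift_posterior` additionally
samples the conditional Normal(mean diff, sigma_kappa^2/(T-1)) posterior
per draw: the plug-in per-draw estimate concentrates on the realised
path's average step, which deviates from the generative drift by an
O(sigma_kappa/sqrt(T-1)) term that the conditional spread restores.
Recovery checks of the drift use this construction.

Region- and deprivation-related effects are held at their fitted values
over the horizon.  Interactions involving year contribute exactly zero at
the anchor year under the anchored contrast coding, so projections carry
no year-interaction extrapolation.  Future covariates default to
"pre-pandemic conditions continue": NS prevalence follows its fitted or
simulated trend; AAD is frozen at its baseline-year value unless a
scenario shifts it.  Future exposures default to the baseline year's
values held constant, with an explicit exposure table overriding that
(synthetic runs pass the generator's deterministic future exposures).
Future cells receive fresh `eps` draws per posterior draw — predictive
semantics — configurable off for deterministic-limit checks.

Intervals everywhere are equal-tailed posterior quantiles, default 95%
(configurable; some published companion tables use 90%).

## Statistics

- **ASMR**: per draw, `100000 * sum_x w_x m_x` with European Standard
  Population 2013 weights renormalised over the modelled age range
  (bundled as a constants file; the 45-54 weight is the sum of the two
  5-year bands, 14,000 per 100,000).
- **Relative deprivation gap**: `(ASMR_q1 - ASMR_q5) / ASMR_q1` per draw,
  quintile 1 being the most deprived fifth.
- **Observed/expected ratios**: registered counts are treated as fixed;
  uncertainty comes from the posterior(-predictive) expected-death draws.
  Multi-year aggregates sum registered counts and per-draw expectations
  over years before dividing.  Calibration checks add the flagged Poisson
  predictive layer on the expected side, since counts simulated from the
  fitted model carry that noise; posterior-only intervals would be
  anti-conservative there.
- **Scenario excess**: a delay of d months adds d/12 years to AAD from
  2020 onward; excess is `E * (m_scenario - m_baseline)` per draw and
  cell, with scenario and baseline sharing seed lineage so a zero delay
  gives identically zero excess and delay ordering is compared
  within-draw.
- Reporting rounds ratios to 2 d.p., ASMR to 1 d.p. and excess deaths to
  integers; full precision is persisted in the CSVs.

## Synthetic data

The generator emulates the structure of the restricted registry extract:
9 regions x 5 quintiles (optionally 10 deciles) x sexes x cause-specific
age bands x years 2001-2018.

- **Exposures** are deterministic — regional population shares, a
  single-sex age pyramid, equal quintile shares, 0.5%/year growth on a
  56M population — so all sampling noise lives in the death counts,
  which keeps parameter-recovery tests clean.
- **Baseline rates** anchor near published English magnitudes (e.g. male
  LC ~400 per 100,000 at 70-74; BC ~220 per 100,000 at 85-89).
- **Trends**: male LC drift -0.025/year; female LC drift 0 with a
  deprivation-year interaction (deprived quintiles stagnate, affluent
  improve); BC drift -0.015/year.  Random-walk innovation s.d. 0.008.
- **Deprivation gradients** are monotone: LC spans 0.65 on the log scale
  from quintile 1 to 5; BC 0.2.  Region effects span ~0.2 (LC), northern
  regions higher.
- **Covariates**: NS prevalence follows logistic-in-year trends per age
  band with age-varying slopes (faster and more uniform for men), noise
  on the logit scale so bounds hold for every seed; AAD drifts slowly
  upward per region around 71 (LC) / 63 (BC) years with region-year
  fluctuations.  The *age-varying* and *region-varying* slopes matter:
  they give the covariates non-additive structure that separates
  `beta_NS` and `beta_AAD` from the free year and age effects at fitting
  time.  Synthetic fits consume the same series the generator used
  (lag 0); the NS-trend GLM smoothing and 20-year lag (a documented
  convention, not an estimate) apply when feeding observed survey data.
- **Overdispersion** defaults to `sigma_eps = 0.05`, a small but
  detectable heterogeneity.
- One global seed expands into substreams (child 0: covariates, child 1:
  deaths) via `SeedSequence.spawn`, so partial re-runs reproduce.

What the generator does *not* emulate: migration and cohort composition
changes, deprivation-rank churn between census revisions, registration
delays, competing causes, and COVID-19 as a cause of death.  Passing
recovery tests therefore demonstrate the estimator is consistent for this
model family, not that the model is correct for real registry data.

## Problem sizes in the checks

The suite states its scales explicitly as its own design: recovery runs
10 replicate fits of the full 6,480-cell grid at 2 chains x 3,000
iterations; the sigma-concentration check uses the full grid (72 cells of
~80 deaths cannot resolve 3% heterogeneity); DIC ranking uses 20 tiny
fixtures with a strengthened (span 1.2) gradient; ratio calibration uses
100 count replicates over one tiny fit; the moment oracle uses 2,000
replicate draws with a 3-standard-error band.

## Known limitations

- The joint fixed-effect block mixes slowly for the year-effect path at
  full scale (R-hat up to ~1.3-1.5 at the short settings); interval
  endpoints are correspondingly noisy.  Longer chains or a gradient-based
  engine would sharpen them; point estimates and coverage behaviour are
  already stable at the documented settings.
- DIC is computed in conditional focus; marginal-focus DIC (integrating
  the cell effects) would penalise differently.
- The NS-trend GLM treats survey prevalences as binomial proportions with
  optional denominators; absent denominators its standard errors are
  nominal.
- Decile-level inputs are supported structurally (pairwise collapse to
  quintiles, conservation-checked) but all shipped defaults work at
  quintile granularity.
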