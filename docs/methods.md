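# Methods

This note documents the statistical machinery in `arealepi`: the models,
the synthetic data-generating process, the numerical choices, and what the
test-bed does and does not demonstrate about real registry data.

## The outcome model

The observation unit is an (area, year) cell of an areal panel: `Y_it`
events among `P_it` births.  Population size is absorbed by an
indirect-standardisation offset, the expected count

    E_it = P_it * (sum_it Y_it / sum_it P_it),

with the reference rate pooled over the whole panel (a per-year variant is
available as a config switch; pooling is the default because the
standardised ratio `Y/E` then carries the secular trend, which the model
terms absorb explicitly).  `sum E = sum Y` holds to machine precision and
is tested.

The likelihood is negative binomial (mean `mu`, size `r`; variance
`mu + mu^2/r`), chosen over Poisson after overdispersion diagnostics; the
Poisson variant is retained for those diagnostics.  The linear predictor is

    log mu_it = log E_it + beta0 + X_it' beta + b_i + (temporal term),

with the temporal term one of: nothing; IID year effects; a linear trend
`delta * t_c` in centred year (`t_c = year - mean(year)`, so `beta0` is
the mid-study baseline); or a first-order random walk
`gamma_t - gamma_{t-1} ~ N(0, s^2)`.  An optional area-specific
differential trend `d_i * t_c` (hierarchically shrunk) ships switched off:
with only seven years, area-level trends are weakly identified and the
parametric-trend reading of the base model does not require them.

## The BYM2 spatial prior

The area effect is the BYM2 reparameterisation

    b_i = sigma * ( sqrt(1-phi) * v_i + sqrt(phi) * u*_i ),

`v ~ N(0, I)` unstructured, `u*` an intrinsic CAR field on the binary
Queen-contiguity graph: density proportional to
`exp(-0.5 * u' Q_scaled u)` with `Q_scaled = c * (D - A)` and a
sum-to-zero constraint within each connected component.  The scaling
factor `c` is the geometric mean of the diagonal of the constrained
generalized inverse of `D - A` (computed by eigendecomposition per
component, zero eigenvalues thresholded at 1e-9), which makes the ICAR
field's generalized marginal variance one; `sigma` is then interpretable
as the SD of the combined effect and `phi` as its spatially structured
fraction.  Multi-component graphs are scaled per component; isolated
single areas carry no spatial information and fall back to the IID part
alone.  Binary Queen weights feed the BYM2 precision throughout;
row-standardised weights exist for descriptive statistics (the two
constructions are the ones worth comparing for this class of model).

Priors are penalised-complexity-style defaults: `beta ~ N(0, 5^2)` on the
original covariate scale, `sigma ~ Exponential` with rate `-log(0.01)` so
`P(sigma > 1) = 0.01`, `phi ~ Beta(1, log3/log2)` so `P(phi < 0.5) = 2/3`
(mass toward the simpler, unstructured model), `r ~ Gamma(2, 0.1)` (weakly
informative, mean 20), and the RW1 increment SD gets the same exponential
tail as `sigma`.

## Sampling

Inference is full MCMC with a No-U-Turn sampler written for this package:
slice-variable tree doubling, dual-averaging step-size adaptation (target
acceptance 0.8), and a windowed diagonal inverse-metric estimate, with the
joint log-posterior and its analytic gradient compiled with numba.  The
spatial field is non-centred (`u*, v` sampled on their prior scale), which
keeps the geometry benign when the data are informative.

Two numerical choices matter:

* Covariates are standardised internally for sampling and the draws are
  mapped back by an exact linear change of variables; priors are specified
  on the original scale.
* The ICAR and year-effect sum-to-zero constraints are imposed softly
  during sampling — `mean(u) ~ N(0, (0.5/sqrt(n))^2)` per component — and
  exactly afterwards by projection (centring each draw, with the year-mean
  folded into the intercept).  A much tighter soft constraint creates a
  stiff direction along the constant vector that a diagonal metric cannot
  absorb and forces the step size down by an order of magnitude; the loose
  constraint plus exact projection gives identical reported quantities at
  a fraction of the cost.  Reported `u*` and year-effect draws satisfy
  their constraints to better than 1e-6.

Convergence is summarised by split R-hat and effective sample size
(via arviz) over all reported parameters, plus the divergence count.
Non-spatial fits treat `max R-hat > 1.05` as an error; BYM2 fits flag the
results as unconverged but still return them (the mixing fraction `phi` is
weakly identified at 100 areas and is routinely the slowest-mixing
parameter; its R-hat can sit near the threshold while every fixed effect
has R-hat < 1.01).

Model comparison uses WAIC (`-2 * (lppd - p_waic)` from pointwise
log-likelihood draws; an independent-formula recomputation is tested to
1e-8) with DIC alongside (`D(theta_hat) + 2 p_DIC`, plug-in at the
posterior mean of the linear predictor and size).

## Diagnostics

* **Moran's I** on the non-spatial model's Pearson residuals (averaged per
  area; residual choice is configurable) with a permutation p-value
  (999 label permutations, seeded; analytic-normal option available).  In
  the pipeline this is a logged gate, not a hard stop.
* **Overdispersion**: parametric bootstrap of the sum of squared Pearson
  residuals of the standard (fixed-effects) Poisson GLM against datasets
  simulated from its fitted means; the statistic is the observed value
  over the bootstrap mean, p two-sided from the bootstrap rank.
* **Zero inflation**: the observed number of zeros against its parametric
  bootstrap distribution under the fitted model (doubled tail probability,
  capped at one).

## Effect modification, E-values, sensitivity analyses

Interaction models refit the full regression with product terms; stratum
ARRs are computed within each posterior draw as
`exp(beta_exposure + beta_interaction[stratum])` and summarised afterwards
— exact posterior functionals, no delta-method step (tested against a
brute-force per-draw recomputation).  E-values use the closed form
`RR* + sqrt(RR*(RR*-1))` after moving the association above one; the
interval E-value uses the CrI limit closer to the null and reports one
when the interval crosses it.  The sensitivity suite re-runs the model on
transformed inputs: guideline-categorical exposures, exclusion of the
2020–2021 pandemic years, pollutant residualisation (each pollutant
regressed on the other, OLS with intercept), single (`lag1`) and moving
(`lag0`) exposure lags with the first panel year dropped, and block
aggregation of the lattice (2x2 by default) for the modifiable-areal-unit
check, with expected counts recomputed on each transformed panel.  Every
analysis failure is recorded and the suite continues.

## The synthetic data-generating process

The simulator emulates an SA2-like study at configurable scale (default
100 areas x 7 years; the full-scale study is ~1,977 areas x 7 years):

* **Lattice**: an n x n grid of unit squares; a contiguous peripheral
  block is labelled `regional` (fraction configurable, default 0.3), the
  rest `major_city`; west/east halves carry state labels.
* **Exposure fields**: iid Gaussian noise smoothed three times with
  `(I + W_rs)/2` (`W_rs` the row-standardised contiguity operator) and
  rescaled to exactly standard-normal marginals, mixed from a
  70% area-persistent and 30% year-specific component.  PM2.5 and NO2
  share a Gaussian copula with latent correlation `2 sin(pi rho_S / 6)` —
  the exact value yielding a target Spearman correlation of 0.78 — and are
  mapped to lognormal marginals, which preserves ranks and hence the
  copula exactly.  NO2 matches the reported national median and IQR
  (5.92 (4.51) ppb).  PM2.5 keeps the reported median (7.64 µg/m³) but its
  spread is calibrated to the reported guideline exceedance (about 92% of
  areas above 5 µg/m³) rather than to the IQR: the two printed statistics
  are not jointly attainable under a two-parameter marginal, and the
  binary guideline split — which the categorical analyses and the
  PM2.5-by-SES interaction depend on — is degenerate under the IQR-based
  spread.  NDVI is `0.39 + 0.104 z` clipped to [0, 1];
  temperature is `25.8 + 3.77 z` °C.
* **Social covariates** (area-level, time-constant, as census reuse would
  make them): SES quintiles from a smoothed latent score; a migrant
  location quotient whose latent is negatively coupled to the SES latent
  (overlap 0.5) so high-concentration areas skew toward disadvantage;
  lognormal population density by urbanicity; median age.
* **Counts**: births lognormal with mean 150 per area-year (floor 10,
  persistent per area with mild yearly jitter — the skewed-population
  stand-in for the 3,000–25,000 resident band); expected counts from a
  baseline event rate of 0.118; cases negative-binomial with the
  BYM2-linear mean (`sigma = 0.3`, `phi = 0.5`, `delta = 0.08/yr`,
  greenness RR 0.89 per 0.10 NDVI by default, size 10), truncated at
  births.  Covariates are panel-centred inside the generator so the
  baseline rate is interpretable; with `delta = 0.08` the aggregate yearly
  rate rises from roughly 0.09 to 0.15 across seven years.  The paper
  trail for between-area variance is absent in this literature's printed
  results, so `sigma` and `phi` defaults are conventions chosen once, not
  calibrations.

What passing tests show: the estimation machinery is unbiased and
calibrated *under its own assumptions* — correct model recovery, interval
coverage, diagnostic calibration, information-criterion ordering.  What
they do not show: robustness to misspecification present in real registry
data (reporting artefacts, postcode-allocation error, exposure measurement
error correlated with outcomes, non-lognormal population sizes), none of
which the generator emulates.

## Problem sizes and determinism

Recovery and model-selection checks run at 100 areas x 7 years with
2 chains x 500 draws after 500 warmup iterations — posterior-mean ARRs are
then estimated to about +-0.002 Monte-Carlo error, ample for effects of
the 0.89 magnitude; unit tests use 25-36 areas and shorter chains.
Diagnostic calibration uses a 196-area panel so the dispersion statistic's
own sampling noise (sd about sqrt(2/m)) sits well inside the assessment
band.  Every random stage (simulation, chains, bootstraps, permutations)
is driven by explicit seeds; same seed means bit-identical output, and the
CLI derives all stage seeds from one root seed.

## Known limitations

* `phi` is weakly identified at desk scale; expect wide posteriors and
  slow mixing for it (not for the fixed effects).
* The NB likelihood ignores the simulator's truncation of cases at births
  (it binds only in tiny areas with extreme draws).
* DIC uses a plug-in at the posterior mean of the linear predictor, the
  common but not unique convention.
* The sampler is single-threaded; chains run sequentially.
* MCMC point estimates differ from deterministic-approximation fits of the
  same model (e.g. nested-Laplace implementations) by approximation and
  Monte-Carlo error; the contract here is posterior correctness, checked
  by recovery, coverage and prior-recovery tests rather than by matching
  another engine's numbers.
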