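# Methods

`banddist` estimates animal density, long-term population trend and total
abundance from roadside spotlight-survey panels in which each sighting's
perpendicular distance is recorded in bands. It was built around the design
of the Tasmanian mammal spotlight programme — annual counts along fixed
10-km road transects, both road sides, six distance bands
(0–5, 5–10, 10–20, 20–40, 40–60, 60–100 m) — but all dimensions (bands,
transects, years, habitats, regions) are data-driven.

## Observation model

The probability of detecting an animal at perpendicular distance `x`
declines with distance according to one of two detection families:

* **Two-exponential mixture** (sparse island panels):
  `g(x,t) = q(t) e^{-x/mu1} + (1-q(t)) e^{-x/mu2}` with
  `logit q(t) = alpha0 + alpha1 (t - T)`. `mu1 <= mu2` are two scales of
  detectability (the detection probability at distance `mu` is
  `1/e ≈ 0.37`); the year-varying weight `q(t)` captures a temporal shift
  in how far out animals are seen. `T` is the reference year (default
  2020).
* **Floor-plus-exponential** (large mainland panels):
  `g(x) = kappa + (1-kappa) e^{-alpha_l x}`, where `kappa` is the minimum
  detection probability at any distance and `alpha_l` a per-transect
  decline rate.

Counts are banded, so the likelihood uses the exact mean of `g` over each
band `[x0, x1)`; both families integrate in closed form
(`mean of e^{-x/mu}` over a band is `mu (e^{-x0/mu} - e^{-x1/mu})/(x1-x0)`),
and the closed forms are tested against adaptive quadrature at 1e-10.
Distances beyond the outermost edge (100 m) are outside the model: the
strip is truncated and no right-tail correction is applied.

Expected counts multiply banded detection, strip geometry and density:

    nbar_{i,j,t} = p_{i,t} * 2 (x_i - x_{i-1}) * l_j * lambdabar_{j,t}

with `l_j` the transect length. Internally all geometry is in metres and
density in ha^-1; the single ha/m^2 conversion lives in `expected_count`.

Count noise is negative binomial with mean `nbar` and variance
`nbar (1 + Phi nbar)`; `Phi = 0` recovers the Poisson. This quadratic
overdispersion form is the only parameterisation that is a proper count
distribution for all means while nesting the Poisson.

## Density model

Log-density is linear in time with zero-mean normal random effects:

* island variant: `lambdabar_{j,t} = lambda0 exp(r (t-T) + delta_j + eps_t)`
* mainland variant: the same times `exp(eta_m)` for the region and times the
  habitat mixture `sum_i p_{ij} e^{beta_i}`, treating a transect as an
  area-weighted mixture of habitat-specific densities. The habitat term is
  multiplicative (not inside the exponent's argument) so that the abundance
  extrapolation `lambda0 * sum_n a_n e^{beta_n}` is dimensionally and
  algebraically consistent with the per-transect expectation.

`delta_j ~ N(0, sigma_transect^2)`, `eps_t ~ N(0, sigma_year^2)`,
`eta_m ~ N(0, sigma_region^2)`. Because a linear-in-time component of
`eps_t` is exactly confounded with `r`, the trend's posterior uncertainty
correctly inflates with `sigma_year`; this is intended, not a defect.

Identifiability choices:

* `(lambda0, beta)`: multiplying all `e^{beta_i}` by `c` and dividing
  `lambda0` by `c` leaves every expected count unchanged, so the habitat
  with the largest length-weighted transect coverage is the reference and
  its `beta` is fixed at 0; `lambda0` is then the reference-habitat density
  at year `T`.
* `(mu1, q) <-> (mu2, 1-q)` label switching: resolved by the smooth
  ordering `mu2 = mu1 + gap`, `gap > 0`.
* `alpha_l`: 172 free decline rates would be weakly informed, so the rates
  are partially pooled, `log alpha_l ~ N(mu_alpha, sigma_alpha^2)`,
  degrading gracefully to a shared rate as `sigma_alpha -> 0`.

## Priors

Weakly informative on interpretable scales, all overridable
(`PriorConfig`): `log lambda0 ~ N(log 0.1, 2^2)`; `r ~ N(0, 0.5^2)`;
`alpha0, alpha1 ~ N(0, 5^2)`; `mu1, mu2 ~ LogNormal(log 20, 1.5^2)`
restricted to the ordered region; `kappa ~ Uniform(0,1)`;
`mu_alpha ~ N(log 0.05, 1.5^2)`; all spread parameters `~ HalfNormal(1)`;
`Phi ~ HalfNormal(2)`; non-reference `beta_i ~ N(0, 2^2)`. A
prior-predictive check in the test suite confirms the implied density prior
spans at least [0.001, 10] ha^-1.

## Inference

The joint posterior is sampled by a no-U-turn sampler implemented in
`banddist/_nuts.py`, with analytic gradients of the full log posterior
(verified against finite differences). Design details:

* Unconstrained parameterisation: logs for positive parameters, logit for
  `kappa`, non-centred random effects (`delta = sigma z`), all Jacobians
  included. Non-centring removes the funnel between effects and their
  spread, which is essential at the short chain lengths used in practice.
* Each chain starts from a jittered posterior mode (L-BFGS on the analytic
  gradient) and seeds its metric with the Laplace covariance (central
  differences of the gradient at the mode, eigenvalue-clipped to positive
  definite, marginal scales capped at 5 in unconstrained units to guard
  against flat prior ridges).
* Warm-up: dual-averaging step-size adaptation (target acceptance 0.8)
  with expanding dense-covariance windows ending at 40%, 75% and 90% of
  warm-up; a dense metric is important because the trend, year effects and
  detection-trend parameters are strongly correlated. With the default
  dimensions (36–110 parameters) the dense linear algebra is negligible
  next to a gradient evaluation.
* Divergent transitions (energy error > 1000) are counted and warned about
  above a 2% rate — a warning, not a failure. A warning is also emitted
  when the effective sample size of `lambda0` or `r` falls below 100,
  recommending a longer run than the historical 2 x 400 (200 warm-up)
  default budget, which is kept as the default for comparability but is
  genuinely short; the recovery tests use 2 x 1500.
* Convergence is summarised by the split potential-scale-reduction
  statistic per parameter (flagged above 1.05); constant draws report the
  defined limit 1.

Seeded determinism: identical (dataset, config, seed) produce bit-identical
draws; all randomness flows from `numpy.random.default_rng` seeded by the
config.

## Post-processing

All derived quantities are computed per draw and then summarised as order
statistics (median, central 95%); summaries are never transformed.

* Island abundance in year `y`: per-draw realised density
  `lambda0 e^{r(y-T) + eps_y}` times the island area — the realised year
  effect, not the trend line, matching how annual densities are plotted.
* Mainland abundance: `lambda0 sum_n a_n e^{beta_n}` over a habitat-area
  ledger (ha). Region effects are zero-mean deviations and deliberately do
  not enter the extrapolation. The conservative variant re-runs the sum
  with excluded (under-surveyed) habitats' densities set to zero; per draw,
  conservative + excluded components reconstruct the full total exactly.
* Growth is reported as `100 (e^r - 1)` percent per year (the realised
  annual multiplier); at a few percent this differs from `100 r` by under
  0.05 points, and the reporting utility records both.
* The mainland "mean density" time series is the area-weighted mean over
  the habitat ledger, `lambda0 e^{...} sum_n (a_n / sum a) e^{beta_n}`;
  this aggregation convention is recorded in the output.

## Synthetic data

`synthetic_data` draws counts from exactly the model the likelihood
assumes: banded negative-binomial counts with means from the expected-count
equation, random effects realised once and recorded in a truth sidecar.
Recovery tests therefore check the estimator, not model mismatch. An
optional position-level mode (animals placed uniformly in the strip,
thinned by `g(x)`, then binned; Poisson only) is provided as a
model-mismatch probe.

Default generating values are testing conveniences of realistic magnitude
for a medium-sized burrowing herbivore surveyed by spotlight — island:
`lambda0 = 0.5 ha^-1`, `r = 0.029` (≈2.9%/yr), `mu1 = 5 m`, `mu2 = 40 m`,
`alpha0 = 0.5`, `alpha1 = 0.08`, `Phi = 0.5`, `sigma_transect = 0.3`,
`sigma_year = 0.15`; mainland: `lambda0 = 0.1 ha^-1`, `r = 0.012`,
`kappa = 0.05`, `mu_alpha = log 0.08`, `sigma_alpha = 0.3`,
`beta = (0, 0.4, -0.6)` over three habitats, `sigma_region = 0.3`, with the
island's `Phi`, `sigma_transect` and `sigma_year` reused. What the
generator does *not* emulate: spatial autocorrelation between transects,
animal movement or road avoidance, observer and weather covariates,
rangefinder error, and within-band distance distributions other than
uniform — so passing recovery tests demonstrate correct inference under
the stated model, not robustness to these features of real surveys.

## Problem sizes used in the checks

The recovery checks run the island panel at its full dimensions
(8 transects x 19 years, seeds 1–10, chains 2 x 1500 with 750 warm-up) and
the mainland panel scaled down to 40 transects x 10 years with 3 habitats
and 4 regions (same chain budget), with interval-calibration sweeps at
8 transects x 12 years (20 replicates, 2 x 800). These sizes give
per-replicate posteriors with effective sample sizes in the hundreds for
the headline parameters while keeping a full sweep in the minutes range on
a single CPU.

## Numerical notes and edge cases

* `count_loglik` evaluates the exact Poisson limit at `Phi = 0` and defines
  `log P = 0` for a zero count at zero mean (`-inf` otherwise).
* The negative-binomial gradient uses
  `lgamma(y + 1/Phi) - lgamma(1/Phi) = sum_{k<y} log(1/Phi + k)` via
  cumulative tables over `0..max(count)`, avoiding large 2-D `lgamma`
  evaluations in the sampler's hot loop.
* Band intervals are half-open `[lower, upper)`; a distance exactly on a
  boundary belongs to the upper band. Survey seasons spanning New Year are
  labelled by the starting calendar year.
* Missing (transect, year) pairs contribute nothing to the likelihood;
  within a surveyed pair, bands without a record are zero counts.
* Habitat proportions within 1e-6 of summing to 1 are renormalised on
  read; anything further off is rejected with the offending row number.

## Known limitations

* Detection-trend and density-trend parameters are separated only by
  band-share information; on very sparse panels their joint posterior is
  wide (correctly so), and point estimates of `r` inherit that width.
* The posterior-mode initialisation assumes a unimodal posterior after the
  ordering and reference constraints; multimodal posteriors (e.g. from
  bimodal detection shapes) would need over-dispersed starts.
* Abundance extrapolation treats the area ledger as exact; no uncertainty
  is propagated from the area measurements themselves.
* With fewer than ~6 transects or years, the prior on `lambda0` pulls
  estimates toward 0.1 ha^-1 noticeably; interval calibration at fixed
  generating values is demonstrated at 8 transects x 12 years and above.
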