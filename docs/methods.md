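# Methods

## Models

Counts in N areas are modelled as `y_i ~ Poisson(E_i exp(mu_i))`, where
`E_i > 0` is the expected count and `mu_i` the log relative risk.  Two
conditional-autoregressive (CAR) specifications are provided, both built on
binary first-order adjacency weights `w_ij`:

* **Leroux**: `mu_i = beta' x_i + s_i`, with full conditionals
  `s_i | s_-i ~ N( rho * sum_j w_ij s_j / (rho * d_i + 1 - rho),
  sigma_s^2 / (rho * d_i + 1 - rho) )` where `d_i = sum_j w_ij`, and
  `rho ~ Unif(0, 1)` mixing between independent (`rho = 0`) and intrinsic
  CAR (`rho = 1`) behaviour.  The joint prior precision is
  `(rho (D - W) + (1 - rho) I) / sigma_s^2`, proper for `rho < 1`.
* **BYM** (convolution): `mu_i = beta' x_i + s_i + u_i`, with the intrinsic
  CAR (ICAR) prior for `s` (conditional mean the neighbour average,
  conditional variance `sigma_s^2 / d_i`) and iid `u_i ~ N(0, sigma_u^2)`,
  `sigma_u^2 ~ N(0, 10)+` (a normal truncated to positive values,
  parameterised by mean and variance).

Regression coefficients have `N(0, 100)` priors (variance configurable).
The hyperprior for `sigma_s^2` is either inverse-gamma `IG(alpha, eta)`
(shape/rate) or a left-truncated normal `N(pi, nu)+`.  This hyperprior is
the package's main smoothing dial: informative mass near zero forces the
structured field flat (over-smoothing), diffuse or large-mean settings let
it chase the raw rates (under-smoothing).  `gosmap.models.variant_grid`
ships a documented 12-point grid per family, labelled A–L in approximately
descending order of smoothing intensity; the labels are a convention of
this package, chosen to span both failure modes, not a reconstruction of
any external table.

### Sampler

Metropolis-within-Gibbs, written for lattices and county maps of up to a
few hundred areas:

* `s` (and `u`): single-site random-walk Metropolis.  Updates are
  vectorised over the classes of a greedy proper colouring of the adjacency
  graph; within one class no two areas are adjacent, so the sites are
  conditionally independent and simultaneous accept/reject decisions leave
  the target invariant.  `u` has no graph coupling and is updated in one
  vectorised sweep.
* `beta`: coordinatewise random-walk Metropolis on the log-linear
  predictor.
* `sigma_s^2`: conjugate Gibbs under IG — the CAR quadratic form gives an
  `IG(alpha + r/2, eta + q/2)` full conditional with `q = s'(rho(D-W) +
  (1-rho)I)s` and rank `r = N` for Leroux, `q = s'(D-W)s` and
  `r = N - (number of graph components)` for ICAR.  Under LTN, log-scale
  random-walk Metropolis with the Jacobian term.
* `rho`: Metropolis on `logit(rho)`.  The determinant of the Leroux
  precision is evaluated from the eigenvalues `lambda_k` of `D - W`
  (computed once): `log det = sum_k log(rho lambda_k + 1 - rho)`.
* ICAR impropriety: after each `s` sweep the field is recentred to sum to
  zero with the mean shifted into the intercept, so `mu` is untouched.

Step sizes adapt by Robbins–Monro (gain `t^-0.6`) toward 40% acceptance
during burn-in only; retained draws come from a fixed kernel.  Proposal
exponents are clipped at |log risk| = 40 to guard `exp` overflow during
early adaptation.  Chains are initialised at `beta_0 = log(sum y / sum E)`,
`s = u = 0`, `rho = 0.5`, and the hyperprior mode for `sigma_s^2` (clipped
to `[1e-4, 10]`).  Seeded runs are bit-reproducible.

Defaults are 20 000 iterations, 10 000 burn-in, thinning 10.  The test
suite uses much shorter chains (900–5 000 iterations) on 16–100 area
lattices; those sizes were chosen because the quantities tested there
(coverage of credible intervals, orderings of smoothing statistics) are
stable at that scale.

### BYM identifiability

`s` and `u` are identified only through their sum.  Following the
standard-deviation reallocation approach, each draw is rescaled as
`s* = w (s + u)`, `u* = (1 - w)(s + u)` with
`w = sd(s) / (sd(s) + sd(u))`, preserving `s + u` (and `mu`) elementwise.
A draw in which both fields are constant has no variation to reallocate and
is left unchanged.  The workflow applies this rescaling to every BYM fit
before computing any smoothing statistic.

## Derived surfaces

* raw SIR `y_i / E_i`; posterior SIR `exp(mu_i)`.
* CASIR `exp(mu_i - beta' x_i) = exp(s_i)` (BYM: `u_i` also removed).
* CARSIR `(y_i / E_i) exp(-beta' x_i)`; zero where `y_i = 0`.  The
  covariate adjustment uses each draw's `beta` and then averages; a flag
  switches to a single posterior-mean-`beta` evaluation for sensitivity
  analysis (the two differ only by Jensen-gap terms of order
  `Var(beta' x_i)`).
* Residuals `eps_i = E_i exp(mu_i) - y_i` (Leroux) or
  `E_i exp(mu_i - u_i) - y_i` (BYM).

Summary conventions: posterior mean for SIR/CASIR/CARSIR, posterior median
for `s` and `eps` wherever they enter a variance (psi, Moran's I).

## Goodness-of-smoothing statistics

**Variogram ratio.**  The areal variogram at lag `h` for area `i` is
`gamma_i(h) = sum_{j != i, d_ij <= h} (z_i - z_j)^2 / (2 N_i(h))`, with
`d_ij` the boundary-crossing distance (graph geodesic on the adjacency
graph) and `N_i(h)` the number of included pairs.  Inclusion is
`d_ij <= h`: with integer boundary distances a strict inequality would
leave lag 1 empty, contradicting the defining idea that areas "no more
distant than the lag" contribute.  The statistic is the mean over lags
`1..H` of `mean_i gamma_i^CASIR(h) / mean_i gamma_i^CARSIR(h)` (ratio of
area-averaged variograms, not average of per-area ratios — per-area ratios
are unstable wherever an area's CARSIR variogram is near zero).  `H`
defaults to `min(graph diameter, 10)`.  For a surface that is an affine
function `a + b * CARSIR` the ratio is exactly `b^2`; a flat CASIR gives 0
(over-smoothing), a CASIR as rough as its baseline gives ~1
(under-smoothing).

**Kurtosis preservation.**  With `e_i = z_i - (neighbour mean of z at i)`,
the spatial excess kurtosis is `mean(e^4) / mean(e^2)^2 - 3` over areas
with neighbours, and the roughness is the ddof-1 standard deviation of the
same deviations.  A model passes when the smoothed surface's kurtosis is at
least the raw surface's (rare large deviations survived) and its roughness
is within a tolerance (30% or 10%) of the minimum roughness across the
models being compared.  The surface pair defaults to smoothed SIR vs raw
SIR, with a flag for CASIR vs CARSIR; both readings are defensible and the
statistic is reported with the input surface named.

**Kappa.**  CASIR and CARSIR are each categorised by their own type-7
empirical quantiles (3 categories with cuts 0.25/0.75, or 5 with
0.1/0.3/0.7/0.9; category membership by half-open intervals
`[q_{k-1}, q_k)` — the quantile type and tie rule change category sizes, so
both are fixed and documented).  Cohen's kappa
`(Pr(Ao) - Pr(Ae)) / (1 - Pr(Ae))` then measures rank agreement with
CARSIR as baseline: small kappa = heavy smoothing, kappa near 1 = almost
none.  The criteria use the 3-category value, which is the more robust of
the two (more counts per confusion-matrix cell).

**Fraction of spatial variation.**
`psi = Var(s*) / (Var(s*) + Var(eps*))`, with per-area posterior medians
taken before the ddof-1 variances over areas.  Reported for completeness;
it carries no PASS/FAIL criterion because there is no defensible general
cut-off.

**Relative position of CASIR.**  For each area the CASIR estimate is
placed between the no-shrinkage endpoint (CARSIR, position 0) and the
full-shrinkage endpoint (the posterior mean of the neighbours' CASIR,
position 1):
`r_i = (log CASIR_i - log CARSIR_i) / (log m_i - log CARSIR_i)`.
The upper endpoint `m_i` is estimated as the neighbour mean of the
posterior-mean CASIR surface (a per-draw neighbour-mean average is
available by option; the two differ by a Jensen gap that is negligible at
the posterior spreads seen here).  Computed on the log scale, which makes
the exclusion rule natural: areas whose log-range of potential values is
below 0.03 are excluded (tiny ranges exaggerate the position), as are areas
with `y_i = 0` (no log-scale baseline) and isolated areas (no neighbour
endpoint).  Positions are capped at [-0.2, 1.2] for summaries only; the
PASS rule counts the proportion of non-excluded areas whose uncapped
position falls in the profile's band.

### Cut-off profiles

| statistic        | (u) unbiased   | (c) conservative | (pu) penalise under-smoothing |
|------------------|----------------|------------------|-------------------------------|
| variogram ratio  | [0.2, 0.8]     | [0.25, 0.75]     | [0.1, 0.4]                    |
| kurtosis         | preserve + 30% | preserve + 10%   | —                             |
| kappa            | [0.05, 0.95]   | [0.1, 0.9]       | [0.05, 0.7]                   |
| rel. position    | ≥75% in [0.01, 0.99] | ≥85% in [0.02, 0.98] | ≥75% in [0.2, 0.98]    |

All bounds are user-overridable.  The consensus count per model is the
number of PASSes among the three (pu) criteria (variogram ratio, kappa,
relative position); 2 or more marks a consensus choice.

## Goodness-of-fit criteria

* `DIC = 2 p_D - 2 log p(y | theta-bar)` with
  `p_D = mean deviance - deviance at the plug-in`; the plug-in evaluates
  the Poisson likelihood at the posterior mean of `mu` (DIC is
  parameterisation-dependent; this choice is fixed and documented).
* `WAIC = 2 sum_i { var_m[log p(y_i|theta^(m))] - log mean_m
  p(y_i|theta^(m)) }`, `p_W = sum_i var_m[...]` with the ddof-1 sample
  variance over draws and a max-shifted log-mean-exp.
* CPO by the harmonic-mean estimator
  `CPO_i = [mean_m 1/p(y_i|theta^(m))]^{-1}` (stable log-sum-exp of the
  negated log-likelihoods).  The harmonic mean is the standard
  posterior-sample estimator but has infinite-variance pathologies when a
  draw assigns the datum near-zero likelihood; such areas are excluded from
  the sum with a warning.  Models are compared on `-sum_i log CPO_i`, and
  areas with scaled CPO (`CPO_i / max_j CPO_j`) below 0.01 are flagged as
  poorly fit.  The estimator is validated in the tests against the exact
  negative-binomial leave-one-out predictive of a conjugate gamma-Poisson
  model.
* Moran's I on the posterior-median residuals, with the two-sided
  normal-approximation p-value (`E[I] = -1/(N-1)` and the standard
  normality variance).  Its type-I error is calibration-checked in the
  acceptance suite.
* Comparison bands: minimum DIC/WAIC flagged best; within 2 and within 7
  units flagged as reasonable fits; minimum `-sum log CPO` flagged; small
  Moran's p-values highlighted (default 0.05).

## Synthetic data

The generator emulates small-area disease-count studies: a rook lattice
(56 areas by default, the scale of a small national county map), one
spatially autocorrelated covariate (an independent Leroux field with
`rho = 0.9`, standardised), a structured field drawn from the Leroux GMRF
via dense Cholesky of the precision (or from the ICAR pseudo-inverse,
sum-to-zero), expected counts log-uniform on [5, 50], and Poisson counts.
Generating the covariate as a smooth spatial field makes fixtures exhibit
the smoothing paradox — the SIR surface can look *rougher* under more
smoothing because the covariate contribution dominates it — which is the
situation the CASIR-based statistics exist for.

`smoothing_gradient_fixture` bundles one such dataset (truth
`beta = (0, 0.5)`, `rho = 0.9`, `sigma_s = 0.4`) with three Leroux IG
hyperpriors: `IG(200, 0.2)` (mass near `sigma_s^2 = 0.001`, forces
over-smoothing), `IG(4, 0.6)` (weakly informative, mean 0.2 near the
truth), and `IG(2.5, 15)` (wide, centred on a large variance, induces
under-smoothing).  Their prior variances are strictly ordered and finite.

What the generator does **not** emulate: irregular county geographies and
their skewed degree distributions, population-size confounding between `E`
and the covariate, overdispersion beyond the log-normal random effect,
missing or suppressed counts, and multiple covariates.  Passing tests
demonstrate correctness of the statistics and the expected qualitative
response to a known smoothing gradient under these idealised conditions —
not that any particular cut-off profile is well calibrated for a given
real map.

## Numerical and design notes

* Area ordering is fixed by first appearance in the data table; all
  matrices use it.  Isolated areas are retained and flagged; they are
  excluded from neighbour-mean statistics with NaN/warnings, and rejected
  outright by the ICAR-based BYM model.
* Polygon contiguity defaults to queen (any shared point); rook (shared
  boundary of positive length) by flag.
* Degenerate inputs: constant fields make spatial kurtosis and Moran's I
  undefined (errors); a constant surface categorises into a single
  quantile class (warning; kappa against a varied baseline is then 0);
  variogram lags with zero baseline variogram are dropped with a warning;
  `psi` errors when both variance components vanish.
* Per-variant seeds are `crc32(master_seed:label) mod 2^31-1`, so adding a
  variant to a grid never perturbs the other chains.
* Known limitations: single-chain sampler (no R-hat across chains;
  acceptance rates are logged per variant), harmonic-mean CPO instability
  (above), and the kurtosis criterion's sensitivity to which SIR pair it is
  fed — both readings are implemented, neither is privileged beyond the
  default.
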