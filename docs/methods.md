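# Methods

`dcelogit` implements the complete analysis workflow of a discrete choice
experiment (DCE) on integrated family-planning/HIV outreach services for
young people: choice-data construction and coding, estimation of the
multinomial logit (MNL), random parameters logit (RPL), generalized mixed
logit (GMXL) and WTP-space GMXL models by maximum simulated likelihood,
willingness-to-pay (WTP) estimation, choice-share scenario simulation,
and D-efficiency evaluation of experimental designs.  Because the
original survey microdata were never deposited, a first-class synthetic
data generator reproduces the study conditions so that every stage can
be validated against a known truth.

## Random utility models

Utility of respondent i for service alternative j is
U_ji = V_ji + eps_ji with IID standard Gumbel errors and
V_ji = x_ji' beta_i; the opt-out alternative carries only an
alternative-specific constant (ASC).  The families differ in beta_i:

- **MNL** — beta_i = beta (+ delta z_i when socio-demographic
  interactions are included); closed-form choice probabilities.
- **RPL** — beta_i = beta + delta z_i + Gamma v_i, v_i ~ N(0, I);
  Gamma is diagonal (uncorrelated) or lower-triangular Cholesky
  (correlated).  The panel likelihood multiplies a respondent's task
  probabilities *inside* the simulation average.
- **GMXL** — beta_i = sigma_i (beta + delta z_i)
  + (gamma + sigma_i (1 - gamma)) Gamma v_i, with an individual
  log-normal scale factor sigma_i = exp(sigma_bar + tau w_i).
  sigma_bar is normalized to -tau^2/2 so that E[sigma_i] = 1; the model
  is otherwise not identified and the sample mean of the simulated
  sigma_i is reported as a diagnostic.  The weighting parameter gamma
  in [0, 1] governs how residual heterogeneity scales; gamma -> 0 is
  the GMNL-II limit, and a fit that pins gamma at a boundary carries an
  explanatory note in the result.
- **WTP-space GMXL** — non-price coefficients are money-denominated
  WTPs theta: beta_i = sigma_i beta_c (theta + delta z_i)
  + (gamma + sigma_i (1 - gamma)) beta_c Gamma v_i and the price
  coefficient is -sigma_i beta_c with beta_c > 0.  Price itself is not
  given an own mixing dimension: its randomness comes from the scale
  factor, which is what makes the WTP ratios well-behaved.  At mapped
  parameters (beta = beta_c theta, beta_price = -beta_c,
  Gamma = beta_c Gamma_w) the preference-space and WTP-space
  likelihoods are identical; the test suite asserts this to 1e-6 and it
  holds to machine precision.

Scale multiplies the design-attribute utilities only; the opt-out ASC is
a fixed parameter.  Observed heterogeneity in scale (a delta'h_i term in
log sigma_i) is fixed to zero.  Interactions delta z_i sit inside
sigma_i(beta + delta z_i), price interactions included, in preference
space; in WTP-space, delta shifts the non-price WTPs only, since the
price coefficient has no mean shift in this parameterisation.

## Coding conventions

Categorical service attributes are effects coded: the base level maps to
-1 in every column, non-base level m to +1 in column m; a two-level
attribute becomes a single +-1 column.  The four-level youth-friendly
component yields three columns against the base "no additional
activities".  Price enters in raw Malawi Kwacha (0/50/150/500).  The
default schema therefore has 8 design columns.  Respondent
characteristics are dummy coded with base categories male, aged 15-19,
and single; the default interaction set (8 columns x 3 dummies) adds 24
columns.  Reported WTP is per coded unit: a base -> non-base level
change moves the code by two units, so the package-level WTP for a level
change is twice the per-unit figure.

## Simulated maximum likelihood

Draws are Halton sequences on consecutive primes (one per random
coefficient, plus one for the scale draw), first 10 points discarded, no
scrambling, mapped through the standard-normal quantile function and
assigned to respondents in consecutive blocks.  Draws are generated once
per fit and reused across optimizer iterations.  The simulated
log-likelihood is sum_i log((1/R) sum_r prod_t P_irt) evaluated with
log-sum-exp stabilisation; simulated probabilities are floored at 1e-300
before logs and any floored evaluation is counted and logged.

Estimation uses L-BFGS-B with analytic gradients for every family
(score-weighted draw averages; the Jacobians of the GMXL and WTP-space
coefficient constructions are applied by the chain rule).  tau is
estimated as exp(t), gamma on a logistic transform, beta_c as exp(b), so
constraints never bind during optimization.  Linear parameters are
internally rescaled by the magnitude of their design column — the
raw-MK price column otherwise makes the Hessian condition number of
order 10^5 and triples the iteration count — and all reported values,
standard errors and covariances are mapped back to the natural scale
exactly.  Start values come from the MNL fit (in WTP-space, through the
ratio map theta_0 = beta_MNL / beta_c0), with Cholesky diagonals started
at 0.1 utility units.  Convergence follows the optimizer's gradient and
function-change tests (gtol 1e-5, iteration cap 1000); a fit that
exhausts the cap is returned flagged, never silently.

Standard errors invert the numerically differentiated Hessian (central
differences of the analytic gradient) with a delta-method map to the
reported scale, including implied coefficient SDs (row norms of Gamma).
P-values use the normal approximation with the conventional significance
stars (*** 0.01, ** 0.05, * 0.1).

## Synthetic data generator

The generator emulates the study conditions: 537 respondents x 12 tasks,
two generic service profiles plus an opt-out, the six-attribute schema
above, independent socio-demographic margins matching the study sample
(female 49.8%, aged 15-19 60.7%, in a relationship 64.3%), and choices
drawn by utility maximisation with IID Gumbel errors under an MNL, RPL
or GMXL process.  Default true parameters are anchored to the fitted
GMXL magnitudes of the study (means, spreads, interaction block, ASC
-2.529, tau ~ 1).  Designs come from a seeded balanced randomizer
(per-attribute level counts differ by at most one; within-task duplicate
profiles are removed by balance-preserving swaps); D-efficiency is the
business of the `design_efficiency` module, which can also select the
best-of-pool candidate by point D-error, standing in for the external
D-efficient design search used for the original survey.

What the generator does **not** emulate: the image-based survey
instrument, field nonresponse, blocking across questionnaires, or any
dependence between socio-demographics (margins are independent).
Passing recovery tests therefore show the estimator is consistent and
well-calibrated under the stated process at the study's scale — not
that the original survey's numbers are reproduced; the fitted
coefficient tables of the study are not reproducible without its raw
data.

## Design efficiency

The MNL information matrix of a design is
sum_t sum_j P_j (x_j - xbar_t)(x_j - xbar_t)' at prior coefficients,
with xbar_t the probability-weighted mean profile; the D-error is
det(inverse)^1/K and Bayesian D-error averages it over seeded normal
prior draws (zero-SD priors degenerate to the point case; the prior
draws reuse the Halton machinery).  Designs can be scored with and
without the opt-out (ASC column appended) and averaged across variants
with user weights — equal by default, since the weighting used in the
original multi-model design optimisation is not stated.  A singular
information matrix (an attribute that never varies) yields an infinite
D-error sentinel.  No design search beyond best-of-pool selection is
implemented.

## Scenario simulation

A scenario compares a base and a simulated package configuration.  For
each respondent and each *fresh* seeded draw from the fitted mixing and
scale distributions (unconditional simulation — individual-posterior
coefficients conditioned on observed choices are deliberately not used,
as they require choice histories and an additional conditioning step;
this is a known source of divergence from analyses that use them), the
binary-logit share Pr(sim) = e^{U_sim} / (e^{U_sim} + e^{U_base}) is
averaged.  The headline number is 100 x (mean Pr(sim) - 0.5), the
percentage-point shift from indifference; raw means, per-subgroup
(gender, age group, relationship) deltas, and a Monte-Carlo standard
error over draws are co-reported.  Default 2,000 draws per respondent.
The catalogue of 16 study scenarios (price steps, single-attribute
additions, combined packages) ships as `default_scenarios`.

## Numerical and testing choices

- Gumbel error scale is fixed at 1 (identification); every random stage
  takes an explicit integer seed with independent substreams for
  design, respondents, coefficients and errors.
- Brute-force oracles (softmax row loops, triple-loop simulated
  likelihood) back the vectorised implementations at 1e-10 relative
  tolerance; the degeneracy chain GMXL(tau=0) = RPL, RPL(Gamma=0) = MNL
  is asserted at 1e-8.
- Recovery tests run at the study geometry (537 x 12, 200 Halton draws)
  with true parameters set to the study's published RPL estimates
  (means, SDs, ASC) and, for WTP-space, the published WTP means and SDs
  with beta_c = 0.01.  The scale-dispersion used for the WTP recovery
  run is tau = 0.5 rather than the published 1.37: at the larger value
  the log-normal scale draws span two orders of magnitude and a
  desk-scale synthetic run is dominated by a handful of extreme
  respondents.  The 15% recovery band is asserted for the WTPs that are
  statistically unambiguous in the anchor estimates (confidential
  service, HCT+ART); relative error on coefficients whose anchor SEs
  are of the same order as their means carries no information.
- The likelihood-ratio size study uses 200 replicates of 150
  respondents x 8 tasks (restricted: no interactions; general: gender
  interactions, 8 df) — sizes chosen to put roughly a thousand choice
  tasks in each replicate while keeping the whole study under a minute.
- Known limitations: no sign-constrained (log-normal) price
  coefficients — the underlying distribution of price sensitivity
  beyond "normal" is not specified in the source analysis, so no shape
  is guessed; no conditional individual-level coefficients; no design
  search; no best-worst or labelled formats.
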