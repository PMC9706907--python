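# Methods

## The model

Child-level survival times are observed on the 0–59 month eligibility
window as `y_ij = min(t_ij, C_ij)` months with death indicator
`delta_ij = 1{t_ij <= C_ij}`, where `C_ij` is the child's age at the
survey interview. The censored likelihood is

    L = prod_ij f(y_ij | lambda_ij)^delta_ij * S(y_ij | lambda_ij)^(1-delta_ij),

with `S = integral_y^inf f`, equivalently `S = f/h`. Five hazard families
are supported — exponential, gamma (shape `s*phi`, mean `mu`), Weibull,
log-normal (`log y ~ N(mu, 1/tau)`), and a Cox model with
piecewise-constant baseline `h0(t) = exp(c_k)` on a time grid. The
location parameter of each family is linked to the structured additive
predictor

    eta_ij = x_ij' beta + z_ij' psi + w_ij' theta

(log link for exponential/gamma/Weibull, identity for log-normal/Cox).
`z` and `w` are one-hot incidences: each child maps to exactly one
maternal-age bin (integer ages 15–49 re-coded 1..35) and one region.

Priors: `beta ~ N_p(0, 100 I)`; RW2 on `psi` (second differences i.i.d.
`N(0, 1/tau_psi)`, kernel exponent `(r-2)/2` on `log tau_psi`); intrinsic
CAR on `theta` with precision `Q = tau_theta (D - W)` (symmetric, `Q 1 = 0`
per connected component, rank `G - #components`); RW1 on the Cox baseline
levels `c`. All intrinsic fields carry sum-to-zero constraints (per
component for the spatial field). Precisions get Gamma(1, 5e-5)
hyperpriors stated on the log scale; the gamma-family `phi` gets
Gamma(1, 0.01); the Weibull shape gets the penalized-complexity prior
`pi(alpha) = (lambda/2) exp(-lambda d(alpha)) |d'(alpha)|`,
`d = sqrt(2 KLD(alpha))` with the exponential model (`alpha = 1`) as base
and rate `lambda = 5`. The gamma multiplier `s` is fixed at 1 (so the
shape is `phi`); it is configurable but nothing identifies `s` separately.

### Identifiability conventions

* The fixed design contains an intercept; the intrinsic fields are
  centered, so levels live in `beta` (for the Cox family the baseline's
  overall level is likewise absorbed by the intercept, the centered `c`
  carrying only the shape).
* The RW2 kernel is invariant to linear trends in `psi`. Only the
  sum-to-zero (constant) direction is removed by constraint; the linear
  direction is identified by the likelihood and explored by a dedicated
  scalar move. With the likelihood disabled that direction has no
  stationary distribution, so the move is skipped in prior-sampling mode.

## Posterior computation

The full model is estimated by blocked MCMC (2 chains, 20,000
iterations, 50% burn-in, thinning 5 by default; all examples below state
the sizes actually used).

* **Log-normal family — data-augmentation Gibbs.** Censored log-times are
  imputed from their truncated-normal full conditionals
  (`z_i ~ N(eta_i, 1/tau)` restricted to `z_i > log y_i`, drawn by
  inverse-CDF in the survival tail). Given the augmented data the model is
  linear-Gaussian: `beta`, `psi`, `theta` have exact Gaussian full
  conditionals (sparse precision = prior structure + diagonal incidence
  counts), sampled by Cholesky with sum-to-zero enforced exactly by
  conditioning-by-kriging (`x* = x - P^{-1}A'(AP^{-1}A')^{-1}Ax`), and
  every precision (including the observation `tau`) is conjugate Gamma
  with rank-corrected degrees of freedom. This path exists because
  random-walk updates mix impractically slowly under ~90% censoring: the
  intercept–`tau` ridge left split-R-hat at 3–10 after 20,000 Metropolis
  iterations, versus ~1.00 after 4,000 Gibbs iterations.
* **Other families — blocked Metropolis.** `beta` uses joint adaptive
  random-walk Metropolis (Haario-style covariance learned during burn-in
  only, scale tuned by Robbins–Monro toward 0.3 acceptance, frozen after
  burn-in to preserve detailed balance). `psi`, `theta`, `c` use block
  random-walk proposals drawn from the pseudo-inverse of their prior
  structure scaled by the current `1/sqrt(tau)` — so proposals follow the
  prior's geometry at every hyperparameter level — then re-centered to
  sum-to-zero. GMRF precisions are exact Gibbs draws from
  `Gamma(1 + rank/2, 5e-5 + quad/2)`. `alpha`, `phi`, and the log-normal
  `tau` (whose full conditional is non-conjugate under censoring in this
  path) use log-scale random-walk Metropolis with the appropriate Jacobian.
* **Initialization.** Fields start at small draws from their prior at
  precision 100 and the likelihood `tau` at a moments estimate; the
  intercept starts at a moment-matched event-rate value (overall deaths
  per child-month, or its reciprocal for location links). Starting
  precisions at the hyperprior mean (20,000) pins the fields at zero and
  traps the chain in the shrinkage corner, so it is deliberately avoided.
* **Diagnostics.** Split-R-hat and a Geyer-type effective sample size are
  computed for every fixed effect, every hyperparameter and three spatial
  components; R-hat above 1.1 raises a warning.

DIC is `Dbar + pD` with the plug-in deviance at the posterior mean of all
blocks; WAIC is `-2(lppd - pWAIC)` from the stored pointwise
log-likelihood, with per-child variances above 0.4 flagged as unstable.
Exceedance probabilities `pi(theta_i < 0 | y)` are Monte-Carlo averages
over N = 10,000 draws (posterior draws resampled with replacement, with a
warning, when fewer are available). Interpretation is link-dependent: for
the identity-link location families (log-normal, gamma mean) a higher
exceedance probability flags *higher* mortality risk; for the hazard-rate
links the reading flips. The summary object carries this flag.

## Nonparametric estimators

The product-limit and Nelson–Aalen estimators follow the printed
conventions exactly: `S(t)` multiplies over death times `t_i <= t`, while
`H(t)` and the Greenwood sum use the strict `t_i < t`; children censored
at a death time remain in the risk set (deaths-before-censorings
tie-break). Greenwood intervals are plain-scale `S ± z(alpha/2) sqrt(V)`
clipped to [0, 1]; past a time where the whole risk set dies the variance
is undefined and the tail is flagged. The DHS-style component
probabilities chain segment-wise death probabilities over the standard
segments 0, 1–2, 3–5, 6–11, 12–23, 24–35, 36–47, 48–59 months; a child
censored inside a segment contributes half a unit of exposure. This is a
synthetic-cohort approximation to the DHS manual's rule; with no
censoring it reduces to deaths over survivors entering.

## The synthetic-data generator

The generator produces the data structure the analysis assumes, with
every latent stored for recovery testing:

* regions on a 6×6 rook lattice (36 nodes, standing in for the study's 37
  states; any adjacency file can be substituted), spatial effects drawn
  from the intrinsic CAR restricted to the sum-to-zero subspace
  (default `tau_theta = 4`, giving regional effects of sd ≈ 0.35 — on the
  log-time scale roughly a 3-fold spread in mortality odds across regions,
  comparable to observed state-level disparities);
* a smooth RW2 maternal-age effect over the 35 bins
  (default `tau_psi = 100`);
* one balanced binary covariate ("female") and a five-level wealth
  ordinal, with true effects at the magnitudes the study reports
  (0.226 for female; 0.106–0.409 across wealth levels), maternal age
  uniform on 15–49;
* family-specific event times drawn through the model's own link;
  interview ages uniform on (0, 60) months (births uniform over the
  59-month eligibility window);
* the intercept calibrated by Brent root-finding so the expected death
  fraction (trapezoid quadrature of the family CDF against the
  interview-age law, averaged over children) hits the 10% target — the
  study's ~90% censoring rate.

The log-normal default log-time precision is `tau = 0.05` (sigma ≈ 4.5).
This is calibrated to the study's observed early-mortality concentration —
survival ≈ 0.96 by month 2, i.e. roughly a third of under-five deaths in
the first two months. It matters: with a more moderate sigma the simulated
death ages spread almost uniformly over the window and the exponential
model fits such data nearly as well as the log-normal, which would
misrepresent the strong family separation the study's criteria table
shows.

What the generator does **not** emulate: the two-stage cluster survey
design and sampling weights, the ~30-variable covariate set, age heaping
and reporting error in death ages, cause-of-death structure, and the real
Nigeria adjacency (available by supplying an adjacency file). Passing
recovery tests therefore demonstrates correctness of the estimators under
the model's own assumptions, not robustness to survey artefacts.

## Numerical choices

* All likelihoods on the log scale; gamma survival via the regularized
  upper incomplete gamma with a leading-order asymptotic continuation
  where it underflows (the log-survival never hits -inf inside the
  representable tail); log-normal survival via the normal log-sf.
* Deaths at completed age 0 months are assigned 0.5 months (half-interval
  convention) so log-time models are defined; configurable.
* Cox baseline grid: 10 intervals at deciles of observed event times by
  default, end extended to the horizon; `H0` accumulates exactly over
  complete intervals plus the partial one.
* Pseudo-determinants by eigendecomposition with a relative rank tolerance
  of 1e-9, computed once per graph; `log pdet(tau M) = rank log tau +
  log pdet M`.
* The PC-prior derivative `|d'(alpha)|` is analytic away from the base
  model and filled by its finite limit `sqrt(KLD''(1))` (central
  differences) within 1e-6 of `alpha = 1`; the density is set to 0 where
  the distance overflows.
* CSV round trips use `%.17g` formatting and round-trip float parsing, so
  a written dataset re-reads bit-identically.

## Problem sizes used in validation

The test suite and the acceptance script run scaled versions of the
study-size analyses: nonparametric summaries at the full n = 33,697;
interval-coverage checks over 5 replicate cohorts of n = 500 (2,000
iterations, 2 chains); model-selection recovery over 10 replicates of
n = 400; prior-recovery runs of 12,000 iterations with the likelihood
disabled. These sizes are the package's validation choices; the same code
paths run unchanged at the full scale.

## Known limitations

* The spatial precision `tau_theta` is weakly identified at realistic
  censoring: with ~10% events the posterior is near-bimodal between the
  data-driven level and the fully shrunk corner, and a chain can settle in
  the shrunk mode on unlucky replicates (observed in roughly one of three
  n = 3,000 cohorts). The fixed effects are unaffected.
* DIC's plug-in deviance uses posterior means blockwise, which can
  misbehave for strongly skewed posteriors; WAIC is the primary criterion.
* The Metropolis path's adaptation is frozen at the end of burn-in;
  very short runs can freeze before reaching the 0.2–0.4 acceptance band.
* Exceedance probabilities resample with replacement when fewer than
  10,000 draws are kept, which understates Monte-Carlo error slightly.
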