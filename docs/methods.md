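# Methods

`reefdesign` implements a Bayesian adaptive-design workflow for
long-term coral-cover monitoring: a semiparametric binomial mixed model
for the historical counts, and an expected-information-gain criterion
for choosing which sampling units to visit at the next survey.  This
note documents the model, the approximations, the numerical choices,
and what the synthetic test bed does and does not establish.

## The observation model

Each survey of site *s* nested in reef location *r* at decimal-year
time *t* yields a count

    y_srt ~ Binomial(n, pi_srt),        n = 1250 photo points,

with logit link `logit(pi_srt) = mu_srt` and linear predictor

    mu_srt = gamma_sr + beta_t' z_t + beta_d' d_rt + f(x_srt)
             + beta_l BLE98_srt + beta_s Time98_srt.

* **Nested random effects.** `gamma_sr ~ N(lambda_r, sigma_s^2)`,
  `lambda_r ~ N(0, sigma_r^2)`.  Normality is an assumption of this
  package (the distributions are left generic in some presentations of
  such models).  `lambda_r` enters the predictor only through the
  hierarchy.
* **Time-varying covariates** `z_t`: a whole-of-reef bleaching
  indicator, square-root-transformed cyclone exposure hours, and their
  product.  The square root linearizes the count-valued exposure hours
  against the logit.  All time-varying covariates (and survey time
  itself) are centered on their historical means; the centering
  constants are frozen and reused for future-time evaluation.
* **Location exposure dummies** `d_rt`: cyclone, severe-cyclone, and
  bleaching exposure of reef *r* in the interval before survey *t*.
  Severe exposure implies ordinary cyclone exposure (nested severity
  coding; switchable).  A static per-reef dummy table is also accepted
  and broadcast over surveys, but note that static dummies are exactly
  collinear with the reef effects, which both weakens their
  identification and distorts design comparisons (see "Design-stage
  fidelity" below).
* **Interrupted time series.** `BLE98 = 1{t >= t_event}` and
  `Time98 = max(t - t_event, 0)` capture the level drop and the
  post-event slope change of the 1998 mass bleaching event.  The event
  time defaults to the first post-event survey (the event occurred
  between surveys, so the first post-event survey registers the level
  change with `Time98 = 0`); the boundary `t = t_event` is post-event.
* **Smooth trend.** `f(x) = beta_0 + beta_1 x + sum_k delta_k |x -
  eta_k|^3` is a low-rank thin-plate spline of centered time with
  K = 3 knots at the k/(K+1) sample quantiles of the distinct centered
  survey times (order statistics with linear interpolation — numpy's
  default quantile convention).  `delta_k ~ N(0, sigma_delta^2)`.  The
  raw cubic radial basis is numerically ill-conditioned, so by default
  the basis columns are post-multiplied by the inverse matrix square
  root (via SVD) of `Omega_kk' = |eta_k - eta_k'|^3`; this is an
  invertible linear reparameterization, so fitted mean responses are
  identical between the two modes.  Over a two-decade window the
  standardized basis columns are O(100), so spline-coefficient values
  of order 0.01 correspond to trend excursions of about one logit.

The fixed-effect column order (intercept, time, bleaching,
sqrt-cyclone, interaction, three dummies, BLE98, Time98) is frozen so
packed parameter indices are stable across runs.  Model components
(spline, random effects, covariate subsets, interruption terms) are
individually switchable for candidate-model comparison by DIC
(`DIC = Dbar + pD`, smaller preferred).

## Priors and posterior computation

Default priors are proper and vague on the logit scale: N(0, 10^2) on
regression coefficients and N(0, 1) on the three log standard
deviations (all overridable per parameter).  The spline coefficients
are hierarchical through `sigma_delta`.

**MCMC.** `fit_mcmc` runs an adaptive random-walk Metropolis scheme
within blocked Gibbs: one jointly-adapted block for (beta, delta) —
their posterior correlations are strong — one for the log sds,
conjugate Gibbs updates for `lambda_r`, and vectorized single-site
Metropolis for the `gamma_sr` (their full conditionals are independent
given `lambda` and theta).  Three additional move families repair the
geometry that plain random walks handle poorly:

* *translation sweeps*: any fixed-effect column constant within
  sampling units (the intercept and the exposure dummies when static)
  trades off exactly against the site/reef effect levels; the
  likelihood is invariant along these directions, so the shift is
  Gibbs-sampled from the Gaussian priors;
* *scale (funnel) moves*: joint rescaling of each log sd with its
  effects (with the stretch Jacobian in the acceptance ratio), which
  traverses the hierarchical funnels;
* *independence proposals* (every 5th iteration): (theta, xi) proposed
  from a tail-inflated Laplace approximation of the joint posterior,
  Metropolis-corrected — these jump across the long correlated ridges
  (e.g. spline-vs-trend) that random walks crawl along.

Chains are initialized at the Laplace mode with the Laplace covariance
preconditioning the block proposals; adaptation runs only during
burn-in (diminishing + frozen afterwards).  Defaults: 4 chains x
10,000 iterations, 50% burn-in; split-chain R-hat is reported per
parameter (warning above 1.05).  Identical seeds give bitwise-identical
draws.

**Laplace.** `laplace_approx` returns a Gaussian over theta with the
latent effects integrated out by a *nested* Laplace: an inner Newton
(exact, analytic curvature) finds `xi_hat(theta)`, and the outer
objective `l(theta) = log p(theta, xi_hat) + (n_xi/2) ln 2pi - 0.5 ln
det(-H_xi)` is maximized by damped saddle-free Newton with an
analytic gradient (envelope term plus the total derivative of the
log-determinant).  The outer Hessian uses central finite differences
of that gradient with two-pass, curvature-scaled steps — the
coordinate curvatures span ~9 orders of magnitude, and a common step
drowns the weak directions in rounding noise.  Joint-mode
maximization over (theta, xi) with Schur-complement marginalization
was rejected: the joint mode of a hierarchy is displaced in the log-sd
coordinates (with no data it does not return the prior, and every
design's information gain inherits that bias); the nested form is
exact in the no-data limit.  Non-positive curvature is clipped at
1e-8 with a warning.

## Design stage

The fitted posterior becomes the prior for design.  The design prior
is the moment-matched Gaussian over the *joint* (theta, xi) —
parameters and latent effects are drawn together from what history has
established.  A theta-only prior (latent effects re-drawn from the
bare hierarchy each round) is retained as a sensitivity mode; it
answers a different question, effectively discarding the historical
information about the reef and site effects, and correspondingly
inflates the apparent value of each sampling unit.

For a candidate design d (a subset of the 21 (reef, site) units) and a
disturbance scenario z, the expected utility is the Monte Carlo
average over J >= 100 rounds of:

1. draw (theta_j, xi_j) from the design prior;
2. simulate counts at the next survey time t = 2016.33 for the
   design's units, with the mean response extrapolated by a
   first-order bivariate Taylor expansion of the time-dependent part
   of the predictor (the spline trend and the post-event slope) around
   the last historical survey — exact when the spline coefficients are
   zero, O(dt^2) otherwise;
3. update the design prior by a Laplace approximation given the
   simulated counts — with a joint Gaussian prior and the canonical
   logit link the observed information is exact, so this is a plain
   damped Newton on a strictly concave objective (no finite
   differences);
4. score the Kullback-Leibler divergence KL(posterior || prior) of the
   theta-marginals in closed form.

Rounds are keyed by (seed, j) and counts are drawn for all 21 units in
a fixed order before subsetting, so designs sharing a seed share
parameter draws and unit-level counts — paired comparisons then cancel
most Monte Carlo noise.  An empty design returns the prior exactly and
scores zero.

**Design efficiency** is the ratio of a design's expected utility to
that of the full 21-unit design, averaged over 20 replicates (paired
by default through shared substreams; an unpaired mode reproduces
fully independent repetitions).  The seven drop-one-reef candidates
are evaluated exhaustively; the 3^7 one-site-per-reef space is
searched by coordinate exchange from 5 random starting designs:
within a sweep every candidate exchange is scored with one shared
substream, the incumbent is kept on ties, fresh substreams separate
sweeps, and each start is capped at 10 sweeps (near-tied designs can
otherwise toggle indefinitely under re-estimated utilities).

**Scenarios.**  The disturbance covariates — including the per-reef
exposure dummies — describe the interval before the next survey, so
they are scenario settings.  Scenario (a) continues the last observed
time-varying covariates and withdraws all cyclone and location
exposures; scenario (b) activates bleaching and cyclone exposure with
their interaction at every reef location, with cyclone hours
defaulting to the historical mean of the nonzero exposures.

## The synthetic test bed

`synthetic_data` generates Scott-Reef-like programs: 7 reef locations
x 3 nested sites, 25 irregular surveys spanning 1994.83-2016.08
(jittered Octobers plus anchored 1998 pre/post-bleaching surveys and a
final 2016.08 survey), n = 1250, a mass bleaching event at 1998.83
interrupting the trend, reef-heterogeneous interval-varying exposure
dummies, and occasional cyclone years.  Default true parameters
(intercept 0.3, level change -1.8, recovery slope +0.08/yr, reef sd
0.3, site sd 0.2, spline-coefficient sd 0.01, negative disturbance
effects of 0.04-0.3) are illustrative, chosen so cover trajectories
fall roughly in the 0.05-0.6 range with the characteristic post-1998
collapse and partial recovery; they are not estimates from real
monitoring data.

What the generator does *not* emulate: extra-binomial dispersion
(spatial correlation of photo points within images and transects),
habitat stratification, and image-level structure.  This matters for
one headline quantity: after 525 exactly-binomial historical surveys
the fitted posterior is extremely tight, so one additional survey sits
in the *linear* information regime (prior covariance x new-survey
information << 1 in every direction) and the drop-one-reef efficiency
lands near the unit share 18/21 ~ 86% plus shared-direction overlap
(we measure 87-95% depending on scenario), rather than the >= 95%
observed for the real program, whose posterior was effectively wider
relative to one survey's information.  The qualitative findings do
reproduce: efficiencies are nearly identical across the seven
candidates (range < 2 points), no reef location is special, the full
design scores exactly 1 against itself, an empty design gains nothing,
and augmenting a design never loses information beyond pairing noise.
Passing tests on this bed therefore validate the machinery and the
qualitative design conclusions, not the numeric efficiency levels of
any real reef.

## Numerical choices and degenerate inputs

* Quantile convention for knots: numpy's linear-interpolation order
  statistics; documented bit-exactly in the model module.
* Gaussian summaries are symmetrized; eigenvalues below -1e-10
  (relative) are an error, smaller negatives are clipped to PSD with a
  warning.  KLD requires an invertible prior covariance and raises
  `LinAlgError` otherwise.
* Laplace: analytic gradients throughout; FD steps 1e-5 x (1 + |x|)
  rescaled by measured curvature; eigenvalue floor 1e-8; saturated
  counts (y = 0 or y = n) flatten the logit direction and are flagged.
* Ties in coordinate exchange keep the incumbent; ties across starts
  break to the lexicographically smallest site assignment.
* Missing covariate or dummy rows are validation errors, never
  imputed.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; per-draw substreams are keyed by
  (seed, replicate, draw) tuples so paired designs share them.

## Known limitations

* The Gaussian moment-matched design prior understates heavy tails of
  the variance-parameter posteriors; with few reefs the Laplace sds
  for log sigma_r can disagree with MCMC well beyond 10%.
* DIC with hierarchical effects uses the conditional (not marginal)
  deviance; pD is reliable for fixed-effects candidates and indicative
  otherwise.
* The coordinate-exchange search is a local method; on structureless
  utility landscapes a single start reaches the global optimum only
  ~30% of the time (use more starts; the one-site-per-reef monitoring
  utilities are near-additive, where almost every start converges).
* One-visit horizon only: the criterion scores the next survey, not a
  multi-year sampling policy.
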