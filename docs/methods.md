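# Methods

## The movement model

A trajectory is a regularly sampled sequence of planar fixes. At a fixed
time unit `T` the observables are the headings `theta_t` (bearing of the
displacement from retained fix `t` to `t+1`; 0 = east, `pi/2` = north,
wrapped to `[-pi, pi)`) and speeds `v_t` (displacement length / `T`).
Positions follow the deterministic update

    x_{t+1} = x_t + T * v_t * (cos theta_t, sin theta_t),

so all stochastic structure lives in the heading and speed series.

### Headings: circular auto-regression

The core object is the smooth circle map

    M(theta; alpha, w) = alpha + 2 * arctan( w * tan((theta - alpha)/2) ),

a tan-half-angle (Moebius) attraction of `theta` toward the focal direction
`alpha` with strength controlled by the regression coefficient `w`:
`w = 1` is the identity, `w = 0` collapses everything onto `alpha`,
`0 < w < 1` attracts, `w < 0` reflects across `alpha` (reciprocating,
zigzag headings). `M` is a continuous bijection of the circle for every
`w != 0`; the antipode `theta = alpha + pi` is mapped to its continuous
limit `alpha + pi` rather than evaluated through `tan(pi/2)`.

The heading model sets `mu_t = M(theta_{t-1}; alpha, w)` and draws

* symmetric noise: `theta_t = mu_t + e_t`, `e_t` i.i.d. von Mises
  `VM(0, kappa)` or wrapped Cauchy `WC(0, r)`;
* skewed noise: `theta_t ~ KJ(mu_t, kappa, r, nu_t)` with
  `nu_t = lambda - mu_t`, so each step's error distribution leans from the
  intended direction `mu_t` toward a fixed forcing direction `lambda`
  (read as the leeward direction for a bird flying in wind).

The correlated random walk (CRW) is the `w = 1` special case and is
implemented on the same code path with `w` frozen and `alpha` dropped.

### The Kato-Jones family

`KJ(mu, kappa, r, nu)` is generated from `X ~ VM(0, kappa)` by attracting
`X` toward `nu` with Moebius coefficient `(1 - r)/(1 + r)` and rotating by
`mu`:

    Y = mu + nu + 2 * arctan( ((1 - r)/(1 + r)) * tan((X - nu)/2) ).

Its closed-form density is

    f(y) = (1 - r^2) / (2 pi I0(kappa))
           * exp( kappa * (xi cos(y - eta) - 2 r cos nu) / D(y) ) / D(y),

with `gamma = mu + nu`, `D(y) = 1 + r^2 - 2 r cos(y - gamma)`,
`xi = |1 + r^2 e^{2 i nu}|`, `eta = mu + arg(1 + r^2 e^{2 i nu})`.
The change-of-variables route `f_VM(g^{-1}(y); 0, kappa) |dg^{-1}/dy|`
is implemented independently (`kj_pdf_via_transform`) and the two must
agree to 1e-8 — this dual-route check pins the algebra, including the
attraction coefficient `(1 - r)/(1 + r)`, which is the unique choice
consistent with the `nu = 0` (pure concentration increase) and
`r = 0` (pure rotation, `KJ = VM`) reductions. The family reduces to
`VM(mu, kappa)` at `nu = r = 0`, shifts its mode between `mu` and
`mu + nu` with a tail toward `mu` for moderate parameters, and can be
bimodal ("abnormal") when `nu` nears `pi` or `r` is large; summaries
return the global mode with a multimodality flag.

### Speeds

    v_t = a v_{t-1} + b cos(theta_t - c) + d cos(theta_t - theta_{t-1})
          + c0 + eta_t,      eta_t ~ N(0, sigma^2) i.i.d.

Speed peaks when heading in direction `c`; for flight in wind `c` estimates
the leeward direction. Fitting is conditional Gaussian ML, i.e. least
squares in the `(b cos c, b sin c)` parameterisation (which removes the
`(b, c) <-> (-b, c + pi)` aliasing; `b >= 0` is restored on conversion) and
`sigma^2 = ` mean squared residual. The untruncated Gaussian likelihood is
used for fitting; at simulation time non-positive draws are rejected and
redrawn. In the cruising regime (`c0/sigma > 4`, mean speed >> sigma)
redraws essentially never occur and the truncation bias on the MLEs is
below one standard error (verified by a test that simulates with
truncation and fits without).

## Estimation

The heading likelihood is conditional on the first observed heading:
`sum_{t=1}^{n-1} log f(theta_t | theta_{t-1})`. Free parameters are
optimised by multi-start BFGS on unconstrained scales (`log kappa`,
`logit r`, angles periodic, `w` unbounded). The start design is
stratified: angles on a coarse circular grid around the circular mean
heading, `w in {-0.5, 0.3, 0.7, 0.95}`, `kappa in {1, 10}`,
`r in {0.1, 0.5}`, plus one data-informed start; the best converged start
is kept. A start counts as converged when BFGS reports success or the
finite-difference gradient infinity-norm falls below
`1e-4 * max(1, |loglik|)` — the tolerance is relative because the
conditional log-likelihood scales with series length and the
finite-difference gradient noise scales with it.

An exact aliasing of the attraction map,
`M(theta; alpha + pi, w) = M(theta; alpha, 1/w)`, makes `(alpha, w)` and
`(alpha + pi, 1/w)` observationally identical. Fits report the canonical
representative `|w| <= 1` whenever `alpha` is free; for fixed-`alpha` and
focal-point models the alias is not reachable and `w` (including `w > 1`)
is reported as estimated.

Model comparison uses `AIC = -2 loglik + 2k` with `k` the number of free
parameters (CRW(VM|WC): 1; C-AR(VM|WC): 3; C-AR(KJ): 5; each constraint —
fixed `lambda`, fixed `alpha`, focal point — removes exactly one).
`select_model` warm-starts richer candidates from fitted nested ones
(CRW -> C-AR via `w = 1`; symmetric -> KJ via small `r`), which also keeps
maximised log-likelihoods monotone across nested families in practice.
Ties are broken toward fewer parameters, then declaration order.

### Model variants

* fixed `lambda`: the skew target frozen at the leeward direction
  `c` fitted by the speed model at time unit 1;
* fixed `alpha`: the focal direction frozen at the bearing from the first
  to the last fix (the entire observed flight direction);
* focal point: `alpha` replaced, each step, by the bearing from the
  current location to a known point (homing); in simulation the target is
  recomputed from the simulated position every step.

Whether a focal-point model also estimates `lambda` freely or fixes it is
exposed as two separate specs rather than hard-wired.

## Diagnostics

**Residuals and time unit.** Innovations are
`wrap(theta_t - mu_t)` for symmetric noise and the inverse generating
transform (which recovers the underlying `VM(0, kappa)` variate) for KJ
noise. They are screened by the lag-1 autocorrelation of the residuals
treated as linear values, with the white-noise band `+-1.96/sqrt(n)`.
`choose_time_unit` resamples the trajectory at each candidate `T`, fits
the model ladder, and returns the smallest `T` whose best model has
non-significant `rho_1` and an adequate heading GOF; if none qualifies it
returns the per-`T` table with no selection. The time unit is read as the
pace at which the animal controls its heading; no formal theory selects
the exact unit.

**Heading-distribution GOF.** 24 classes on `[-pi, pi)`; observed counts
against the mean counts of simulated series from the fitted model (all
starting at the observed first heading); classes with expected count < 3
excluded; statistic `sum (E_d - O_d)^2 / E_d` referred to chi-square with
`(included classes) - 1` degrees of freedom; pointwise 95% envelopes from
the 2.5/97.5 percentiles of the simulated counts. *Known limitation:* the
chi-square reference treats the binned headings as independent draws. For
strongly autocorrelated heading series (attraction `w` well above ~0.1,
or CRW) the statistic is stochastically larger than chi-square and the
test over-rejects; the calibration tests therefore run in a
weak-attraction regime where the reference is exact. For real, strongly
dependent series the p-value should be read as conservative screening,
exactly as a practitioner would use it.

**Final-location GOF.** Full trajectories are simulated from the fitted
heading + speed pair starting at the observed first fix, heading and
speed; the simulated endpoints are summarised by their mean `M` and
covariance `Sigma`, and

    P_FL = exp(-D^2 / 2),

the bivariate-normal mass outside the density contour through the observed
endpoint (`D^2` its Mahalanobis distance). The model is rejected when
`P_FL < 0.05`, i.e. when `D^2 > 2 ln 20 ~= 5.99`, the chi-square(2) 95%
quantile. The closed form replaces 2-D quadrature of the contour integral;
they are identical under the normal approximation. `P_FL` is invariant
under rigid motions of the frame.

**Bootstrap.** Parametric bootstrap of the MLEs: series of the original
length are simulated from the fitted model and refitted (fitted values as
one start plus a few random starts); per-parameter SDs and skewness are
reported, failures counted and excluded. SDs scale as `1/sqrt(n)`;
`kappa`-hat is right-skewed when the true concentration is large, because
enlarging an already large `kappa` barely changes the von Mises shape.

## Synthetic scenarios

No public trajectory deposit exists for the motivating data, so the
package ships parameterised scenario generators used by tests, examples
and the acceptance script:

| scenario       | heading model | true parameters |
|----------------|---------------|-----------------|
| oriented       | C-AR(VM)      | alpha=0, w=0.5, kappa=6 |
| wind_skewed    | C-AR(KJ)      | alpha=-pi/8, w=0.7, kappa=6, r=0.3, lambda=5pi/8 |
| zigzag         | C-AR(VM)      | alpha=0, w=-0.5, kappa=6 |
| tortuous_loop  | C-AR(KJ)      | alpha=3pi/4, w=0.85, kappa=4, r=0.5, lambda=-pi/2 |
| homing         | C-AR(KJ), focal point (0, 30 km) | w=0.8, kappa=8, r=0.2, lambda=5pi/8 |

All share a cruising speed model (`a=0.3, b=1.5 m/s, c=5pi/8,
d=0.3 m/s, c0=6 m/s, sigma^2=0.64 (m/s)^2`; stationary mean speed
~9 m/s), chosen so simulated speeds are effectively always positive, as in
fast continuous flight. What these scenarios emulate — stationary
parameters, exactly regular sampling, no positional noise, no stops — is
deliberately idealised: passing tests demonstrate that the estimation and
diagnostic machinery is correct under the model, not that real GPS series
are free of measurement error, behavioural regime switches or irregular
gaps. Segmenting heterogeneous trajectories is out of scope.

## Numerical choices

* Angles are kept in the half-open interval `[-pi, pi)` everywhere, so the
  histogram seam is never double-counted.
* Sampling uses uniform-proposal rejection with acceptance probability
  `f(x)/f_max` (normalising by the density maximum keeps the sampler exact
  for concentrated densities whose maximum exceeds 1); Kato-Jones
  variates are generated by transforming von Mises draws, which is also
  the construction the density is derived from. Every stochastic routine
  takes a single integer seed or a NumPy `Generator`.
* Quadrature checks use adaptive integration with absolute tolerance
  1e-10; the KJ mode search uses a 4096-point grid plus bounded
  refinement.
* `log I0(kappa)` is evaluated via the exponentially scaled Bessel
  function, so likelihoods are stable up to `kappa ~ e^25` (the optimiser
  caps `log kappa` at 25).
* Resampling anchors at the first fix; trailing fixes that do not complete
  a step are dropped. Zero-displacement steps get NaN headings and are
  refused by the fitting routines, since their heading is undefined.

## Sizes used by the shipped test-suite and acceptance script

Parameter recovery runs 50 replicate 2000-step flights per scenario;
selection power uses 20 replicates at n=2000; GOF calibration uses 150
replicates of length 500 with 400 inner simulations (acceptance script:
60/300); bootstrap checks use 50-200 refits. These sizes are the
package's choices for routine verification; all thresholds are
independent of them.
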