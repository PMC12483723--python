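# Methods

This note records the statistical model, the estimation choices, what the
simulator does and does not emulate, and the numerical conventions, at the
level of detail a user auditing results would want.

## 1. The auxiliary (measurement) layer

Each ordinal response `y_it` with `C` categories is a discretized normal
variable `y*_it`: `y_it = c` iff `tau_{c,t} < y*_it <= tau_{c+1,t}`. Ordinal
data identify only the *standardized* scale of `y*`: the probit-scale
thresholds `tau~_{c,t} = (tau_{c,t} - mu*_t)/sigma*_t` and the correlations
of the underlying variables. Every identification row is therefore
implemented as a model-side map onto those standardized statistics, and the
sample-statistic vector is the same for all rows:

    s = ( tau~_{c,v,t}  for all variables, waves, cut-points;
          r_ij          polychoric correlations, i < j over the VT columns ).

This is also how WLSMV software treats the delta/theta distinction
internally, and it makes degrees of freedom uniform:

    df = sum_v T (C_v - 1) + VT (VT - 1) / 2  -  (# free parameters).

Stage-1 point estimation: `tau~` by normal quantiles of cumulative
proportions; each `r_ij` maximizes the Olsson log-likelihood with thresholds
fixed (pseudo-ML), by bounded scalar search on the Fisher-z scale
(`|z| <= atanh(1 - 1e-6)`, tolerance 1e-8). Bivariate rectangle
probabilities use an Owen's-T decomposition of the bivariate normal CDF
(vectorized over cut-point grids; unit-tested against `scipy`'s CDF to
~1e-13). Cells are floored at 1e-12 inside the log only; degenerate tables
(all mass in one cell, monotone likelihoods) are flagged, never smoothed —
there is no continuity correction. Missing data are handled by listwise
deletion only, so Stage-1 and Stage-2 use the identical sample.

Identification rows (per variable; binary variables substitute their
analogues, configurable `alt1 -> bin_myt | bin_mm`, `alt2 -> bin_joreskog`):

* `standard` — `mu*_t = 0, sigma*_t = 1`, thresholds free per wave;
* `alt1(_inv)` — first-wave scale anchor `mu*_1 = 0, sigma*_1 = 1`; the first
  two thresholds (all thresholds under `_inv`) time-invariant; later means
  and variances free. Inversion: `sigma*_t = (tau~_{2,1} - tau~_{1,1}) /
  (tau~_{2,t} - tau~_{1,t})`, `mu*_t = tau~_{1,1} - sigma*_t tau~_{1,t}`;
* `alt2(_inv)` — threshold anchors `tau_1 = 0, tau_2 = 1` every wave;
  inversion `sigma*_t = 1/(tau~_{2,t} - tau~_{1,t})`,
  `mu*_t = -tau~_{1,t} sigma*_t`;
* binary rows — `bin_myt` (unit variances, free means, invariant threshold),
  `bin_mm` (zero means, free variances, invariant threshold), `bin_joreskog`
  (zero threshold, unit variances, free means). `bin_mm`'s scale map
  `sigma*_t = tau / tau~_t` requires all probit thresholds on one side of
  zero; outside that region the row is inadmissible (this is a domain
  restriction of the parameterization, not of the software).

Threshold invariance is testable for `C >= 3` by the constrained DWLS fit of
the auxiliary model (saturated correlations, equated thresholds); under
either alternative row the test has
`df = sum_v [T(C_v-1) - (C_v-1) - 2(T-1)]` and the two rows give identical
chi-square — they parameterize the same restriction. For binary variables
invariance is required for identification and is not testable. The
ratio diagnostic reports `(tau~_{c,t} - tau~_{c',t}) / (tau~_{c,t'} -
tau~_{c',t'})` over all threshold pairs: constant across pairs under
invariance (it estimates the SD ratio), unequal when any threshold moves.

## 2. Structural layers

All families produce implied moments `(mu*(theta), Sigma*(theta))` of the VT
underlying variables plus model-scale thresholds, then standardize.

* **LGM** `y*_t = alpha + (t-1) beta + eps_t`, slope loadings `t-1`
  (configurable origin was considered and rejected — one convention, stated
  here, keeps the transformation tables simple). Variance placement: `delta`
  constrains underlying variances (errors as remainders, negative remainders
  flagged as inadmissible, non-fatal during optimization); `theta` constrains
  error variances.
* **AR(1)** `y*_t = nu_t + rho_t y*_{t-1} + eps_t` with `y*_1` predetermined
  (free or anchored mean/variance per row). Only theta placement: with
  autoregression the underlying variances are nonlinear in the coefficients.
* **ALT** adds the growth factors to the AR recursion from wave 2 and lets
  `y*_1` correlate with `(alpha, beta)`. The predetermined initial condition
  is the only variant implemented; the endogenous-`y*_1` ALT is covariance
  equivalent to it and out of scope. Multivariate ALT: lag-one cross-lagged
  coefficients, same-wave concomitant error covariances, full growth-factor
  covariance, free cross-series first-wave couplings.

Moments are computed by forward recursion of the state (mean and covariance
propagated wave by wave); an independent generic evaluator
`mu = G (I-B)^{-1} nu`, `Sigma = G (I-B)^{-1} Psi (I-B)^{-T} G'` built from
the explicit coefficient matrices serves as the algebra oracle in the tests
(agreement to 1e-12, and to 4 MC standard errors against 10^6 simulated
trajectories).

Stationarity (`rho_t = rho`, and shared cross-lags) is an optional flag, off
by default.

## 3. Estimation

DWLS: minimize `F = (s - sigma(theta))' W^{-1} (s - sigma(theta))`,
`W = diag(Gamma)`.

**Gamma.** Default is the analytic influence-function form of the two-step
estimator: threshold influence `(1{y<=c} - p_c)/phi(tau~_c)`; polychoric
influence `A^{-1}[score_i + sum_c (dE score/d tau_c) IF_tau_c,i]` with
`A = sum_cells (d pi/d rho)^2 / pi` and the threshold cross-terms from the
bivariate normal corner densities — i.e. the estimating-equation asymptotics
of the conditional two-step procedure, including the correction for
estimated thresholds. `Gamma` is the sample covariance of the stacked
influence functions (positive semidefinite by construction). A
subject-resampling bootstrap (seeded, any `B`) is provided and cross-checked
against the analytic form in the tests; it is not the default because the
replication studies would multiply its cost by several hundred.

**Optimizer.** The objective is an exact weighted least-squares problem, so
the fit uses a Levenberg–Marquardt / trust-region least-squares routine on
`W^{-1/2}(s - sigma(theta))` with `xtol = ftol = 1e-14`, multistart (a
closed-form method-of-moments start obtained by projecting the sample
statistics onto the model — exact on-manifold — plus perturbed copies). The
tight tolerances are what make equivalent specifications agree in chi-square
to ~1e-11 rather than to optimizer noise.

**Inference.** Sandwich covariance
`(D'W^{-1}D)^{-1} D'W^{-1} Gamma W^{-1} D (D'W^{-1}D)^{-1} / n` with `D` the
central-difference Jacobian (relative step 1e-6); collapses to the naive
form when `Gamma = W`. Test statistic: second-order (mean *and* variance)
Satterthwaite adjustment, `T_adj = (m1/m2) nF`, `df* = m1^2/m2`,
`m_k = tr((U Gamma)^k)`, `U = W^{-1} - W^{-1}D(D'W^{-1}D)^{-1}D'W^{-1}`;
p-values against chi-square with (non-integer) `df*`. The one-moment
(mean-only) variant was not implemented; the second-order version is the one
whose size the acceptance study checks (empirical 5%-level rejection ~0.04 to
0.05 at n = 2000). Fit indices: RMSEA and CFI/TLI from the adjusted
statistic against an independence baseline (free thresholds, zero
correlations), and Raftery's `BIC' = chi2 - df ln n` with the counted df.
`df = 0` uses the perfect-fit conventions. Rank-deficient Jacobians at the
optimum raise in `robust_se`; `dwls_fit` converts this to NaN standard
errors plus a warning so misspecified boundary fits still report their fit
value.

## 4. Equivalence machinery

`transform_params` transports the source's standardized implied moments and
re-solves the target's parameters in closed form (the same recovery used for
starting values, which is exact on-manifold for the saturated, growth and
AR(1) families). Moment preservation below 1e-10 is verified on every call.
Anchors realized this way reproduce the textbook tables: growth Models C/D
rescale by the first error variance (equivalently `1 + psi_alpha` of the
theta model); the alternative-row pair rescales by the invariant threshold
distance; the binary Millsap–Yun-Tein/Joreskog pair swaps threshold and
intercept mean with a sign flip; AR(1) Models E/F exchange the first-wave
variance anchor for the threshold anchor.

The ALT model is the designed exception: an affine latent shift `a` would
require an occasion intercept `a(rho_t - 1)` that the recursion does not
contain, so with time-varying `rho_t` the two alternative ALT rows are not
equivalent — `check_equivalence` exhibits witness panels where their
chi-squares differ by orders of magnitude more than solver tolerance. When
`rho` is constant the shift folds into the random intercept's mean and the
rows *do* map onto each other; the closed-form stationary map is shipped and
verified. Users comparing ALT parameterizations should be aware the
distinction is driven by the time-varying coefficients.

`check_equivalence` fits both candidates on seeded probe panels simulated
from saturated (unstructured) processes — deliberately misspecified for both
candidates, since equivalence is a statement about constraint sets, not
about fit at the truth — and requires equal df, `|delta chi2| < 1e-4` on
every probe, and a validated map. `omega_constraint_report` counts
constraints as (moment dimension − Jacobian rank) at random admissible
draws, on three scales: the covariance structure `vech(Sigma*)` (the
convention under which the four-wave growth model carries
`T(T+1)/2 - 3 = 7` constraints), the mean structure relative to the means
the row leaves free, and the standardized statistics (where the count equals
df).

## 5. Simulator and packaged scenarios

Latent trajectories are sampled by the structural recursion (exogenous block
by Cholesky, then wave-by-wave propagation) — never by factoring the implied
covariance — so simulation is an independent oracle for the moment
calculations. All shocks sit in one `(n, k)` standard-normal matrix in
subject-major order: growing `n` under a fixed seed leaves earlier subjects
unchanged. Saturated probe scenarios draw the latent vector directly from
its specified joint normal.

Packaged scenarios (defaults chosen once, as study conditions):

* `lgm_scenario` — T = 6 waves, C = 4, n = 5000: invariant thresholds
  (0, 1, 1.9) on the anchored scale, growth means (0.20, 0.10), growth
  covariance [[0.50, 0.04], [0.04, 0.03]], underlying variances `1 + 0.35 t`.
  Used for the 200-replication recovery/coverage study.
* `ar1_scenario` — T = 5, C = 4, n = 2000: `rho = 0.45`, unit innovations,
  mildly time-varying thresholds. Used for the 500-replication size study.
* `nlsy_like_scenario` — three series over six waves (binary + two
  4-category), multivariate ALT with autoregression ~0.3, cross-lagged paths
  of magnitude 0.06–0.10 (health responding negatively to prior drug and
  depression propensities, depression to prior health, drug weakly to prior
  depression), concomitant error covariances, invariant thresholds, and a
  negative drug slope mean so the marginal use proportion declines across
  waves (0.22 to 0.13 at the defaults).

What the simulator does *not* emulate about real panel data: attrition and
other missingness mechanisms (the estimator assumes listwise-complete data),
non-normal underlying variables, measurement non-invariance of loadings
(only threshold non-invariance is representable), survey weights and
clustering. Passing tests therefore certify the estimator and the
equivalence algebra under the generating assumptions, not robustness to
their violation.

## 6. Numerical conventions and limitations

* Polychoric search interval `(-1 + 1e-6, 1 - 1e-6)`; `|rho| > 1 - 1e-4`
  flagged as boundary. Tied thresholds (empty interior category) make the
  polychoric refuse; empty extreme categories give ±inf thresholds and are
  flagged, never collapsed.
* Standardization guards `diag(Sigma*)` at 1e-12 during optimization so the
  objective stays smooth near inadmissible regions; admissibility warnings
  (negative error remainders, non-PSD blocks) are reported on the result.
* Identification checks are local: Jacobian column rank at random admissible
  draws (default 10), singular values below `1e-8 x` the largest counted as
  zero. Global identification is not claimed.
* Equality constraints are implemented by slot sharing in the parameter
  table (one free slot, many positions), so df accounting is structural, not
  numerical.
* The bootstrap `Gamma` warns below B = 100; replication studies below 50
  replications warn likewise.
* Multivariate growth (LGM with V > 1) is not a separate family; use the
  multivariate ALT with zero autoregression if needed. RI-CLPM-style models,
  quadratic growth, and multiple indicators per occasion are out of scope.
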