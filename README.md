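# ordalt

Structural equation models for **binary and ordinal repeated measures**:
linear latent growth, first-order autoregressive, and autoregressive latent
trajectory (ALT) models fitted on the underlying continuous variables that a
threshold model links to the observed categories — with particular care for
the **identification constraints** ("parameterizations") that make such models
estimable, the closed-form maps between constraint sets that are equivalent,
and numerical detection of the ones that are not.

## Who this is for

Analysts of longitudinal survey items — substance-use indicators, symptom
scales, self-rated health — where the response is a handful of ordered
categories repeated over waves. Standard software standardizes the underlying
variable at every wave, which silently forbids the latent mean and variance
from changing over time: often exactly the quantity of interest. The
alternative identification rows implemented here free those moments, at the
price of threshold constraints, and the choice among them is *not* always
innocuous. This package makes the consequences computable.

## The model

An observed category `y_it in {0,..,C-1}` arises by discretizing a normal
underlying variable `y*_it` at thresholds `tau_{1,t} < .. < tau_{C-1,t}`
(`tau_0 = -inf`, `tau_C = +inf`):

    y_it = c  iff  tau_{c,t} < y*_it <= tau_{c+1,t}.

**Stage 1 (auxiliary layer).** Thresholds are standard-normal percentiles of
the cumulative category proportions; each pairwise correlation of the
underlying variables is a polychoric correlation, maximizing the Olsson
log-likelihood `sum_jk n_jk log pi_jk(rho)` with thresholds held fixed
(pseudo-ML). Identification rows:

| row | constraint set |
|---|---|
| `standard` | `mu*_t = 0`, `sigma*_t = 1` every wave; thresholds free |
| `alt1` / `alt1_inv` | `mu*_1 = 0`, `sigma*_1 = 1`; two (all) thresholds time-invariant; later means/variances free |
| `alt2` / `alt2_inv` | `tau_1 = 0`, `tau_2 = 1` every wave; all means/variances free |
| `bin_myt`, `bin_mm`, `bin_joreskog` | the binary analogues (free means / free variances / zero threshold) |

**Stage 2 (structural layer).** On the underlying scale,

* LGM: `y*_t = alpha + (t-1) beta + eps_t`
* AR(1): `y*_t = nu_t + rho_t y*_{t-1} + eps_t`, `y*_1` predetermined
* ALT: `y*_t = rho_t y*_{t-1} + alpha + (t-1) beta + eps_t`, `y*_1`
  predetermined and correlated with `(alpha, beta)`; multivariate ALT adds
  lag-one cross-lagged paths and same-wave ("concomitant") error covariances.

Estimation is **DWLS/WLSMV**: minimize
`F = (s - sigma(theta))' W^{-1} (s - sigma(theta))` over the sample vector
`s` of thresholds and polychoric correlations, `W = diag(Gamma)` with `Gamma`
the asymptotic covariance of `s` (influence-function form; bootstrap
available). Standard errors use the full-`Gamma` sandwich; the test statistic
`n F` is mean-and-variance adjusted (Satterthwaite): `T_adj = (m1/m2) nF`,
`df* = m1^2/m2`, `m_k = tr((U Gamma)^k)`.

**Equivalence.** Two specifications are equivalent when a parameter
transformation preserves the implied moments (Raykov–Penev sense) — then they
share chi-square, df and fit indices on *any* data. The package ships the
maps (anchored at the first-wave variance, the first error variance, or the
threshold distance) and a checker that fits candidate pairs on seeded probe
panels. Headline facts it reproduces: the growth-model alternative rows are
all equivalent to each other but not to the standard delta/theta pair (which
also differ from each other); all free-threshold AR(1) rows are equivalent,
as are all four binary AR(1) rows; the two alternative **ALT** rows are *not*
equivalent when the autoregressive coefficients vary over time; ALT needs
five waves for identification.

## A worked example

```python
from ordalt import compute_sample_stats, dwls_fit
from ordalt.simulate import lgm_scenario, simulate

scenario = lgm_scenario(T=6, n=5000)   # 4-category growth process, anchored thresholds
panel = simulate(scenario, seed=42)
fit = dwls_fit(compute_sample_stats(panel), scenario.spec)
print(fit.summary())
```

prints (abridged)

```
DWLS fit: chi2_adj = 14.6891, df = 21 (df* = 20.29), p = 0.6374
  RMSEA = 0.0000
  CFI = 1.0000
  tau[0][2]       1.895  (se 0.015)
  mu_alpha[0]     0.198  (se 0.015)
  mu_beta[0]      0.102  (se 0.005)
  psi[0][0][0]    0.525  (se 0.025)
  ...
```

`mu_beta` is the mean latent growth per wave (truth 0.10), `psi[0][0][0]` the
random-intercept variance (truth 0.50); the adjusted chi-square near its df
says the growth structure fits. The `examples/` directory walks through the
auxiliary layer, the threshold-invariance test, equivalent vs non-equivalent
specifications, and the packaged three-series multivariate ALT scenario; a
thin CLI (`ordalt simulate|auxiliary|fit|equivalence|recovery`) wraps the
same calls for shell use.

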