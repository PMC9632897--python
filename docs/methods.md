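# Methods

## Model

A response `Y` on (0, 1) follows the unit Burr XII (UBXII) distribution,
`F(y; c, d) = (1 + (-log y)^c)^(-d)` with shapes `c, d > 0`. Because the
quantile function is closed-form, the distribution can be re-indexed by
its `tau`-th quantile: solving `Q(tau) = q` gives
`d = log(1/tau) / log(1 + (-log q)^c)`, and substituting yields a
`(c, q, tau)` parameterization in which `q` is directly interpretable and
can carry a regression structure. `tau` is fixed and known (0.5
throughout by default, i.e. median regression); the argument order is
`(c, q, tau)` everywhere.

The regression assumes independent `Y_i ~ UBXII(c, q_i)` with
`g(q_i) = x_i' beta` for a strictly monotone, twice-differentiable link
`g`, a full-column-rank design with leading intercept, and a single
scalar shape `c` (no dispersion submodel). Special cases `c = 1` (unit
Lomax) and `d = 1` (a unit log-logistic variant) are parameter settings,
not separate APIs.

## Estimation

Everything is maximum likelihood.

* **Distribution (two parameters).** `U_q = 0` has the closed-form
  solution `log t(q_hat) = log(1/tau) * mean(log t(y_i))`, where
  `t(x) = 1 + (-log x)^c`. The likelihood is therefore profiled to a
  one-dimensional function of `c`, maximized by BFGS with the analytic
  profile score, started at `c = 1` and polished by secant-Newton steps
  on the score. `c` is optimized as `log c` so positivity is structural;
  the optimum is invariant to this transform.
* **Regression.** BFGS on `(beta, log c)` with the analytic score
  (assembled per observation and mapped through the link by the chain
  rule), started from least-squares coefficients of the link-transformed
  responses (responses clamped to `[1e-6, 1 - 1e-6]` for the transform
  only) and `c = 1`, then polished by damped Newton steps using the
  analytic observed information. The observed information is the exact
  negative Hessian, assembled from per-observation second derivatives in
  `(q_i, c)` and mapped through `g` — algebraically equivalent to the
  usual diagonal-matrix presentation, and cross-checked against a
  central-difference Hessian oracle in the tests at 1e-4 relative.
* **Inference.** Standard errors are square roots of the diagonal of the
  inverse observed information at the MLE; Wald statistics use the
  standard normal reference (reported as z statistics), and confidence
  intervals are `estimate ± z_{1-alpha/2} * SE` with alpha = 0.05 by
  default.
* **Convergence** is declared from the score sup-norm at the reported
  optimum (at most 1e-5, relatively scaled for large log-likelihoods),
  not from the optimizer's status flag — scipy's BFGS routinely stops
  with a "precision loss" message after effectively locating the
  optimum. Non-converged fits are returned flagged, never silently.

The competitor families (Kumaraswamy median–dispersion, unit-Weibull
quantile with tau = 0.5, beta mean–precision) share the same engine with
logit-linked location and a constant second parameter optimized on the
log scale; their derivatives are numerical (central differences), which
is accurate and fast at these dimensions. Starting values: link-transformed
least squares for the location coefficients; 1 for `d_p` and `gamma`; a
moment estimate for the beta precision `phi`.

## Numerical design

All kernels work through `z = c * log(-log y)`: `log t(y)` is
`logaddexp(0, z)` and `(t-1)/t` is `expit(z)`, so nothing is lost when
`y` approaches either end of (0, 1). Observations exactly 0 or 1 are
rejected with the offending index — the support is open and silent
clipping would corrupt likelihoods.

Two genuine floating-point limits are worth knowing:

* the lower tail is polynomially heavy in `w = -log y`; mass of order
  1e-4 (scenario-dependent) lies below the smallest positive double.
  Inversion sampling therefore nudges draws that round to 0.0 or 1.0 to
  the nearest representable interior value. Quadrature checks of the
  density integrate in the `w` domain for the same reason.
* extremely concentrated responses push the MLE of `c` beyond ~1e3,
  where likelihood-curvature intermediates underflow; such fits come
  back flagged rather than returning garbage. During optimization,
  parameter regions where fitted quantiles leave (0, 1) numerically, or
  `|log c| > 35`, receive a large finite penalty so line searches back
  off smoothly.

## Diagnostics

Quantile residuals `r_i = Phi^{-1}(F(y_i; c_hat, q_hat_i))` are standard
normal under a correctly specified model; fitted cdf values that
underflow are clipped with a warning. The Anderson–Darling check is the
composite normality test (mean and variance estimated) — the weaker,
safer null, so its p-values are comparable across implementations only
at the decision level. The RESET-like test augments the design with
`q_hat^2` and `q_hat^3`, refits all parameters freely, and refers the
likelihood-ratio statistic to chi-square with 2 df; the restricted fit
is exactly the original fit. It is undefined for intercept-only models
(the testing columns are collinear with the intercept). The generalized
pseudo-R² is `1 - exp(-2/n (l_full - l_null))` with the intercept-only
fit as null. AIC `= 2(p - l)` and BIC `= p log n - 2l` with
`p = k + 1`. LOOCV refits without each row, predicts the held-out
response by the fitted location (the `tau`-th quantile; the mean for the
beta family), and averages the squared errors; refits warm-start at the
full-data optimum, retry cold on failure, and exclude the fold with a
warning if both fail (warm and cold starts agree to 1e-6 on small data
by test). The generalized Cook distance uses the full-fit observed
information as the metric, exactly as its usual definition prints it
(some literature scales by the inverse instead); the influence threshold
is 4/n. No multiple-testing correction is applied anywhere.

## Monte Carlo engine

A master seed spawns one `SeedSequence` stream per replication, so every
study is bit-reproducible and chunking-independent. The distribution
study covers six `(c, q)` scenarios — (1.5, 0.3), (0.9, 0.7), (1.1, 0.4),
(2.0, 0.4), (1.7, 0.6), (3.5, 0.5) — over n in {25, 75, 150, 300},
summarizing percentage relative bias and RMSE per parameter together
with a Monte Carlo standard error for each RMSE. The regression study
uses `logit(q_i) = beta1 + beta2 x_i2` with a standard-normal covariate
redrawn each replication (the stricter reading; a flag fixes it instead)
across six coefficient scenarios. The comparison study generates n = 100
observations per replication from each family in turn (location
coefficients 1.3 and 1.4; second parameter 2.0 for every family), fits
the true family and the UBXII regression (all four candidates under
UBXII generation), and records in-sample MSE of the location predictions
plus the AIC/BIC winner. A replication whose fit fails is dropped and
counted; observed failure rates are zero at the default scenarios.

Replication counts used by the shipped checks are a compromise between
Monte Carlo error and turnaround: 10,000 for the headline distribution
RMSE, 1,000 for the comparison study in `scripts/acceptance.py`; 2,000 /
1,000 / 500 and smaller consistency sweeps in the test suite, always
with tolerance bands derived from the run's own Monte Carlo standard
errors (or binomial errors for selection rates).

## Synthetic example data

The packaged table is generated by `synthesize_fixture`: n = 77;
vacancies covariate zero with probability 0.55, otherwise a rounded
exponential of mean 32 capped at 120 (matching the reported
right-skewed, zero-heavy structure of the real covariate); accessibility
and night-shift dummies with rates 0.60 and 0.25; responses drawn by
inversion from the UBXII median regression at the published coefficient
estimates (-0.0509, 0.0082, 0.5389, 0.8310; c = 2.378). It reproduces
the *structure* of the application data — sample size, covariate types,
response range — and the generating coefficients are recoverable from it
within sampling error, but it is not the original survey data: numerical
results computed from it (fits, information criteria, descriptive
statistics) are properties of the synthetic draw, not of the study.

## Known limitations

* Expected (Fisher) information is not computed in closed form; the
  observed information at the MLE stands in for it, as is standard.
* Moments of the distribution have no closed form and are not provided.
* The shape `c` is constant across observations; no time-series or
  serial-dependence structure.
* The RESET-like test requires at least one non-constant covariate.
* For responses concentrated within ~1e-3 of a point, the shape MLE
  exceeds the numerically tractable range (see above).
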