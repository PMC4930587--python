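# Methods

## Model and assumptions

Daily intake of an occasionally-consumed component is modelled in two
coupled parts. For person *i* (i = 1..m) on day *j* (j = 1..n_i), with
covariate vector x_ij:

- **Occurrence.** The consumption indicator I_ij is Bernoulli with
  logit Pr(I_ij = 1 | v_i) = x_ij'γ + v_i.
- **Amount.** Given consumption, the consumed amount A_ij > 0 is lognormal:
  log A_ij = x_ij'β + u_i + ε_ij with ε_ij ~ N(0, σ_ε²).
- **Person effects.** (u_i, v_i) are bivariate normal, mean 0, standard
  deviations (σ_u, σ_v) and correlation ρ. Conditional on (u_i, v_i) all
  responses are independent; ε is independent of the person effects.

The assumptions to be aware of: log-amounts are conditionally normal (no
heavier-tailed or Box–Cox alternatives), everyone is a potential consumer
(no structural never-consumer class), random effects enter as intercepts
only, and covariate effects are shared across days.

Variant A estimates ρ; variant B fixes ρ = 0, under which the likelihood
factorises and the two parts are fitted separately. Fitting B when ρ ≠ 0
biases amount-part inference and, more visibly, the upper tail of the
habitual intake distribution, which is why both variants are first-class.

## Marginal likelihood and quadrature

Each person's likelihood contribution integrates the Bernoulli × lognormal
product over (u_i, v_i). The additive constant is fixed as the exact density
product (the lognormal Jacobian −Σ log A_ij is included), so log-likelihood
values are comparable across parameter vectors and between variants.

The 2-D integral is evaluated by adaptive Gauss–Hermite quadrature: a damped
Newton search (the integrand is log-concave, so this always converges) finds
each person's conditional mode and curvature, and the product Hermite rule
is recentred and rescaled there. Defaults: 15 nodes per dimension, adaptive.
Non-adaptive (prior-scaled) quadrature is available for comparison. On a
500-person × 7-day cohort the log-likelihood moves by < 1e-3 between 21 and
41 nodes per dimension; the amount part's integrand is exactly Gaussian, so
its adaptive rule is exact at any node count.

Optimisation is quasi-Newton (BFGS) over the unconstrained parameterisation
(γ, β, log σ_u, log σ_v, atanh ρ, log σ_ε), which keeps Σ positive definite
by construction. Variant-B separate fits (moment-based starts) provide the
variant-A starting point with atanh ρ = 0. Convergence requires the
optimizer's gradient criterion (sup-norm 1e-5 by default); standard errors
come from the central-difference Hessian of the negative log-likelihood at
the optimum. Wald CIs are computed on the unconstrained scale and
back-transformed; the ρ p-value uses the atanh scale, where the normal
approximation is better near the boundary. Quadrature is deterministic, so
fits carry no seed; only synthetic data do.

## Habitual weekly intake

A person's habitual weekly intake for covariate pattern (x₀ weekday, x₁
weekend) weights expected daily intakes 4:3 (configurable):

T(u, v) = 4 exp(x₀'β + u + σ_ε²/2) expit(x₀'γ + v)
        + 3 exp(x₁'β + u + σ_ε²/2) expit(x₁'γ + v).

The σ_ε²/2 term is the lognormal mean correction — expected amount, not
median — implementing unbiasedness on the log scale exactly as written; no
additional transformation-bias correction is applied.

Since T is strictly increasing in u, {T ≤ c} = {u ≤ h(c, v)} with
h(c, v) = ln c − ln T(0, v). The inner u-integral of the CDF is then the
conditional-normal CDF Φ((h(c,v) − ρ(σ_u/σ_v)v) / (σ_u√(1−ρ²))) — an
analytic reduction, valid because (u, v) is bivariate normal, that removes
one numerical dimension — and the outer v-integral uses a 41-node
Gauss–Hermite rule (results move by < 1e-4 relative between 41 and 81
nodes). Quantiles: bracket from the deterministic intake T(0,0) by repeated
doubling/halving, then Brent iteration; the CDF is continuous and strictly
increasing in c, so the root exists and is unique. The round-trip defect
|CDF(quantile(p)) − p| is < 1e-6 across the grid (measured at machine
precision in practice).

Degenerate scales are handled exactly rather than by limiting quadrature:
σ_u = σ_v = 0 gives a point mass at T(0,0); σ_v = 0 a lognormal law in u;
σ_u = 0 a one-dimensional law in v inverted by bisection. The parameter type
admits σ = 0 for this purpose; the likelihood itself requires σ > 0.

Parameter uncertainty is *not* propagated into quantiles — they are plug-in
functionals of the point estimates. An optional parametric-bootstrap
wrapper (`bootstrap_quantile`) resamples the unconstrained parameter vector
from its asymptotic normal law; it is off by default.

Named constants carry the recommended weekly maxima used for exceedance
summaries: 224 g (men) and 168 g (women).

## Monte-Carlo reference method

The simulation route draws N pairs (u, v) ~ N(0, Σ) via the Cholesky factor,
maps them through T, and takes empirical quantiles using linear
interpolation of order statistics (type 7; recorded in the output so
alternates can be swapped). The convergence table contrasts the numerical
quantiles with MC quantiles at N = 1000, 5000, 10000 and 50000 per pattern —
the draw-count grid of the convergence study — using one substream per
pattern (seed + pattern index). MC error concentrates in the tails: at the
0.95 quantile the mean absolute deviation from the numerical value shrinks
roughly ninefold from N = 10³ to N = 5·10⁴ on the test parameterisation.

## Synthetic cohorts

The generator emulates a ~300-person food-diary screening cohort: 81 % of
persons contribute 4 diary days, the remainder 2–7, days 6–7 of each 7-day
block are weekend days, and person-level covariates (e.g. sex ~
Bernoulli(0.58), age ~ uniform on [40, 65]) are drawn per person. The
canonical test parameterisation `fixture_params()` is an alcohol-like
configuration: weekend consumption odds ratio 3.8, weekend amount ratio
1.40, weekday amount scale exp(3.0) = 20 g, σ_u = 0.8, σ_v = 1.2, ρ = 0.5,
σ_ε = 0.9 — chosen once to sit inside the plausible ranges for such data
(weekend OR ≈ 3.6–4, amount ratio ≈ 1.3–1.5, ρ ≈ 0.3–0.55).

All randomness flows from one integer seed through a counter-based
substream per person ((seed, person-index) seeding), so growing the cohort
or regenerating a subset leaves earlier persons' records bit-identical.

What the generator does *not* emulate: under- or mis-reporting (no
plausibility screening is built in; the reader accepts an external
person-id exclusion list instead), instrument differences between diaries
and recalls, seasonality, or amount distributions heavier-tailed than the
lognormal. Passing tests therefore demonstrate correctness of the
estimation and integration machinery under the model, not robustness to
model misspecification in real diaries.

## Numerical and design choices

- Likelihood evaluation is vectorised across persons and quadrature nodes
  (segment sums over person blocks); a 500 × 7 variant-A fit takes seconds.
- Frequency-bin summaries use closed upper bounds ((0, .25], (.25, .5],
  (.5, .75], > .75) with ratio 0 its own category; bin assignment is
  exhaustive and order-invariant.
- The consumption indicator is always derived from the amount column, never
  read, so indicator/amount inconsistencies cannot enter through I/O.
- Input format: delimited text with a header (comma by default), one row per
  person-day; a schema mapping renames columns. Parameters serialise to a
  JSON file of named coefficients plus (σ_u, σ_v, ρ, σ_ε) consumed by the
  distribution and MC modules.
- Problem sizes used by the test suite and the acceptance script — 500 × 7
  for recovery, 20 seeds × {10³, 5·10⁴} draws plus one 10⁶-draw sample for
  MC comparisons, 2001² dense-grid oracles on 3-person fixtures — were
  chosen so each check is decisive yet the whole suite runs in a couple of
  minutes on one core.

## Known limitations

- No Box–Cox or generalized-gamma amount models, no bridge-distribution
  random effects, no never-consumer mass at zero, no random slopes, no
  survey weights, no multivariate (several-component) intake.
- Wald inference relies on asymptotic normality on the transformed scale;
  with few persons or ρ near ±1 profile-likelihood intervals would be more
  trustworthy.
- Quantile uncertainty is available only through the optional bootstrap
  wrapper; the default output is a plug-in estimate.
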