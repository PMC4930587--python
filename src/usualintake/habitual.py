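"""Habitual weekly intake distributions by numerical integration.

Given fitted two-part model parameters, a person's *habitual* (long-term
expected) weekly intake is the weighted average of expected daily intakes
over a week of 4 weekday and 3 weekend days,

    T_i = 4 exp(x0'b + u + s_e^2/2) expit(x0'g + v)
        + 3 exp(x1'b + u + s_e^2/2) expit(x1'g + v),

a deterministic function of the bivariate-normal person effects (u, v). The
exp(s_e^2/2) factor is the lognormal mean correction: the expected amount on
a consumption day, not the median.

For a covariate pattern (x0, x1) the distribution of T_i over the population
is characterised without simulation. Because T_i is strictly increasing in u,
the event {T_i <= c} is {u <= h(c, v)} where h inverts the weekly intake in
u at a given v; the CDF is then a bivariate-normal probability. The inner
u-integral is the conditional-normal CDF in closed form, leaving a single
Gauss-Hermite integral over v, and quantiles are found by safeguarded root
finding on the resulting monotone CDF. The solution exists and is unique
because the CDF is continuous and strictly increasing in c.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .twopart import FitResult, ModelParams, QuadratureSpec

__all__ = [
    "MEN_WEEKLY_LIMIT_G",
    "WOMEN_WEEKLY_LIMIT_G",
    "CovariatePattern",
    "IntakeDistribution",
    "expected_weekly_intake",
    "h_function",
    "intake_cdf",
    "intake_quantile",
    "exceedance_fraction",
    "quantile_table",
    "bootstrap_quantile",
]

#: UK maximum recommended weekly alcohol intake, grams (7 x 32 g for men).
MEN_WEEKLY_LIMIT_G = 224.0
#: UK maximum recommended weekly alcohol intake, grams (7 x 24 g for women).
WOMEN_WEEKLY_LIMIT_G = 168.0

#: Default quantile grid for intake tables.
DEFAULT_QUANTILE_GRID = (0.1, 0.25, 0.5, 0.75, 0.9, 0.95)

_SIGMA_ZERO = 0.0  # exact zero triggers the degenerate closed forms


@dataclasses.dataclass(frozen=True)
class CovariatePattern:
    """A sub-population: one covariate vector per day type plus week weights.

    ``x_weekday``/``x_weekend`` map covariate names (shared with the fitted
    model) to values; ``intercept`` is implied. The default weights (4, 3)
    compose a week from 4 working-week days and 3 weekend days.
    """

    x_weekday: Mapping[str, float]
    x_weekend: Mapping[str, float]
    weights: tuple[float, float] = (4.0, 3.0)
    label: str = ""

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ValueError("week weights must be non-negative")
        object.__setattr__(self, "x_weekday", dict(self.x_weekday))
        object.__setattr__(self, "x_weekend", dict(self.x_weekend))

    @classmethod
    def from_covariates(
        cls,
        covariates: Mapping[str, float],
        weekend_name: str = "weekend",
        weights: tuple[float, float] = (4.0, 3.0),
        label: str = "",
    ) -> "CovariatePattern":
        """Build the (weekday, weekend) pair from shared covariates by
        toggling the weekend indicator."""
        x0 = dict(covariates)
        x1 = dict(covariates)
        x0[weekend_name] = 0.0
        x1[weekend_name] = 1.0
        return cls(x0, x1, weights, label)

    def _vector(self, x: Mapping[str, float], names: Sequence[str]) -> np.ndarray:
        out = np.empty(len(names))
        for i, name in enumerate(names):
            if name == "intercept":
                out[i] = 1.0
            elif name in x:
                out[i] = float(x[name])
            else:
                raise KeyError(f"pattern does not define covariate {name!r}")
        return out

    def linear_predictors(self, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
        """(eta_gamma, eta_beta): each length 2, ordered (weekday, weekend)."""
        eg = np.array(
            [
                self._vector(self.x_weekday, params.gamma_names) @ params.gamma,
                self._vector(self.x_weekend, params.gamma_names) @ params.gamma,
            ]
        )
        eb = np.array(
            [
                self._vector(self.x_weekday, params.beta_names) @ params.beta,
                self._vector(self.x_weekend, params.beta_names) @ params.beta,
            ]
        )
        return eg, eb


def _weekly_at_u0(
    params: ModelParams, pattern: CovariatePattern, v: np.ndarray | float
) -> np.ndarray | float:
    """Weekly intake at u = 0 as a function of v (the divisor inside h)."""
    eg, eb = pattern.linear_predictors(params)
    w = np.asarray(pattern.weights, dtype=float)
    amt = w * np.exp(eb + 0.5 * params.sigma_eps**2)  # length 2
    v_arr = np.asarray(v, dtype=float)
    probs = special.expit(eg + v_arr[..., None])
    return (amt * probs).sum(axis=-1)


def expected_weekly_intake(
    params: ModelParams,
    pattern: CovariatePattern,
    u: np.ndarray | float,
    v: np.ndarray | float,
) -> np.ndarray | float:
    """Habitual weekly intake T(u, v) in grams/week for given person effects.

    Strictly positive, and strictly increasing in both u and v (adding d to u
    multiplies the result by exp(d) exactly).
    """
    params.validate()
    return np.exp(np.asarray(u, dtype=float)) * _weekly_at_u0(params, pattern, v)


def h_function(
    c: float,
    v: np.ndarray | float,
    params: ModelParams,
    pattern: CovariatePattern,
) -> np.ndarray | float:
    """Threshold on u below which weekly intake stays under c, at a given v.

    h(c, v) = ln c - ln T(0, v); by construction T(h(c, v), v) = c. Strictly
    increasing in c and decreasing in v, with h(2c, v) - h(c, v) = ln 2.
    """
    if not c > 0:
        raise ValueError("c must be > 0")
    return np.log(c) - np.log(_weekly_at_u0(params, pattern, v))


@dataclasses.dataclass(frozen=True)
class IntakeDistribution:
    """Queryable habitual weekly intake law for one covariate pattern."""

    params: ModelParams
    pattern: CovariatePattern
    quad: QuadratureSpec = QuadratureSpec(n_nodes=41, adaptive=False)

    def cdf(self, c: float) -> float:
        return intake_cdf(c, self)

    def quantile(self, p: float) -> float:
        return intake_quantile(p, self)

    def exceedance(self, limit: float) -> float:
        return exceedance_fraction(limit, self)


def _cdf_sigma_u_zero(c: float, dist: IntakeDistribution) -> float:
    """With u degenerate at 0, T depends on v alone and is increasing in v."""
    params, pattern = dist.params, dist.pattern
    eg, eb = pattern.linear_predictors(params)
    w = np.asarray(pattern.weights, dtype=float)
    amt = w * np.exp(eb + 0.5 * params.sigma_eps**2)
    t_max = float(amt.sum())  # v -> +inf limit (probabilities -> 1)
    if c <= 0:
        return 0.0
    if c >= t_max:
        return 1.0
    if params.sigma_v == _SIGMA_ZERO:
        return 1.0 if c >= _weekly_at_u0(params, pattern, 0.0) else 0.0
    f = lambda v: _weekly_at_u0(params, pattern, v) - c
    lo, hi = -1.0, 1.0
    while f(lo) > 0:
        lo *= 2.0
    while f(hi) < 0:
        hi *= 2.0
    v_star = optimize.brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    return float(stats.norm.cdf(v_star / params.sigma_v))


def intake_cdf(c: float, dist: IntakeDistribution) -> float:
    """P(habitual weekly intake <= c) for the pattern's sub-population.

    The probability mass of {(u, v): u <= h(c, v)} under the bivariate-normal
    person effects. The inner u-integral is evaluated in closed form as the
    conditional-normal CDF Phi((h(c, v) - rho (s_u / s_v) v) / (s_u
    sqrt(1 - rho^2))); the outer v-integral by Gauss-Hermite quadrature.
    Degenerate scales (sigma = 0) fall back to exact one-dimensional or
    point-mass forms.
    """
    params = dist.params
    params.validate()
    if c <= 0:
        return 0.0
    su, sv, rho = params.sigma_u, params.sigma_v, params.rho
    if su == _SIGMA_ZERO:
        return _cdf_sigma_u_zero(c, dist)
    if sv == _SIGMA_ZERO:
        h0 = h_function(c, 0.0, params, dist.pattern)
        return float(stats.norm.cdf(h0 / su))
    z, w = special.roots_hermite(dist.quad.n_nodes)
    v_nodes = math.sqrt(2.0) * sv * z
    h = h_function(c, v_nodes, params, dist.pattern)
    mu_cond = rho * (su / sv) * v_nodes
    sd_cond = su * math.sqrt(1.0 - rho * rho)
    inner = stats.norm.cdf((h - mu_cond) / sd_cond)
    val = float((w * inner).sum() / math.sqrt(math.pi))
    return min(max(val, 0.0), 1.0)


def intake_quantile(p: float, dist: IntakeDistribution) -> float:
    """Quantile c_p of habitual weekly intake: the c with CDF(c) = p.

    Unique by strict monotonicity of the CDF. Bracketing starts from the
    deterministic intake at u = v = 0 and expands geometrically; a Brent
    root finder then solves CDF(c) - p = 0 to within 1e-6 in probability.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    params = dist.params
    c0 = float(expected_weekly_intake(params, dist.pattern, 0.0, 0.0))
    if params.sigma_u == _SIGMA_ZERO and params.sigma_v == _SIGMA_ZERO:
        return c0
    lo = hi = c0
    for _ in range(200):
        if intake_cdf(lo, dist) <= p:
            break
        lo /= 2.0
    for _ in range(200):
        if intake_cdf(hi, dist) >= p:
            break
        hi *= 2.0
    if lo == hi:
        return lo
    root = optimize.brentq(
        lambda c: intake_cdf(c, dist) - p, lo, hi, xtol=1e-12, rtol=8.9e-16
    )
    return float(root)


def exceedance_fraction(limit: float, dist: IntakeDistribution) -> float:
    """Fraction of the sub-population whose habitual weekly intake exceeds
    ``limit`` grams/week (1 - CDF; habitual intake is strictly positive, so a
    limit of 0 yields 1)."""
    if limit < 0:
        raise ValueError("limit must be >= 0")
    return 1.0 - intake_cdf(limit, dist)


def quantile_table(
    params: ModelParams,
    patterns: Sequence[CovariatePattern],
    probs: Sequence[float] = DEFAULT_QUANTILE_GRID,
    quad: QuadratureSpec = QuadratureSpec(n_nodes=41, adaptive=False),
) -> pd.DataFrame:
    """Quantiles of habitual weekly intake: one row per covariate pattern,
    one column per probability."""
    rows = []
    for i, pattern in enumerate(patterns):
        dist = IntakeDistribution(params, pattern, quad)
        row = {"pattern": pattern.label or f"pattern_{i}"}
        for p in probs:
            row[f"q{p:g}"] = intake_quantile(p, dist)
        rows.append(row)
    return pd.DataFrame(rows)


def bootstrap_quantile(
    fit: FitResult,
    pattern: CovariatePattern,
    p: float,
    n_boot: int = 200,
    seed: int = 0,
    quad: QuadratureSpec = QuadratureSpec(n_nodes=41, adaptive=False),
) -> dict:
    """Optional parametric bootstrap for quantile uncertainty.

    Point estimates are the default everywhere (parameter uncertainty is not
    propagated into quantiles); this wrapper resamples the unconstrained
    parameter vector from its asymptotic normal law and recomputes the
    quantile, returning the point estimate and a percentile 95% interval.
    """
    rng = np.random.default_rng(seed)
    params = fit.params
    est = intake_quantile(p, IntakeDistribution(params, pattern, quad))
    names = fit.param_names
    center = _pack_unconstrained(fit)
    draws = rng.multivariate_normal(center, fit.vcov, size=n_boot)
    vals = []
    for x in draws:
        try:
            vals.append(
                intake_quantile(
                    p, IntakeDistribution(_unpack_unconstrained(x, names, params), pattern, quad)
                )
            )
        except (ValueError, OverflowError):
            continue
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return {"estimate": est, "ci_low": float(lo), "ci_high": float(hi), "n_used": len(vals)}


def _pack_unconstrained(fit: FitResult) -> np.ndarray:
    p = fit.params
    vals = []
    for name in fit.param_names:
        if name.startswith("gamma["):
            vals.append(p.gamma[p.gamma_names.index(name[6:-1])])
        elif name.startswith("beta["):
            vals.append(p.beta[p.beta_names.index(name[5:-1])])
        elif name == "log_sigma_u":
            vals.append(math.log(p.sigma_u))
        elif name == "log_sigma_v":
            vals.append(math.log(p.sigma_v))
        elif name == "atanh_rho":
            vals.append(math.atanh(p.rho))
        elif name == "log_sigma_eps":
            vals.append(math.log(p.sigma_eps))
    return np.array(vals)


def _unpack_unconstrained(
    x: np.ndarray, names: Sequence[str], template: ModelParams
) -> ModelParams:
    gamma = np.array(template.gamma)
    beta = np.array(template.beta)
    su, sv, rho, se = template.sigma_u, template.sigma_v, 0.0, template.sigma_eps
    for val, name in zip(x, names):
        if name.startswith("gamma["):
            gamma[template.gamma_names.index(name[6:-1])] = val
        elif name.startswith("beta["):
            beta[template.beta_names.index(name[5:-1])] = val
        elif name == "log_sigma_u":
            su = math.exp(val)
        elif name == "log_sigma_v":
            sv = math.exp(val)
        elif name == "atanh_rho":
            rho = math.tanh(val)
        elif name == "log_sigma_eps":
            se = math.exp(val)
    return ModelParams(
        gamma, beta, su, sv, rho, se, template.gamma_names, template.beta_names
    )
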