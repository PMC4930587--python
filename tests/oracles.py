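"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's quadrature code paths: dense-grid
trapezoidal integration of the marginal-likelihood and CDF integrands, and
plain Monte-Carlo draws of the person effects.
"""

import numpy as np
from scipy import special, stats

from usualintake import expected_weekly_intake, h_function


def brute_force_loglik(params, dataset, n_grid=1201, half_width=8.0):
    """Dense 2-D trapezoidal integration of each person's likelihood integrand."""
    df = dataset.table.sort_values(["person_id", "day_index"]).reset_index(drop=True)
    su, sv, se = params.sigma_u, params.sigma_v, params.sigma_eps
    us = np.linspace(-half_width * su, half_width * su, n_grid)
    vs = np.linspace(-half_width * sv, half_width * sv, n_grid)
    U, V = np.meshgrid(us, vs, indexing="ij")
    prior = stats.multivariate_normal(mean=[0, 0], cov=params.sigma_mat).pdf(
        np.dstack([U, V])
    )
    gname = list(params.gamma_names)
    bname = list(params.beta_names)
    total = 0.0
    for _, g in df.groupby("person_id"):
        integrand = np.array(prior)
        for _, row in g.iterrows():
            xg = np.array([1.0 if n == "intercept" else row[n] for n in gname])
            p = special.expit(xg @ params.gamma + V)
            integrand *= p if row["indicator"] == 1 else (1.0 - p)
            if row["indicator"] == 1:
                xb = np.array([1.0 if n == "intercept" else row[n] for n in bname])
                integrand *= stats.lognorm.pdf(
                    row["amount"], s=se, scale=np.exp(xb @ params.beta + U)
                )
        val = np.trapezoid(np.trapezoid(integrand, vs, axis=1), us)
        total += np.log(val)
    return total


def brute_force_cdf(c, params, pattern, n_grid=2001, half_width=8.0):
    """Dense 2-D trapezoidal integration of the CDF integrand over (u, v)."""
    su, sv = params.sigma_u, params.sigma_v
    us = np.linspace(-half_width * su, half_width * su, n_grid)
    vs = np.linspace(-half_width * sv, half_width * sv, n_grid)
    U, V = np.meshgrid(us, vs, indexing="ij")
    pdf = stats.multivariate_normal(mean=[0, 0], cov=params.sigma_mat).pdf(
        np.dstack([U, V])
    )
    h = np.asarray(h_function(c, vs, params, pattern))
    masked = np.where(U <= h[None, :], pdf, 0.0)
    return float(np.trapezoid(np.trapezoid(masked, vs, axis=1), us))


def mc_effects(params, n, seed):
    """Plain Monte-Carlo draws of (u, v) ~ N(0, Sigma)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    u = params.sigma_u * z[:, 0]
    v = params.rho * params.sigma_v * z[:, 0] + params.sigma_v * np.sqrt(
        1.0 - params.rho**2
    ) * z[:, 1]
    return u, v


def mc_weekly_intakes(params, pattern, n, seed):
    u, v = mc_effects(params, n, seed)
    return np.asarray(expected_weekly_intake(params, pattern, u, v))
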