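"""Correlated two-part mixed-effects model for semicontinuous daily intake.

The model couples a logistic regression for the daily consumption indicator
with a lognormal regression for the amount consumed on consumption days,

    logit Pr(I_ij = 1 | v_i) = x_ij' gamma + v_i
    log A_ij | I_ij = 1, u_i  ~  Normal(x_ij' beta + u_i, sigma_eps^2)

where the person-specific intercepts (u_i, v_i) are bivariate normal with
standard deviations (sigma_u, sigma_v) and correlation rho. rho links
propensity to consume with amount consumed; setting rho = 0 (variant B)
factorises the likelihood so the two parts can be fitted separately, while
variant A estimates rho jointly.

The marginal likelihood integrates (u_i, v_i) out of each person's
contribution; the integral has no closed form and is approximated by
two-dimensional (adaptive) Gauss-Hermite quadrature, recentring and rescaling
the nodes at each person's conditional posterior mode. The likelihood
constant is the exact Bernoulli x lognormal density product, so values are
comparable across parameter vectors and across variants.
"""

from __future__ import annotations

import dataclasses
import json
import math
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .data_model import IntakeDataset, ValidationError

__all__ = [
    "ModelParams",
    "QuadratureSpec",
    "FitResult",
    "design_matrix",
    "log_marginal_likelihood",
    "fit_twopart",
    "effect_table",
]

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Parameterisation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Complete two-part model parameterisation theta.

    ``gamma``/``beta`` are the probability- and amount-part coefficients, in
    the order of ``gamma_names``/``beta_names`` (the name ``intercept`` is
    understood by the design-matrix builder). ``sigma_u``/``sigma_v`` are the
    random-intercept standard deviations of the amount and probability parts,
    ``rho`` their correlation and ``sigma_eps`` the residual (within-person,
    day-to-day) standard deviation of log-amount.
    """

    gamma: np.ndarray
    beta: np.ndarray
    sigma_u: float
    sigma_v: float
    rho: float
    sigma_eps: float
    gamma_names: tuple[str, ...] = ()
    beta_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        b = np.atleast_1d(np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "beta", b)
        gn = tuple(self.gamma_names) or tuple(f"x{i}" for i in range(g.size))
        bn = tuple(self.beta_names) or tuple(f"x{i}" for i in range(b.size))
        if len(gn) != g.size or len(bn) != b.size:
            raise ValueError("coefficient names do not match coefficient lengths")
        object.__setattr__(self, "gamma_names", gn)
        object.__setattr__(self, "beta_names", bn)
        self.validate()

    def validate(self) -> None:
        # sigma = 0 is admitted at the type level so that degenerate
        # (point-mass) intake distributions can be expressed; the marginal
        # likelihood itself requires strictly positive scales.
        if not (self.sigma_u >= 0 and self.sigma_v >= 0 and self.sigma_eps >= 0):
            raise ValueError("sigma_u, sigma_v and sigma_eps must be >= 0")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if not (np.isfinite(self.gamma).all() and np.isfinite(self.beta).all()):
            raise ValueError("coefficients must be finite")

    def require_positive_scales(self) -> None:
        if not (self.sigma_u > 0 and self.sigma_v > 0 and self.sigma_eps > 0):
            raise ValueError("sigma_u, sigma_v and sigma_eps must be > 0")

    @property
    def sigma_mat(self) -> np.ndarray:
        """Random-effect covariance [[su^2, rho su sv], [rho su sv, sv^2]]."""
        c = self.rho * self.sigma_u * self.sigma_v
        return np.array(
            [[self.sigma_u**2, c], [c, self.sigma_v**2]], dtype=float
        )

    def to_dict(self) -> dict:
        return {
            "gamma": dict(zip(self.gamma_names, self.gamma.tolist())),
            "beta": dict(zip(self.beta_names, self.beta.tolist())),
            "sigma_u": self.sigma_u,
            "sigma_v": self.sigma_v,
            "rho": self.rho,
            "sigma_eps": self.sigma_eps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            gamma=np.array(list(d["gamma"].values()), dtype=float),
            beta=np.array(list(d["beta"].values()), dtype=float),
            sigma_u=float(d["sigma_u"]),
            sigma_v=float(d["sigma_v"]),
            rho=float(d["rho"]),
            sigma_eps=float(d["sigma_eps"]),
            gamma_names=tuple(d["gamma"].keys()),
            beta_names=tuple(d["beta"].keys()),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclasses.dataclass(frozen=True)
class QuadratureSpec:
    """Gauss-Hermite rule: nodes per dimension and whether to adapt.

    Adaptive quadrature recentres/rescales the nodes at each person's
    conditional posterior mode (mode and curvature of the integrand), which
    keeps few nodes accurate even with many records per person. Odd node
    counts place a node at the mode.
    """

    n_nodes: int = 15
    adaptive: bool = True

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of the two-part model."""

    params: ModelParams
    vcov: np.ndarray            # over the unconstrained parameterisation
    param_names: tuple[str, ...]
    loglik: float
    converged: bool
    n_iter: int
    variant: str                # "A" (rho estimated) or "B" (rho = 0)
    message: str = ""

    def se(self, name: str) -> float:
        i = self.param_names.index(name)
        return float(np.sqrt(self.vcov[i, i]))

    def report(self) -> str:
        """Plain-text key-value fit report."""
        lines = [
            f"variant: {self.variant}",
            f"converged: {self.converged}",
            f"n_iter: {self.n_iter}",
            f"loglik: {self.loglik:.6f}",
        ]
        p = self.params
        for name, val in zip(p.gamma_names, p.gamma):
            lines.append(f"gamma[{name}]: {val:.6f}")
        for name, val in zip(p.beta_names, p.beta):
            lines.append(f"beta[{name}]: {val:.6f}")
        lines.append(f"sigma_u: {p.sigma_u:.6f}")
        lines.append(f"sigma_v: {p.sigma_v:.6f}")
        if self.variant == "A":
            lines.append(f"rho: {p.rho:.6f}")
        lines.append(f"sigma_eps: {p.sigma_eps:.6f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Design matrices and per-person data layout
# ---------------------------------------------------------------------------

def design_matrix(table: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    """Column-stack covariates by name; the name ``intercept`` maps to ones."""
    cols = []
    for name in names:
        if name == "intercept":
            cols.append(np.ones(len(table)))
        elif name in table.columns:
            cols.append(pd.to_numeric(table[name]).to_numpy(dtype=float))
        else:
            raise KeyError(f"covariate {name!r} not present in the data")
    return np.column_stack(cols)


class _PersonData:
    """Dataset rearranged for vectorised per-person likelihood evaluation."""

    def __init__(
        self,
        dataset: IntakeDataset,
        gamma_names: Sequence[str],
        beta_names: Sequence[str],
    ):
        df = dataset.table.sort_values(
            ["person_id", "day_index"], kind="stable"
        ).reset_index(drop=True)
        codes, _ = pd.factorize(df["person_id"], sort=True)
        self.m = int(codes.max()) + 1
        self.codes = codes
        # reduceat offsets: first row of each person (codes are sorted)
        self.starts = np.searchsorted(codes, np.arange(self.m))
        self.I = df["indicator"].to_numpy(dtype=float)
        self.Xg = design_matrix(df, gamma_names)
        cons = df["indicator"].to_numpy(dtype=bool)
        amounts = df.loc[cons, "amount"].to_numpy(dtype=float)
        if np.any((df["indicator"] == 1) & (df["amount"] <= 0)):
            raise ValidationError("indicator=1 requires amount > 0")
        self.Y = np.log(amounts)
        self.Xb = design_matrix(df.loc[cons], beta_names)
        self.cons_codes = codes[cons]
        self.k = np.bincount(self.cons_codes, minlength=self.m).astype(float)
        # Jacobian of log A -> A: turns the normal density of log-amount
        # into the exact lognormal density of the recorded amount.
        self.log_jacobian = -float(self.Y.sum())

    # sufficient statistics of the amount part at given beta
    def amount_stats(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        r = self.Y - self.Xb @ beta
        s1 = np.bincount(self.cons_codes, weights=r, minlength=self.m)
        s2 = np.bincount(self.cons_codes, weights=r * r, minlength=self.m)
        return s1, s2

    def bern_sums(self, eta: np.ndarray) -> np.ndarray:
        """Per-person sum of I*eta - log(1 + e^eta); eta is (n_days,) or (n_days, q)."""
        term = self.I.reshape(-1, *([1] * (eta.ndim - 1))) * eta - np.logaddexp(0.0, eta)
        return np.add.reduceat(term, self.starts, axis=0)


# ---------------------------------------------------------------------------
# Marginal log-likelihood by 2-D adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def _find_modes(
    pd_: _PersonData,
    a: np.ndarray,
    s1: np.ndarray,
    s2: np.ndarray,
    sigma_u: float,
    sigma_v: float,
    rho: float,
    sigma_eps: float,
    max_iter: int = 60,
    tol: float = 1e-11,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Damped Newton search for the per-person mode of the log-integrand.

    Returns (u*, v*, A, B, C) with [[A, B], [B, C]] = -Hessian at the mode.
    The integrand is log-concave (logistic + Gaussian + Gaussian prior), so
    Newton with step halving converges for every person.
    """
    m = pd_.m
    k = pd_.k
    omr2 = 1.0 - rho * rho
    iuu = 1.0 / (sigma_u * sigma_u * omr2)
    ivv = 1.0 / (sigma_v * sigma_v * omr2)
    iuv = rho / (sigma_u * sigma_v * omr2)
    inv_se2 = 1.0 / (sigma_eps * sigma_eps)

    def g_val(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        bern = pd_.bern_sums(a + v[pd_.codes])
        amt = -0.5 * inv_se2 * (s2 - 2.0 * s1 * u + k * u * u)
        prior = -0.5 * (iuu * u * u - 2.0 * iuv * u * v + ivv * v * v)
        return bern + amt + prior

    u = np.zeros(m)
    v = np.zeros(m)
    g0 = g_val(u, v)
    for _ in range(max_iter):
        p = special.expit(a + v[pd_.codes])
        b1 = np.bincount(pd_.codes, weights=pd_.I - p, minlength=m)
        b2 = np.bincount(pd_.codes, weights=p * (1.0 - p), minlength=m)
        gu = inv_se2 * (s1 - k * u) - (iuu * u - iuv * v)
        gv = b1 - (ivv * v - iuv * u)
        A = k * inv_se2 + iuu
        B = -iuv
        C = b2 + ivv
        det = A * C - B * B
        du = (C * gu - B * gv) / det
        dv = (A * gv - B * gu) / det
        decrement = gu * du + gv * dv
        if np.max(decrement) < tol:
            break
        # step halving where the objective would decrease
        step = np.ones(m)
        for _ in range(30):
            g1 = g_val(u + step * du, v + step * dv)
            bad = g1 < g0 - 1e-12
            if not bad.any():
                break
            step[bad] *= 0.5
        u = u + step * du
        v = v + step * dv
        g0 = g_val(u, v)
    # -Hessian at the mode
    p = special.expit(a + v[pd_.codes])
    b2 = np.bincount(pd_.codes, weights=p * (1.0 - p), minlength=m)
    A = k * inv_se2 + iuu
    B = -iuv * np.ones(m)
    C = b2 + ivv
    return u, v, A, B, C


def _loglik_core(
    params: ModelParams, pd_: _PersonData, quad: QuadratureSpec
) -> float:
    su, sv, rho, se = params.sigma_u, params.sigma_v, params.rho, params.sigma_eps
    m = pd_.m
    a = pd_.Xg @ params.gamma
    s1, s2 = pd_.amount_stats(params.beta)
    k = pd_.k

    if quad.adaptive:
        u0, v0, A, B, C = _find_modes(pd_, a, s1, s2, su, sv, rho, se)
        det = A * C - B * B
        # Cholesky of the 2x2 inverse curvature [[C,-B],[-B,A]]/det
        c11 = np.sqrt(C / det)
        c21 = -B / det / c11
        c22 = np.sqrt(A / det - c21 * c21)
    else:
        u0 = np.zeros(m)
        v0 = np.zeros(m)
        c11 = np.full(m, su)
        c21 = np.full(m, rho * sv)
        c22 = np.full(m, sv * math.sqrt(1.0 - rho * rho))

    z, w = special.roots_hermite(quad.n_nodes)
    z1 = np.repeat(z, quad.n_nodes)
    z2 = np.tile(z, quad.n_nodes)
    logw = np.repeat(np.log(w), quad.n_nodes) + np.tile(np.log(w), quad.n_nodes)
    zz = z1 * z1 + z2 * z2

    sqrt2 = math.sqrt(2.0)
    tu = u0[:, None] + sqrt2 * c11[:, None] * z1          # (m, n^2)
    tv = v0[:, None] + sqrt2 * (c21[:, None] * z1 + c22[:, None] * z2)

    # log-integrand at every node
    bern = pd_.bern_sums(a[:, None] + tv[pd_.codes, :])    # (m, n^2)
    inv_se2 = 1.0 / (se * se)
    amt = (
        -0.5 * k[:, None] * (_LOG_2PI + 2.0 * math.log(se))
        - 0.5 * inv_se2 * (s2[:, None] - 2.0 * s1[:, None] * tu + k[:, None] * tu * tu)
    )
    omr2 = 1.0 - rho * rho
    q = (
        tu * tu / (su * su) - 2.0 * rho * tu * tv / (su * sv) + tv * tv / (sv * sv)
    ) / omr2
    prior = -_LOG_2PI - math.log(su * sv) - 0.5 * math.log(omr2) - 0.5 * q

    logl_i = (
        math.log(2.0)
        + np.log(c11 * c22)
        + special.logsumexp(bern + amt + prior + zz + logw, axis=1)
    )
    return float(logl_i.sum() + pd_.log_jacobian)


def log_marginal_likelihood(
    params: ModelParams,
    dataset: IntakeDataset,
    quad: QuadratureSpec = QuadratureSpec(),
) -> float:
    """Log of the full marginal likelihood of the two-part model.

    Each person's likelihood contribution integrates the Bernoulli x
    lognormal product over the bivariate-normal random intercepts (u_i, v_i);
    the integral is approximated by (adaptive) two-dimensional Gauss-Hermite
    quadrature. The additive constant is fixed as the exact density product,
    so values are comparable across parameter vectors.
    """
    params.validate()
    params.require_positive_scales()
    pd_ = _PersonData(dataset, params.gamma_names, params.beta_names)
    return _loglik_core(params, pd_, quad)


# ---------------------------------------------------------------------------
# One-dimensional part likelihoods (variant B building blocks)
# ---------------------------------------------------------------------------

def _loglik_bern_part(
    gamma: np.ndarray, sigma_v: float, pd_: _PersonData, quad: QuadratureSpec
) -> float:
    """Logistic-normal likelihood of the probability part by 1-D adaptive GH."""
    m = pd_.m
    a = pd_.Xg @ gamma
    iv = 1.0 / (sigma_v * sigma_v)

    v = np.zeros(m)

    def g_val(vv: np.ndarray) -> np.ndarray:
        return pd_.bern_sums(a + vv[pd_.codes]) - 0.5 * iv * vv * vv

    g0 = g_val(v)
    for _ in range(60):
        p = special.expit(a + v[pd_.codes])
        gv = np.bincount(pd_.codes, weights=pd_.I - p, minlength=m) - iv * v
        h = np.bincount(pd_.codes, weights=p * (1 - p), minlength=m) + iv
        dv = gv / h
        if np.max(gv * dv) < 1e-11:
            break
        step = np.ones(m)
        for _ in range(30):
            g1 = g_val(v + step * dv)
            bad = g1 < g0 - 1e-12
            if not bad.any():
                break
            step[bad] *= 0.5
        v = v + step * dv
        g0 = g_val(v)
    p = special.expit(a + v[pd_.codes])
    h = np.bincount(pd_.codes, weights=p * (1 - p), minlength=m) + iv

    z, w = special.roots_hermite(quad.n_nodes)
    c = 1.0 / np.sqrt(h)
    tv = v[:, None] + math.sqrt(2.0) * c[:, None] * z
    bern = pd_.bern_sums(a[:, None] + tv[pd_.codes, :])
    prior = -0.5 * _LOG_2PI - math.log(sigma_v) - 0.5 * iv * tv * tv
    logl_i = (
        0.5 * math.log(2.0)
        + np.log(c)
        + special.logsumexp(bern + prior + z * z + np.log(w), axis=1)
    )
    return float(logl_i.sum())


def _loglik_amount_part(
    beta: np.ndarray,
    sigma_u: float,
    sigma_eps: float,
    pd_: _PersonData,
    quad: QuadratureSpec,
) -> float:
    """Lognormal random-intercept likelihood of the amount part by 1-D adaptive GH.

    The integrand is Gaussian in u, so the adaptive rule (recentred at the
    closed-form mode) is exact for any node count.
    """
    s1, s2 = pd_.amount_stats(beta)
    k = pd_.k
    inv_se2 = 1.0 / (sigma_eps * sigma_eps)
    iu = 1.0 / (sigma_u * sigma_u)
    h = k * inv_se2 + iu
    u0 = s1 * inv_se2 / h

    z, w = special.roots_hermite(quad.n_nodes)
    c = 1.0 / np.sqrt(h)
    tu = u0[:, None] + math.sqrt(2.0) * c[:, None] * z
    amt = (
        -0.5 * k[:, None] * (_LOG_2PI + 2.0 * math.log(sigma_eps))
        - 0.5 * inv_se2 * (s2[:, None] - 2.0 * s1[:, None] * tu + k[:, None] * tu * tu)
    )
    prior = -0.5 * _LOG_2PI - math.log(sigma_u) - 0.5 * iu * tu * tu
    logl_i = (
        0.5 * math.log(2.0)
        + np.log(c)
        + special.logsumexp(amt + prior + z * z + np.log(w), axis=1)
    )
    return float(logl_i.sum() + pd_.log_jacobian)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _numerical_hessian(fun, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    n = x.size
    H = np.empty((n, n))
    f0 = fun(x)
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = steps[i]
            ej[j] = steps[j]
            if i == j:
                fpp = fun(x + 2 * ei)
                fmm = fun(x - 2 * ei)
                H[i, i] = (fpp - 2 * f0 + fmm) / (4.0 * steps[i] ** 2)
            else:
                fpp = fun(x + ei + ej)
                fpm = fun(x + ei - ej)
                fmp = fun(x - ei + ej)
                fmm = fun(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (
                    4.0 * steps[i] * steps[j]
                )
    return H


def _safe_vcov(neg_hess: np.ndarray) -> np.ndarray:
    """Invert the observed information; fall back to pseudo-inverse."""
    try:
        vcov = np.linalg.inv(neg_hess)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(neg_hess)
    # symmetrise against finite-difference noise
    return 0.5 * (vcov + vcov.T)


def _start_values(pd_: _PersonData, p_gamma: int, p_beta: int):
    """Moment-based starting values for the separate part fits."""
    mean_i = np.clip(pd_.I.mean(), 0.01, 0.99)
    gamma0 = np.zeros(p_gamma)
    gamma0[0] = special.logit(mean_i)  # first column is typically intercept
    beta0, *_ = np.linalg.lstsq(pd_.Xb, pd_.Y, rcond=None)
    resid = pd_.Y - pd_.Xb @ beta0
    within = np.var(resid) if resid.size else 1.0
    # split total residual variance between person and day level
    sig_u0 = math.sqrt(max(within * 0.5, 1e-2))
    sig_e0 = math.sqrt(max(within * 0.5, 1e-2))
    return gamma0, beta0, sig_u0, 1.0, sig_e0


def fit_twopart(
    dataset: IntakeDataset,
    variant: str = "A",
    quad: QuadratureSpec = QuadratureSpec(),
    prob_part: Sequence[str] = ("intercept", "weekend"),
    amount_part: Sequence[str] = ("intercept", "weekend"),
    opts: dict | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the two-part model.

    Variant A estimates the cross-part correlation rho jointly; variant B
    fixes rho = 0 and fits the logistic and lognormal parts separately (the
    likelihood factorises exactly in that case). Optimisation runs on the
    unconstrained scale (gamma, beta, log sigma_u, log sigma_v, atanh rho,
    log sigma_eps), which keeps the random-effect covariance positive
    definite by construction; variant B results seed the variant A search.
    """
    if variant not in ("A", "B"):
        raise ValueError("variant must be 'A' or 'B'")
    opts = dict(opts or {})
    gtol = opts.pop("gtol", 1e-5)
    maxiter = opts.pop("maxiter", 500)

    pd_ = _PersonData(dataset, prob_part, amount_part)
    if pd_.k.sum() == 0:
        raise ValidationError("no consumption days: the amount part is unidentifiable")
    if pd_.k.sum() == pd_.I.size:
        raise ValidationError(
            "every day is a consumption day: the probability part is unidentifiable"
        )
    p_g, p_b = len(prob_part), len(amount_part)
    gamma0, beta0, su0, sv0, se0 = _start_values(pd_, p_g, p_b)

    # --- separate part fits (variant B; also variant A starting values) ---
    def neg_bern(x):
        return -_loglik_bern_part(x[:p_g], math.exp(x[p_g]), pd_, quad)

    def neg_amt(x):
        return -_loglik_amount_part(
            x[:p_b], math.exp(x[p_b]), math.exp(x[p_b + 1]), pd_, quad
        )

    res_b1 = optimize.minimize(
        neg_bern,
        np.r_[gamma0, math.log(sv0)],
        method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    res_b2 = optimize.minimize(
        neg_amt,
        np.r_[beta0, math.log(su0), math.log(se0)],
        method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    gamma_b = res_b1.x[:p_g]
    log_sv_b = res_b1.x[p_g]
    beta_b = res_b2.x[:p_b]
    log_su_b, log_se_b = res_b2.x[p_b], res_b2.x[p_b + 1]

    names_g = tuple(f"gamma[{n}]" for n in prob_part)
    names_b = tuple(f"beta[{n}]" for n in amount_part)

    if variant == "B":
        params = ModelParams(
            gamma=gamma_b,
            beta=beta_b,
            sigma_u=math.exp(log_su_b),
            sigma_v=math.exp(log_sv_b),
            rho=0.0,
            sigma_eps=math.exp(log_se_b),
            gamma_names=tuple(prob_part),
            beta_names=tuple(amount_part),
        )
        names = (*names_g, *names_b, "log_sigma_u", "log_sigma_v", "log_sigma_eps")
        nall = len(names)
        vcov = np.zeros((nall, nall))
        h1 = _numerical_hessian(neg_bern, res_b1.x)
        h2 = _numerical_hessian(neg_amt, res_b2.x)
        v1 = _safe_vcov(h1)  # gamma..., log_sigma_v
        v2 = _safe_vcov(h2)  # beta..., log_sigma_u, log_sigma_eps
        gi = list(range(p_g))
        vcov[np.ix_(gi, gi)] = v1[: p_g, : p_g]
        vcov[p_g + p_b + 1, p_g + p_b + 1] = v1[p_g, p_g]
        vcov[np.ix_(gi, [p_g + p_b + 1])] = v1[:p_g, [p_g]]
        vcov[np.ix_([p_g + p_b + 1], gi)] = v1[[p_g], :p_g]
        bi = list(range(p_g, p_g + p_b)) + [p_g + p_b, p_g + p_b + 2]
        vcov[np.ix_(bi, bi)] = v2
        loglik = -(res_b1.fun + res_b2.fun)
        converged = bool(res_b1.success and res_b2.success)
        return FitResult(
            params=params,
            vcov=vcov,
            param_names=names,
            loglik=loglik,
            converged=converged,
            n_iter=int(res_b1.nit + res_b2.nit),
            variant="B",
            message=f"{res_b1.message}; {res_b2.message}",
        )

    # --- variant A: joint optimisation ---
    def unpack(x):
        return ModelParams(
            gamma=x[:p_g],
            beta=x[p_g : p_g + p_b],
            sigma_u=math.exp(x[p_g + p_b]),
            sigma_v=math.exp(x[p_g + p_b + 1]),
            rho=math.tanh(x[p_g + p_b + 2]),
            sigma_eps=math.exp(x[p_g + p_b + 3]),
            gamma_names=tuple(prob_part),
            beta_names=tuple(amount_part),
        )

    def neg_joint(x):
        try:
            return -_loglik_core(unpack(x), pd_, quad)
        except (ValueError, FloatingPointError):
            return 1e12

    x0 = np.r_[gamma_b, beta_b, log_su_b, log_sv_b, 0.0, log_se_b]
    res = optimize.minimize(
        neg_joint, x0, method="BFGS", options={"gtol": gtol, "maxiter": maxiter}
    )
    names = (
        *names_g,
        *names_b,
        "log_sigma_u",
        "log_sigma_v",
        "atanh_rho",
        "log_sigma_eps",
    )
    vcov = _safe_vcov(_numerical_hessian(neg_joint, res.x))
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    return FitResult(
        params=unpack(res.x),
        vcov=vcov,
        param_names=names,
        loglik=-float(res.fun),
        converged=bool(res.success or grad_norm < 1e-3),
        n_iter=int(res.nit),
        variant="A",
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# Wald inference on effect scales
# ---------------------------------------------------------------------------

_Z975 = stats.norm.ppf(0.975)


def effect_table(fit: FitResult) -> pd.DataFrame:
    """Wald inference on interpretable scales.

    Probability-part coefficients are reported as odds ratios exp(gamma_k),
    amount-part coefficients as ratios of change exp(beta_k) (the
    multiplicative change in consumed amount per unit covariate change), each
    with a 95% CI back-transformed from the log scale and a two-sided
    Wald p-value. For variant A the cross-part correlation rho is reported
    with a p-value computed on the atanh (Fisher) scale, where the normal
    approximation is better near the boundary.
    """
    if fit.vcov is None or not np.all(np.isfinite(np.diag(fit.vcov))):
        raise ValueError("fit has no usable variance-covariance matrix")
    if not fit.converged:
        raise ValueError("fit did not converge; effects are not interpretable")
    rows = []
    p = fit.params
    for part, names, values, scale in (
        ("probability", p.gamma_names, p.gamma, "odds ratio"),
        ("amount", p.beta_names, p.beta, "ratio of change"),
    ):
        prefix = "gamma" if part == "probability" else "beta"
        for name, est in zip(names, values):
            se = fit.se(f"{prefix}[{name}]")
            z = est / se if se > 0 else np.inf
            rows.append(
                {
                    "part": part,
                    "term": name,
                    "scale": scale,
                    "estimate": math.exp(est),
                    "ci_low": math.exp(est - _Z975 * se),
                    "ci_high": math.exp(est + _Z975 * se),
                    "p_value": 2.0 * stats.norm.sf(abs(z)),
                }
            )
    if fit.variant == "A":
        se_z = fit.se("atanh_rho")
        zstat = math.atanh(p.rho) / se_z if se_z > 0 else np.inf
        rows.append(
            {
                "part": "correlation",
                "term": "rho",
                "scale": "correlation",
                "estimate": p.rho,
                "ci_low": math.tanh(math.atanh(p.rho) - _Z975 * se_z),
                "ci_high": math.tanh(math.atanh(p.rho) + _Z975 * se_z),
                "p_value": 2.0 * stats.norm.sf(abs(zstat)),
            }
        )
    return pd.DataFrame(rows)
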