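"""Marginal likelihood, maximum-likelihood fitting and Wald inference."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from usualintake import (
    IntakeDataset,
    ModelParams,
    QuadratureSpec,
    ValidationError,
    effect_table,
    fit_twopart,
    log_marginal_likelihood,
)
from usualintake.twopart import (
    FitResult,
    _loglik_amount_part,
    _loglik_bern_part,
    _loglik_core,
    _PersonData,
)
from usualintake import PopulationSpec, generate_dataset

from oracles import brute_force_loglik


def _with(params, **kw):
    fields = dict(
        gamma=params.gamma,
        beta=params.beta,
        sigma_u=params.sigma_u,
        sigma_v=params.sigma_v,
        rho=params.rho,
        sigma_eps=params.sigma_eps,
        gamma_names=params.gamma_names,
        beta_names=params.beta_names,
    )
    fields.update(kw)
    return ModelParams(**fields)


class TestLogMarginalLikelihood:
    def test_matches_dense_grid_oracle(self, theta, tiny_dataset):
        oracle = brute_force_loglik(theta, tiny_dataset, n_grid=1201)
        ll = log_marginal_likelihood(theta, tiny_dataset)
        assert ll == pytest.approx(oracle, rel=1e-4)

    def test_degenerate_random_effects_reduce_to_iid_model(self, theta, small_dataset):
        # sigma_u = sigma_v -> 0: the integral collapses onto the exact
        # Bernoulli + lognormal log-density at the fixed effects
        t0 = _with(theta, sigma_u=1e-8, sigma_v=1e-8, rho=0.0)
        ll = log_marginal_likelihood(t0, small_dataset)
        df = small_dataset.table
        eta = t0.gamma[0] + t0.gamma[1] * df["weekend"]
        closed = stats.bernoulli.logpmf(df["indicator"], special.expit(eta)).sum()
        cons = df["indicator"] == 1
        mu = t0.beta[0] + t0.beta[1] * df.loc[cons, "weekend"]
        closed += stats.lognorm.logpdf(
            df.loc[cons, "amount"], s=t0.sigma_eps, scale=np.exp(mu)
        ).sum()
        assert ll == pytest.approx(closed, abs=1e-4)

    def test_rho_zero_factorises_into_part_likelihoods(self, theta, small_dataset):
        t0 = _with(theta, rho=0.0)
        quad = QuadratureSpec(15, True)
        pd_ = _PersonData(small_dataset, t0.gamma_names, t0.beta_names)
        separate = _loglik_bern_part(
            t0.gamma, t0.sigma_v, pd_, quad
        ) + _loglik_amount_part(t0.beta, t0.sigma_u, t0.sigma_eps, pd_, quad)
        joint = log_marginal_likelihood(t0, small_dataset, quad)
        assert joint == pytest.approx(separate, abs=1e-8)

    def test_quadrature_node_count_stability(self, theta_star, recovery_dataset):
        ll21 = log_marginal_likelihood(
            theta_star, recovery_dataset, QuadratureSpec(21, True)
        )
        ll41 = log_marginal_likelihood(
            theta_star, recovery_dataset, QuadratureSpec(41, True)
        )
        assert abs(ll21 - ll41) < 1e-3

    def test_invariant_to_person_ordering(self, theta, small_dataset):
        shuffled = IntakeDataset(
            small_dataset.table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        )
        assert log_marginal_likelihood(theta, shuffled) == pytest.approx(
            log_marginal_likelihood(theta, small_dataset), abs=1e-10
        )

    def test_domain_errors(self, theta, tiny_dataset):
        with pytest.raises(ValueError):
            log_marginal_likelihood(_with(theta, sigma_u=0.0), tiny_dataset)
        with pytest.raises(ValueError):
            _with(theta, rho=1.0)

    def test_inconsistent_indicator_amount_rejected(self, theta, tiny_dataset):
        tampered = tiny_dataset.table.copy()
        cons = tampered.index[tampered["indicator"] == 1][0]
        tampered.loc[cons, "amount"] = 0.0  # indicator stays 1
        ds = IntakeDataset.__new__(IntakeDataset)
        object.__setattr__(ds, "table", tampered)
        object.__setattr__(ds, "covariate_names", ())
        with pytest.raises(ValidationError):
            log_marginal_likelihood(theta, ds)


class TestFit:
    def test_parameter_recovery_within_3se(self, theta_star, recovery_fit):
        fit = recovery_fit
        assert fit.converged
        p = fit.params
        checks = [
            ("gamma[intercept]", p.gamma[0], theta_star.gamma[0]),
            ("gamma[weekend]", p.gamma[1], theta_star.gamma[1]),
            ("beta[intercept]", p.beta[0], theta_star.beta[0]),
            ("beta[weekend]", p.beta[1], theta_star.beta[1]),
            ("log_sigma_u", math.log(p.sigma_u), math.log(theta_star.sigma_u)),
            ("log_sigma_v", math.log(p.sigma_v), math.log(theta_star.sigma_v)),
            ("atanh_rho", math.atanh(p.rho), math.atanh(theta_star.rho)),
            ("log_sigma_eps", math.log(p.sigma_eps), math.log(theta_star.sigma_eps)),
        ]
        for name, est, true in checks:
            assert abs(est - true) < 3.0 * fit.se(name), name

    def test_rho_consistent_at_the_null(self, rho0_fit_a):
        fit = rho0_fit_a
        z = math.atanh(fit.params.rho) / fit.se("atanh_rho")
        assert abs(z) < 2.0

    def test_variant_b_matches_rho_constrained_joint_fit(self, rho0_dataset, rho0_fit_b):
        # independent route: optimise the full 2-D quadrature likelihood
        # with rho pinned at 0, and compare coefficient for coefficient
        quad = QuadratureSpec(15, True)
        pd_ = _PersonData(rho0_dataset, ("intercept", "weekend"), ("intercept", "weekend"))

        def neg(x):
            params = ModelParams(
                x[:2], x[2:4], math.exp(x[4]), math.exp(x[5]), 0.0, math.exp(x[6]),
                ("intercept", "weekend"), ("intercept", "weekend"),
            )
            return -_loglik_core(params, pd_, quad)

        b = rho0_fit_b.params
        x0 = np.r_[b.gamma, b.beta,
                   math.log(b.sigma_u), math.log(b.sigma_v), math.log(b.sigma_eps)]
        res = optimize.minimize(neg, x0 + 0.05, method="BFGS", options={"gtol": 1e-7})
        assert np.allclose(res.x[:4], np.r_[b.gamma, b.beta], atol=1e-3)
        assert np.allclose(
            np.exp(res.x[4:]), [b.sigma_u, b.sigma_v, b.sigma_eps], atol=1e-3
        )
        assert -res.fun == pytest.approx(rho0_fit_b.loglik, abs=1e-4)

    def test_variant_b_amount_part_matches_mixedlm(self, rho0_dataset, rho0_fit_b):
        # external oracle: ML random-intercept fit of log-amount on consumers
        sm = pytest.importorskip("statsmodels.api")
        df = rho0_dataset.table
        cons = df[df["indicator"] == 1].copy()
        cons["logA"] = np.log(cons["amount"])
        md = sm.MixedLM.from_formula("logA ~ weekend", groups="person_id", data=cons)
        res = md.fit(reml=False)
        b = rho0_fit_b.params
        assert b.beta[0] == pytest.approx(res.params["Intercept"], abs=1e-3)
        assert b.beta[1] == pytest.approx(res.params["weekend"], abs=1e-3)
        assert b.sigma_u**2 == pytest.approx(float(res.cov_re.iloc[0, 0]), abs=2e-3)
        assert b.sigma_eps**2 == pytest.approx(res.scale, abs=2e-3)

    def test_loglik_profile_rho0_data(self, rho0_fit_a, rho0_fit_b):
        # on data generated with rho = 0 the correlation buys almost nothing
        diff = rho0_fit_a.loglik - rho0_fit_b.loglik
        assert -1e-3 < diff < 2.5

    def test_loglik_profile_rho05_data(self, recovery_dataset, recovery_fit):
        fit_b = fit_twopart(recovery_dataset, variant="B")
        assert recovery_fit.loglik - fit_b.loglik > 3.84  # chi2_1 at 5%

    def test_unidentifiable_datasets_rejected(self):
        df = pd.DataFrame(
            {"person_id": [1, 1, 2, 2], "day_index": [1, 2, 1, 2],
             "weekend": [0, 1, 0, 1], "amount": [0.0, 0.0, 0.0, 0.0]}
        )
        with pytest.raises(ValidationError):
            fit_twopart(IntakeDataset(df))
        df_pos = df.assign(amount=[1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValidationError):
            fit_twopart(IntakeDataset(df_pos))

    def test_hessian_se_matches_replicate_spread(self, theta_star):
        # scaled-down Monte-Carlo check on the (fast, exactly-integrable)
        # amount part: the Wald SE of the amount intercept should match the
        # seed-to-seed spread of its MLE
        quad = QuadratureSpec(15, True)
        n_rep = 200
        estimates = []
        ses = []
        from usualintake.twopart import _numerical_hessian, _safe_vcov

        for rep in range(n_rep):
            ds = generate_dataset(
                PopulationSpec(m=100, days_per_person=7, seed=10_000 + rep), theta_star
            )
            pd_ = _PersonData(ds, ("intercept", "weekend"), ("intercept", "weekend"))

            def neg(x):
                return -_loglik_amount_part(
                    x[:2], math.exp(x[2]), math.exp(x[3]), pd_, quad
                )

            x0 = np.array([3.0, 0.4, math.log(0.8), math.log(0.9)])
            res = optimize.minimize(neg, x0, method="BFGS", options={"gtol": 1e-6})
            estimates.append(res.x[0])
            if rep < 40:  # SEs are stable; average a subset
                ses.append(math.sqrt(_safe_vcov(_numerical_hessian(neg, res.x))[0, 0]))
        spread = np.std(estimates, ddof=1)
        assert np.mean(ses) == pytest.approx(spread, rel=0.15)


class TestEffectTable:
    @staticmethod
    def _fake_fit(gamma, beta, ses, variant="A", rho=0.0, se_atanh_rho=0.1):
        names = (
            "gamma[intercept]", "gamma[weekend]",
            "beta[intercept]", "beta[weekend]",
            "log_sigma_u", "log_sigma_v", "atanh_rho", "log_sigma_eps",
        )
        if variant == "B":
            names = tuple(n for n in names if n != "atanh_rho")
        full_ses = list(ses) + [0.1] * (len(names) - len(ses))
        if variant == "A":
            full_ses[names.index("atanh_rho")] = se_atanh_rho
        vcov = np.diag(np.square(full_ses))
        params = ModelParams(
            np.asarray(gamma), np.asarray(beta), 0.8, 1.2, rho, 0.9,
            ("intercept", "weekend"), ("intercept", "weekend"),
        )
        return FitResult(params, vcov, names, -1.0, True, 10, variant)

    def test_null_effect_gives_unit_or_with_symmetric_ci(self):
        fit = self._fake_fit([0.0, 0.0], [0.0, 0.0], [0.3, 0.3, 0.3, 0.3])
        tab = effect_table(fit)
        row = tab[(tab["part"] == "probability") & (tab["term"] == "intercept")].iloc[0]
        assert row["estimate"] == pytest.approx(1.0)
        assert row["ci_low"] * row["ci_high"] == pytest.approx(1.0)  # log-symmetric

    def test_wald_arithmetic_odds_ratio(self):
        # gamma = ln 2, SE = 0.1: OR 2.00, CI = exp(0.6931 -+ 1.96 x 0.1)
        fit = self._fake_fit([math.log(2.0), 0.0], [0.0, 0.0], [0.1, 0.1, 0.1, 0.1])
        row = effect_table(fit).iloc[0]
        assert row["estimate"] == pytest.approx(2.0, abs=5e-4)
        assert row["ci_low"] == pytest.approx(1.6440, abs=5e-4)
        assert row["ci_high"] == pytest.approx(2.4329, abs=5e-4)

    def test_wald_arithmetic_ratio_of_change(self):
        fit = self._fake_fit([0.0, 0.0], [0.3001, 0.0], [0.1, 0.1, 0.05, 0.1])
        tab = effect_table(fit)
        row = tab[(tab["part"] == "amount") & (tab["term"] == "intercept")].iloc[0]
        assert row["estimate"] == pytest.approx(1.3500, abs=5e-4)
        assert row["ci_low"] == pytest.approx(1.2240, abs=5e-4)
        assert row["ci_high"] == pytest.approx(1.4891, abs=5e-4)

    def test_variant_a_reports_rho_variant_b_does_not(self):
        fit_a = self._fake_fit([0.0, 0.0], [0.0, 0.0], [0.1] * 4, rho=0.4)
        fit_b = self._fake_fit([0.0, 0.0], [0.0, 0.0], [0.1] * 4, variant="B")
        assert "correlation" in set(effect_table(fit_a)["part"])
        assert "correlation" not in set(effect_table(fit_b)["part"])

    def test_unconverged_fit_rejected(self):
        fit = self._fake_fit([0.0, 0.0], [0.0, 0.0], [0.1] * 4)
        bad = FitResult(
            fit.params, fit.vcov, fit.param_names, fit.loglik, False, 5, "A"
        )
        with pytest.raises(ValueError):
            effect_table(bad)


def test_report_round_trips_through_parameter_file(tmp_path, recovery_fit):
    path = tmp_path / "params.json"
    recovery_fit.params.save(path)
    loaded = ModelParams.load(path)
    assert np.allclose(loaded.gamma, recovery_fit.params.gamma)
    assert loaded.rho == pytest.approx(recovery_fit.params.rho)
    text = recovery_fit.report()
    assert "variant: A" in text and "rho:" in text
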