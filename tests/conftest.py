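import numpy as np
import pytest

from usualintake import (
    CovariatePattern,
    ModelParams,
    PopulationSpec,
    fit_twopart,
    fixture_params,
    generate_dataset,
)

#: Generating parameters for the parameter-recovery experiments.
THETA_STAR = ModelParams(
    gamma=np.array([-0.5, 1.2]),
    beta=np.array([3.0, 0.4]),
    sigma_u=0.8,
    sigma_v=1.2,
    rho=0.5,
    sigma_eps=0.9,
    gamma_names=("intercept", "weekend"),
    beta_names=("intercept", "weekend"),
)


@pytest.fixture(scope="session")
def theta():
    return fixture_params()


@pytest.fixture(scope="session")
def pattern():
    return CovariatePattern.from_covariates({}, label="all")


@pytest.fixture(scope="session")
def theta_star():
    return THETA_STAR


@pytest.fixture(scope="session")
def tiny_dataset(theta):
    """3 persons x 2 days: small enough for dense-grid likelihood oracles."""
    return generate_dataset(PopulationSpec(m=3, days_per_person=2, seed=42), theta)


@pytest.fixture(scope="session")
def small_dataset(theta):
    """80 persons x 4 days: quadrature stability and invariance checks."""
    return generate_dataset(PopulationSpec(m=80, days_per_person=4, seed=7), theta)


@pytest.fixture(scope="session")
def recovery_dataset(theta_star):
    """500 persons x 7 days simulated at theta*."""
    return generate_dataset(
        PopulationSpec(m=500, days_per_person=7, seed=11), theta_star
    )


@pytest.fixture(scope="session")
def recovery_fit(recovery_dataset):
    """Variant A maximum-likelihood fit on the recovery dataset."""
    return fit_twopart(recovery_dataset, variant="A")


@pytest.fixture(scope="session")
def rho0_params(theta_star):
    return ModelParams(
        theta_star.gamma,
        theta_star.beta,
        theta_star.sigma_u,
        theta_star.sigma_v,
        0.0,
        theta_star.sigma_eps,
        theta_star.gamma_names,
        theta_star.beta_names,
    )


@pytest.fixture(scope="session")
def rho0_dataset(rho0_params):
    """Cohort generated with independent random intercepts (rho = 0).

    Seven-day diaries so both day types appear and the weekend effects are
    identified.
    """
    return generate_dataset(
        PopulationSpec(m=200, days_per_person=7, seed=23), rho0_params
    )


@pytest.fixture(scope="session")
def rho0_fit_a(rho0_dataset):
    return fit_twopart(rho0_dataset, variant="A")


@pytest.fixture(scope="session")
def rho0_fit_b(rho0_dataset):
    return fit_twopart(rho0_dataset, variant="B")
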