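"""Shared fixtures: the OK-Diabetes worked example and its optimised designs.

The expensive optimisations are session-scoped so the acceptance tests and
unit tests share one computation.
"""

from __future__ import annotations

import pytest

from pilotopt import (
    BivariateEffectPrior,
    Constraints,
    EffectPrior,
    ElicitationInputs,
    Endpoint,
    Scenario,
    UtilityParams,
    derive_weights,
    optimise,
    optimise_internal,
)

MU_STAR = 0.5


@pytest.fixture(scope="session")
def endpoint() -> Endpoint:
    return Endpoint(sigma=1.5)


@pytest.fixture(scope="session")
def ok_elicitation() -> ElicitationInputs:
    return ElicitationInputs(d_bar=0.005, d_hat=0.3, n_star=50)


@pytest.fixture(scope="session")
def ok_params(ok_elicitation) -> UtilityParams:
    return UtilityParams(weights=derive_weights(ok_elicitation), rho=2.0)


@pytest.fixture(scope="session")
def ok_scenario(endpoint, ok_params) -> Scenario:
    return Scenario(
        endpoint=endpoint,
        prior=EffectPrior(m=0.0, s=0.6),
        utility=ok_params,
        mu_star=MU_STAR,
    )


@pytest.fixture(scope="session")
def ok_constraints() -> Constraints:
    return Constraints(n1_min=30)


@pytest.fixture(scope="session")
def ok_bivariate_scenario(endpoint, ok_params) -> Scenario:
    return Scenario(
        endpoint=endpoint,
        prior=BivariateEffectPrior(mp=0.0, sp=0.6, m=0.0, s=0.6, tau=0.9),
        utility=ok_params,
        mu_star=MU_STAR,
    )


@pytest.fixture(scope="session")
def opt_unrestricted(ok_scenario, ok_constraints):
    return optimise(ok_scenario, ok_constraints)


@pytest.fixture(scope="session")
def opt_no_pilot(ok_scenario):
    return optimise(ok_scenario, Constraints(n1_min=30, no_pilot_test=True))


@pytest.fixture(scope="session")
def opt_internal(ok_scenario):
    return optimise_internal(ok_scenario, Constraints(n1_min=30, pilot_type="internal"))


@pytest.fixture(scope="session")
def opt_heterogeneous(ok_bivariate_scenario, ok_constraints):
    return optimise(ok_bivariate_scenario, ok_constraints)
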