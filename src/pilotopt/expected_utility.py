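"""Expected utility of an external pilot + definitive trial programme.

The programme design z = (n1, c1, n2, c2) fixes the decision rules: proceed
to the definitive trial when the pilot mean difference exceeds c1, adopt the
intervention when the definitive mean difference exceeds c2.  Conditional on
the true effect ``mu`` the two stage statistics are independent normals, so
the three terminal branches

* adopt           (G1=1, G2=1): n = n1+n2, d = mu, b = 0
* definitive-negative (G1=1, G2=0): n = n1+n2, d = 0,  b = 1
* pilot-negative  (G1=0):       n = n1,    d = 0,  b = 1

have closed-form probabilities.  The prior N(m, s^2) on ``mu`` is then
integrated out by Gauss-Hermite quadrature.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .frequentist import (
    Endpoint,
    OperatingCharacteristics,
    alpha_of,
    critical_value,
    overall_rates,
    rejection_probability,
)
from .utility import UtilityParams, utility_from_value

PilotType = Literal["external", "internal"]

DEFAULT_NODES = 150


@dataclass(frozen=True)
class EffectPrior:
    """Normal prior N(m, s^2) on the true mean difference ``mu``.

    ``s = 0`` is a supported point mass.
    """

    m: float
    s: float

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError(f"s must be >= 0, got {self.s}")


@dataclass(frozen=True)
class ProgrammeDesign:
    """Decision variable z = (n1, c1, n2, c2) plus the pilot type.

    Critical values are the stored primitive; the equivalent stage-level
    alpha representation is a view requiring the endpoint SD.  For internal
    pilots c2 applies to the pooled mean difference across both stages.
    Degenerate stages (n = 0) carry c = -inf, the "always proceed"
    convention.
    """

    n1: float
    c1: float
    n2: float
    c2: float
    pilot_type: PilotType = "external"

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError("sample sizes must be >= 0")
        if self.pilot_type not in ("external", "internal"):
            raise ValueError(f"unknown pilot_type {self.pilot_type!r}")
        if self.pilot_type == "internal" and self.n1 < 1:
            raise ValueError("an internal pilot requires n1 >= 1")
        if self.n1 == 0 and self.c1 != -math.inf:
            object.__setattr__(self, "c1", -math.inf)
        if self.n2 == 0 and self.pilot_type == "external" and self.c2 != -math.inf:
            object.__setattr__(self, "c2", -math.inf)

    @classmethod
    def from_alphas(
        cls,
        n1: float,
        alpha1: float,
        n2: float,
        alpha2: float,
        endpoint: Endpoint,
        pilot_type: PilotType = "external",
    ) -> "ProgrammeDesign":
        """Build a design from stage-level type I error rates.

        For internal pilots ``alpha2`` is defined on the null distribution of
        the pooled statistic, i.e. c2 = sigma*sqrt(2/(n1+n2))*Phi^{-1}(1-alpha2).
        """
        c1 = critical_value(n1, alpha1, endpoint)
        n_for_c2 = n1 + n2 if pilot_type == "internal" else n2
        c2 = critical_value(n_for_c2, alpha2, endpoint)
        return cls(n1=n1, c1=c1, n2=n2, c2=c2, pilot_type=pilot_type)

    def alphas(self, endpoint: Endpoint) -> tuple[float, float]:
        """Stage-level null rejection probabilities (marginal, for internal)."""
        a1 = alpha_of(self.n1, self.c1, endpoint)
        n_for_c2 = self.n1 + self.n2 if self.pilot_type == "internal" else self.n2
        a2 = alpha_of(n_for_c2, self.c2, endpoint)
        return a1, a2

    def total_n(self) -> float:
        """Total of the per-arm sample sizes, the ``n`` utility attribute."""
        return self.n1 + self.n2

    def rounded(self) -> "ProgrammeDesign":
        return replace(self, n1=round(self.n1), n2=round(self.n2))


@dataclass(frozen=True)
class Scenario:
    """An assembled design problem: endpoint, effect prior, utility, quadrature.

    ``prior`` is either an :class:`EffectPrior` or (for heterogeneous
    pilot/definitive effects) an ``extensions.BivariateEffectPrior``.
    ``mu_star`` is the alternative at which operating characteristics are
    reported; it does not enter the expected utility.
    """

    endpoint: Endpoint
    prior: object
    utility: UtilityParams
    quadrature_nodes: int = DEFAULT_NODES
    mu_star: float | None = None

    def __post_init__(self) -> None:
        if self.quadrature_nodes < 5:
            raise ValueError("quadrature_nodes must be >= 5")


@functools.lru_cache(maxsize=8)
def _hermgauss(nodes: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.hermite.hermgauss(nodes)


def gauss_hermite_expectation(f, m: float, s: float, nodes: int):
    """E[f(mu)] for mu ~ N(m, s^2) by Gauss-Hermite quadrature.

    Uses the change of variable mu = m + sqrt(2)*s*t against the physicists'
    weight exp(-t^2); a point-mass prior (s = 0) evaluates f at m directly.
    ``f`` must accept and return an ndarray.  The node/weight tables are
    cached across calls.
    """
    if s == 0.0:
        return float(np.asarray(f(np.array([m])))[0])
    t, w = _hermgauss(nodes)
    mu = m + math.sqrt(2.0) * s * t
    return float(w @ np.asarray(f(mu))) / math.sqrt(math.pi)


def branch_probabilities(z: ProgrammeDesign, mu, endpoint: Endpoint):
    """Terminal-branch probabilities of an external programme given ``mu``.

    Returns ``(p_adopt, p_definitive_negative, p_pilot_negative)``; the
    stages are independent given ``mu`` so the first two factor through
    Pr[G1=1 | mu].  Vectorised over ``mu``.
    """
    if z.pilot_type != "external":
        raise ValueError("branch_probabilities applies to external designs")
    mu = np.asarray(mu, dtype=float)
    p1 = rejection_probability(z.n1, z.c1, mu, endpoint)
    p2 = rejection_probability(z.n2, z.c2, mu, endpoint)
    return p1 * p2, p1 * (1.0 - p2), 1.0 - p1


def _branch_utilities(z: ProgrammeDesign, mu, params: UtilityParams):
    """Utilities of the three terminal branches (adopt depends on mu)."""
    w = params.weights
    u_adopt = utility_from_value(w.kn * z.total_n() + w.kd * np.asarray(mu, float), params.rho)
    u_neg2 = utility_from_value(w.kn * z.total_n() + w.kb, params.rho)
    u_neg1 = utility_from_value(w.kn * z.n1 + w.kb, params.rho)
    return u_adopt, u_neg2, u_neg1


def conditional_eu(z: ProgrammeDesign, mu, scenario: Scenario):
    """Expected utility of an external programme conditional on ``mu``."""
    p11, p10, p0 = branch_probabilities(z, mu, scenario.endpoint)
    u_adopt, u_neg2, u_neg1 = _branch_utilities(z, mu, scenario.utility)
    out = np.asarray(p11 * u_adopt + p10 * u_neg2 + p0 * u_neg1)
    return out if out.ndim else float(out)


def expected_utility(z: ProgrammeDesign, scenario: Scenario) -> float:
    """Prior expected utility of an external programme.

    Integrates :func:`conditional_eu` over the normal prior by Gauss-Hermite
    quadrature with ``scenario.quadrature_nodes`` nodes.
    """
    prior = scenario.prior
    if not isinstance(prior, EffectPrior):
        raise TypeError("expected_utility requires a univariate EffectPrior")
    if z.pilot_type != "external":
        raise ValueError("expected_utility applies to external designs")
    return gauss_hermite_expectation(
        lambda mu: conditional_eu(z, mu, scenario), prior.m, prior.s, scenario.quadrature_nodes
    )


def quadrature_convergence(z: ProgrammeDesign, scenario: Scenario) -> float:
    """Absolute change in EU when the node count is doubled (diagnostic)."""
    doubled = replace(scenario, quadrature_nodes=2 * scenario.quadrature_nodes)
    return abs(expected_utility(z, doubled) - expected_utility(z, scenario))


def operating_characteristics(
    z: ProgrammeDesign, endpoint: Endpoint, mu_star: float
) -> OperatingCharacteristics:
    """Stage and overall error rates of a design at the alternative ``mu_star``.

    Stage-level rates always use the stage's own (marginal) sampling
    distribution — for internal pilots this is the convention under which
    published operating-characteristic tables are stated — while the overall
    rates of an internal design account for the correlation between the
    pilot and pooled statistics.
    """
    a1, a2 = z.alphas(endpoint)
    b1 = 1.0 - rejection_probability(z.n1, z.c1, mu_star, endpoint)
    n_for_c2 = z.n1 + z.n2 if z.pilot_type == "internal" else z.n2
    b2 = 1.0 - rejection_probability(n_for_c2, z.c2, mu_star, endpoint)
    if z.pilot_type == "external":
        at, bt = overall_rates(a1, b1, a2, b2)
    else:
        from .extensions import internal_joint_rejection  # lazy: avoid cycle

        at = internal_joint_rejection(z, 0.0, endpoint)
        bt = 1.0 - internal_joint_rejection(z, mu_star, endpoint)
    return OperatingCharacteristics(
        alpha1=a1, beta1=b1, alpha2=a2, beta2=b2, alpha_t=float(at), beta_t=float(bt), mu_star=mu_star
    )
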