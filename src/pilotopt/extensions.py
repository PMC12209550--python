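"""Internal pilots and heterogeneous pilot/definitive effects.

Internal pilots reuse the pilot data at the final analysis: the second test
is applied to the pooled mean difference

    xt = (n1*x1 + n2*x2) / (n1 + n2),

and (x1, xt) given mu are bivariate normal with correlation
sqrt(n1/(n1+n2)), so branch probabilities become orthant probabilities.

Heterogeneous effects relax the assumption that the pilot and definitive
trials share one true effect: (mu_p, mu) get a bivariate normal prior with
correlation tau, and the pilot estimate x1 given the definitive effect mu is
normal with mean m_p + tau*(s_p/s)*(mu - m) and variance
(1 - tau^2)*s_p^2 + 2*sigma^2/n1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal, norm

from .expected_utility import (
    EffectPrior,
    ProgrammeDesign,
    Scenario,
    _branch_utilities,
    expected_utility,
    gauss_hermite_expectation,
)
from .frequentist import Endpoint, rejection_probability


@dataclass(frozen=True)
class BivariateEffectPrior:
    """Bivariate normal prior on the pilot effect mu_p and definitive effect mu.

    ``tau = 1`` with matched marginals recovers the homogeneous single-effect
    model.
    """

    mp: float
    sp: float
    m: float
    s: float
    tau: float

    def __post_init__(self) -> None:
        if self.sp < 0 or self.s < 0:
            raise ValueError("prior SDs must be >= 0")
        if not -1.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must be in [-1, 1], got {self.tau}")

    def marginal(self) -> EffectPrior:
        """Marginal prior of the definitive-trial effect."""
        return EffectPrior(m=self.m, s=self.s)


@dataclass(frozen=True)
class InternalJoint:
    """Mean vector and covariance of (x1, xt) given mu for an internal pilot."""

    mean: np.ndarray
    cov: np.ndarray

    @property
    def correlation(self) -> float:
        return float(self.cov[0, 1] / math.sqrt(self.cov[0, 0] * self.cov[1, 1]))


def internal_joint(n1: float, n2: float, endpoint: Endpoint, mu: float) -> InternalJoint:
    """Joint distribution of pilot and pooled mean differences given ``mu``.

    Var(x1) = 2*sigma^2/n1; Var(xt) = Cov(x1, xt) = 2*sigma^2/(n1+n2), hence
    Corr(x1, xt) = sqrt(n1/(n1+n2)).
    """
    if n1 < 1:
        raise ValueError("an internal pilot requires n1 >= 1")
    if n2 < 0:
        raise ValueError("n2 must be >= 0")
    v1 = 2.0 * endpoint.sigma**2 / n1
    vt = 2.0 * endpoint.sigma**2 / (n1 + n2)
    return InternalJoint(
        mean=np.array([mu, mu]), cov=np.array([[v1, vt], [vt, vt]])
    )


def _bvn_survival(h, k, r: float):
    """Pr[Z1 > h, Z2 > k] for standard bivariate normal with correlation r.

    Vectorised over (h, k); infinite limits are resolved before calling the
    scipy CDF.  By symmetry the survival equals the CDF at (-h, -k).
    """
    h = np.atleast_1d(np.asarray(h, dtype=float))
    k = np.atleast_1d(np.asarray(k, dtype=float))
    h, k = np.broadcast_arrays(h, k)
    out = np.empty(h.shape, dtype=float)
    inf_h = np.isinf(h)
    inf_k = np.isinf(k)
    out[(h == math.inf) | (k == math.inf)] = 0.0
    both_ninf = (h == -math.inf) & (k == -math.inf)
    out[both_ninf] = 1.0
    only_h = (h == -math.inf) & ~inf_k
    out[only_h] = norm.sf(k[only_h])
    only_k = (k == -math.inf) & ~inf_h
    out[only_k] = norm.sf(h[only_k])
    fin = ~inf_h & ~inf_k
    if np.any(fin):
        if r >= 1.0 - 1e-12:
            out[fin] = norm.sf(np.maximum(h[fin], k[fin]))
        elif r <= -1.0 + 1e-12:
            out[fin] = np.clip(norm.sf(h[fin]) - norm.cdf(k[fin]), 0.0, 1.0)
        else:
            mvn = multivariate_normal(
                mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]], allow_singular=True
            )
            pts = np.column_stack([-h[fin], -k[fin]])
            out[fin] = np.clip(mvn.cdf(pts), 0.0, 1.0)
    return out


def internal_joint_rejection(z: ProgrammeDesign, mu, endpoint: Endpoint):
    """Pr[x1 > c1, xt > c2 | mu] for an internal design; vectorised over mu."""
    mu = np.asarray(mu, dtype=float)
    nt = z.n1 + z.n2
    sd1 = endpoint.se(z.n1)
    sdt = endpoint.se(nt)
    r = math.sqrt(z.n1 / nt)
    h = (z.c1 - mu) / sd1 if z.c1 != -math.inf else np.full(np.shape(mu) or (1,), -math.inf)
    k = (z.c2 - mu) / sdt if z.c2 != -math.inf else np.full(np.shape(mu) or (1,), -math.inf)
    out = _bvn_survival(h, k, r)
    return out if np.ndim(mu) else float(out[0])


def internal_branch_probabilities(z: ProgrammeDesign, mu, endpoint: Endpoint):
    """(adopt, definitive-negative, pilot-negative) probabilities given mu."""
    if z.pilot_type != "internal":
        raise ValueError("internal_branch_probabilities needs an internal design")
    mu = np.asarray(mu, dtype=float)
    p1 = rejection_probability(z.n1, z.c1, mu, endpoint)
    p11 = np.clip(internal_joint_rejection(z, mu, endpoint), 0.0, None)
    p11 = np.minimum(p11, p1)
    return p11, p1 - p11, 1.0 - p1


def conditional_eu_internal(z: ProgrammeDesign, mu, scenario: Scenario):
    """Expected utility of an internal-pilot programme conditional on mu."""
    p11, p10, p0 = internal_branch_probabilities(z, mu, scenario.endpoint)
    u_adopt, u_neg2, u_neg1 = _branch_utilities(z, mu, scenario.utility)
    out = np.asarray(p11 * u_adopt + p10 * u_neg2 + p0 * u_neg1)
    return out if out.ndim else float(out)


def expected_utility_internal(z: ProgrammeDesign, scenario: Scenario) -> float:
    """Prior expected utility of an internal-pilot programme."""
    prior = scenario.prior
    if not isinstance(prior, EffectPrior):
        raise TypeError("expected_utility_internal requires a univariate EffectPrior")
    if z.pilot_type != "internal":
        raise ValueError("expected_utility_internal needs an internal design")
    return gauss_hermite_expectation(
        lambda mu: conditional_eu_internal(z, mu, scenario),
        prior.m,
        prior.s,
        scenario.quadrature_nodes,
    )


def pilot_sampling_given_mu(
    prior: BivariateEffectPrior, mu: float, n1: float, endpoint: Endpoint
) -> tuple[float, float]:
    """Mean and variance of the pilot estimate x1 given the definitive effect mu.

    Marginalises the unknown pilot effect: x1 | mu is normal with mean
    m_p + tau*(s_p/s)*(mu - m) and variance (1-tau^2)*s_p^2 + 2*sigma^2/n1.
    """
    if prior.s == 0 and prior.tau != 0:
        raise ValueError("conditional on mu undefined: s = 0 with tau != 0")
    slope = prior.tau * prior.sp / prior.s if prior.tau != 0 else 0.0
    mean = prior.mp + slope * (mu - prior.m)
    var = (1.0 - prior.tau**2) * prior.sp**2 + 2.0 * endpoint.sigma**2 / n1
    return mean, var


def _heterogeneous_p1(z: ProgrammeDesign, mu, prior: BivariateEffectPrior, endpoint: Endpoint):
    """Pr[x1 > c1 | mu] under the bivariate effect prior; vectorised over mu."""
    mu = np.asarray(mu, dtype=float)
    if z.n1 == 0 or z.c1 == -math.inf:
        return np.ones_like(mu)
    if prior.s == 0 and prior.tau != 0:
        raise ValueError("conditional on mu undefined: s = 0 with tau != 0")
    slope = prior.tau * prior.sp / prior.s if prior.tau != 0 else 0.0
    mean = prior.mp + slope * (mu - prior.m)
    sd = math.sqrt((1.0 - prior.tau**2) * prior.sp**2 + 2.0 * endpoint.sigma**2 / z.n1)
    return norm.sf((z.c1 - mean) / sd)


def conditional_eu_heterogeneous(z: ProgrammeDesign, mu, scenario: Scenario):
    """Conditional expected utility when pilot and definitive effects differ.

    The adopt branch's realised change in outcome is the *definitive* effect
    mu; only the pilot's progression probability is attenuated.
    """
    prior: BivariateEffectPrior = scenario.prior
    mu = np.asarray(mu, dtype=float)
    p1 = _heterogeneous_p1(z, mu, prior, scenario.endpoint)
    p2 = rejection_probability(z.n2, z.c2, mu, scenario.endpoint)
    u_adopt, u_neg2, u_neg1 = _branch_utilities(z, mu, scenario.utility)
    out = np.asarray(p1 * p2 * u_adopt + p1 * (1.0 - p2) * u_neg2 + (1.0 - p1) * u_neg1)
    return out if out.ndim else float(out)


def expected_utility_heterogeneous(z: ProgrammeDesign, scenario: Scenario) -> float:
    """Prior expected utility under heterogeneous pilot/definitive effects.

    Quadrature runs over the marginal prior of the definitive effect mu; at
    tau = 1 with matched marginals this coincides with the homogeneous
    :func:`~pilotopt.expected_utility.expected_utility`.
    """
    prior = scenario.prior
    if not isinstance(prior, BivariateEffectPrior):
        raise TypeError("expected_utility_heterogeneous requires a BivariateEffectPrior")
    if z.pilot_type != "external":
        raise ValueError("heterogeneous effects are implemented for external pilots")
    return gauss_hermite_expectation(
        lambda mu: conditional_eu_heterogeneous(z, mu, scenario),
        prior.m,
        prior.s,
        scenario.quadrature_nodes,
    )


def programme_expected_utility(z: ProgrammeDesign, scenario: Scenario) -> float:
    """Dispatch to the EU routine matching the design and prior kinds."""
    if isinstance(scenario.prior, BivariateEffectPrior):
        if z.pilot_type != "external":
            raise ValueError("bivariate effect priors support external pilots only")
        return expected_utility_heterogeneous(z, scenario)
    if z.pilot_type == "internal":
        return expected_utility_internal(z, scenario)
    return expected_utility(z, scenario)
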