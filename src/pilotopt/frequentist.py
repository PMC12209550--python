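"""One-sided z-test operating characteristics for two-stage programmes.

Each stage compares the sample mean difference x_i ~ N(mu, 2*sigma^2/n_i)
against a critical value c_i, rejecting (proceeding / adopting) when
x_i > c_i.  A stage with n = 0 degenerates to "always proceed"
(alpha = 1, beta = 0), represented by c = -inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import norm


@dataclass(frozen=True)
class Endpoint:
    """Normally distributed endpoint with known common SD ``sigma``."""

    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def se(self, n):
        """Standard error of the mean difference with n per arm."""
        n = np.asarray(n, dtype=float)
        with np.errstate(divide="ignore"):
            out = self.sigma * np.sqrt(2.0 / n)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class StageTest:
    """Per-arm sample size and critical value on the mean-difference scale."""

    n: float
    c: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n}")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Stage-wise and overall error rates at a stated alternative ``mu_star``."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    alpha_t: float
    beta_t: float
    mu_star: float


def critical_value(n: float, alpha: float, endpoint: Endpoint) -> float:
    """Critical value with null rejection probability ``alpha``.

    c = sigma*sqrt(2/n)*Phi^{-1}(1-alpha); alpha = 1 maps to -inf (always
    proceed), which is also the convention for degenerate n = 0 stages.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if alpha == 1.0 or n == 0:
        return -math.inf
    if n < 1:
        raise ValueError(f"n must be >= 1 (or 0 degenerate), got {n}")
    return float(endpoint.se(n) * ndtri(1.0 - alpha))


def rejection_probability(n, c, mu, endpoint: Endpoint):
    """Pr[x > c | mu] for a stage with n per arm; n = 0 -> 1 (always proceed).

    Vectorised over ``mu``.
    """
    mu = np.asarray(mu, dtype=float)
    if n == 0 or c == -math.inf:
        out = np.ones_like(mu)
    elif c == math.inf:
        out = np.zeros_like(mu)
    else:
        out = ndtr((mu - c) / endpoint.se(n))
    return out if out.ndim else float(out)


def stage_power(test: StageTest, mu, endpoint: Endpoint):
    """Probability of a positive stage result at effect ``mu``."""
    return rejection_probability(test.n, test.c, mu, endpoint)


def alpha_of(n: float, c: float, endpoint: Endpoint) -> float:
    """Null rejection probability implied by a critical value."""
    return rejection_probability(n, c, 0.0, endpoint)


def beta_at_alpha(n: float, alpha: float, mu: float, endpoint: Endpoint) -> float:
    """Type II error at the alternative ``mu`` when testing at level ``alpha``."""
    c = critical_value(n, alpha, endpoint)
    return 1.0 - rejection_probability(n, c, mu, endpoint)


def overall_rates(alpha1: float, beta1: float, alpha2: float, beta2: float) -> tuple[float, float]:
    """Programme-level error rates from independent stage-level rates.

    alpha_t = alpha1*alpha2 (both stages must reject under the null);
    beta_t = beta1 + (1-beta1)*beta2 (fail at either stage under the
    alternative).
    """
    for name, p in (("alpha1", alpha1), ("beta1", beta1), ("alpha2", alpha2), ("beta2", beta2)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    return alpha1 * alpha2, beta1 + (1.0 - beta1) * beta2


def solve_sample_size(power: float, alpha: float, mu: float, endpoint: Endpoint) -> int:
    """Smallest integer per-arm n whose one-sided z-test attains ``power``.

    n = ceil(2*sigma^2*(z_{1-alpha} + z_{power})^2 / mu^2).
    """
    if not 0.0 < alpha < power < 1.0:
        raise ValueError("require 0 < alpha < power < 1")
    if mu == 0:
        raise ValueError("mu must be nonzero")
    z = norm.ppf(1.0 - alpha) + norm.ppf(power)
    n_cont = 2.0 * (endpoint.sigma * z / mu) ** 2
    n = math.ceil(n_cont - 1e-9)
    # guard against floating-point slack at the boundary
    while 1.0 - beta_at_alpha(n, alpha, mu, endpoint) < power:
        n += 1
    return n
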