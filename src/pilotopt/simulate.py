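"""Seeded Monte Carlo execution of whole trial programmes.

Draws true effects from the prior (or fixes them), simulates the stage
statistics, applies the decision rules, and averages realised utilities —
an independent check of every analytic expected-utility and operating-
characteristic computation in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .expected_utility import EffectPrior, ProgrammeDesign, Scenario
from .extensions import BivariateEffectPrior
from .utility import utility_from_value


@dataclass(frozen=True)
class SimulationResult:
    mean_utility: float
    se: float
    branch_freqs: dict
    n_sims: int
    seed: int
    final_positive_rate: float
    fixed_mu: float | None = None


def simulate_programme(
    z: ProgrammeDesign,
    scenario: Scenario,
    n_sims: int,
    seed: int,
    fixed_mu: float | None = None,
) -> SimulationResult:
    """Simulate ``n_sims`` runs of the programme; reproducible given ``seed``.

    With ``fixed_mu`` the true definitive effect is held fixed (the pilot
    effect, under a bivariate prior, is drawn from its conditional
    distribution), so the final-positive rate estimates alpha_t (at 0) or
    1 - beta_t (at the alternative).  Otherwise effects are drawn from the
    prior and the mean realised utility estimates the prior expected
    utility.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    prior = scenario.prior
    sigma = scenario.endpoint.sigma

    if isinstance(prior, BivariateEffectPrior):
        if z.pilot_type != "external":
            raise ValueError("bivariate effect priors support external pilots only")
        if fixed_mu is None:
            zz = rng.standard_normal((2, n_sims))
            mu = prior.m + prior.s * zz[0]
            mu_p = prior.mp + prior.sp * (
                prior.tau * zz[0] + math.sqrt(1.0 - prior.tau**2) * zz[1]
            )
        else:
            mu = np.full(n_sims, float(fixed_mu))
            if prior.s == 0 and prior.tau != 0:
                raise ValueError("conditional on mu undefined: s = 0 with tau != 0")
            slope = prior.tau * prior.sp / prior.s if prior.tau != 0 else 0.0
            cond_sd = prior.sp * math.sqrt(1.0 - prior.tau**2)
            mu_p = (
                prior.mp
                + slope * (mu - prior.m)
                + cond_sd * rng.standard_normal(n_sims)
            )
    elif isinstance(prior, EffectPrior):
        if fixed_mu is None:
            mu = prior.m + prior.s * rng.standard_normal(n_sims)
        else:
            mu = np.full(n_sims, float(fixed_mu))
        mu_p = mu
    else:
        raise TypeError(f"unsupported prior type {type(prior)!r}")

    if z.n1 > 0:
        x1 = rng.normal(mu_p, sigma * math.sqrt(2.0 / z.n1))
        g1 = x1 > z.c1
    else:
        x1 = np.zeros(n_sims)
        g1 = np.ones(n_sims, dtype=bool)

    if z.n2 > 0:
        x2 = rng.normal(mu, sigma * math.sqrt(2.0 / z.n2))
    else:
        x2 = np.zeros(n_sims)
    if z.pilot_type == "internal":
        nt = z.n1 + z.n2
        xt = (z.n1 * x1 + z.n2 * x2) / nt
        g2 = xt > z.c2
    else:
        g2 = x2 > z.c2 if z.n2 > 0 else np.ones(n_sims, dtype=bool)

    w = scenario.utility.weights
    nt = z.total_n()
    v = np.where(
        g1 & g2,
        w.kn * nt + w.kd * mu,
        np.where(g1, w.kn * nt + w.kb, w.kn * z.n1 + w.kb),
    )
    u = utility_from_value(v, scenario.utility.rho)
    mean = float(np.mean(u))
    se = float(np.std(u, ddof=1) / math.sqrt(n_sims)) if n_sims > 1 else float("nan")
    freq = {
        "adopt": float(np.mean(g1 & g2)),
        "definitive_negative": float(np.mean(g1 & ~g2)),
        "pilot_negative": float(np.mean(~g1)),
    }
    return SimulationResult(
        mean_utility=mean,
        se=se,
        branch_freqs=freq,
        n_sims=n_sims,
        seed=seed,
        final_positive_rate=freq["adopt"],
        fixed_mu=fixed_mu,
    )
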