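"""Regret analysis of a fixed proposed design under perturbed assumptions.

A design chosen as optimal for one set of prior and utility parameters is
evaluated against the *locally* optimal design for perturbed parameters.
The expected-utility shortfall is translated into participant-equivalent
units (the *regret*) through the utility-to-value transform and the
per-participant weight of the perturbed scenario, so each cell of a regret
surface is self-contained: both expected utilities, the conversion, and the
local optimum all use the perturbed parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .expected_utility import EffectPrior, ProgrammeDesign, Scenario
from .extensions import programme_expected_utility
from .optimise import Constraints, OptimalProgramme, optimise
from .utility import (
    ElicitationInputs,
    UtilityParams,
    derive_weights,
    regret_in_participants,
)

_REGRET_FLOOR = -1e-6


@dataclass(frozen=True)
class RegretCell:
    """Regret of a proposed design at one point of the parameter grid."""

    params: dict
    regret: float
    local_optimum: ProgrammeDesign
    eu_optimal: float
    eu_proposed: float


def regret_at(
    proposed: ProgrammeDesign,
    perturbed_scenario: Scenario,
    constraints: Constraints | None = None,
    params: dict | None = None,
    warm_start: ProgrammeDesign | None = None,
) -> RegretCell:
    """Participant-equivalent regret of ``proposed`` under a perturbed scenario.

    Optimises the programme design under the perturbed scenario, evaluates
    the proposed design under the same scenario, and converts the EU gap to
    participants with the perturbed utility parameters.  Small negative gaps
    (within the 1e-6 numerical floor) are clipped to zero.
    """
    extra = [proposed] + ([warm_start] if warm_start is not None else [])
    opt: OptimalProgramme = optimise(perturbed_scenario, constraints, extra_starts=extra)
    eu_prop = programme_expected_utility(proposed, perturbed_scenario)
    eu_best = max(opt.expected_utility, eu_prop)
    regret = regret_in_participants(eu_best, eu_prop, perturbed_scenario.utility)
    if regret < _REGRET_FLOOR:  # pragma: no cover - guarded by the max above
        raise RuntimeError(f"negative regret {regret}: optimiser failure")
    return RegretCell(
        params=dict(params or {}),
        regret=max(regret, 0.0),
        local_optimum=opt.design,
        eu_optimal=opt.expected_utility,
        eu_proposed=eu_prop,
    )


def perturb_scenario(
    base: Scenario, elicitation: ElicitationInputs, **changes
) -> Scenario:
    """Rebuild a scenario with perturbed parameters.

    Recognised keys: ``m``, ``s`` (prior), ``rho`` (risk attitude) and
    ``d_bar`` (sampling cost, which re-derives the value weights from the
    elicited inputs).  Only univariate-prior scenarios are supported.
    """
    prior = base.prior
    if not isinstance(prior, EffectPrior):
        raise TypeError("perturb_scenario supports univariate priors only")
    util = base.utility
    unknown = set(changes) - {"m", "s", "rho", "d_bar"}
    if unknown:
        raise ValueError(f"unknown perturbation parameters: {sorted(unknown)}")
    if "m" in changes or "s" in changes:
        prior = replace(
            prior, m=changes.get("m", prior.m), s=changes.get("s", prior.s)
        )
    if "d_bar" in changes:
        weights = derive_weights(replace(elicitation, d_bar=changes["d_bar"]))
        util = UtilityParams(weights=weights, rho=util.rho)
    if "rho" in changes:
        util = replace(util, rho=changes["rho"])
    return replace(base, prior=prior, utility=util)


def regret_surface(
    proposed: ProgrammeDesign,
    base_scenario: Scenario,
    elicitation: ElicitationInputs,
    param1: str,
    values1,
    param2: str,
    values2,
    constraints: Constraints | None = None,
) -> pd.DataFrame:
    """Regret of ``proposed`` over a 2-D grid of prior/utility parameters.

    Cells are visited in row-major order and warm-started from the previous
    cell's local optimum.  Returns a long-format frame with one row per cell
    (columns: the two parameters, regret, and the local optimum's n1, n2,
    alpha1, alpha2), suitable for contour plotting.
    """
    rows = []
    warm: ProgrammeDesign | None = None
    for v1 in values1:
        for v2 in values2:
            params = {param1: float(v1), param2: float(v2)}
            sc = perturb_scenario(base_scenario, elicitation, **params)
            cell = regret_at(proposed, sc, constraints, params=params, warm_start=warm)
            warm = cell.local_optimum
            a1, a2 = cell.local_optimum.alphas(sc.endpoint)
            rows.append(
                {
                    param1: float(v1),
                    param2: float(v2),
                    "regret": cell.regret,
                    "n1": cell.local_optimum.n1,
                    "n2": cell.local_optimum.n2,
                    "alpha1": a1,
                    "alpha2": a2,
                    "eu_optimal": cell.eu_optimal,
                    "eu_proposed": cell.eu_proposed,
                }
            )
    return pd.DataFrame(rows)
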