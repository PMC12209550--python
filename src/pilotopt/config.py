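"""Scenario/constraint configuration: YAML schema, validation, round-trip.

A run config has two blocks::

    scenario:
      endpoint: {sigma: 1.5}
      prior: {kind: univariate, m: 0.0, s: 0.6}        # or kind: bivariate
      utility: {d_bar: 0.005, d_hat: 0.3, n_star: 50, rho: 2.0}
      mu_star: 0.5            # optional, for operating characteristics
      quadrature_nodes: 150   # optional
    constraints:              # optional block, all keys optional
      n1_min: 30
      pilot_type: external

The risk attitude may be given directly (``rho``) or through the certainty
equivalent of a 50/50 gamble (``gamble: {d_min, d_max, ce}``).  Unknown keys
are rejected with an error naming the offending key.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .expected_utility import DEFAULT_NODES, EffectPrior, Scenario
from .extensions import BivariateEffectPrior
from .frequentist import Endpoint
from .optimise import Constraints
from .utility import (
    ElicitationInputs,
    GambleSpec,
    UtilityParams,
    derive_weights,
    rho_from_gamble,
)


class ConfigError(ValueError):
    """Raised for malformed or incomplete run configurations."""


@dataclass(frozen=True)
class RunConfig:
    """A validated scenario plus design constraints."""

    scenario: Scenario
    constraints: Constraints
    elicitation: ElicitationInputs


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    if not isinstance(block, dict):
        raise ConfigError(f"'{where}' must be a mapping")
    for key in block:
        if key not in allowed:
            raise ConfigError(f"unknown key '{key}' in '{where}'")


def _require(block: dict, key: str, where: str):
    if key not in block:
        raise ConfigError(f"missing key '{key}' in '{where}'")
    return block[key]


def parse_config(raw: dict) -> RunConfig:
    """Validate a raw mapping and assemble the scenario and constraints."""
    if not raw:
        raise ConfigError("empty configuration")
    _check_keys(raw, {"scenario", "constraints"}, "config")
    sc_block = _require(raw, "scenario", "config")
    _check_keys(
        sc_block,
        {"endpoint", "prior", "utility", "mu_star", "quadrature_nodes"},
        "scenario",
    )

    ep_block = _require(sc_block, "endpoint", "scenario")
    _check_keys(ep_block, {"sigma"}, "scenario.endpoint")
    endpoint = Endpoint(sigma=float(_require(ep_block, "sigma", "scenario.endpoint")))

    pr = _require(sc_block, "prior", "scenario")
    kind = pr.get("kind", "univariate")
    if kind == "univariate":
        _check_keys(pr, {"kind", "m", "s"}, "scenario.prior")
        prior = EffectPrior(
            m=float(_require(pr, "m", "scenario.prior")),
            s=float(_require(pr, "s", "scenario.prior")),
        )
    elif kind == "bivariate":
        _check_keys(pr, {"kind", "mp", "sp", "m", "s", "tau"}, "scenario.prior")
        prior = BivariateEffectPrior(
            mp=float(_require(pr, "mp", "scenario.prior")),
            sp=float(_require(pr, "sp", "scenario.prior")),
            m=float(_require(pr, "m", "scenario.prior")),
            s=float(_require(pr, "s", "scenario.prior")),
            tau=float(_require(pr, "tau", "scenario.prior")),
        )
    else:
        raise ConfigError(f"unknown prior kind '{kind}' in 'scenario.prior'")

    ut = _require(sc_block, "utility", "scenario")
    _check_keys(ut, {"d_bar", "d_hat", "n_star", "rho", "gamble"}, "scenario.utility")
    elicitation = ElicitationInputs(
        d_bar=float(_require(ut, "d_bar", "scenario.utility")),
        d_hat=float(_require(ut, "d_hat", "scenario.utility")),
        n_star=float(_require(ut, "n_star", "scenario.utility")),
    )
    if ("rho" in ut) == ("gamble" in ut):
        raise ConfigError("'scenario.utility' needs exactly one of 'rho' or 'gamble'")
    if "rho" in ut:
        rho = float(ut["rho"])
    else:
        gb = ut["gamble"]
        _check_keys(gb, {"d_min", "d_max", "ce"}, "scenario.utility.gamble")
        rho = rho_from_gamble(
            GambleSpec(
                d_min=float(_require(gb, "d_min", "scenario.utility.gamble")),
                d_max=float(_require(gb, "d_max", "scenario.utility.gamble")),
                certainty_equivalent=float(_require(gb, "ce", "scenario.utility.gamble")),
            )
        )
    utility = UtilityParams(weights=derive_weights(elicitation), rho=rho)

    scenario = Scenario(
        endpoint=endpoint,
        prior=prior,
        utility=utility,
        quadrature_nodes=int(sc_block.get("quadrature_nodes", DEFAULT_NODES)),
        mu_star=(float(sc_block["mu_star"]) if "mu_star" in sc_block else None),
    )

    cons_block = raw.get("constraints", {}) or {}
    _check_keys(
        cons_block,
        {"n1_min", "n1_max", "n2_min", "n2_max", "no_pilot_test", "pilot_type"},
        "constraints",
    )
    constraints = Constraints(
        n1_min=int(cons_block.get("n1_min", 0)),
        n1_max=int(cons_block.get("n1_max", 1000)),
        n2_min=int(cons_block.get("n2_min", 0)),
        n2_max=int(cons_block.get("n2_max", 1000)),
        no_pilot_test=bool(cons_block.get("no_pilot_test", False)),
        pilot_type=str(cons_block.get("pilot_type", "external")),
    )
    return RunConfig(scenario=scenario, constraints=constraints, elicitation=elicitation)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise ConfigError(f"empty configuration file: {path}")
    return parse_config(raw)


def dump_config(cfg: RunConfig) -> dict:
    """Serialise a run config back to its mapping form (defaults filled)."""
    prior = cfg.scenario.prior
    if isinstance(prior, BivariateEffectPrior):
        prior_block = {
            "kind": "bivariate",
            "mp": prior.mp,
            "sp": prior.sp,
            "m": prior.m,
            "s": prior.s,
            "tau": prior.tau,
        }
    else:
        prior_block = {"kind": "univariate", "m": prior.m, "s": prior.s}
    e = cfg.elicitation
    sc: dict = {
        "endpoint": {"sigma": cfg.scenario.endpoint.sigma},
        "prior": prior_block,
        "utility": {
            "d_bar": e.d_bar,
            "d_hat": e.d_hat,
            "n_star": e.n_star,
            "rho": cfg.scenario.utility.rho,
        },
        "quadrature_nodes": cfg.scenario.quadrature_nodes,
    }
    if cfg.scenario.mu_star is not None:
        sc["mu_star"] = cfg.scenario.mu_star
    c = cfg.constraints
    return {
        "scenario": sc,
        "constraints": {
            "n1_min": c.n1_min,
            "n1_max": c.n1_max,
            "n2_min": c.n2_min,
            "n2_max": c.n2_max,
            "no_pilot_test": c.no_pilot_test,
            "pilot_type": c.pilot_type,
        },
    }


def ok_diabetes_path() -> Path:
    """Path to the bundled OK-Diabetes worked-example configuration."""
    return Path(resources.files("pilotopt").joinpath("data/ok_diabetes.yaml"))


def ok_diabetes_config() -> RunConfig:
    """The OK-Diabetes worked example: sigma=1.5, N(0, 0.6^2) prior,
    d_bar=0.005, d_hat=0.3, n_star=50, rho=2, mu_star=0.5, n1 >= 30."""
    return load_config(ok_diabetes_path())
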