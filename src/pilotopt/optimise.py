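"""Expected-utility maximisation over programme designs.

The design space is (n1, c1, n2, c2) with integer per-arm sample sizes.  The
continuous relaxation is optimised by multi-start box-constrained L-BFGS-B on
transformed variables — log sample sizes and logit stage-level type I error
rates (the critical values are recovered from the alphas given sigma) — and
the integer neighbourhood of the continuous optimum is then enumerated with
the critical values re-optimised for each candidate.

Degenerate boundary designs cannot be reached on the log scale and are
treated as explicit candidate sub-problems:

* pilot-only programmes (n2 = 0, alpha2 = 1),
* "no pilot test" programmes (alpha1 = 1, n1 fixed at its lower bound),
* run-nothing programmes (adopt immediately, or retain control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .expected_utility import (
    ProgrammeDesign,
    Scenario,
    operating_characteristics,
)
from .extensions import BivariateEffectPrior, programme_expected_utility
from .frequentist import OperatingCharacteristics

_ALPHA_LOGIT_BOUND = 12.0  # alpha in (about 6e-6, 1 - 6e-6)
_ALPHA_GRID = (0.05, 0.3, 0.7, 0.95)
_TIE_TOL = 1e-10


@dataclass(frozen=True)
class Constraints:
    """Box constraints and structural restrictions on the design."""

    n1_min: int = 0
    n1_max: int = 1000
    n2_min: int = 0
    n2_max: int = 1000
    no_pilot_test: bool = False
    pilot_type: str = "external"

    def __post_init__(self) -> None:
        if not 0 <= self.n1_min <= self.n1_max:
            raise ValueError("require 0 <= n1_min <= n1_max")
        if not 0 <= self.n2_min <= self.n2_max:
            raise ValueError("require 0 <= n2_min <= n2_max")
        if self.pilot_type not in ("external", "internal"):
            raise ValueError(f"unknown pilot_type {self.pilot_type!r}")


@dataclass
class OptimalProgramme:
    """An optimised programme: design, its EU, OCs, and solver diagnostics."""

    design: ProgrammeDesign
    expected_utility: float
    oc: OperatingCharacteristics | None
    diagnostics: dict = field(default_factory=dict)


class OptimisationFailure(RuntimeError):
    """All optimisation starts failed to converge."""


def _make_design(
    n1: float, a1: float, n2: float, a2: float, scenario: Scenario, pilot_type: str
) -> ProgrammeDesign:
    return ProgrammeDesign.from_alphas(n1, a1, n2, a2, scenario.endpoint, pilot_type)


def _neg_eu(design: ProgrammeDesign, scenario: Scenario) -> float:
    try:
        return -programme_expected_utility(design, scenario)
    except (ValueError, FloatingPointError):  # pragma: no cover - guard rail
        return np.inf


class _Candidate:
    """A sub-problem with a fixed structure and free transformed variables.

    ``kind`` is one of "full" (both stages active), "pilot_only" (n2 = 0,
    alpha2 = 1) and "no_pilot" (alpha1 = 1, n1 pinned at the lower bound).
    """

    def __init__(self, kind: str, scenario: Scenario, cons: Constraints):
        self.kind = kind
        self.scenario = scenario
        self.cons = cons
        self.pilot_type = cons.pilot_type
        n1_lo = max(cons.n1_min, 1)
        n2_lo = max(cons.n2_min, 1)
        ab = _ALPHA_LOGIT_BOUND
        if kind == "full":
            self.bounds = [
                (math.log(n1_lo), math.log(cons.n1_max)),
                (-ab, ab),
                (math.log(n2_lo), math.log(cons.n2_max)),
                (-ab, ab),
            ]
        elif kind == "pilot_only":
            self.bounds = [(math.log(n1_lo), math.log(cons.n1_max)), (-ab, ab)]
        elif kind == "no_pilot":
            self.n1_fixed = cons.n1_min if cons.pilot_type == "external" else max(cons.n1_min, 1)
            self.bounds = [(math.log(n2_lo), math.log(cons.n2_max)), (-ab, ab)]
        else:  # pragma: no cover
            raise ValueError(kind)

    def design(self, x: np.ndarray) -> ProgrammeDesign:
        sc, pt = self.scenario, self.pilot_type
        if self.kind == "full":
            return _make_design(math.exp(x[0]), expit(x[1]), math.exp(x[2]), expit(x[3]), sc, pt)
        if self.kind == "pilot_only":
            return _make_design(math.exp(x[0]), expit(x[1]), 0.0, 1.0, sc, pt)
        return _make_design(self.n1_fixed, 1.0, math.exp(x[0]), expit(x[1]), sc, pt)

    def objective(self, x: np.ndarray) -> float:
        return _neg_eu(self.design(x), self.scenario)

    def starts(self, n_hints: dict, extra_designs: list[ProgrammeDesign]) -> list[np.ndarray]:
        lo1 = max(self.cons.n1_min, 1)
        lo2 = max(self.cons.n2_min, 1)
        n1s = [min(max(v, lo1), self.cons.n1_max) for v in n_hints["n1"]]
        n2s = [min(max(v, lo2), self.cons.n2_max) for v in n_hints["n2"]]
        pts: list[np.ndarray] = []
        if self.kind == "full":
            for i, a1 in enumerate(_ALPHA_GRID):
                for j, a2 in enumerate(_ALPHA_GRID):
                    for k in range(2):
                        pts.append(
                            np.array(
                                [
                                    math.log(n1s[(i + k) % 2]),
                                    logit(a1),
                                    math.log(n2s[(j + k) % 2]),
                                    logit(a2),
                                ]
                            )
                        )
        else:
            ns = n1s if self.kind == "pilot_only" else n2s
            for a in _ALPHA_GRID:
                for n in ns:
                    pts.append(np.array([math.log(n), logit(a)]))
        for d in extra_designs:
            pts.append(self._vector_from(d))
        return [np.clip(p, [b[0] for b in self.bounds], [b[1] for b in self.bounds]) for p in pts]

    def _vector_from(self, d: ProgrammeDesign) -> np.ndarray:
        a1, a2 = d.alphas(self.scenario.endpoint)
        cl = lambda a: float(np.clip(a, 1e-5, 1 - 1e-5))
        if self.kind == "full":
            return np.array(
                [math.log(max(d.n1, 1)), logit(cl(a1)), math.log(max(d.n2, 1)), logit(cl(a2))]
            )
        if self.kind == "pilot_only":
            return np.array([math.log(max(d.n1, 1)), logit(cl(a1))])
        return np.array([math.log(max(d.n2, 1)), logit(cl(a2))])

    def refine_integer(self, x_best: np.ndarray, radius: int = 2):
        """Enumerate the integer neighbourhood, re-optimising the alphas."""
        sc, pt = self.scenario, self.pilot_type
        out = []
        if self.kind == "full":
            n1c, n2c = math.exp(x_best[0]), math.exp(x_best[2])
            a_start = x_best[[1, 3]]
            for n1 in _int_window(n1c, max(self.cons.n1_min, 1), self.cons.n1_max, radius):
                for n2 in _int_window(n2c, max(self.cons.n2_min, 1), self.cons.n2_max, radius):
                    obj = lambda a, n1=n1, n2=n2: _neg_eu(
                        _make_design(n1, expit(a[0]), n2, expit(a[1]), sc, pt), sc
                    )
                    res = minimize(
                        obj,
                        a_start,
                        method="L-BFGS-B",
                        bounds=[(-_ALPHA_LOGIT_BOUND, _ALPHA_LOGIT_BOUND)] * 2,
                    )
                    out.append(
                        (_make_design(n1, expit(res.x[0]), n2, expit(res.x[1]), sc, pt), -res.fun)
                    )
        else:
            nc = math.exp(x_best[0])
            lo = max(self.cons.n1_min, 1) if self.kind == "pilot_only" else max(self.cons.n2_min, 1)
            hi = self.cons.n1_max if self.kind == "pilot_only" else self.cons.n2_max
            for n in _int_window(nc, lo, hi, radius):
                if self.kind == "pilot_only":
                    obj = lambda a, n=n: _neg_eu(_make_design(n, expit(a[0]), 0.0, 1.0, sc, pt), sc)
                    mk = lambda a, n=n: _make_design(n, expit(a[0]), 0.0, 1.0, sc, pt)
                else:
                    obj = lambda a, n=n: _neg_eu(
                        _make_design(self.n1_fixed, 1.0, n, expit(a[0]), sc, pt), sc
                    )
                    mk = lambda a, n=n: _make_design(self.n1_fixed, 1.0, n, expit(a[0]), sc, pt)
                res = minimize(
                    obj,
                    x_best[1:2],
                    method="L-BFGS-B",
                    bounds=[(-_ALPHA_LOGIT_BOUND, _ALPHA_LOGIT_BOUND)],
                )
                out.append((mk(res.x), -res.fun))
        return out


def _int_window(center: float, lo: int, hi: int, radius: int) -> list[int]:
    vals = range(math.floor(center) - radius, math.ceil(center) + radius + 1)
    return sorted({min(max(v, lo), hi) for v in vals})


def _degenerate_candidates(scenario: Scenario, cons: Constraints) -> list[ProgrammeDesign]:
    """Run-nothing designs: adopt immediately, or retain control outright."""
    out = []
    if cons.no_pilot_test or cons.pilot_type == "internal":
        return out
    if cons.n2_min == 0:
        n1 = cons.n1_min
        # adopt with no testing (any pilot data are ignored)
        out.append(ProgrammeDesign(n1, -math.inf, 0.0, -math.inf))
        # never adopt: stop after the mandatory pilot, or run nothing at all
        out.append(ProgrammeDesign(n1, math.inf, 0.0, -math.inf))
    return out


def _n_hints(scenario: Scenario, cons: Constraints) -> dict:
    from .frequentist import solve_sample_size

    mu_ref = scenario.mu_star
    if mu_ref is None or mu_ref == 0:
        prior = scenario.prior
        s = prior.s if hasattr(prior, "s") else 0.0
        m = prior.m
        mu_ref = abs(m) + s or 1.0
    try:
        n_conv = solve_sample_size(0.9, 0.025, mu_ref, scenario.endpoint)
    except ValueError:  # pragma: no cover
        n_conv = 100
    return {
        "n1": [max(cons.n1_min, 20), max(cons.n1_min, min(60, cons.n1_max))],
        "n2": [min(n_conv, cons.n2_max), max(1, min(n_conv // 2, cons.n2_max))],
    }


def optimise(
    scenario: Scenario,
    constraints: Constraints | None = None,
    extra_starts: list[ProgrammeDesign] | None = None,
    refine_radius: int = 2,
) -> OptimalProgramme:
    """Maximise expected utility over programme designs under constraints.

    Runs a deterministic multi-start L-BFGS-B over each structural candidate
    (both stages active; pilot-only; no pilot test), refines the integer
    sample-size neighbourhood of each continuous optimum with the critical
    values re-optimised, and returns the best design found.  Ties in EU
    (within 1e-10) prefer the smaller total sample size, then the smaller
    pilot.
    """
    cons = constraints or Constraints()
    if isinstance(scenario.prior, BivariateEffectPrior) and cons.pilot_type == "internal":
        raise ValueError("bivariate effect priors support external pilots only")
    extra = extra_starts or []
    hints = _n_hints(scenario, cons)

    kinds: list[str]
    if cons.no_pilot_test:
        kinds = ["no_pilot"]
    else:
        kinds = ["full"]
        if cons.n2_min == 0:
            kinds.append("pilot_only")
        kinds.append("no_pilot")

    evaluated: list[tuple[ProgrammeDesign, float]] = []
    n_starts = n_converged = 0
    for kind in kinds:
        cand = _Candidate(kind, scenario, cons)
        best_x, best_f = None, np.inf
        for x0 in cand.starts(hints, extra):
            n_starts += 1
            res = minimize(cand.objective, x0, method="L-BFGS-B", bounds=cand.bounds)
            if np.isfinite(res.fun):
                n_converged += 1
                if res.fun < best_f:
                    best_x, best_f = res.x, res.fun
        if best_x is None:
            continue
        evaluated.extend(cand.refine_integer(best_x, refine_radius))
    for d in _degenerate_candidates(scenario, cons):
        evaluated.append((d, -_neg_eu(d, scenario)))

    evaluated = [(d, eu) for d, eu in evaluated if np.isfinite(eu)]
    if not evaluated:
        raise OptimisationFailure(
            f"no start converged ({n_starts} starts over candidates {kinds})"
        )
    best_eu = max(eu for _, eu in evaluated)
    contenders = [(d, eu) for d, eu in evaluated if eu >= best_eu - _TIE_TOL]
    contenders.sort(key=lambda t: (t[0].total_n(), t[0].n1))
    design, eu = contenders[0]
    oc = None
    if scenario.mu_star is not None:
        oc = operating_characteristics(design, scenario.endpoint, scenario.mu_star)
    return OptimalProgramme(
        design=design,
        expected_utility=eu,
        oc=oc,
        diagnostics={
            "n_starts": n_starts,
            "n_converged": n_converged,
            "candidates": kinds,
            "n_refined": len(evaluated),
        },
    )


def optimise_internal(
    scenario: Scenario,
    constraints: Constraints | None = None,
    extra_starts: list[ProgrammeDesign] | None = None,
) -> OptimalProgramme:
    """Maximise EU over internal-pilot designs (pooled final analysis)."""
    cons = constraints or Constraints()
    if cons.pilot_type != "internal":
        cons = replace(cons, pilot_type="internal")
    return optimise(scenario, cons, extra_starts=extra_starts)


def rho_sweep(
    scenario: Scenario,
    rho_grid,
    constraints: Constraints | None = None,
) -> "pd.DataFrame":
    """Optimal programmes across a grid of risk attitudes ``rho``.

    Each point is warm-started from its neighbour's optimum in addition to
    the standard start grid; per-point failures are flagged, not fatal.
    """
    import pandas as pd

    rows = []
    prev: ProgrammeDesign | None = None
    for rho in rho_grid:
        sc = replace(scenario, utility=replace(scenario.utility, rho=float(rho)))
        rows.append(_sweep_row({"rho": float(rho)}, sc, constraints, prev))
        prev = rows[-1].pop("_design")
    return pd.DataFrame(rows)


def tau_sweep(
    scenario: Scenario,
    tau_grid,
    constraints: Constraints | None = None,
) -> "pd.DataFrame":
    """Optimal programmes across a grid of pilot/definitive correlations."""
    import pandas as pd

    prior = scenario.prior
    if not isinstance(prior, BivariateEffectPrior):
        raise TypeError("tau_sweep requires a BivariateEffectPrior template")
    rows = []
    prev: ProgrammeDesign | None = None
    for tau in tau_grid:
        sc = replace(scenario, prior=replace(prior, tau=float(tau)))
        rows.append(_sweep_row({"tau": float(tau)}, sc, constraints, prev))
        prev = rows[-1].pop("_design")
    return pd.DataFrame(rows)


def _sweep_row(
    params: dict, sc: Scenario, constraints: Constraints | None, prev: ProgrammeDesign | None
) -> dict:
    row = dict(params)
    try:
        opt = optimise(sc, constraints, extra_starts=[prev] if prev is not None else None)
    except OptimisationFailure as exc:  # pragma: no cover - defensive
        row.update(converged=False, error=str(exc), _design=prev)
        return row
    d = opt.design
    a1, a2 = d.alphas(sc.endpoint)
    row.update(
        n1=d.n1,
        n2=d.n2,
        alpha1=a1,
        alpha2=a2,
        eu=opt.expected_utility,
        converged=True,
        _design=d,
    )
    if opt.oc is not None:
        row.update(
            beta1=opt.oc.beta1, beta2=opt.oc.beta2, alpha_t=opt.oc.alpha_t, beta_t=opt.oc.beta_t
        )
    return row
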