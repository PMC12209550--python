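"""Value and utility functions for two-arm trial programmes.

The decision-maker's preferences over a completed pilot/definitive trial
programme are summarised by three attributes:

* ``n`` — the total per-arm sample size across both stages (n1 + n2),
* ``d`` — the realised change in mean outcome (the true effect ``mu`` if the
  intervention is adopted, 0 otherwise),
* ``b`` — an indicator equal to 1 if the control treatment is retained and
  0 if the intervention is adopted.

Preferences under certainty are encoded by an additive *value* function

    v(n, d, b) = kn * n + kd * d + kb * b,

whose weights are derived from two elicited quantities: ``d_bar``, the change
in mean outcome that would justify increasing the total sample size from 0 to
a reference size ``n_star``; and ``d_hat``, the change in mean outcome that
would justify switching from control to the intervention.  Attitude to risk
is layered on top through an exponential (constant absolute risk aversion)
transform with parameter ``rho``: risk-averse for ``rho > 0``, risk-neutral
(utility equals value) at ``rho = 0``, risk-seeking for ``rho < 0``.  The
``rho`` parameter can be pinned down from the certainty equivalent of a 50/50
gamble over the effect attribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq


class InvalidElicitationError(ValueError):
    """Raised when elicited inputs violate their constraints."""


@dataclass(frozen=True)
class ElicitationInputs:
    """Elicited quantities pinning down the value-function weights.

    Parameters
    ----------
    d_bar : float
        Change in mean outcome justifying a total sample-size increase from
        0 to ``n_star`` (effect units; must be positive).
    d_hat : float
        Change in mean outcome justifying switching from control to the
        intervention (effect units; negative values express a non-inferiority
        framing).
    n_star : float
        Reference total sample size used in the sampling-cost elicitation
        (participants; must be positive).
    """

    d_bar: float
    d_hat: float
    n_star: float

    def __post_init__(self) -> None:
        if not self.d_bar > 0:
            raise InvalidElicitationError(f"d_bar must be > 0, got {self.d_bar}")
        if not self.n_star > 0:
            raise InvalidElicitationError(f"n_star must be > 0, got {self.n_star}")


@dataclass(frozen=True)
class Weights:
    """Additive value-function weights (kn <= 0 is the sampling cost)."""

    kd: float
    kn: float
    kb: float


@dataclass(frozen=True)
class UtilityParams:
    """Value weights together with the risk-attitude parameter ``rho``."""

    weights: Weights
    rho: float


@dataclass(frozen=True)
class GambleSpec:
    """A 50/50 gamble over the effect attribute and its certainty equivalent.

    The decision-maker faces a gamble paying ``d_min`` or ``d_max`` with
    probability one half each (on the raw effect-change scale, with no
    sampling and the intervention adopted) and states the sure effect change
    ``certainty_equivalent`` they judge equally desirable.
    """

    d_min: float
    d_max: float
    certainty_equivalent: float

    def __post_init__(self) -> None:
        if not self.d_min < self.d_max:
            raise InvalidElicitationError("require d_min < d_max")


@dataclass(frozen=True)
class AttributeRealisation:
    """A terminal programme outcome: (total per-arm n, realised d, retain b)."""

    n: float
    d: float
    b: int

    def __post_init__(self) -> None:
        if self.b not in (0, 1):
            raise ValueError(f"b must be 0 or 1, got {self.b}")
        if self.b == 1 and self.d != 0:
            raise ValueError("d must be 0 when the control is retained (b=1)")


def derive_weights(e: ElicitationInputs) -> Weights:
    """Derive the value-function weights from elicited quantities.

    The weights satisfy ``kd = 1/(1 + d_hat - d_bar/n_star)``,
    ``kn = -kd * d_bar / n_star`` and ``kb = 1 - kd - kn * d_hat``, which
    normalises the value of adopting an intervention with effect ``d_hat``
    at zero sample size to equal the value of retaining control.
    """
    denom = 1.0 + e.d_hat - e.d_bar / e.n_star
    if denom <= 0:
        raise InvalidElicitationError(
            "require 1 + d_hat - d_bar/n_star > 0 so the effect weight is positive"
        )
    kd = 1.0 / denom
    kn = -kd * e.d_bar / e.n_star
    kb = 1.0 - kd - kn * e.d_hat
    return Weights(kd=kd, kn=kn, kb=kb)


def value(a: AttributeRealisation, w: Weights) -> float:
    """Additive value ``kn*n + kd*d + kb*b`` of a terminal outcome."""
    return w.kn * a.n + w.kd * a.d + w.kb * a.b


def utility_from_value(v, rho: float):
    """Map value to utility through the exponential risk transform.

    ``rho > 0``: ``1 - exp(-rho*v)``; ``rho = 0``: ``v`` (linear branch,
    handled explicitly); ``rho < 0``: ``-1 + exp(-rho*v)``.  Strictly
    increasing in ``v`` for every ``rho``, with ``utility(0) = 0``.
    Vectorised over ``v``.
    """
    v = np.asarray(v, dtype=float)
    if rho > 0:
        out = 1.0 - np.exp(-rho * v)
    elif rho < 0:
        out = -1.0 + np.exp(-rho * v)
    else:
        out = v.copy()
    return out if out.ndim else float(out)


def utility(a: AttributeRealisation, p: UtilityParams) -> float:
    """Utility of a terminal programme outcome."""
    return utility_from_value(value(a, p.weights), p.rho)


def utility_to_value(u, rho: float):
    """Invert the risk transform, mapping utility back to the value scale.

    Raises ``ValueError`` when ``u`` lies outside the transform's range
    (``u >= 1`` for ``rho > 0``; ``u <= -1`` for ``rho < 0``).
    """
    u = np.asarray(u, dtype=float)
    if rho > 0:
        if np.any(u >= 1.0):
            raise ValueError("utility must be < 1 for rho > 0")
        out = -np.log1p(-u) / rho
    elif rho < 0:
        if np.any(u <= -1.0):
            raise ValueError("utility must be > -1 for rho < 0")
        out = -np.log1p(u) / rho
    else:
        out = u.copy()
    return out if out.ndim else float(out)


def certainty_equivalent(rho: float, d_min: float, d_max: float) -> float:
    """Certainty equivalent of the 50/50 gamble between d_min and d_max.

    Both exponential branches reduce to the same condition
    ``exp(-rho*ce) = (exp(-rho*d_min) + exp(-rho*d_max)) / 2``, so

        ce(rho) = -(1/rho) * log( (e^{-rho d_min} + e^{-rho d_max}) / 2 )

    with the arithmetic midpoint as the ``rho = 0`` limit.  Strictly
    decreasing in ``rho``; computed through logaddexp for stability.
    """
    if rho == 0.0:
        return 0.5 * (d_min + d_max)
    log_mean = np.logaddexp(-rho * d_min, -rho * d_max) - np.log(2.0)
    return float(-log_mean / rho)


def rho_from_gamble(g: GambleSpec, bracket: float = 50.0, tol: float = 1e-12) -> float:
    """Solve for the risk-attitude ``rho`` implied by a stated gamble.

    Finds the root of ``certainty_equivalent(rho) = g.certainty_equivalent``
    by bisection (Brent) on an expanding bracket.  The certainty equivalent
    is strictly decreasing in ``rho`` with range ``(d_min, d_max)``, so the
    root is unique; a stated equivalent at the midpoint gives ``rho = 0``
    exactly.
    """
    ce = g.certainty_equivalent
    if not (g.d_min < ce < g.d_max):
        raise InvalidElicitationError(
            f"certainty equivalent {ce} must lie strictly between "
            f"d_min={g.d_min} and d_max={g.d_max}"
        )
    mid = 0.5 * (g.d_min + g.d_max)
    if ce == mid:
        return 0.0

    def f(rho: float) -> float:
        return certainty_equivalent(rho, g.d_min, g.d_max) - ce

    lo, hi = -bracket, bracket
    # ce decreasing in rho: f(lo) > 0 > f(hi) once the bracket is wide enough
    for _ in range(60):
        if f(lo) > 0 and f(hi) < 0:
            break
        lo *= 2.0
        hi *= 2.0
    else:  # pragma: no cover - unreachable for valid gambles
        raise InvalidElicitationError("failed to bracket rho")
    return float(brentq(f, lo, hi, xtol=tol, rtol=8.9e-16))


def regret_in_participants(u_best: float, u_alt: float, p: UtilityParams) -> float:
    """Express a utility shortfall in participant-equivalent units.

    Both utilities are translated back to the value scale and the difference
    divided by the per-participant cost ``|kn|``: the number of participants
    whose sampling cost has the same value as the gap between the two
    programmes.  Requires ``u_best >= u_alt``.
    """
    if u_best < u_alt - 1e-12:
        raise ValueError("u_best must be at least u_alt")
    dv = utility_to_value(u_best, p.rho) - utility_to_value(u_alt, p.rho)
    return float(dv / abs(p.weights.kn))
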