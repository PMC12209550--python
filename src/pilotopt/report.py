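"""Tabular reports of optimised programmes.

Renders one row per optimised programme with the published table layout:
sample sizes, stage-level error rates at the stated alternative, overall
rates, and expected utility.  Probabilities are printed to 3 decimals and
expected utilities to 5.
"""

from __future__ import annotations

import pandas as pd

from .frequentist import Endpoint
from .optimise import OptimalProgramme

_PROB_COLS = ["alpha1", "beta1", "alpha2", "beta2", "alpha_t", "beta_t"]


def results_table(
    results: list[tuple[str, OptimalProgramme]], endpoint: Endpoint
) -> pd.DataFrame:
    """One row per labelled programme, in the published column layout."""
    if not results:
        raise ValueError("no results to report")
    rows = []
    for label, opt in results:
        d = opt.design
        a1, a2 = d.alphas(endpoint)
        row = {
            "problem": label,
            "pilot_type": d.pilot_type,
            "n1": int(round(d.n1)),
            "n2": int(round(d.n2)),
            "alpha1": a1,
            "alpha2": a2,
            "eu": opt.expected_utility,
        }
        if opt.oc is not None:
            row.update(
                beta1=opt.oc.beta1,
                beta2=opt.oc.beta2,
                alpha_t=opt.oc.alpha_t,
                beta_t=opt.oc.beta_t,
            )
        rows.append(row)
    cols = ["problem", "pilot_type", "n1", "n2", "alpha1", "beta1", "alpha2", "beta2", "alpha_t", "beta_t", "eu"]
    df = pd.DataFrame(rows)
    return df[[c for c in cols if c in df.columns]]


def format_table(df: pd.DataFrame) -> str:
    """Aligned text rendering: probabilities to 3 decimals, EU to 5."""
    if df.empty:
        raise ValueError("no results to report")
    shown = df.copy()
    for col in _PROB_COLS:
        if col in shown.columns:
            shown[col] = shown[col].map(lambda v: f"{v:.3f}")
    if "eu" in shown.columns:
        shown["eu"] = shown["eu"].map(lambda v: f"{v:.5f}")
    return shown.to_string(index=False)
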