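# pilotopt

Bayesian decision-theoretic design of pilot and definitive trial programmes.

## The problem

External pilot trials usually avoid testing effectiveness: at conventional
significance levels a small pilot has hopeless power, so an effective
intervention risks being discarded. But nothing forces a pilot test to use a
conventional level — not testing at all is simply the extreme choice
α₁ = 1, β₁ = 0, and between that extreme and α₁ = 0.025 lies a trade-off
that should be *optimised*, not assumed away.

`pilotopt` frames the joint design of a two-arm pilot (stage 1) and
definitive trial (stage 2) — normal endpoint, known SD σ, one-sided z-tests
of the mean difference x_i against critical values c_i — as expected-utility
maximisation over the design z = (n₁, c₁, n₂, c₂). The terminal outcomes of
a programme are summarised by three attributes: the total per-arm sample
size n, the realised change in mean outcome d, and an indicator b of
retaining control. Preferences are encoded by

    v(n, d, b) = kₙ·n + k_d·d + k_b·b,
    u = 1 − exp(−ρ·v)   (ρ > 0; linear at ρ = 0; −1 + exp(−ρ·v) for ρ < 0),

with the weights derived from two elicited quantities (d̄, the effect change
worth a sample-size increase from 0 to n*; d̂, the effect change worth
switching treatments) and the risk attitude ρ pinned down by the certainty
equivalent of a 50/50 gamble. Uncertainty about the true effect μ is a
normal prior N(m, s²); expected utility integrates the three programme
branches (adopt / stop after the definitive trial / stop after the pilot)
over this prior by Gauss–Hermite quadrature, and a multi-start quasi-Newton
optimiser with integer refinement maximises it.

Beyond external pilots the package covers:

* **internal pilots** — the pilot data re-enter the final pooled analysis;
  branch probabilities come from the bivariate normal of (x₁, x_t);
* **heterogeneous effects** — the pilot and definitive true effects are
  correlated (τ < 1) rather than identical, attenuating what the pilot says
  about the definitive trial;
* **regret analysis** — how many participants' worth of value a fixed design
  loses against the locally optimal design when the prior or utility
  parameters are perturbed;
* **Monte Carlo simulation** of whole programmes, as an independent check of
  every analytic quantity.

It is aimed at trial statisticians designing pilot/definitive programmes and
methodologists studying progression rules.

## Worked example

The bundled configuration (`pilotopt.ok_diabetes_path()`) re-designs
OK-Diabetes, a feasibility study of supported self-management in adults with
learning disabilities and type II diabetes: HbA1c change at six months with
σ = 1.5, target difference μ* = 0.5 (benefit coded positive), sceptical
prior N(0, 0.6²), elicited utility d̄ = 0.005, d̂ = 0.3, n* = 50, ρ = 2, and
a feasibility floor of 30 participants per arm in the pilot.

```sh
pilotopt design --config src/pilotopt/data/ok_diabetes.yaml --compare-no-pilot
```

prints

```
      problem pilot_type  n1  n2 alpha1 beta1 alpha2 beta2 alpha_t beta_t      eu
      optimal   external  41 146  0.387 0.111  0.041 0.133   0.016  0.229 0.42869
no pilot test   external  30 110  1.000 0.000  0.036 0.252   0.036  0.252 0.42287
```

The optimal programme tests effectiveness in the pilot at the decidedly
unconventional one-sided level α₁ ≈ 0.39: with 41 per arm that keeps pilot
power at 0.89 while screening out weak interventions, and the definitive
trial then runs 146 per arm at α₂ ≈ 0.041, for overall programme error rates
α_t = 0.016 and power 0.77 at μ* = 0.5. Forbidding the pilot test costs
0.00582 in expected utility, which the utility→value transform converts to
the sampling cost of about 66 participants:

```python
>>> import dataclasses
>>> import pilotopt as po
>>> cfg = po.ok_diabetes_config()
>>> best = po.optimise(cfg.scenario, cfg.constraints)
>>> worst = po.optimise(cfg.scenario, dataclasses.replace(cfg.constraints, no_pilot_test=True))
>>> po.regret_in_participants(best.expected_utility, worst.expected_utility, cfg.scenario.utility)
65.84658981481036
```

The same scenario with an internal pilot (`pilot_type: internal`) yields
n₁ = 45, n₂ = 121, α₁ ≈ 0.42 and a slightly higher expected utility 0.42949
(all data reach the final analysis); with pilot/definitive effect
correlation τ = 0.9 the optimal pilot shrinks to the feasibility floor and
its test relaxes to α₁ ≈ 0.69.

Other subcommands: `evaluate` (EU + operating characteristics of a stated
design), `simulate` (seeded Monte Carlo), `sweep-rho`, `sweep-tau`, and
`sensitivity` (regret surfaces as long-format CSV for contour plotting).

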