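# Methods

## Model

A programme has two stages run on the same two-arm comparison: a pilot
(stage 1, n₁ per arm) and a definitive trial (stage 2, n₂ per arm). The
primary endpoint is normal with known SD σ common to both arms, so each
stage's sample mean difference satisfies x_i | μ ~ N(μ, 2σ²/n_i). Stage i is
"positive" (G_i = 1) when x_i > c_i: a positive pilot means *proceed*, a
positive definitive trial means *adopt the intervention*. The design
variable is z = (n₁, c₁, n₂, c₂); the equivalent stage-level error-rate view
(α_i from the null, β_i at a stated alternative μ*) is derived from it given
σ. Overall, an external programme falsely adopts with probability
α_t = α₁α₂ and misses a true effect μ* with probability
β_t = β₁ + (1 − β₁)β₂.

Three terminal branches carry the utility attributes (n = n₁ + n₂ is the sum
of *per-arm* sizes, matching how the sampling-cost weight is elicited):

| branch | probability given μ | n | d | b |
|---|---|---|---|---|
| adopt | Pr[G₁=1, G₂=1 \| μ] | n₁+n₂ | μ | 0 |
| definitive negative | Pr[G₁=1, G₂=0 \| μ] | n₁+n₂ | 0 | 1 |
| pilot negative | Pr[G₁=0 \| μ] | n₁ | 0 | 1 |

Value is the additive v = kₙn + k_d d + k_b b with weights derived from the
elicited pair (d̄, n*) — the effect change justifying a sample-size increase
from 0 to n* — and d̂, the effect change justifying a switch of treatments:

    k_d = 1/(1 + d̂ − d̄/n*),  kₙ = −k_d·d̄/n*,  k_b = 1 − k_d − kₙ·d̂.

The elicitation requires 1 + d̂ − d̄/n* > 0 (a positive effect weight);
negative d̂ (non-inferiority framing) is allowed. Risk attitude enters
through the exponential (constant absolute risk aversion) transform
u = 1 − e^{−ρv} for ρ > 0, u = v at ρ = 0, u = −1 + e^{−ρv} for ρ < 0.
These branch forms are the conventional zero-anchored representatives of
their preference classes; they converge to the linear branch as ρ → 0 only
after the affine rescaling u/|ρ| (utilities are equivalence classes under
positive affine maps), which is how the continuity tests are stated. ρ = 0
is an explicit code branch, never a numerical limit.

ρ is elicited from a 50/50 gamble on the effect attribute alone (n = 0,
b = 0, no k_d weighting — the convention under which the reference
elicitation's certainty equivalent of 0.19 for a 0–0.5 gamble maps to
ρ = 2). Both exponential branches reduce the indifference condition to
e^{−ρ·ce} = (e^{−ρ·d_min} + e^{−ρ·d_max})/2, whose left side is strictly
monotone in ρ; the root is found by Brent's method on a bracket starting at
[−50, 50] and expanding geometrically, with the certainty-equivalent
function evaluated through `logaddexp` for stability. A certainty equivalent
at the midpoint returns ρ = 0 exactly; one outside (d_min, d_max) has no
finite solution and raises.

## Expected utility and quadrature

Belief about μ is a normal prior N(m, s²) (s = 0 is a supported point
mass). Expected utility integrates the branch-weighted conditional utility
over this prior by Gauss–Hermite quadrature with the change of variable
μ = m + √2·s·t.

**Node count.** The integrand contains stage CDFs varying on the standard
error scale (σ√(2/n) ≈ 0.2–0.3 in the worked example), finer than the prior
scale s = 0.6, so the rule converges slowly: 35 nodes still carries ~3×10⁻⁵
error, enough to displace the optimum by several participants. The default
is **150 nodes**, where doubling the node count moves the worked-example EU
by ~10⁻¹² and agreement with adaptive quadrature is better than 10⁻¹⁰.
`quadrature_convergence` exposes the doubling check; node tables are cached.

Degenerate stages use the convention n = 0 ⇒ c = −∞ (always proceed,
α = 1, β = 0); the sample mean of an empty stage is never evaluated.

## Internal pilots

An internal pilot re-enters the final analysis: the second test applies to
the pooled mean x_t = (n₁x₁ + n₂x₂)/(n₁ + n₂). Given μ, (x₁, x_t) is
bivariate normal with Var(x₁) = 2σ²/n₁, Var(x_t) = Cov = 2σ²/(n₁+n₂), hence
correlation √(n₁/(n₁+n₂)). Branch probabilities are orthant probabilities of
this distribution, evaluated through `scipy.stats.multivariate_normal.cdf`
vectorised over quadrature nodes; |correlation| within 10⁻¹² of 1 falls back
to the exact single-variable expression, and infinite critical values are
resolved before the CDF call. The published-table convention is kept for
reporting: stage-level α₂/β₂ use the pooled statistic's *marginal* null and
alternative distributions, while α_t and β_t use the joint law. The
internal design's α₂ is parameterised on the pooled null,
c₂ = σ√(2/(n₁+n₂))·Φ⁻¹(1−α₂).

## Heterogeneous pilot and definitive effects

When the pilot's true effect μ_p may differ from the definitive effect μ,
the pair gets a bivariate normal prior with marginals (m_p, s_p), (m, s) and
correlation τ. Only the pilot's progression probability changes: integrating
μ_p out, x₁ | μ ~ N(m_p + τ(s_p/s)(μ − m), (1 − τ²)s_p² + 2σ²/n₁). The
definitive stage and the adopt branch's d attribute use the definitive
effect μ (the quantity the programme ultimately acts on), and the outer
quadrature runs over the marginal prior of μ. τ = 1 with matched marginals
recovers the homogeneous model to 10⁻¹⁰; s = 0 with τ ≠ 0 leaves the
conditional undefined and raises. Operating characteristics are still
reported from the homogeneous sampling distribution at μ* — the convention
under which published design tables print "power" columns.

## Optimisation

The continuous relaxation is optimised by multi-start L-BFGS-B on
transformed variables — log n_i (box-bounded by the constraints) and
logit α_i (bounded at ±12, i.e. α ∈ (6×10⁻⁶, 1 − 6×10⁻⁶)) — with the
critical values recovered from the α's. The start grid is deterministic:
α ∈ {0.05, 0.3, 0.7, 0.95}² crossed with two sample-size anchors (a
near-lower-bound pilot and a conventionally powered definitive size), 32
starts for the full problem; sweeps add the neighbouring optimum as a warm
start. The integer neighbourhood (±2 per stage) of the best continuous
solution is then enumerated with the α's re-optimised for each candidate,
because the EU surface is asymmetric around the continuous optimum. Ties
within 10⁻¹⁰ prefer the smaller n₁ + n₂, then the smaller n₁.

Boundary structures are unreachable on the log scale and run as explicit
sub-problems whose winners compete with the interior solution: pilot-only
programmes (n₂ = 0, α₂ = 1), "no pilot test" programmes (α₁ = 1 with n₁
pinned at its lower bound — also the n₁ = 0 route when the bound is 0), and
the run-nothing designs (adopt immediately; retain control outright). The
`no_pilot_test` constraint restricts the candidate set to that sub-problem.
Gradients are finite-differenced by the optimiser on the transformed scale;
diagnostics record start counts and candidate structures, and an
optimisation where no start converges raises rather than returning silently.

## Regret and sensitivity

A utility difference converts to value through the inverse transform
−(1/ρ)ln(1 − u) (matching branches for ρ ≤ 0) and then to participants by
dividing by |kₙ|: the *regret* of a fixed design under perturbed
assumptions. Each grid cell of a regret surface is self-contained — the
local optimum, both EUs, and the ρ, kₙ used in the conversion all belong to
the perturbed scenario (perturbing d̄ re-derives all three weights).
Warm-starting along the grid is validated in tests against cold starts. The
numerical floor is −10⁻⁶: the proposed design's own EU participates as a
candidate start, so regret at the elicitation point is exactly zero.

Because the conversion inverts the utility transform exactly, regret equals
(value gap)/|kₙ| and is invariant to common shifts in value for *every* ρ;
what is not shift-invariant for ρ ≠ 0 is the raw utility gap. Note the
amplification: at the worked example's perturbed point,
1/(ρ(1 − u)|kₙ|) ≈ 2.3×10⁴ participants per unit of expected utility, so a
5×10⁻⁴ EU discrepancy — the reproduction tolerance used for published
expected utilities — corresponds to ~11 participants of regret. Published
regret figures should be read with that sensitivity in mind; this package's
regret values are anchored by the brute-force and quadrature oracles in the
test suite.

## Simulation oracle

`simulate_programme` draws μ (and μ_p jointly, under a bivariate prior) from
the prior or fixes it, simulates x₁, x₂ (and the pooled x_t for internal
pilots), applies the decision rules and averages realised utilities, with a
single `numpy` Generator stream per call — bit-identical under a repeated
seed. It emulates exactly the idealised data-generating mechanism of the
model: normal outcomes, known common σ, no accrual dynamics, no missing
data, no interim modification of the intervention. Agreement between the
simulator and the analytic machinery therefore validates the *computation*,
not the model's fit to any real trial; the defence of the modelling
assumptions has to come from the application.

## Problem sizes and test design

The test suite reproduces every published worked-example quantity at the
printed precision (sample sizes ±1, α's ±0.02, EU magnitudes ±5×10⁻⁴) and
checks properties at sizes chosen to keep the full suite under a minute of
optimisation time: Monte Carlo oracles use 1.2–1.5×10⁵ replicates with 3-SE
bands, the risk-attitude sweeps of the nine-scenario evaluation grid use
coarse ρ grids ({−5, −3} for the definitive-trial-drop check; {−5, −2, 1, 4}
for the untested-pilot check), and regret surfaces are spot grids rather
than the 21×21 default. The CLI defaults keep the finer resolutions.

## Limitations

Known, common σ and z-tests throughout (no t-tests or unequal variances);
a single interim decision (no group-sequential generalisation, no efficacy
stopping at the pilot); normal priors only (the quadrature exploits them);
no set-up costs or patient-population weighting in the utility; no posterior
updating between stages — the pilot affects the definitive trial only
through the progression decision. Internal pilots with heterogeneous effects
are not combined. Multi-start local optimisation has no global guarantee;
the start grid, boundary candidates, warm starts and the random-design
dominance test are the practical mitigations.
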