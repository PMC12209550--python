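"""Value/utility construction, risk-attitude elicitation, regret conversion."""

import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from pilotopt import (
    AttributeRealisation,
    ElicitationInputs,
    GambleSpec,
    InvalidElicitationError,
    UtilityParams,
    Weights,
    certainty_equivalent,
    derive_weights,
    regret_in_participants,
    rho_from_gamble,
    utility,
    utility_from_value,
    utility_to_value,
    value,
)

OK_PRINTED = Weights(kd=0.769, kn=-0.0000769, kb=0.231)


class TestDeriveWeights:
    @pytest.mark.parametrize(
        "d_bar, d_hat, n_star, kd, kn, kb, tol",
        [
            # OK-Diabetes elicitation, published to 3 significant figures
            (0.005, 0.3, 50, 0.769, -0.0000769, 0.231, 5e-4),
            # independent evaluation of the three weight formulas
            (0.0025, 0.3, 50, 0.769261, -3.8463e-5, 0.230751, 1e-6),
        ],
    )
    def test_published_and_independent_values(self, d_bar, d_hat, n_star, kd, kn, kb, tol):
        w = derive_weights(ElicitationInputs(d_bar, d_hat, n_star))
        assert w.kd == pytest.approx(kd, abs=tol)
        assert w.kn == pytest.approx(kn, abs=tol * abs(kn) / abs(kd) + 1e-12)
        assert w.kb == pytest.approx(kb, abs=tol)

    def test_zero_sampling_cost_limit(self):
        w = derive_weights(ElicitationInputs(1e-12, 0.3, 50))
        assert w.kd == pytest.approx(1 / 1.3, rel=1e-9)
        assert w.kn == pytest.approx(0.0, abs=1e-12)
        assert w.kb == pytest.approx(1 - 1 / 1.3, rel=1e-8)

    @given(
        d_bar=st.floats(1e-6, 1.0),
        d_hat=st.floats(-0.5, 2.0),
        n_star=st.floats(1.0, 1e4),
    )
    @settings(max_examples=50, deadline=None)
    def test_weight_identities(self, d_bar, d_hat, n_star):
        """The three defining identities hold exactly, and kn < 0."""
        assume(1 + d_hat - d_bar / n_star > 0.01)
        e = ElicitationInputs(d_bar, d_hat, n_star)
        w = derive_weights(e)
        assert w.kd == pytest.approx(1 / (1 + d_hat - d_bar / n_star))
        assert w.kn == pytest.approx(-w.kd * d_bar / n_star)
        assert w.kb == pytest.approx(1 - w.kd - w.kn * d_hat)
        assert w.kn < 0

    @pytest.mark.parametrize("bad", [dict(d_bar=0.0), dict(d_bar=-1.0), dict(n_star=0.0)])
    def test_invalid_elicitation(self, bad):
        kwargs = dict(d_bar=0.005, d_hat=0.3, n_star=50) | bad
        with pytest.raises(InvalidElicitationError):
            ElicitationInputs(**kwargs)


class TestValueAndUtility:
    @pytest.mark.parametrize(
        "n, d, b, expected",
        [
            (0, 0.0, 1, 0.231),  # value of retaining control
            (0, 0.0, 0, 0.0),  # origin
            (100, 0.5, 0, 0.37681),  # hand evaluation of the published value fn
        ],
    )
    def test_value_examples(self, n, d, b, expected):
        a = AttributeRealisation(n=n, d=d, b=b)
        assert value(a, OK_PRINTED) == pytest.approx(expected, abs=1e-9)

    def test_invalid_realisation(self):
        with pytest.raises(ValueError):
            AttributeRealisation(n=10, d=0.2, b=1)

    def test_risk_neutral_utility_is_value(self, ok_params):
        a = AttributeRealisation(n=200, d=0.4, b=0)
        p0 = UtilityParams(weights=ok_params.weights, rho=0.0)
        assert utility(a, p0) == value(a, ok_params.weights)

    def test_published_utility_of_published_value(self):
        # the published expected-utility magnitude pairs with a value of 0.2800
        assert utility_from_value(0.2800, 2.0) == pytest.approx(0.42874, abs=1e-4)
        assert utility_from_value(0.0, 2.0) == 0.0

    @given(v=st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_branches_continuous_at_rho_zero(self, v):
        """Scaled by 1/|rho| (utilities are affine-equivalent), both
        exponential branches converge to the linear branch as rho -> 0."""
        eps = 1e-8
        for rho in (eps, -eps):
            assert utility_from_value(v, rho) / eps == pytest.approx(v, abs=1e-6)

    @given(
        v1=st.floats(-2, 2),
        v2=st.floats(-2, 2),
        rho=st.floats(-5, 5).filter(lambda r: r == 0.0 or abs(r) > 1e-6),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_value(self, v1, v2, rho):
        lo, hi = sorted([v1, v2])
        assume(hi - lo > 1e-9)  # a resolvable gap at float precision
        assert utility_from_value(lo, rho) < utility_from_value(hi, rho)

    @given(
        v=st.floats(-2, 2),
        rho=st.floats(-5, 5).filter(lambda r: r == 0.0 or abs(r) > 1e-6),
    )
    @settings(max_examples=100, deadline=None)
    def test_value_utility_round_trip(self, v, rho):
        u = utility_from_value(v, rho)
        assert utility_to_value(u, rho) == pytest.approx(v, abs=1e-9)

    def test_published_value_translation(self):
        assert utility_to_value(0.42874, 2.0) == pytest.approx(0.2800, abs=2e-4)
        assert utility_to_value(0.0, 1.7) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            utility_to_value(1.0, 2.0)
        with pytest.raises(ValueError):
            utility_to_value(-1.0, -2.0)


class TestRhoFromGamble:
    def test_midpoint_is_risk_neutral(self):
        assert rho_from_gamble(GambleSpec(0.0, 0.5, 0.25)) == 0.0

    def test_published_certainty_equivalent(self):
        # stated CE of 0.19 for the 0-0.5 gamble corresponds to rho = 2
        rho = rho_from_gamble(GambleSpec(0.0, 0.5, 0.19))
        assert rho == pytest.approx(2.0, abs=0.01)
        assert certainty_equivalent(2.0, 0.0, 0.5) == pytest.approx(0.19, abs=5e-4)

    def test_risk_seeking_inverse(self):
        # CE forward-evaluated at rho = -2, then inverted
        ce = certainty_equivalent(-2.0, 0.0, 0.5)
        assert ce == pytest.approx(0.31006, abs=1e-5)
        assert rho_from_gamble(GambleSpec(0.0, 0.5, ce)) == pytest.approx(-2.0, abs=1e-8)

    @pytest.mark.parametrize("rho", [-5.0, -1.3, -0.01, 0.6, 2.0, 5.0])
    def test_exact_inverse_of_forward_ce(self, rho):
        ce = certainty_equivalent(rho, -0.1, 0.7)
        assert rho_from_gamble(GambleSpec(-0.1, 0.7, ce)) == pytest.approx(rho, abs=1e-8)

    @pytest.mark.parametrize("ce", [-0.01, 0.0, 0.5, 0.7])
    def test_ce_outside_gamble_range_rejected(self, ce):
        with pytest.raises(InvalidElicitationError):
            rho_from_gamble(GambleSpec(0.0, 0.5, ce))


class TestRegretInParticipants:
    def test_zero_for_equal_utilities(self, ok_params):
        assert regret_in_participants(0.3, 0.3, ok_params) == 0.0

    def test_published_sixty_six_participants(self):
        # published optimal vs no-pilot-test expected utilities
        p = UtilityParams(weights=OK_PRINTED, rho=2.0)
        r = regret_in_participants(0.42874, 0.42292, p)
        assert round(r) == 66
        # equivalently, a value difference of 0.0051 at |kn| = 0.0000769
        assert 0.0051 / 0.0000769 == pytest.approx(66.3, abs=0.05)

    @given(
        v_best=st.floats(-1, 1),
        gap=st.floats(0, 0.5),
        rho=st.floats(-4, 4).filter(lambda r: r == 0.0 or abs(r) > 1e-6),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_two_step_translation(self, v_best, gap, rho, ok_params):
        p = UtilityParams(weights=ok_params.weights, rho=rho)
        u_best = utility_from_value(v_best, rho)
        u_alt = utility_from_value(v_best - gap, rho)
        direct = regret_in_participants(u_best, u_alt, p)
        brute = (utility_to_value(u_best, rho) - utility_to_value(u_alt, rho)) / abs(
            p.weights.kn
        )
        assert direct == pytest.approx(brute, rel=1e-12, abs=1e-9)
        assert direct == pytest.approx(gap / abs(p.weights.kn), rel=1e-6, abs=1e-6)

    def test_depends_only_on_value_difference(self, ok_params):
        """The exact transform makes regret shift-invariant for every rho
        (it recovers the underlying value gap), unlike the raw utility gap,
        which shrinks under a common value shift when rho > 0."""
        w = ok_params.weights
        base = (0.25, 0.20)
        shifted = (0.45, 0.40)
        for rho in (0.0, 2.0, -1.5):
            p = UtilityParams(weights=w, rho=rho)
            r = regret_in_participants(
                utility_from_value(base[0], rho), utility_from_value(base[1], rho), p
            )
            rs = regret_in_participants(
                utility_from_value(shifted[0], rho), utility_from_value(shifted[1], rho), p
            )
            assert r == pytest.approx(rs, rel=1e-9)
            assert r == pytest.approx(0.05 / abs(w.kn), rel=1e-9)
        du_base = utility_from_value(base[0], 2.0) - utility_from_value(base[1], 2.0)
        du_shift = utility_from_value(shifted[0], 2.0) - utility_from_value(shifted[1], 2.0)
        assert du_shift < du_base

    def test_requires_ordering(self, ok_params):
        with pytest.raises(ValueError):
            regret_in_participants(0.1, 0.2, ok_params)
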