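"""Payoffs, advantage polynomials, and the replicator field."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trigov import (
    GameParameters,
    PARAM_NAMES,
    StrategyState,
    ValidationError,
    ConfigurationError,
    advantage_functions,
    expected_payoffs,
    replicator_rhs,
    validate_parameters,
)
from trigov.model import advantage_array

from conftest import random_parameters, random_state


class TestParameterValidation:
    def test_accepts_printed_baseline_map(self):
        raw = dict(Cm=6, Ct=2, Cp=10, Ci=0.5, Wm=9, Wt=4, Gf=6, Gs=5,
                   Er=2, Cr=1, Oc=1.5, Eg=7, Gg=2, Pg=1)
        params = validate_parameters(raw)
        assert params.Wm == 9.0 and params.Ci == 0.5

    def test_rejects_negative_value(self):
        raw = {name: 1.0 for name in PARAM_NAMES}
        raw["Cm"] = -1.0
        with pytest.raises(ValidationError, match="Cm"):
            validate_parameters(raw)

    def test_rejects_non_finite_value(self):
        raw = {name: 1.0 for name in PARAM_NAMES}
        raw["Eg"] = float("nan")
        with pytest.raises(ValidationError, match="Eg"):
            validate_parameters(raw)

    def test_missing_key_named_in_error(self):
        raw = {name: 1.0 for name in PARAM_NAMES if name != "Pg"}
        with pytest.raises(ConfigurationError, match="Pg"):
            validate_parameters(raw)

    def test_unknown_key_rejected(self):
        raw = {name: 1.0 for name in PARAM_NAMES}
        raw["Qx"] = 3.0
        with pytest.raises(ConfigurationError, match="Qx"):
            validate_parameters(raw)

    def test_strategy_state_bounds(self):
        with pytest.raises(ValidationError):
            StrategyState(1.2, 0.5, 0.5)


class TestExpectedPayoffs:
    def test_all_cooperative_corner(self, scenario1):
        """At (1,1,1) the recognizing patient gets Ct and the reasonable
        institution gets Wt+Gs+Er-Oc."""
        pay = expected_payoffs(StrategyState(1, 1, 1), scenario1)
        assert pay.patient_recognize == pytest.approx(2.0)
        assert pay.institution_reasonable == pytest.approx(9.5)

    def test_strict_regulator_payoff_depends_only_on_x_y(self, scenario1):
        for z in (0.0, 0.3, 1.0):
            pay = expected_payoffs(StrategyState(1, 1, z), scenario1)
            assert pay.regulator_strict == pytest.approx(4.0)  # Eg - Cr - Gg


class TestAdvantageFunctions:
    def test_center_values(self, scenario1, center):
        adv = advantage_functions(center, scenario1)
        assert adv.patient == pytest.approx(2.875)
        assert adv.institution == pytest.approx(4.125)
        assert adv.regulator == pytest.approx(-1.25)

    def test_institution_advantage_at_origin_face(self, scenario1):
        adv = advantage_functions(StrategyState(0, 0.7, 0), scenario1)
        assert adv.institution == pytest.approx(2.0)  # Er+Gs-Wm+Wt

    def test_zero_parameters_give_zero_advantage(self):
        zero = GameParameters(**{name: 0.0 for name in PARAM_NAMES})
        adv = advantage_functions(StrategyState(0.3, 0.6, 0.9), zero)
        assert adv.as_array() == pytest.approx(np.zeros(3))

    def test_matches_expected_payoff_differences_on_random_draws(self):
        """The expanded polynomials and the mixture-weighted payoff
        differences are the same algebraic object."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            params = random_parameters(rng)
            state = random_state(rng)
            diffs = np.array(expected_payoffs(state, params).differences())
            adv = advantage_functions(state, params).as_array()
            np.testing.assert_allclose(adv, diffs, atol=1e-9)

    def test_symbolic_identity_with_payoff_differences(self):
        """Symbolic proof that each advantage polynomial equals the payoff
        difference of the corresponding population, for all states and
        parameters at once."""
        sympy = pytest.importorskip("sympy")
        syms = {name: sympy.Symbol(name, nonnegative=True) for name in PARAM_NAMES}
        x, y, z = sympy.symbols("x y z")

        class SymbolicParams:
            def __getattr__(self, name):
                return syms[name]

        class SymbolicState:
            def __iter__(self):
                return iter((x, y, z))

            def as_array(self):
                return np.array([x, y, z], dtype=object)

        pay = expected_payoffs(SymbolicState(), SymbolicParams())
        adv = advantage_array(np.array([x, y, z], dtype=object), SymbolicParams())
        for poly, diff in zip(adv, pay.differences()):
            assert sympy.expand(poly - diff) == 0

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bilinearity_of_each_advantage(self, seed):
        """Each advantage component is affine in each of its two foreign
        frequencies: second finite differences vanish."""
        rng = np.random.default_rng(seed)
        params = random_parameters(rng)
        s = rng.uniform(0.1, 0.9, size=3)
        h = 0.05
        foreign = {0: (1, 2), 1: (0, 2), 2: (0, 1)}
        for comp, axes in foreign.items():
            for axis in axes:
                plus, minus = s.copy(), s.copy()
                plus[axis] += h
                minus[axis] -= h
                second_diff = (
                    advantage_array(plus, params)[comp]
                    - 2 * advantage_array(s, params)[comp]
                    + advantage_array(minus, params)[comp]
                )
                assert abs(second_diff) < 1e-9

    def test_positive_scaling_of_parameters_scales_field(self):
        rng = np.random.default_rng(5)
        params = random_parameters(rng)
        state = random_state(rng)
        lam = 3.7
        scaled = GameParameters(**{k: lam * v for k, v in params.to_dict().items()})
        np.testing.assert_allclose(
            replicator_rhs(state, scaled).as_array(),
            lam * replicator_rhs(state, params).as_array(),
            rtol=1e-12,
        )


class TestReplicatorField:
    def test_center_values(self, scenario1, center):
        field = replicator_rhs(center, scenario1)
        np.testing.assert_allclose(
            field.as_array(), [0.71875, 1.03125, -0.3125], rtol=0, atol=1e-15
        )

    def test_vertices_are_fixed_points(self):
        rng = np.random.default_rng(3)
        params = random_parameters(rng)
        for x in (0, 1):
            for y in (0, 1):
                for z in (0, 1):
                    field = replicator_rhs(StrategyState(x, y, z), params)
                    assert field.as_array() == pytest.approx(np.zeros(3), abs=0)

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_face_invariance(self, seed):
        """A component pinned at 0 or 1 has exactly zero derivative."""
        rng = np.random.default_rng(seed)
        params = random_parameters(rng)
        s = rng.uniform(0, 1, size=3)
        axis = int(rng.integers(0, 3))
        s[axis] = float(rng.integers(0, 2))
        field = replicator_rhs(StrategyState(*s), params).as_array()
        assert field[axis] == 0.0
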