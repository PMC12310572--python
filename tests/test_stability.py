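"""Jacobian, vertex eigenvalues, ESS classification, interior roots."""

import numpy as np
import pytest

from trigov import (
    PURE_PROFILES,
    StrategyState,
    ValidationError,
    classify_equilibrium,
    conditionally_stable_profiles,
    enumerate_pure_equilibria,
    ess_conditions,
    find_interior_fixed_points,
    jacobian,
    replicator_rhs,
    vertex_eigenvalues,
)
from trigov.stability import INDETERMINATE, STABLE, UNSTABLE

from conftest import random_parameters, random_state


def finite_difference_jacobian(state, params, h=1e-6):
    s0 = np.asarray(list(state), dtype=float)
    J = np.empty((3, 3))
    for j in range(3):
        plus, minus = s0.copy(), s0.copy()
        plus[j] += h
        minus[j] -= h
        fp = replicator_rhs(StrategyState(*plus), params).as_array()
        fm = replicator_rhs(StrategyState(*minus), params).as_array()
        J[:, j] = (fp - fm) / (2 * h)
    return J


class TestJacobian:
    def test_diagonal_at_overtreatment_vertex(self, scenario1):
        J = jacobian(StrategyState(1, 0, 0), scenario1)
        off_diag = J[~np.eye(3, dtype=bool)]
        assert off_diag == pytest.approx(np.zeros(6), abs=0)
        np.testing.assert_allclose(np.diag(J), [-22.5, -1.5, -5.0])

    def test_matches_central_differences_at_interior_state(self, scenario1):
        J = jacobian(StrategyState(0.3, 0.6, 0.2), scenario1)
        J_fd = finite_difference_jacobian(StrategyState(0.3, 0.6, 0.2), scenario1)
        np.testing.assert_allclose(J, J_fd, rtol=1e-6, atol=1e-6)

    def test_matches_central_differences_random(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            params = random_parameters(rng)
            state = StrategyState(*rng.uniform(0.05, 0.95, size=3))
            J = jacobian(state, params)
            J_fd = finite_difference_jacobian(state, params)
            scale = max(1.0, float(np.max(np.abs(J))))
            assert np.max(np.abs(J - J_fd)) / scale < 1e-5

    def test_diagonal_at_every_vertex_for_random_params(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            params = random_parameters(rng)
            for profile in PURE_PROFILES.values():
                J = jacobian(profile.as_array(), params)
                assert np.all(J[~np.eye(3, dtype=bool)] == 0.0)
                np.testing.assert_allclose(
                    np.diag(J), vertex_eigenvalues(profile, params), atol=1e-9
                )


class TestVertexEigenvalues:
    def test_baseline_closed_forms(self, scenario1):
        assert vertex_eigenvalues("E2", scenario1) == pytest.approx((-22.5, -1.5, -5.0))
        assert vertex_eigenvalues("E1", scenario1) == pytest.approx((22.5, 2.0, 6.0))

    def test_strict_supervision_vertex_has_zero_eigenvalue(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            params = random_parameters(rng)
            assert vertex_eigenvalues("E4", params)[0] == 0.0
            assert vertex_eigenvalues("E6", params)[0] == 0.0

    def test_unknown_label_raises(self, scenario1):
        with pytest.raises(ValidationError, match="E9"):
            vertex_eigenvalues("E9", scenario1)


class TestClassification:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("E1", UNSTABLE),
            ("E2", STABLE),
            ("E3", STABLE),
            ("E4", INDETERMINATE),
            ("E5", UNSTABLE),
            ("E6", INDETERMINATE),
            ("E7", UNSTABLE),
            ("E8", UNSTABLE),
        ],
    )
    def test_baseline_classification_table(self, scenario1, label, expected):
        """Under the first printed scenario the classification of every pure
        profile matches the published stability table (the two conditional
        vertices are both stable there: 7.5 < Wm=9 < 11)."""
        assert classify_equilibrium(label, scenario1).classification == expected

    def test_scenario2_unique_ess(self, scenario2):
        report = ess_conditions(scenario2)
        assert report.stable_labels == {"E3"}
        # E2 loses stability through the institution eigenvalue Er+Oc-Wm+Wt
        by_label = {r.profile.label: r for r in report.reports}
        assert by_label["E2"].eigenvalues[1] == pytest.approx(1.5)

    def test_baseline_bistable(self, scenario1):
        report = ess_conditions(scenario1)
        assert report.stable_labels == {"E2", "E3"}
        assert report.e2_condition_holds and report.e3_condition_holds

    def test_high_overtreatment_income_leaves_only_e2(self, scenario1):
        report = ess_conditions(scenario1.replace(Wm=20.0))
        assert report.stable_labels == {"E2"}

    def test_tolerance_must_be_positive(self, scenario1):
        with pytest.raises(ValidationError):
            classify_equilibrium("E1", scenario1, tol=0.0)

    def test_inequality_eigenvalue_coherence(self):
        """Across random positive draws, E2 is stable exactly when
        Wm > Er+Oc+Wt and E3 exactly when Wm < Gs+Wt+Er (ties excluded)."""
        rng = np.random.default_rng(41)
        tol = 1e-9
        for _ in range(1000):
            params = random_parameters(rng, low=0.01)
            e2 = classify_equilibrium("E2", params, tol)
            e3 = classify_equilibrium("E3", params, tol)
            m2 = params.Wm - (params.Er + params.Oc + params.Wt)
            m3 = (params.Gs + params.Wt + params.Er) - params.Wm
            if abs(m2) > tol:
                assert (e2.classification == STABLE) == (m2 > 0)
            if abs(m3) > tol:
                assert (e3.classification == STABLE) == (m3 > 0)


class TestEquilibriumEnumeration:
    def test_exactly_eight_pure_equilibria(self, scenario1):
        profiles = enumerate_pure_equilibria(scenario1)
        assert {p.label for p in profiles} == set(PURE_PROFILES)
        assert len(profiles) == 8

    def test_enumeration_for_random_parameters(self):
        rng = np.random.default_rng(2)
        params = random_parameters(rng)
        assert len(enumerate_pure_equilibria(params)) == 8


class TestInteriorFixedPoints:
    def test_scenario2_has_none(self, scenario2):
        """With Wt=7 the institution advantage is >= 1.5 on the whole cube,
        so the institution equation has no interior zero."""
        assert find_interior_fixed_points(scenario2) == []

    def test_baseline_roots_verified_and_interior(self, scenario1):
        roots = find_interior_fixed_points(scenario1)
        for fp in roots:
            assert fp.interior_flag
            assert fp.residual < 1e-10
            assert all(0 < c < 1 for c in fp.location)

    def test_grid_precondition(self, scenario1):
        with pytest.raises(ValidationError):
            find_interior_fixed_points(scenario1, grid_n=3)

    def test_brute_force_oracle_agreement(self, scenario1, scenario2):
        """A dense brute-force scan finds no cube point with a smaller field
        residual than any root the search reports (and confirms emptiness
        where the search reports none)."""
        from trigov.model import make_rhs

        for params in (scenario1, scenario2):
            rhs = make_rhs(params)
            axis = np.linspace(0.02, 0.98, 33)
            best = min(
                float(np.max(np.abs(rhs(0.0, np.array([a, b, c])))))
                for a in axis for b in axis for c in axis
            )
            roots = find_interior_fixed_points(params)
            if not roots:
                # no interior root: the field residual is bounded away from 0
                assert best > 1e-4


class TestConditionalStability:
    def test_only_two_profiles_ever_stabilize(self):
        counts = conditionally_stable_profiles(n_draws=300, seed=9)
        stabilizers = {label for label, c in counts.items() if c > 0}
        assert stabilizers == {"E2", "E3"}

    def test_structurally_signed_eigenvalues(self):
        """For strictly positive parameters: E1, E5, E8 always carry a
        positive eigenvalue, E4 and E6 a zero one, and E7's regulator
        eigenvalue Cr+Gg is positive."""
        rng = np.random.default_rng(31)
        for _ in range(200):
            p = random_parameters(rng, low=0.01)
            assert vertex_eigenvalues("E1", p)[0] > 0
            assert vertex_eigenvalues("E5", p)[0] > 0
            assert vertex_eigenvalues("E8", p)[0] > 0
            assert vertex_eigenvalues("E4", p)[0] == 0
            assert vertex_eigenvalues("E6", p)[0] == 0
            assert vertex_eigenvalues("E7", p)[2] > 0
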