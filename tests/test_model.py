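"""Closed-form model core: vector field, fixed points, linearization, Hopf."""

import numpy as np
import pytest
import sympy as sp

from biotrio import (
    ModelParameters,
    PopulationState,
    analytic_steady_states,
    characteristic_coefficients,
    hopf_k3_critical,
    hopf_k3_numeric,
    jacobian_at,
    positive_steady_state,
    rhs,
    stability_report,
)
from biotrio.model import classify_eigenvalues

from conftest import random_params


class TestRhs:
    @pytest.mark.parametrize(
        "state, expected",
        [
            ((0, 0, 0), (0, 0, 0)),  # origin annihilates every term
            ((1, 1, 1), (2, 0, 0)),  # 1*4*1 - 1 - 1*1*1 = 2
            ((3, 3, 3), (0, 0, 0)),  # the positive fixed point
        ],
    )
    def test_default_parameter_values(self, defaults, state, expected):
        assert rhs(PopulationState(*state), defaults) == pytest.approx(expected)

    def test_general_formula(self, rng):
        p = random_params(rng, with_hopf=False)
        R, P, M = rng.uniform(0.1, 5.0, 3)
        dR, dP, dM = rhs((R, P, M), p)
        assert dR == pytest.approx(p.k1 * p.N * R - p.k4 * R - p.k2 * R * P)
        assert dP == pytest.approx(-p.k3 * P + p.k5 * M)
        assert dM == pytest.approx(p.k4 * R - p.k5 * M)

    @pytest.mark.parametrize("bad", [(-1, 1, 1), (1, float("nan"), 1), (1, 1, float("inf"))])
    def test_rejects_invalid_states(self, defaults, bad):
        with pytest.raises(ValueError):
            rhs(bad, defaults)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            ModelParameters(k3=0.0)
        with pytest.raises(ValueError):
            ModelParameters(N=-4.0)


class TestSteadyStates:
    def test_defaults_give_origin_and_3_3_3(self, defaults):
        states = analytic_steady_states(defaults)
        assert len(states) == 2
        assert states[0] == PopulationState(0, 0, 0)
        assert states[1].as_array() == pytest.approx([3, 3, 3])

    def test_k3_scaling_moves_resistant_arm(self, defaults):
        # P* stays at (k1 N - k4)/k2; R* and M* scale with k3
        states = analytic_steady_states(defaults.replace(k3=10.0))
        assert states[1].as_array() == pytest.approx([30, 3, 30])

    def test_washout_only_when_growth_below_transition(self):
        states = analytic_steady_states(ModelParameters(k1=0.1))  # k1 N = 0.4 < k4
        assert len(states) == 1
        with pytest.raises(ValueError):
            positive_steady_state(ModelParameters(k1=0.1))

    def test_rhs_vanishes_at_every_steady_state(self, rng):
        for _ in range(20):
            p = random_params(rng, with_hopf=False)
            for s in analytic_steady_states(p):
                assert np.linalg.norm(rhs(s, p)) < 1e-12


class TestJacobian:
    def test_origin_defaults(self, defaults):
        expected = [[3, 0, 0], [0, -1, 1], [1, 0, -1]]
        np.testing.assert_allclose(jacobian_at(PopulationState(0, 0, 0), defaults), expected)

    def test_positive_steady_state_defaults(self, defaults):
        j = jacobian_at(positive_steady_state(defaults), defaults)
        np.testing.assert_allclose(j, [[0, -3, 0], [0, -1, 1], [1, 0, -1]])

    def test_matches_central_differences(self, defaults, rng):
        state = rng.uniform(0.5, 4.0, 3)
        j = jacobian_at(state, defaults)
        h = 1e-6
        for col in range(3):
            hi, lo = state.copy(), state.copy()
            hi[col] += h
            lo[col] -= h
            fd = (np.array(rhs(hi, defaults)) - np.array(rhs(lo, defaults))) / (2 * h)
            assert j[:, col] == pytest.approx(fd, abs=1e-6)


class TestCharacteristicPolynomial:
    @pytest.mark.parametrize(
        "k3, expected",
        [(1.0, (2, 1, 3)), (2.0, (3, 2, 6)), (10.0, (11, 10, 30))],
    )
    def test_coefficients_at_defaults(self, defaults, k3, expected):
        c = characteristic_coefficients(defaults.replace(k3=k3))
        assert (c.a1, c.a2, c.a3) == pytest.approx(expected)

    def test_marginal_case_has_pure_imaginary_pair(self, defaults):
        # at k3 = 2 the Routh-Hurwitz product a1*a2 equals a3: eigenvalues -3, +-i*sqrt(2)
        c = characteristic_coefficients(defaults.replace(k3=2.0))
        assert c.a1 * c.a2 == pytest.approx(c.a3)
        roots = sorted(c.roots(), key=lambda z: z.real)
        assert roots[0] == pytest.approx(-3)
        assert sorted(z.imag for z in roots[1:]) == pytest.approx([-np.sqrt(2), np.sqrt(2)])

    def test_symbolic_identity(self):
        """The characteristic polynomial of the Jacobian at the coexistence
        state is lambda^3 + (k3+k5) l^2 + k3 k5 l + k3 k5 (k1 N - k4),
        proven symbolically for all parameter values."""
        k1, k2, k3, k4, k5, N = sp.symbols("k1 k2 k3 k4 k5 N", positive=True)
        lam = sp.symbols("lam")
        P = (k1 * N - k4) / k2
        R = k3 * P / k4
        J = sp.Matrix(
            [
                [k1 * N - k4 - k2 * P, -k2 * R, 0],
                [0, -k3, k5],
                [k4, 0, -k5],
            ]
        )
        char = (lam * sp.eye(3) - J).det()
        expected = lam**3 + (k3 + k5) * lam**2 + k3 * k5 * lam + k3 * k5 * (k1 * N - k4)
        assert sp.expand(char - expected) == 0

    def test_roots_match_jacobian_eigenvalues(self, rng):
        for _ in range(25):
            p = random_params(rng)
            roots = np.sort_complex(characteristic_coefficients(p).roots())
            eig = np.sort_complex(np.linalg.eigvals(jacobian_at(positive_steady_state(p), p)))
            assert np.max(np.abs(roots - eig)) < 1e-9

    def test_requires_positive_steady_state(self):
        with pytest.raises(ValueError):
            characteristic_coefficients(ModelParameters(k1=0.1))


class TestHopfPoint:
    def test_reference_value(self, defaults):
        assert hopf_k3_critical(defaults) == pytest.approx(2.0)
        assert hopf_k3_numeric(defaults) == pytest.approx(2.0, abs=1e-6)

    def test_shifted_parameters(self):
        p = ModelParameters(k4=0.5)
        assert hopf_k3_critical(p) == pytest.approx(2.5)
        assert hopf_k3_numeric(p) == pytest.approx(2.5, abs=1e-6)

    def test_no_hopf_point_below_threshold(self):
        assert hopf_k3_critical(ModelParameters(k1=0.25)) is None

    def test_closed_form_and_bisection_agree_for_random_families(self, rng):
        for _ in range(5):
            p = random_params(rng)
            crit = hopf_k3_critical(p)
            num = hopf_k3_numeric(p, bracket=(crit / 4, crit * 4))
            assert num == pytest.approx(crit, abs=1e-6)

    def test_independent_of_cost_of_resistance(self, rng):
        """k2 rescales the steady state but cancels from the characteristic
        polynomial, so the Hopf point cannot depend on it."""
        base = hopf_k3_critical(ModelParameters())
        for _ in range(20):
            k2 = float(rng.uniform(0.01, 100.0))
            assert hopf_k3_critical(ModelParameters(k2=k2)) == base

    def test_stability_flips_across_critical_value(self, defaults):
        crit = hopf_k3_critical(defaults)
        for k3, unstable in [(0.9 * crit, True), (1.1 * crit, False)]:
            p = defaults.replace(k3=k3)
            eig = np.linalg.eigvals(jacobian_at(positive_steady_state(p), p))
            pair = eig[np.abs(eig.imag) > 1e-9]
            assert pair.size == 2
            assert (pair.real.max() > 0) == unstable


class TestStabilityReport:
    def test_positive_state_unstable_focus_below_hopf(self, defaults):
        rep = stability_report(positive_steady_state(defaults), defaults)
        assert rep.classification == "unstable_focus"

    def test_positive_state_stable_focus_above_hopf(self, defaults):
        p = defaults.replace(k3=3.0)
        rep = stability_report(positive_steady_state(p), p)
        assert rep.classification == "stable_focus"

    def test_origin_is_a_saddle(self, defaults):
        rep = stability_report(PopulationState(0, 0, 0), defaults)
        assert rep.classification == "saddle"

    def test_marginal_hopf_case_is_nonhyperbolic(self, defaults):
        p = defaults.replace(k3=2.0)
        rep = stability_report(positive_steady_state(p), p)
        assert rep.classification == "nonhyperbolic"

    def test_eigenvalues_satisfy_characteristic_polynomial(self, rng):
        p = random_params(rng)
        c = characteristic_coefficients(p)
        for z in stability_report(positive_steady_state(p), p).eigenvalues:
            assert abs(z**3 + c.a1 * z**2 + c.a2 * z + c.a3) < 1e-9

    def test_classify_eigenvalues_categories(self):
        assert classify_eigenvalues(np.array([-1.0, -2.0, -3.0])) == "stable_node"
        assert classify_eigenvalues(np.array([1.0, 2.0, 3.0])) == "unstable_node"
        assert classify_eigenvalues(np.array([-1.0, 2.0, 3.0])) == "saddle"
        assert classify_eigenvalues(np.array([-1.0, 1j, -1j])) == "nonhyperbolic"


class TestSerialization:
    def test_config_round_trip(self, rng):
        p = random_params(rng, with_hopf=False)
        assert ModelParameters.from_config(p.to_config()) == p

    def test_json_round_trip(self, defaults):
        import json

        assert ModelParameters.from_dict(json.loads(defaults.to_json())) == defaults
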