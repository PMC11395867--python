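"""Model-layer tests: vector fields, equilibria, Jacobian, stability."""

import numpy as np
import pytest

from fraclung.model import (ModelParameters, InterventionStrengths, alpha_scale,
                            rhs_base, rhs_treated, rhs_closed_loop, equilibria,
                            jacobian, jacobian_shorthands,
                            characteristic_coefficients, stability_check)


class TestAlphaScale:
    def test_order_one_is_identity(self):
        p = ModelParameters()
        assert alpha_scale(p, 1.0, "power") is p

    def test_power_convention(self):
        p = alpha_scale(ModelParameters(lambda_=0.3), 0.5, "power")
        assert p.lambda_ == pytest.approx(0.3 ** 0.5)
        # the immune source baseline is an initial condition, never scaled
        assert p.immune_source_baseline == ModelParameters().immune_source_baseline

    def test_literal_convention_unchanged(self):
        p = ModelParameters()
        assert alpha_scale(p, 0.5, "literal") is p

    def test_unknown_convention(self):
        with pytest.raises(ValueError, match="convention"):
            alpha_scale(ModelParameters(), 0.5, "squared")


class TestVectorFields:
    def test_immune_only_point_is_fixed(self, base_scenario):
        p = base_scenario.params
        state = [0.0, p.phi1 * p.immune_source_baseline / p.phi3, 0.0, 0.0, 0.0]
        assert np.linalg.norm(rhs_base(state, p)) < 1e-12

    def test_enhancement_needs_both_populations(self, base_scenario):
        d = rhs_base([1.0, 0.0, 2.0, 3.0, 0.0], base_scenario.params)
        assert d[4] == 0.0

    def test_origin_is_not_fixed_due_to_immune_source(self, base_scenario):
        # the constant source phi1*I0 = 0.03*0.7 survives at the origin
        d = rhs_base(np.zeros(5), base_scenario.params)
        assert d[1] == pytest.approx(0.021)
        assert np.all(d[[0, 2, 3, 4]] == 0.0)

    def test_treated_reduces_to_base_at_zero_dose(self, base_scenario, rng):
        p, c = base_scenario.params, base_scenario.strengths
        for _ in range(1000):
            s = rng.uniform(-2, 5, 5)
            np.testing.assert_array_equal(rhs_treated(s, p, c, (0.0, 0.0)), rhs_base(s, p))

    def test_immunotherapy_kill_term(self, base_scenario):
        p = base_scenario.params
        c = InterventionStrengths(chi1=0.3, chi2=0, chi3=0, chi4=0, chi5=0, chi6=0)
        s = [2.0, 1.0, 1.0, 1.0, 1.0]
        diff = rhs_treated(s, p, c, (1.0, 0.0)) - rhs_base(s, p)
        np.testing.assert_allclose(diff, [-0.3 * 2.0, 0, 0, 0, 0], atol=1e-14)

    def test_source_survives_at_zero_state_any_dose(self, base_scenario):
        p, c = base_scenario.params, base_scenario.strengths
        d = rhs_treated(np.zeros(5), p, c, (0.7, 0.9))
        assert d[1] == pytest.approx(p.phi1 * p.immune_source_baseline)

    def test_closed_loop_signal_adds_to_dosage(self, base_scenario, rng):
        p, c = base_scenario.params, base_scenario.strengths
        s = rng.uniform(0, 3, 5)
        np.testing.assert_array_equal(
            rhs_closed_loop(s, p, c, (0.0, 0.0), (0.4, 0.6)),
            rhs_treated(s, p, c, (0.4, 0.6)))
        np.testing.assert_array_equal(
            rhs_closed_loop(s, p, c, (0.3, 0.2), (0.0, 0.0)),
            rhs_treated(s, p, c, (0.3, 0.2)))


class TestEquilibria:
    def test_immune_only_point(self, base_scenario):
        eqs = {e.label: e for e in equilibria(base_scenario.params)}
        e2 = eqs["E2"]
        np.testing.assert_allclose(e2.coordinates, [0, 0.21, 0, 0, 0], atol=1e-14)
        assert e2.residual_norm < 1e-12
        assert e2.feasible

    def test_tumor_capacity_point_carries_nonzero_residual(self, base_scenario):
        p = base_scenario.params
        eqs = {e.label: e for e in equilibria(p)}
        e6 = eqs["E6"]
        np.testing.assert_allclose(e6.coordinates, [10000, 0, 0, 0, 0])
        # the immune equation keeps phi1*I0 + phi2*K^2 at this candidate
        expected = p.phi1 * p.immune_source_baseline + p.phi2 * p.K ** 2
        assert e6.residual_norm == pytest.approx(expected, rel=1e-9)

    def test_low_residual_points_solve_every_equation(self, base_scenario):
        for e in equilibria(base_scenario.params):
            if e.defined and e.residual_norm < 1e-8:
                assert np.all(np.abs(rhs_base(e.coordinates, base_scenario.params)) < 1e-8)

    def test_degenerate_parameters_flagged_not_raised(self):
        p = ModelParameters(zeta4=0.0, phi3=0.0)
        eqs = {e.label: e for e in equilibria(p)}
        assert not eqs["E1"].defined
        assert not eqs["E2"].defined

    def test_all_candidates_always_emitted(self, base_scenario):
        labels = [e.label for e in equilibria(base_scenario.params)]
        assert len(labels) == 16  # E0..E13 (E8 duplicates E7) plus both E14 branches
        assert labels[0] == "E0" and "E14+" in labels and "E14-" in labels


class TestJacobian:
    def test_growth_rate_at_origin(self, base_scenario):
        J = jacobian(np.zeros(5), base_scenario.params)
        assert J[0, 0] == base_scenario.params.lambda_

    def test_enhancement_diagonal_entry(self, base_scenario, rng):
        s = rng.uniform(0, 4, 5)
        J = jacobian(s, base_scenario.params)
        assert J[4, 4] == pytest.approx(base_scenario.params.zeta8 * s[1])

    def test_matches_central_differences(self, base_scenario, rng):
        p = base_scenario.params
        eps = 1e-6
        for _ in range(20):
            s = rng.uniform(0, 5, 5)
            J = jacobian(s, p)
            fd = np.empty((5, 5))
            for k in range(5):
                sp, sm = s.copy(), s.copy()
                sp[k] += eps
                sm[k] -= eps
                fd[:, k] = (rhs_base(sp, p) - rhs_base(sm, p)) / (2 * eps)
            scale = max(1.0, np.abs(J).max())
            assert np.abs(J - fd).max() / scale < 1e-6


class TestCharacteristicCoefficients:
    def test_zero_shorthands_give_pure_quintic(self):
        K = {f"K{i}": 0.0 for i in range(1, 20)}
        c = characteristic_coefficients(K)
        assert (c.stab_a1, c.stab_a2, c.stab_a3, c.stab_a4, c.stab_a5) == (0, 0, 0, 0, 0)
        np.testing.assert_allclose(c.poly, [-1, 0, 0, 0, 0, 0])  # P = -lam^5

    def test_linear_eigen_coefficient_definition(self, base_scenario, rng):
        s = rng.uniform(0, 3, 5)
        K = jacobian_shorthands(jacobian(s, base_scenario.params))
        c = characteristic_coefficients(K)
        assert c.stab_a5 == pytest.approx(K["K12"] + K["K17"] + K["K19"])
        assert c.stab_a1 == pytest.approx(-K["K1"])
        assert c.stab_a3 == pytest.approx(-K["K6"])

    def test_factored_roots_vs_eigenvalues_where_consistent(self):
        # block-diagonal matrix built to satisfy the factorization exactly:
        # two detached 2x2 blocks (rows 1-2: N,I; row pair 3-4: P,M) and the
        # decoupled R eigenvalue
        J = np.zeros((5, 5))
        J[0, 0], J[0, 1], J[1, 0], J[1, 1] = -1.0, 0.5, -0.25, -2.0
        J[2, 2], J[2, 3], J[3, 2], J[3, 3] = -0.5, 0.2, -0.1, -1.5
        J[4, 4] = -0.3
        K = jacobian_shorthands(J)
        c = characteristic_coefficients(K)
        roots = np.sort_complex(np.roots(c.poly))
        eigs = np.sort_complex(np.linalg.eigvals(J))
        # quadratic-factor coefficients must reproduce the block traces/determinants
        assert c.stab_a1 == pytest.approx(1.0)
        assert c.stab_a3 == pytest.approx(2.0)
        assert c.stab_a5 == pytest.approx(J[2, 2] + J[3, 3] + J[4, 4])
        # the printed a2/a4 combinations carry typos, so root agreement is
        # reported (via eigenvalues) rather than required of the quintic
        assert np.all(eigs.real < 0)
        assert roots.shape == eigs.shape


class TestStabilityCheck:
    def test_negative_spectrum_reports_stable(self):
        J = np.diag([-1.0, -2.0, -0.5, -3.0, -0.1])
        c = characteristic_coefficients(jacobian_shorthands(J))
        v = stability_check(c, J, order=0.8)
        assert v["eigenvalue_verdict"] == "stable"
        assert v["fractional_stable"] is True

    def test_positive_linear_coefficient_is_unstable(self):
        # a5 = K12 + K17 + K19 > 0 forces a positive eigenvalue in the
        # factored form; build a matrix where that eigenvalue is explicit
        J = np.diag([-1.0, -1.0, 0.5, 0.3, 0.4])
        c = characteristic_coefficients(jacobian_shorthands(J))
        assert c.stab_a5 > 0
        v = stability_check(c, J)
        assert v["eigenvalue_verdict"] == "unstable"
        assert not v["criterion_stable"]

    def test_zero_matrix_is_marginal(self):
        J = np.zeros((5, 5))
        c = characteristic_coefficients(jacobian_shorthands(J))
        v = stability_check(c, J)
        assert v["eigenvalue_verdict"] == "marginal"
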