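"""Optimal-control tests: objective, Hamiltonian, adjoints, sweep."""

import numpy as np
import pytest

from fraclung.pece import TimeGrid, Trajectory
from fraclung.control import (ObjectiveWeights, ControlSchedule, clamp01,
                              objective_J, hamiltonian, adjoint_rhs,
                              control_update, forward_backward_sweep,
                              _solve_forward)
from fraclung.model import InterventionStrengths


def _traj(grid, values):
    return Trajectory(grid=grid, values=np.asarray(values, dtype=float))


class TestObjective:
    def test_zero_series_zero_cost(self):
        grid = TimeGrid(10, 1.0)
        states = _traj(grid, np.zeros((11, 5)))
        assert objective_J(states, ControlSchedule.constant(grid, 0, 0), ObjectiveWeights()) == 0.0

    def test_constant_integrand_exact(self):
        # trapezoid is exact on constants: integrand c over [0, Tf] gives c*Tf
        grid = TimeGrid(7, 3.0)
        states = _traj(grid, np.ones((8, 5)))
        w = ObjectiveWeights()
        J = objective_J(states, ControlSchedule.constant(grid, 1.0, 1.0), w)
        assert J == pytest.approx(7.0 * 3.0)  # 5 states + 2 squared dosages

    def test_quadrature_refinement(self, optimal_scenario, rng):
        cfg = optimal_scenario
        w = cfg.weights

        def run(n):
            grid = TimeGrid(n, cfg.t_final)
            d = np.clip(0.5 + 0.3 * np.sin(2 * np.pi * grid.nodes / cfg.t_final), 0, 1)
            states = _solve_forward(0.9, grid, cfg.initial_state, cfg.params,
                                    cfg.strengths, d, d)
            return objective_J(states, ControlSchedule(grid, d, d), w)

        j1, j2 = run(150), run(300)
        assert abs(j1 - j2) / abs(j2) < 1e-3

    def test_grid_mismatch(self):
        states = _traj(TimeGrid(10, 1.0), np.zeros((11, 5)))
        controls = ControlSchedule.constant(TimeGrid(20, 1.0), 0, 0)
        with pytest.raises(ValueError):
            objective_J(states, controls, ObjectiveWeights())


class TestHamiltonian:
    def test_only_source_survives_at_zero(self, optimal_scenario):
        p, c, w = optimal_scenario.params, optimal_scenario.strengths, optimal_scenario.weights
        lam = np.array([0.0, 3.0, 0.0, 0.0, 0.0])
        H = hamiltonian(np.zeros(5), lam, (0.0, 0.0), p, c, w)
        assert H == pytest.approx(p.phi1 * p.immune_source_baseline * 3.0)
        assert hamiltonian(np.zeros(5), np.zeros(5), (0.0, 0.0), p, c, w) == 0.0

    def test_second_derivative_in_dosage(self, optimal_scenario, rng):
        p, c, w = optimal_scenario.params, optimal_scenario.strengths, optimal_scenario.weights
        s, lam = rng.uniform(0, 3, 5), rng.uniform(-1, 1, 5)
        eps = 1e-4
        d = 0.4
        second = (hamiltonian(s, lam, (d + eps, 0.3), p, c, w)
                  - 2 * hamiltonian(s, lam, (d, 0.3), p, c, w)
                  + hamiltonian(s, lam, (d - eps, 0.3), p, c, w)) / eps ** 2
        assert second == pytest.approx(2.0 * w.b1, abs=1e-5)

    def test_affine_in_adjoint(self, optimal_scenario, rng):
        p, c, w = optimal_scenario.params, optimal_scenario.strengths, optimal_scenario.weights
        s, lam = rng.uniform(0, 3, 5), rng.uniform(-1, 1, 5)
        H1 = hamiltonian(s, lam, (0.5, 0.5), p, c, w)
        H2 = hamiltonian(s, 2 * lam, (0.5, 0.5), p, c, w)
        running = hamiltonian(s, np.zeros(5), (0.5, 0.5), p, c, w)
        assert H2 - 2 * H1 == pytest.approx(-running, rel=1e-9)


class TestAdjointRHS:
    def test_zero_state_zero_adjoint_gives_minus_penalties(self, optimal_scenario):
        w = optimal_scenario.weights
        d = adjoint_rhs(np.zeros(5), np.zeros(5), (0.0, 0.0),
                        optimal_scenario.params, optimal_scenario.strengths, w)
        np.testing.assert_allclose(d, [-w.a1, -w.a2, -w.a3, -w.a4, -w.a5])

    def test_zero_penalties_zero_adjoint(self, optimal_scenario, rng):
        w0 = ObjectiveWeights(a1=0, a2=0, a3=0, a4=0, a5=0)
        d = adjoint_rhs(rng.uniform(0, 3, 5), np.zeros(5), (0.3, 0.7),
                        optimal_scenario.params, optimal_scenario.strengths, w0)
        np.testing.assert_array_equal(d, np.zeros(5))

    @pytest.mark.parametrize("variant", ["plain", "pid"])
    def test_gradient_oracle_200_points(self, optimal_scenario, rng, variant):
        """Costate derivative equals -dH/dstate by central differences."""
        p, c, w = optimal_scenario.params, optimal_scenario.strengths, optimal_scenario.weights
        eps = 1e-6
        for _ in range(200):
            s = rng.uniform(0, 5, 5)
            lam = rng.uniform(-2, 2, 5)
            dos = tuple(rng.uniform(0, 1, 2))
            sig = tuple(rng.uniform(0, 1, 2)) if variant == "pid" else (0.0, 0.0)
            kw = {"signals": sig} if variant == "pid" else {}
            got = adjoint_rhs(s, lam, dos, p, c, w, variant=variant, signals=sig)
            fd = np.empty(5)
            for k in range(5):
                sp, sm = s.copy(), s.copy()
                sp[k] += eps
                sm[k] -= eps
                fd[k] = (hamiltonian(sp, lam, dos, p, c, w, **kw)
                         - hamiltonian(sm, lam, dos, p, c, w, **kw)) / (2 * eps)
            assert np.abs(got + fd).max() < 1e-6

    def test_unknown_variant(self, optimal_scenario):
        with pytest.raises(ValueError):
            adjoint_rhs(np.zeros(5), np.zeros(5), (0, 0), optimal_scenario.params,
                        optimal_scenario.strengths, optimal_scenario.weights,
                        variant="hybrid")


class TestControlUpdate:
    def test_clamping_rule(self, optimal_scenario):
        c = InterventionStrengths(chi1=1, chi2=0, chi3=0, chi4=0, chi5=0, chi6=0)
        w = optimal_scenario.weights
        # chi1*l1*N = -1 -> Delta_I = -0.5 -> clamp 0
        _, _, di, dt = control_update([1, 0, 0, 0, 0], [-1, 0, 0, 0, 0], c, w)
        assert (di, dt) == (0.0, 0.0)
        # chi1*l1*N = 4 -> Delta_I = 2 -> clamp 1
        _, _, di, _ = control_update([2, 0, 0, 0, 0], [2, 0, 0, 0, 0], c, w)
        assert di == 1.0
        # chi1*l1*N = 2*b1 -> Delta_I = 1 exactly
        d_i, _, di, _ = control_update([1, 0, 0, 0, 0], [2 * w.b1, 0, 0, 0, 0], c, w)
        assert d_i == pytest.approx(1.0) and di == 1.0

    def test_zero_adjoint_zero_controls(self, optimal_scenario, rng):
        out = control_update(rng.uniform(0, 3, 5), np.zeros(5),
                             optimal_scenario.strengths, optimal_scenario.weights)
        assert out[2] == 0.0 and out[3] == 0.0

    def test_clamp_idempotent_and_bounded(self, rng):
        x = rng.uniform(-3, 3, 100)
        once = clamp01(x)
        assert np.array_equal(clamp01(once), once)
        assert np.all((once >= 0) & (once <= 1))

    def test_pid_variant_zero_penalty_raises(self, optimal_scenario):
        w = ObjectiveWeights(c1=0.0)
        with pytest.raises(ZeroDivisionError):
            control_update(np.ones(5), np.ones(5), optimal_scenario.strengths, w,
                           variant="pid")


@pytest.fixture(scope="module")
def sweep(optimal_scenario):
    cfg = optimal_scenario
    return forward_backward_sweep(0.9, cfg.grid, cfg.initial_state,
                                  cfg.params, cfg.strengths, cfg.weights)


class TestForwardBackwardSweep:
    def test_zero_strengths_converge_immediately(self, optimal_scenario):
        cfg = optimal_scenario
        c0 = InterventionStrengths(0, 0, 0, 0, 0, 0)
        res = forward_backward_sweep(0.9, cfg.grid, cfg.initial_state,
                                     cfg.params, c0, cfg.weights)
        assert res.converged and res.iterations == 1
        assert np.all(res.controls.D_I == 0) and np.all(res.controls.D_T == 0)

    def test_converged_and_bounded(self, sweep):
        assert sweep.converged
        for series in (sweep.controls.D_I, sweep.controls.D_T):
            assert np.all((series >= 0) & (series <= 1))

    def test_beats_constant_baselines(self, sweep, optimal_scenario):
        cfg = optimal_scenario
        for d in (0.0, 1.0):
            n = len(cfg.grid)
            states = _solve_forward(0.9, cfg.grid, cfg.initial_state, cfg.params,
                                    cfg.strengths, np.full(n, d), np.full(n, d))
            J_const = objective_J(states, ControlSchedule.constant(cfg.grid, d, d),
                                  cfg.weights)
            assert sweep.J <= J_const + 1e-6

    def test_interior_stationarity(self, sweep):
        assert sweep.stationarity["max_D_I"] <= 1e-3
        assert sweep.stationarity["max_D_T"] <= 1e-3

    def test_transversality(self, sweep):
        assert np.abs(sweep.adjoints[-1]).max() <= 1e-12

    def test_history_reported(self, sweep):
        assert len(sweep.J_history) == sweep.iterations
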