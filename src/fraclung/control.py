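"""Pontryagin-based optimal dosing via a forward-backward sweep.

The objective penalizes the state burden linearly and both dosages
quadratically,

    J = int_0^Tf [ a1 N + a2 I + a3 P + a4 M + a5 R
                   + b1 D_I^2 + b2 D_T^2 (+ c1 u_I^2 + c2 u_T^2) ] dt,

and the stationarity condition dH/dD = 0 of the Hamiltonian yields closed-
form control updates which are clamped to [0, 1].  The adjoint (costate)
system runs backward from the transversality condition lambda(Tf) = 0; it
is stepped either with the same fractional PECE scheme on reversed time
(default, matching how the discrete scheme is applied to the costates) or
with classical RK4 (the costate equations are printed as integer-order).

Default weights a_i = b_i = c_i = 1 and strengths chi_i = 0.1 are this
package's documented choices -- no published values exist for them -- and are
flagged "assumed" in provenance output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

from .model import ModelParameters, InterventionStrengths, rhs_treated
from .pece import FDEProblem, TimeGrid, Trajectory, pece_solve

__all__ = [
    "ObjectiveWeights",
    "ControlSchedule",
    "SweepResult",
    "objective_J",
    "hamiltonian",
    "adjoint_rhs",
    "control_update",
    "clamp01",
    "forward_backward_sweep",
]


@dataclass(frozen=True)
class ObjectiveWeights:
    """State penalties a1..a5, dosage penalties b1,b2, PID-signal penalties c1,c2."""

    a1: float = 1.0
    a2: float = 1.0
    a3: float = 1.0
    a4: float = 1.0
    a5: float = 1.0
    b1: float = 1.0
    b2: float = 1.0
    c1: float = 1.0
    c2: float = 1.0

    def __post_init__(self) -> None:
        if self.b1 <= 0 or self.b2 <= 0:
            raise ValueError("dosage penalties b1, b2 must be strictly positive")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ControlSchedule:
    """Time-gridded dosages (and optionally PID signals) with diagnostics."""

    grid: TimeGrid
    D_I: np.ndarray
    D_T: np.ndarray
    u_I: np.ndarray | None = None
    u_T: np.ndarray | None = None
    delta_I: np.ndarray | None = None
    delta_T: np.ndarray | None = None
    psi_I: np.ndarray | None = None
    psi_T: np.ndarray | None = None

    @classmethod
    def constant(cls, grid: TimeGrid, d_i: float, d_t: float) -> "ControlSchedule":
        n = len(grid)
        return cls(grid, np.full(n, float(d_i)), np.full(n, float(d_t)))


@dataclass
class SweepResult:
    controls: ControlSchedule
    states: Trajectory
    adjoints: np.ndarray
    J: float
    J_history: list
    iterations: int
    converged: bool
    stationarity: dict


def clamp01(x):
    """Pointwise projection onto the admissible dosage interval [0, 1]."""
    return np.minimum(np.maximum(np.asarray(x, dtype=float), 0.0), 1.0)


def objective_J(states: Trajectory, controls: ControlSchedule, weights: ObjectiveWeights) -> float:
    """Trapezoidal quadrature of the running cost over [0, Tf]."""
    if len(states.grid) != len(controls.grid):
        raise ValueError("states and controls must share a grid")
    w = weights
    y = states.values
    integrand = (w.a1 * y[:, 0] + w.a2 * y[:, 1] + w.a3 * y[:, 2]
                 + w.a4 * y[:, 3] + w.a5 * y[:, 4]
                 + w.b1 * controls.D_I ** 2 + w.b2 * controls.D_T ** 2)
    if controls.u_I is not None:
        integrand = integrand + w.c1 * controls.u_I ** 2
    if controls.u_T is not None:
        integrand = integrand + w.c2 * controls.u_T ** 2
    return float(np.trapezoid(integrand, states.grid.nodes))


def hamiltonian(state, adjoint, dosages, params: ModelParameters,
                strengths: InterventionStrengths, weights: ObjectiveWeights,
                signals: tuple[float, float] | None = None) -> float:
    """Running cost plus costate-weighted dynamics.

    With ``signals`` the PID-combined variant is evaluated: the applied
    dosages become D + u and the signal penalties c1 u_I^2 + c2 u_T^2 join
    the running cost.  The Hamiltonian is quadratic in each dosage with
    d2H/dD_I^2 = 2 b1 and d2H/dD_T^2 = 2 b2.
    """
    state = np.asarray(state, dtype=float)
    lam = np.asarray(adjoint, dtype=float)
    w = weights
    d_i, d_t = dosages
    cost = (w.a1 * state[0] + w.a2 * state[1] + w.a3 * state[2]
            + w.a4 * state[3] + w.a5 * state[4] + w.b1 * d_i ** 2 + w.b2 * d_t ** 2)
    if signals is not None:
        u_i, u_t = signals
        cost += w.c1 * u_i ** 2 + w.c2 * u_t ** 2
        applied = (d_i + u_i, d_t + u_t)
    else:
        applied = (d_i, d_t)
    dyn = rhs_treated(state, params, strengths, applied)
    return float(cost + lam @ dyn)


def adjoint_rhs(state, adjoint, dosages, params: ModelParameters,
                strengths: InterventionStrengths, weights: ObjectiveWeights,
                variant: Literal["plain", "pid"] = "plain",
                signals: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Costate derivative d(lambda)/dt = -dH/d(state), exact analytic form.

    The "pid" variant differentiates the PID-combined Hamiltonian, in which
    the drug couplings act through the applied sums D + u; structurally the
    gradient is the plain one evaluated at the applied dosages.
    """
    N, I, P, M, R = np.asarray(state, dtype=float)
    l1, l2, l3, l4, l5 = np.asarray(adjoint, dtype=float)
    p, c, w = params, strengths, weights
    if variant == "pid":
        d_i = dosages[0] + signals[0]
        d_t = dosages[1] + signals[1]
    elif variant == "plain":
        d_i, d_t = dosages
    else:
        raise ValueError(f"unknown adjoint variant {variant!r}")

    dH_dN = (w.a1
             + l1 * (p.lambda_ - 2 * p.lambda_ * N / p.K - p.mu * P - p.beta1 * I
                     - p.zeta1 * M - c.chi1 * d_i)
             + l2 * (2 * p.phi2 * N)
             + l3 * (p.gamma_ * P)
             + l4 * (p.zeta5 * M))
    dH_dI = (w.a2
             + l1 * (-p.beta1 * N)
             + l2 * (-p.phi3 - p.beta2 * P + p.zeta2 * M - p.zeta3 * R + c.chi2 * d_t)
             + l3 * (-p.beta3 * P)
             + l4 * (-p.zeta6 * M)
             + l5 * (p.zeta8 * R))
    dH_dP = (w.a3
             + l1 * (-p.mu * N)
             + l2 * (-p.beta2 * I)
             + l3 * (p.gamma_ * N - p.delta_ - p.beta3 * I + p.zeta4 * M - c.chi3 * d_t)
             + l4 * (-p.zeta7 * M))
    dH_dM = (w.a4
             + l1 * (-p.zeta1 * N)
             + l2 * (p.zeta2 * I)
             + l3 * (p.zeta4 * P)
             + l4 * (p.zeta5 * N - p.zeta6 * I - p.zeta7 * P + c.chi4 * d_t + c.chi5 * d_i))
    dH_dR = (w.a5
             + l2 * (-p.zeta3 * I)
             + l5 * (p.zeta8 * I + c.chi6 * d_i))
    return -np.array([dH_dN, dH_dI, dH_dP, dH_dM, dH_dR])


def control_update(state, adjoint, strengths: InterventionStrengths,
                   weights: ObjectiveWeights,
                   variant: Literal["plain", "pid"] = "plain"):
    """Stationary dosages from dH/dD = 0, clamped to [0, 1].

    Returns ``(delta_I, delta_T, D_I*, D_T*)`` for the plain variant and
    additionally ``(psi_I, psi_T, u_I*, u_T*)`` for the PID-combined one,
    where the psi quantities are the analogous stationary points of the
    signal penalties c1, c2.
    """
    N, I, P, M, R = np.asarray(state, dtype=float)
    l1, l2, l3, l4, l5 = np.asarray(adjoint, dtype=float)
    c, w = strengths, weights
    num_i = c.chi1 * l1 * N - c.chi5 * l4 * M - c.chi6 * l5 * R
    num_t = -(c.chi2 * l2 * I - c.chi3 * l3 * P + c.chi4 * l4 * M)
    delta_i = num_i / (2.0 * w.b1)
    delta_t = num_t / (2.0 * w.b2)
    if variant == "plain":
        return delta_i, delta_t, float(clamp01(delta_i)), float(clamp01(delta_t))
    if variant != "pid":
        raise ValueError(f"unknown control variant {variant!r}")
    if w.c1 <= 0 or w.c2 <= 0:
        raise ZeroDivisionError("PID-signal penalties c1, c2 must be strictly positive")
    psi_i = num_i / (2.0 * w.c1)
    psi_t = num_t / (2.0 * w.c2)
    return (delta_i, delta_t, float(clamp01(delta_i)), float(clamp01(delta_t)),
            psi_i, psi_t, float(clamp01(psi_i)), float(clamp01(psi_t)))


def _solve_forward(order, grid, y0, params, strengths, D_I, D_T, u_I=None, u_T=None):
    """Forward state solve with node-indexed controls."""
    h = grid.step

    def rhs(t, y):
        j = min(int(round(t / h)), grid.n_steps)
        if u_I is None:
            return rhs_treated(y, params, strengths, (D_I[j], D_T[j]))
        return rhs_treated(y, params, strengths, (D_I[j] + u_I[j], D_T[j] + u_T[j]))

    prob = FDEProblem(order, rhs, y0, grid.t_final)
    return pece_solve(prob, grid)


def _solve_adjoint(order, grid, states, params, strengths, weights, D_I, D_T,
                   variant="plain", u_I=None, u_T=None, stepper="fractional"):
    """Backward costate solve by time reversal, lambda(Tf) = 0.

    With s = Tf - t the terminal condition becomes an initial condition and
    the reversed system is stepped with the same fractional PECE scheme
    (default) or with classical RK4 ("integer").
    """
    h = grid.step
    n = grid.n_steps
    y = states.values

    def rev_rhs(s, lam):
        j = min(max(int(round((grid.t_final - s) / h)), 0), n)
        sig = (0.0, 0.0) if u_I is None else (u_I[j], u_T[j])
        return -adjoint_rhs(y[j], lam, (D_I[j], D_T[j]), params, strengths, weights,
                            variant=variant, signals=sig)

    if stepper == "fractional":
        prob = FDEProblem(order, rev_rhs, np.zeros(5), grid.t_final)
        rev = pece_solve(prob, grid).values
    elif stepper == "integer":
        rev = np.zeros((n + 1, 5))
        for k in range(n):
            s = k * h
            lam = rev[k]
            k1 = rev_rhs(s, lam)
            k2 = rev_rhs(s + h / 2, lam + h / 2 * k1)
            k3 = rev_rhs(s + h / 2, lam + h / 2 * k2)
            k4 = rev_rhs(s + h, lam + h * k3)
            rev[k + 1] = lam + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    else:
        raise ValueError(f"unknown adjoint stepper {stepper!r}")
    return rev[::-1]  # index j is now time t_j


def _stationarity(states, adjoints, D_I, D_T, strengths, weights):
    """|dH/dD| at interior (unclamped) nodes of both dosage series."""
    res_i, res_t = [], []
    for j in range(states.values.shape[0]):
        di, dt_, *_ = control_update(states.values[j], adjoints[j], strengths, weights)
        if 0.0 < D_I[j] < 1.0:
            res_i.append(abs(2.0 * weights.b1 * (D_I[j] - di)))
        if 0.0 < D_T[j] < 1.0:
            res_t.append(abs(2.0 * weights.b2 * (D_T[j] - dt_)))
    return {
        "max_D_I": max(res_i) if res_i else 0.0,
        "max_D_T": max(res_t) if res_t else 0.0,
        "n_interior_D_I": len(res_i),
        "n_interior_D_T": len(res_t),
    }


def forward_backward_sweep(order, grid: TimeGrid, y0, params: ModelParameters,
                           strengths: InterventionStrengths, weights: ObjectiveWeights,
                           *, tol: float = 1e-6, max_iter: int = 200,
                           relaxation: float = 0.5,
                           adjoint_stepper: str = "fractional") -> SweepResult:
    """Iterate forward state / backward costate / clamped control update.

    The control update is relaxed, new = (1-r)*old + r*clamp(stationary
    point), which is the standard stabilization for these sweeps.
    Convergence is declared when the maximum absolute change of both dosage
    series falls below ``tol``; on hitting the iteration cap the best
    iterate is returned with ``converged=False`` rather than failing
    silently.  Monotone descent of J is not guaranteed and not asserted;
    the per-iteration history is returned for inspection.
    """
    n_nodes = len(grid)
    D_I = np.zeros(n_nodes)
    D_T = np.zeros(n_nodes)
    J_history: list[float] = []
    converged = False
    states = adjoints = None
    iterations = 0

    for iterations in range(1, max_iter + 1):
        states = _solve_forward(order, grid, y0, params, strengths, D_I, D_T)
        adjoints = _solve_adjoint(order, grid, states, params, strengths, weights,
                                  D_I, D_T, stepper=adjoint_stepper)
        new_I = np.empty(n_nodes)
        new_T = np.empty(n_nodes)
        for j in range(n_nodes):
            _, _, ci, ct = control_update(states.values[j], adjoints[j], strengths, weights)
            new_I[j] = ci
            new_T[j] = ct
        upd_I = (1.0 - relaxation) * D_I + relaxation * new_I
        upd_T = (1.0 - relaxation) * D_T + relaxation * new_T
        change = max(np.abs(upd_I - D_I).max(), np.abs(upd_T - D_T).max())
        D_I, D_T = upd_I, upd_T
        sched = ControlSchedule(grid, D_I, D_T)
        J_history.append(objective_J(states, sched, weights))
        if change < tol:
            converged = True
            break

    states = _solve_forward(order, grid, y0, params, strengths, D_I, D_T)
    adjoints = _solve_adjoint(order, grid, states, params, strengths, weights,
                              D_I, D_T, stepper=adjoint_stepper)
    sched = ControlSchedule(grid, D_I, D_T)
    J_final = objective_J(states, sched, weights)
    stat = _stationarity(states, adjoints, D_I, D_T, strengths, weights)
    return SweepResult(sched, states, adjoints, J_final, J_history,
                       iterations, converged, stat)
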