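"""Long-term treatment effects, quality of life, and cost-benefit accounting.

The cumulative-toxicity burden E(t) follows a linear first-order ODE driven
by the two dosage schedules,

    dE/dt = -theta1 E + theta2 D_I(t) + theta3 D_T(t),

and the quality-of-life trajectory couples to it,

    dQoL/dt = delta0 E - eta QoL.

Both are integer-order equations and are integrated with classical RK4 on
the simulation grid (dosages interpolated linearly at half steps).  A
Caputo-fractional variant of E(t) is available behind a flag for
exploratory use, default off: the fractional order otherwise enters the
outcomes only through the dosage schedules feeding them.

Costs: the direct-cost integral is *linear* in dosages and signals (unlike
the quadratic objective J -- both definitions coexist),

    C_direct   = int_0^Tf (b1 D_I + b2 D_T + c1 u_I + c2 u_T) dt,
    C_indirect = int_0^Tf QoL dt          (a QALY-style aggregate),
    CBR        = C_indirect / (C_direct + C_indirect)  in [0, 1].

All integrals use the composite trapezoid rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .pece import FDEProblem, TimeGrid, pece_solve
from .control import ObjectiveWeights

__all__ = [
    "OutcomeParameters",
    "longterm_effects",
    "qol",
    "direct_cost",
    "indirect_cost",
    "cost_benefit_ratio",
]


@dataclass(frozen=True)
class OutcomeParameters:
    """Rates of the long-term-effect and quality-of-life dynamics.

    theta1: decay of cumulative effects (1/week); theta2/theta3: dosage
    contributions of D_I and D_T; delta0: effect-to-QoL coupling; eta: QoL
    decay; E0/Q0: initial levels.  Defaults are the shipped preset
    (theta = (1, 0.3, 0.5), E0 = 1; delta0 = 0.6, eta = 0.25, Q0 = 1).
    """

    theta1: float = 1.0
    theta2: float = 0.3
    theta3: float = 0.5
    delta0: float = 0.6
    eta: float = 0.25
    E0: float = 1.0
    Q0: float = 1.0

    def __post_init__(self) -> None:
        for k, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"outcome parameter {k} must be non-negative, got {v}")

    def as_dict(self) -> dict:
        return asdict(self)


def _rk4_linear(grid: TimeGrid, y0: float, forcing: np.ndarray, decay: float) -> np.ndarray:
    """RK4 integration of y' = -decay*y + forcing(t) with gridded forcing.

    The forcing is interpolated linearly at half steps, preserving RK4's
    accuracy for the piecewise-linear drive used here.
    """
    f = np.asarray(forcing, dtype=float)
    if f.shape[0] != len(grid):
        raise ValueError("forcing series must live on the grid")
    h = grid.step
    out = np.empty(len(grid))
    out[0] = y0
    for j in range(grid.n_steps):
        f0, f1 = f[j], f[j + 1]
        fm = 0.5 * (f0 + f1)
        y = out[j]
        k1 = -decay * y + f0
        k2 = -decay * (y + h / 2 * k1) + fm
        k3 = -decay * (y + h / 2 * k2) + fm
        k4 = -decay * (y + h * k3) + f1
        out[j + 1] = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return out


def longterm_effects(D_I: np.ndarray, D_T: np.ndarray, params: OutcomeParameters,
                     grid: TimeGrid, *, fractional_order: float | None = None) -> np.ndarray:
    """Cumulative treatment-effect series E(t) on the grid.

    With constant dosages the exact solution is
    E(t) = E0 e^{-theta1 t} + (theta2 D_I + theta3 D_T)(1 - e^{-theta1 t})/theta1,
    approached within 1e-6 at h = 1e-3 by the RK4 path; theta1 = 0
    degenerates to linear accumulation and is handled by the same stepper.

    ``fractional_order`` switches on the exploratory Caputo variant
    (D^alpha E = -theta1 E + forcing) solved with the package's PECE
    scheme; default None keeps the integer-order dynamics.
    """
    D_I = np.asarray(D_I, dtype=float)
    D_T = np.asarray(D_T, dtype=float)
    forcing = params.theta2 * D_I + params.theta3 * D_T
    if fractional_order is None:
        return _rk4_linear(grid, params.E0, forcing, params.theta1)
    h = grid.step

    def rhs(t, y):
        j = min(int(round(t / h)), grid.n_steps)
        return np.array([-params.theta1 * y[0] + forcing[j]])

    prob = FDEProblem(fractional_order, rhs, [params.E0], grid.t_final)
    return pece_solve(prob, grid).values[:, 0]


def qol(E: np.ndarray, params: OutcomeParameters, grid: TimeGrid) -> np.ndarray:
    """Quality-of-life series driven by the effect burden E(t)."""
    return _rk4_linear(grid, params.Q0, params.delta0 * np.asarray(E, dtype=float), params.eta)


def direct_cost(D_I, D_T, grid: TimeGrid, weights: ObjectiveWeights,
                u_I=None, u_T=None) -> float:
    """Drug, monitoring and feedback expenses, linear in the schedules."""
    for name, w in (("b1", weights.b1), ("b2", weights.b2), ("c1", weights.c1), ("c2", weights.c2)):
        if w < 0:
            warnings.warn(f"negative cost weight {name}={w}", stacklevel=2)
    integrand = weights.b1 * np.asarray(D_I, dtype=float) + weights.b2 * np.asarray(D_T, dtype=float)
    if u_I is not None:
        integrand = integrand + weights.c1 * np.asarray(u_I, dtype=float)
    if u_T is not None:
        integrand = integrand + weights.c2 * np.asarray(u_T, dtype=float)
    if integrand.shape[0] != len(grid):
        raise ValueError("dosage series must live on the grid")
    return float(np.trapezoid(integrand, grid.nodes))


def indirect_cost(QoL, grid: TimeGrid) -> float:
    """Time integral of quality of life (quality-adjusted life-year proxy)."""
    q = np.asarray(QoL, dtype=float)
    if q.shape[0] != len(grid):
        raise ValueError("QoL series must live on the grid")
    return float(np.trapezoid(q, grid.nodes))


def cost_benefit_ratio(c_direct: float, c_indirect: float) -> float:
    """Indirect costs over total costs; in [0, 1] for non-negative inputs."""
    total = c_direct + c_indirect
    if total == 0:
        raise ZeroDivisionError("cost-benefit ratio undefined: both costs are zero")
    return c_indirect / total
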