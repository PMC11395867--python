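"""Five-compartment lung tumor-immune dynamics and its stability machinery.

States (all in millions of cells / abstract burden units):

    N  cancer cells in lung tissue
    I  immune cells
    P  spread (metastatic) cancer cells
    M  mutated-subpopulation burden
    R  enhanced cytotoxic immune cells

The base vector field couples logistic tumor growth (carrying capacity K),
immune recruitment driven by a constant source ``phi1 * I0`` plus a
quadratic tumor signal ``phi2 * N^2``, metastatic seeding, a mutation
compartment fed by tumor-mutant contact, and an immune-enhancement
compartment growing with I*R contact.  Drug-extended variants add
immunotherapy (dosage D_I) and targeted-therapy (dosage D_T) couplings with
strengths chi1..chi6.

Under the fractional (Caputo, order alpha) formulation every rate carries an
alpha exponent; ``alpha_scale`` applies that convention ("power") or leaves
the printed base values untouched ("literal").
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict

import numpy as np

__all__ = [
    "STATE_NAMES",
    "ModelParameters",
    "InterventionStrengths",
    "EquilibriumPoint",
    "CharacteristicCoefficients",
    "alpha_scale",
    "rhs_base",
    "rhs_treated",
    "rhs_closed_loop",
    "equilibria",
    "jacobian",
    "jacobian_shorthands",
    "characteristic_coefficients",
    "stability_check",
]

STATE_NAMES = ("N", "I", "P", "M", "R")


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants of the untreated system.

    ``immune_source_baseline`` is the constant I0 multiplying phi1 in the
    immune equation; by convention it equals the immune initial condition of
    the active scenario unless explicitly pinned.
    """

    lambda_: float = 0.3      # tumor growth rate
    K: float = 10000.0        # carrying capacity
    mu: float = 0.01          # inhibition of tumor by spread cells
    beta1: float = 0.01       # tumor-immune interaction
    beta2: float = 0.01       # immune-spread interaction
    beta3: float = 0.4        # immune kill of spread cells
    phi1: float = 0.03        # immune source coefficient
    phi2: float = 0.004       # tumor-driven immune recruitment
    phi3: float = 0.1         # immune decay
    gamma_: float = 0.003     # spread growth via tumor contact
    delta_: float = 0.03      # spread cell death
    zeta1: float = 0.9        # mutation pressure on tumor
    zeta2: float = 0.458      # mutant stimulation of immunity
    zeta3: float = 0.8        # enhanced-cell suppression of immunity
    zeta4: float = 0.045      # mutant boost of spread cells
    zeta5: float = 0.5        # tumor-mutant contact growth
    zeta6: float = 0.6        # immune clearance of mutants
    zeta7: float = 0.5        # spread-cell clearance of mutants
    zeta8: float = 0.6        # immune enhancement rate
    immune_source_baseline: float = 0.7

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"parameter {f.name} must be non-negative, got {v}")
        if not self.K > 0:
            raise ValueError("carrying capacity K must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class InterventionStrengths:
    """Drug-effect coefficients chi1..chi6 coupling D_I and D_T into the states."""

    chi1: float = 0.1
    chi2: float = 0.1
    chi3: float = 0.1
    chi4: float = 0.1
    chi5: float = 0.1
    chi6: float = 0.1

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class EquilibriumPoint:
    label: str
    coordinates: np.ndarray
    residual_norm: float
    feasible: bool
    defined: bool = True
    note: str = ""


@dataclass
class CharacteristicCoefficients:
    """Quintic characteristic-polynomial data at an evaluation state.

    ``stab_a1 .. stab_a5`` are the stability coefficients of the factored
    form (lam^2 + a1 lam + a2)(lam^2 + a3 lam + a4)(a5 - lam); they are
    distinct from the objective weights a1..a5.  ``poly`` holds the expanded
    quintic's coefficients, highest degree first.
    """

    stab_a1: float
    stab_a2: float
    stab_a3: float
    stab_a4: float
    stab_a5: float
    poly: np.ndarray
    K: dict


_ALPHA_CONVENTIONS = ("power", "literal")


def alpha_scale(params, order: float, convention: str = "power"):
    """Apply the fractional-order exponent to every rate constant.

    "power" maps each rate r to r**order (every parameter appears with an
    alpha superscript in the fractional model); "literal" leaves the printed
    base values unchanged.  The carrying capacity and the intervention
    strengths scale the same way; ``immune_source_baseline`` is an initial
    condition, not a rate, and is never scaled.
    """
    if not (0.0 < order <= 1.0):
        raise ValueError(f"order must lie in (0, 1], got {order}")
    if convention not in _ALPHA_CONVENTIONS:
        raise ValueError(f"unknown alpha-scaling convention {convention!r}; options: {_ALPHA_CONVENTIONS}")
    if convention == "literal" or order == 1.0:
        return params
    skip = {"immune_source_baseline"}
    scaled = {
        f.name: (getattr(params, f.name) if f.name in skip else getattr(params, f.name) ** order)
        for f in fields(params)
    }
    return type(params)(**scaled)


def rhs_base(state, params: ModelParameters) -> np.ndarray:
    """Untreated vector field."""
    N, I, P, M, R = np.asarray(state, dtype=float)
    p = params
    dN = p.lambda_ * N * (1.0 - N / p.K) - p.mu * N * P - p.beta1 * N * I - p.zeta1 * N * M
    dI = (p.phi1 * p.immune_source_baseline + p.phi2 * N * N - p.phi3 * I
          - p.beta2 * I * P + p.zeta2 * I * M - p.zeta3 * I * R)
    dP = p.gamma_ * N * P - p.delta_ * P - p.beta3 * I * P + p.zeta4 * P * M
    dM = p.zeta5 * N * M - p.zeta6 * I * M - p.zeta7 * P * M
    dR = p.zeta8 * I * R
    return np.array([dN, dI, dP, dM, dR])


def rhs_treated(state, params: ModelParameters, strengths: InterventionStrengths,
                dosages: tuple[float, float]) -> np.ndarray:
    """Vector field with immunotherapy (D_I) and targeted-therapy (D_T) dosing.

    Dosages are nominally in [0, 1]; clamping is the caller's responsibility
    (closed-loop drivers apply sums D + u up to 2 by design).
    """
    d_i, d_t = dosages
    N, I, P, M, R = np.asarray(state, dtype=float)
    c = strengths
    base = rhs_base(state, params)
    drug = np.array([
        -c.chi1 * N * d_i,
        c.chi2 * I * d_t,
        -c.chi3 * P * d_t,
        c.chi4 * M * d_t + c.chi5 * M * d_i,
        c.chi6 * R * d_i,
    ])
    return base + drug


def rhs_closed_loop(state, params, strengths, dosages, signals) -> np.ndarray:
    """Closed-loop field: the PID signals add to the base dosages."""
    u_i, u_t = signals
    d_i, d_t = dosages
    return rhs_treated(state, params, strengths, (d_i + u_i, d_t + u_t))


# ---------------------------------------------------------------------------
# Equilibria


def _quadratic_roots(a: float, b: float, c: float):
    """Roots (-b +/- sqrt(b^2-4ac)) / 2a; returns (root_plus, root_minus, real?)."""
    if a == 0.0:
        return None, None, False
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        return None, None, False
    s = np.sqrt(disc)
    return (-b + s) / (2.0 * a), (-b - s) / (2.0 * a), True


def _mk_point(label: str, coords, params: ModelParameters) -> EquilibriumPoint:
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        return EquilibriumPoint(label, coords, np.inf, False, defined=False,
                                note="non-finite coordinates")
    res = float(np.linalg.norm(rhs_base(coords, params)))
    feasible = bool(np.all(coords >= -1e-12))
    return EquilibriumPoint(label, coords, res, feasible)


def _undefined(label: str, note: str) -> EquilibriumPoint:
    return EquilibriumPoint(label, np.full(5, np.nan), np.inf, False, defined=False, note=note)


def equilibria(params: ModelParameters) -> list[EquilibriumPoint]:
    """All closed-form equilibrium candidates of the untreated system.

    The closed forms are implemented verbatim from their published
    expressions and then *verified numerically*: each returned point carries
    the Euclidean norm of the vector field evaluated at it.  Several
    candidates do not actually annihilate the immune equation (the constant
    source phi1*I0 and the phi2*N^2 term survive); the residual report is
    authoritative, the list is not silently corrected.  Candidates with a
    vanishing denominator or complex roots are emitted flagged, not raised.
    The mutant-quadratic coefficient ``c`` is printed with an undefined rate
    phi7; it is read here as phi3.
    """
    p = params
    I0 = p.immune_source_baseline
    out: list[EquilibriumPoint] = []

    out.append(_mk_point("E0", [0, 0, 0, 0, 0], p))
    out.append(_mk_point("E1", [0, 0, 0, p.delta_ / p.zeta4, 0], p)
               if p.zeta4 > 0 else _undefined("E1", "zeta4 = 0"))
    out.append(_mk_point("E2", [0, p.phi1 * I0 / p.phi3, 0, 0, 0], p)
               if p.phi3 > 0 else _undefined("E2", "phi3 = 0"))

    if p.beta3 > 0 and p.beta2 > 0 and p.delta_ > 0:
        out.append(_mk_point("E3", [
            0, -p.delta_ / p.beta3,
            (-p.beta3 * p.phi1 * I0 + p.phi3 * p.delta_) / (p.beta2 * p.delta_), 0, 0], p))
    else:
        out.append(_undefined("E3", "zero denominator"))

    # E4/E5: M solves a*M^2 + b*M + c = 0
    qa = p.beta3 ** 2 * p.zeta2 * p.zeta4 * p.zeta7 * p.zeta6 + p.beta3 * p.beta2 * p.zeta4 ** 2 * p.zeta6 ** 2
    qb = -(p.beta3 ** 2 * p.zeta7 * p.zeta2 * p.zeta6 * p.delta_
           + p.beta3 ** 2 * p.zeta7 * p.phi3 * p.zeta6 * p.zeta4
           + 2 * p.beta2 * p.beta3 * p.zeta3 ** 2 * p.delta_ * p.zeta4)
    qc = (p.beta3 ** 3 * p.zeta6 * p.zeta7 * p.phi1 * I0
          + p.beta3 ** 3 * p.zeta7 * p.zeta6 * p.delta_ * p.phi3
          + p.beta3 * p.beta2 * p.zeta6 ** 2 * p.delta_ ** 2)
    m_plus, m_minus, real = _quadratic_roots(qa, qb, qc)
    for label, m_star in (("E4", m_plus), ("E5", m_minus)):
        if not real or p.beta3 == 0 or p.zeta7 == 0:
            out.append(_undefined(label, "complex mutant root or zero denominator"))
            continue
        I_star = (p.zeta4 * m_star - p.delta_) / p.beta3
        P_star = p.zeta6 * (p.delta_ - p.zeta4 * m_star) / (p.beta3 * p.zeta7)
        out.append(_mk_point(label, [0, I_star, P_star, m_star, 0], p))

    out.append(_mk_point("E6", [p.K, 0, 0, 0, 0], p))

    if p.gamma_ > 0 and p.mu > 0:
        N7 = p.delta_ / p.gamma_
        P7 = (p.gamma_ * p.lambda_ * p.K - p.delta_ * p.lambda_) / (p.mu * p.gamma_ * p.K)
        out.append(_mk_point("E7", [N7, 0, P7, 0, 0], p))
        out.append(_mk_point("E8", [N7, 0, P7, 0, 0], p))  # printed twice
    else:
        out.append(_undefined("E7", "gamma or mu zero"))
        out.append(_undefined("E8", "gamma or mu zero"))

    # E9: tumor/spread/mutant coexistence without immunity
    den9 = (p.lambda_ * p.zeta4 * p.zeta7 + p.mu * p.K * p.zeta4 * p.zeta5
            - p.lambda_ * p.zeta1 * p.zeta7 * p.gamma_)
    if den9 != 0 and p.zeta4 > 0 and p.zeta7 > 0:
        N9 = (p.lambda_ * p.K * p.zeta4 * p.zeta7 - p.lambda_ * p.zeta1 * p.zeta7 * p.delta_) / den9
        P9 = (p.lambda_ * p.K * p.zeta4 * p.zeta5 * p.zeta7
              - p.lambda_ * p.zeta1 * p.zeta5 * p.zeta7 * p.delta_) / (den9 * p.zeta7)
        M9 = p.delta_ / p.zeta4 - (p.gamma_ * p.lambda_ * p.K * p.zeta4 * p.zeta7
                                   - p.lambda_ * p.zeta1 * p.zeta7 * p.delta_ * p.gamma_) / (den9 * p.zeta4)
        out.append(_mk_point("E9", [N9, 0, P9, M9, 0], p))
    else:
        out.append(_undefined("E9", "zero denominator"))

    # E10/E11: tumor-immune pair, no spread/mutants
    if p.beta1 > 0 and p.phi2 > 0:
        discN = (p.phi3 ** 2 * p.lambda_ ** 2
                 + 4 * p.K * p.beta1 * p.phi2 * (p.phi3 * p.lambda_ * p.K - p.beta1 * p.K * p.phi1 * I0))
        sI = (p.lambda_ ** 2 * p.phi3 + 2 * p.phi2 * p.lambda_ * p.K ** 2 * p.beta1)
        discI = sI ** 2 - 4 * p.phi2 * p.beta1 ** 2 * p.K ** 2 * (
            p.phi2 * p.lambda_ ** 2 * p.K ** 2 + p.lambda_ ** 2 * p.phi1 * I0)
        if discN >= 0 and discI >= 0:
            denN = 2 * p.K * p.beta1 * p.phi2
            denI = 2 * p.phi2 * p.beta1 ** 2 * p.K ** 2
            out.append(_mk_point("E10", [(-p.phi3 * p.lambda_ - np.sqrt(discN)) / denN,
                                         (sI - np.sqrt(discI)) / denI, 0, 0, 0], p))
            out.append(_mk_point("E11", [(-p.phi3 * p.lambda_ + np.sqrt(discN)) / denN,
                                         (sI + np.sqrt(discI)) / denI, 0, 0, 0], p))
        else:
            out.append(_undefined("E10", "complex root"))
            out.append(_undefined("E11", "complex root"))
    else:
        out.append(_undefined("E10", "beta1 or phi2 zero"))
        out.append(_undefined("E11", "beta1 or phi2 zero"))

    # E12/E13: tumor-immune-spread coexistence; N solves a*N^2 - b*N + c = 0
    sa = (p.beta2 * p.beta3 * p.gamma_ * p.lambda_ + p.mu * p.K * p.phi2 * p.beta3 ** 2
          + p.beta2 * p.beta1 * p.K * p.gamma_ ** 2)
    sb = (p.beta2 * p.beta3 * p.gamma_ * p.lambda_ * p.K + p.beta2 * p.beta3 * p.delta_ * p.lambda_
          + p.mu * p.K * p.phi3 * p.gamma_ + 2 * p.beta1 * p.beta2 * p.gamma_ * p.K * p.delta_)
    sc = (p.beta2 * p.beta3 * p.lambda_ * p.K * p.delta_ + p.beta3 ** 2 * p.mu * p.K * p.phi1 * I0
          + p.mu * p.K * p.phi3 * p.delta_ - p.beta1 * p.beta2 * p.delta_ ** 2 * p.K)
    n_plus, n_minus, real = _quadratic_roots(sa, sb, sc)
    for label, n_star in (("E12", n_plus), ("E13", n_minus)):
        if not real or p.beta3 == 0 or p.beta2 == 0:
            out.append(_undefined(label, "complex root or zero denominator"))
            continue
        den = p.beta2 * p.gamma_ * n_star - p.beta2 * p.delta_
        if den == 0:
            out.append(_undefined(label, "zero denominator in P"))
            continue
        I_star = (p.gamma_ * n_star - p.delta_) / p.beta3
        P_star = (p.beta3 * p.phi1 * I0 + p.beta3 * p.phi2 * n_star ** 2
                  - p.phi3 * p.gamma_ * n_star + p.phi3 * p.delta_) / den
        out.append(_mk_point(label, [n_star, I_star, P_star, 0, 0], p))

    out.extend(_e14_points(p))
    return out


def _e14_points(p: ModelParameters) -> list[EquilibriumPoint]:
    """Full-coexistence candidates (both branches of the spread quadratic)."""
    I0 = p.immune_source_baseline
    z1, z2, z3, z4, z5, z6, z7 = p.zeta1, p.zeta2, p.zeta3, p.zeta4, p.zeta5, p.zeta6, p.zeta7
    qa = z6 * z7 * p.beta3 + z2 * z7 ** 2 * p.beta3
    qb = (z4 * z6 * z7 * p.phi3 - z5 * z6 * p.beta3 - z2 * z5 * z7 * p.beta3
          - 2 * z2 * z5 * z7 * p.beta3 + z2 * z6 * z7 * p.gamma_
          - z2 * z6 * z7 * p.delta_ + z3 * z6 * z7)
    qc = (z4 * z6 ** 2 * p.phi1 * I0 + z4 * z6 ** 2 * p.phi2 - z4 * z5 * z6 * p.phi3
          + z2 * z5 * p.beta3 - z2 * z5 * z6 * p.gamma_ - z3 * z5 * z6)
    p_plus, p_minus, real = _quadratic_roots(qa, qb, qc)
    if not real:
        return [_undefined("E14+", "complex spread root"), _undefined("E14-", "complex spread root")]

    denN = (z4 * z6 ** 2 * p.lambda_ + z4 * z5 * z6 * p.beta1 * p.K
            - z1 * z6 * p.lambda_ * p.gamma_ + z1 * z5 * p.beta3 * p.lambda_)
    denI = (z4 * z6 ** 3 * p.lambda_ + z4 * z5 * z6 ** 2 * p.beta1 * p.K
            - z1 * z6 ** 2 * p.lambda_ * p.gamma_ + z1 * z5 * z6 * p.beta3 * p.lambda_)
    out = []
    for label, P_bar in (("E14+", p_plus), ("E14-", p_minus)):
        if denN == 0 or denI == 0 or z4 == 0:
            out.append(_undefined(label, "zero denominator"))
            continue
        N_bar = (z4 * z6 ** 2 * p.lambda_ * p.K - z1 * z6 * p.delta_ * p.lambda_
                 - (z6 ** 2 * z4 * p.mu * p.K - z4 * z6 * z7 * p.beta1 * p.K
                    - z1 * z7 * p.beta3 * p.lambda_) * P_bar) / denN
        I_bar = (z4 * z5 * z6 ** 2 * p.lambda_ * p.K - z1 * z5 * z6 * p.lambda_
                 - (z4 * z5 * z6 ** 2 * p.mu * p.K - z1 * z5 * z7 * p.beta3 * p.lambda_
                    + z4 * z6 ** 2 * z7 - z1 * z6 * z7 * p.lambda_ * p.gamma_
                    + z1 * z5 * z7 * p.beta3 * p.lambda_) * P_bar) / denI
        M_bar = (p.beta3 * I_bar - p.gamma_ + p.delta_) / z4
        if z3 == 0 or I_bar == 0:
            out.append(_undefined(label, "zero denominator in R"))
            continue
        R_bar = (p.phi1 * I0 + p.phi2 * N_bar ** 2
                 - (p.phi3 + p.beta2 * P_bar - z2 * M_bar) * I_bar) / (z3 * I_bar)
        out.append(_mk_point(label, [N_bar, I_bar, P_bar, M_bar, R_bar], p))
    return out


# ---------------------------------------------------------------------------
# Jacobian and stability


def jacobian(state, params: ModelParameters) -> np.ndarray:
    """Analytic 5x5 Jacobian of the untreated vector field at a state."""
    N, I, P, M, R = np.asarray(state, dtype=float)
    p = params
    return np.array([
        [p.lambda_ - 2 * p.lambda_ * N / p.K - p.mu * P - p.beta1 * I - p.zeta1 * M,
         -p.beta1 * N, -p.mu * N, -p.zeta1 * N, 0.0],
        [2 * p.phi2 * N,
         -p.phi3 - p.beta2 * P + p.zeta2 * M - p.zeta3 * R,
         -p.beta2 * I, p.zeta2 * I, -p.zeta3 * I],
        [p.gamma_ * P, -p.beta3 * P,
         p.gamma_ * N - p.delta_ - p.beta3 * I + p.zeta4 * M,
         p.zeta4 * P, 0.0],
        [p.zeta5 * M, -p.zeta6 * M, -p.zeta7 * M,
         p.zeta5 * N - p.zeta6 * I - p.zeta7 * P, 0.0],
        [0.0, p.zeta8 * R, 0.0, 0.0, p.zeta8 * I],
    ])


def jacobian_shorthands(jac: np.ndarray) -> dict:
    """The K1..K19 entry shorthands used by the characteristic polynomial."""
    J = np.asarray(jac, dtype=float)
    return {
        "K1": J[0, 0], "K2": J[0, 1], "K3": J[0, 2], "K4": J[0, 3],
        "K5": J[1, 0], "K6": J[1, 1], "K7": J[1, 2], "K8": J[1, 3], "K9": J[1, 4],
        "K10": J[2, 0], "K11": J[2, 1], "K12": J[2, 2], "K13": J[2, 3],
        "K14": J[3, 0], "K15": J[3, 1], "K16": J[3, 2], "K17": J[3, 3],
        "K18": J[4, 1], "K19": J[4, 4],
    }


def characteristic_coefficients(K: dict) -> CharacteristicCoefficients:
    """Stability coefficients of the factored quintic from the K shorthands.

    The published a2/a4 expressions carry typographical defects (unbalanced
    subscripts); they are reproduced here under the most literal reading and
    are for comparison only -- direct eigenvalues of the Jacobian are the
    authoritative stability diagnostic.  ``poly`` expands
    (lam^2 + a1 lam + a2)(lam^2 + a3 lam + a4)(a5 - lam).
    """
    g = K.__getitem__
    a1 = -g("K1")
    a3 = -g("K6")
    a5 = g("K12") + g("K17") + g("K19")
    a2 = (-g("K2") * g("K5") + g("K2") * g("K7") * g("K10") + g("K3") * g("K7") * g("K11")
          - g("K3") * g("K10") + g("K3") * g("K13") * g("K14") + g("K4") * g("K10") * g("K16")
          - g("K4") * g("K12") * g("K14") - g("K12") * g("K17") - g("K13") * g("K16")
          - g("K7") * g("K11") * g("K17") + g("K7") * g("K13") * g("K15")
          + g("K8") * g("K11") * g("K16") - g("K8") * g("K15") - g("K4") * g("K14")
          + g("K12") * g("K19") - g("K7") * g("K11") * g("K19") - g("K9") * g("K18")
          + g("K17") * g("K19") - g("K8") * g("K15") - g("K13") * g("K16"))
    a4 = (-g("K7") * g("K11") + g("K12") * g("K17") - g("K13") * g("K16")
          + g("K12") * g("K19") + g("K17") * g("K19"))
    q1 = np.array([1.0, a1, a2])
    q2 = np.array([1.0, a3, a4])
    lin = np.array([-1.0, a5])
    poly = np.polymul(np.polymul(q1, q2), lin)
    return CharacteristicCoefficients(a1, a2, a3, a4, a5, poly, dict(K))


def stability_check(coeffs: CharacteristicCoefficients, jac: np.ndarray, order: float = 1.0) -> dict:
    """Stability verdict at an evaluation state.

    Reports (i) the sign criterion a1..a4 > 0, a5 < 0 on the factored-
    quintic coefficients (Routh-Hurwitz on each quadratic factor plus the
    linear eigenvalue a5), (ii) the direct Jacobian eigenvalues, and (iii)
    the fractional sector margin min |arg(lam_i)| versus order*pi/2 -- an
    extension diagnostic: the sign criterion itself is the integer-order
    test applied verbatim.
    """
    eigs = np.linalg.eigvals(np.asarray(jac, dtype=float))
    crit = (coeffs.stab_a1 > 0 and coeffs.stab_a2 > 0 and coeffs.stab_a3 > 0
            and coeffs.stab_a4 > 0 and coeffs.stab_a5 < 0)
    if np.all(np.abs(eigs) < 1e-12):
        eig_verdict = "marginal"
    elif np.all(eigs.real < 0):
        eig_verdict = "stable"
    elif np.any(eigs.real > 0):
        eig_verdict = "unstable"
    else:
        eig_verdict = "marginal"
    nonzero = eigs[np.abs(eigs) > 1e-12]
    frac_margin = float(np.min(np.abs(np.angle(nonzero)))) if nonzero.size else float("nan")
    return {
        "criterion_stable": bool(crit),
        "eigenvalues": eigs,
        "eigenvalue_verdict": eig_verdict,
        "fractional_margin": frac_margin,
        "fractional_threshold": order * np.pi / 2.0,
        "fractional_stable": bool(frac_margin > order * np.pi / 2.0) if np.isfinite(frac_margin) else None,
        "fractional_note": "sector test |arg(lam)| > alpha*pi/2 is an extension diagnostic",
    }
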