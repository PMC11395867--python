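# Methods

This note records the model, the numerical choices, and the design
decisions behind `fraclung`, in the order a reader would meet them.

## Fractional dynamics and the PECE solver

The five-compartment system is posed with the Caputo derivative of order
α ∈ (0, 1], so each state carries a power-law memory of its history.  The
solver converts the initial-value problem to its Volterra form
y(t) = y₀ + Γ(α)⁻¹ ∫₀ᵗ (t−s)^{α−1} f(s, y(s)) ds and steps it on a uniform
grid t_j = jh, h = T_f/N, with a predict–evaluate–correct–evaluate pair:

* **Predictor** (rectangle rule): yᵖ_{n+1} = y₀ + h^α/Γ(α+1) Σₘ Bₘ f(tₘ, yₘ)
  with Bₘ = (n−m+1)^α − (n−m)^α.  The weights are strictly positive and
  telescope to (n+1)^α, a cheap exactness check the tests enforce up to
  n = 10⁴.
* **Corrector** (product trapezoid from two-point Lagrange interpolation):
  weights [(k+1)^{α+1} − k^α(k+α+1)] on f at the *predicted* states and
  −[(k+1)^α(k−α) − k^{α+1}] on f at the corrected states, k = n−m, with
  prefactor h^α/Γ(α+2).  At α = 1 every weight is 1 and the scheme
  degenerates to a full-memory Heun/trapezoid method.

Two formulation details deserve emphasis.  First, the corrector's memory
sum keeps the predicted states yᵖ_{m+1} at *every* node, not only the
newest one; this is the scheme as formulated and is kept verbatim (one
corrector pass per step, no iterate-to-convergence variant).  Second, the
memory sums are full — no short-memory truncation — so a solve costs
O(N²); at the scales used here (N ≤ a few thousand) that is seconds.
Against the Mittag-Leffler oracle E_α(−t^α) for D^α y = −y the solver is
accurate to ~1.3·10⁻⁴ at h = 10⁻³ over [0, 1] for α ∈ [0.5, 1], an order
better than the 10⁻³ acceptance band.

The Mittag-Leffler function itself is evaluated by its defining series
Σ z^k/Γ(αk+1) with log-gamma terms and a relative-tail stopping rule; the
arguments needed here (|z| of a few units) are far from the region where
the alternating series degrades.  Tests cross-check it against exp and the
α = ½ identity E_{1/2}(z) = e^{z²} erfc(−z).

Residual diagnostics plug a computed trajectory back into the model.  At
α = 1 the derivative is replaced by the forward difference
(y_{j+1} − y_j)/h, a first-order operator (halving h halves the residual,
asserted in tests).  For α < 1 no printed diagnostic exists; the package
extends it with the L1 discrete Caputo operator on the computed
trajectory, flagged as an extension in the output metadata.  Fractional
residuals show the expected power-law initial layer — largest at the first
node, decaying fast away from t = 0 — and tests assert that structure
rather than a flat bound.

Degenerate grids (N = 0) are rejected; a non-finite vector-field value
raises a divergence error naming the node.

## α-scaling of parameters

Every rate appears with an α exponent in the fractional model, while the
reference parameter list gives plain base values.  The package's default
convention, `"power"`, maps each rate r ↦ r^α (including K and the χ's);
`"literal"` leaves the base values untouched.  The choice is recorded in
run metadata.  The immune source baseline I₀ is an initial condition, not
a rate, and is never exponentiated.

## The immune source and the equilibrium list

The immune equation contains the constant source φ₁^α I₀, with I₀ the
immune initial condition of the active scenario (the model conflates the
source constant with the initial condition; changing the scenario's
initial state updates the source unless the parameter is pinned
explicitly).  A consequence: the origin and several of the closed-form
equilibrium candidates (E₀, E₁, E₆, E₇, …) do not annihilate the immune
equation — at the tumor-capacity candidate E₆ = (K, 0, 0, 0, 0) the
residual is φ₁I₀ + φ₂K² ≈ 4·10⁵ with the reference preset.  All fifteen
closed forms are therefore implemented verbatim and *verified
numerically*: every emitted point carries the Euclidean norm of the
vector field at it, complex or divided-by-zero candidates are flagged
rather than raised, and the residual report is authoritative over the
printed list.  The immune-only point E₂ = (0, φ₁I₀/φ₃, 0, 0, 0) =
(0, 0.21, 0, 0, 0) is exact to machine precision.  The mutant-quadratic
coefficient for E₄/E₅ references a rate φ₇ that does not exist in the
model; it is read as φ₃.  The full-coexistence point's spread coordinate
is a quadratic with ±; both branches are emitted ("E14+", "E14-").

Non-negativity is *not* enforced by projection: trajectories that leave
the physical region trigger a logged warning, preserving the diagnostic
value of the raw dynamics over cosmetics.

## Stability machinery

The Jacobian is the exact analytic derivative of the vector field (its
printed rendition contains transcription slips; tests pin it to central
finite differences at 10⁻⁶).  The characteristic quintic is handled
through the K₁…K₁₉ entry shorthands and the factored form
(λ̄² + a₁λ̄ + a₂)(λ̄² + a₃λ̄ + a₄)(a₅ − λ̄) with a₁ = −K₁, a₃ = −K₆,
a₅ = K₁₂ + K₁₇ + K₁₉.  The published a₂/a₄ combinations carry
unbalanced-subscript typos; they are reproduced under the most literal
reading for comparison only, and direct eigenvalues of the Jacobian are
the authoritative stability diagnostic — discrepancies are reported, never
hidden.  The verdict record contains (i) the sign criterion a₁…a₄ > 0,
a₅ < 0, which is an integer-order Routh–Hurwitz test, (ii) the
eigenvalues, and (iii) the fractional sector margin min|arg λ| vs απ/2 as
an extension diagnostic that is informative for α < 1 but not used for
acceptance.

## Optimal dosing

The objective J integrates a₁N + … + a₅R + b₁D_I² + b₂D_T²
(+ c₁u_I² + c₂u_T² when PID signals participate) by the trapezoid rule.
Stationarity of the Hamiltonian gives closed-form updates
Δ_I = (χ₁λ₁N − χ₅λ₄M − χ₆λ₅R)/(2b₁),
Δ_T = −(χ₂λ₂I − χ₃λ₃P + χ₄λ₄M)/(2b₂), clamped to [0, 1]
(D* = min{max{0, Δ}, 1}); the second-order conditions ∂²H/∂D² = 2b > 0
make these minimizers.  The costate equations are implemented as the exact
analytic −∂H/∂state (tests pin both variants to central differences of
the Hamiltonian at 200 seeded random points, 10⁻⁶ tolerance).

Whether the costates should themselves be fractional is genuinely open:
they are written as integer-order d/dt but stepped with the fractional
weights in the discrete treatment.  Both are provided — backward RK4
(`adjoint_stepper="integer"`) and fractional PECE on reversed time
s = T_f − t (default, matching the discrete treatment); the terminal
condition λ(T_f) = 0 becomes the initial condition of the reversed solve,
so transversality holds exactly.

The forward–backward sweep alternates forward state solve, backward
costate solve, and a relaxed control update new = ½·old + ½·clamp(Δ)
(relaxation is the standard stabilization for these sweeps; the update
rule itself has no prescribed damping).  Convergence is declared at
max-abs control change < 10⁻⁶ — chosen so the interior stationarity
residual |∂H/∂D| = 2b|D − Δ| of the converged iterate sits well inside
10⁻³ — with a 200-iteration cap; hitting the cap returns the best iterate
flagged, never silently.  Monotone descent of J is not guaranteed and not
asserted; instead the converged J must not exceed either constant-dose
baseline (D ≡ 0, D ≡ 1) and the per-iteration J history is returned.
The clamping case reading "0 < Δ < 0" in the source formulation is the
evident typo for 0 < Δ < 1.

## PID feedback

The "desired state" of the feedback loops is never defined in the source
material; the default setpoint policy tracks the tumor burden N → 0 for
the immunotherapy error and the spread burden P → 0 for the targeted
error (e = actual − desired), matching the therapies' stated targets, and
any component/reference pair is configurable.  The discrete law uses the
trapezoid integral and a first-order backward-difference derivative (zero
at the first node).  Gains default to K_p = 0.5, K_i = 0.1, K_d = 0.05 —
package choices, flagged "assumed".

`closed_loop_simulate` steps the fractional system with applied dosages
D + u, the signal recomputed causally each step from the error history so
far (the newest node's error is first taken from the predicted state,
then refreshed from the corrected state before entering the history).
The base dosage and the signal are clamped to [0, 1] *separately*, never
their sum, so applied dosages may legitimately reach 2.  With zero gains
the loop reproduces the open-loop solver bit-for-bit (same arithmetic
path).  A `t_off` argument implements the post-treatment policy: PID law
active for t ≤ t_off, zero after, boundary included.

The feedback signal appears in two distinct roles — a dosage increment
(the closed loop above) and an independently optimized control with its
own stationary points Ψ = Δ·(b/c) in the combined optimal+PID system.
Both pathways are implemented as separate operations rather than merged;
in the combined sweep all four controls are clamped to [0, 1], and as
c → ∞ the signals vanish and the plain optimal problem is recovered
(asserted at c = 10⁶).

## Outcomes and economics

E(t) and QoL(t) are integer-order linear ODEs integrated with classical
RK4 on the simulation grid, with the dosage forcing interpolated linearly
at half steps; against the constant-input closed forms they are accurate
to ~10⁻¹⁴ at h = 10⁻³ (the 10⁻⁶ band is met with orders to spare), and
θ₁ = 0 degenerates gracefully to linear accumulation.  An exploratory
Caputo-order variant of E(t) exists behind a flag (default off): the
fractional order otherwise reaches the outcomes only through the dosage
schedules feeding them.  The direct-cost integral is *linear* in dosages
and signals even though J penalizes their squares — both definitions
coexist deliberately.  All cost integrals are composite-trapezoid on the
grid (h = 0.01, T_f = 3 in the shipped cost preset).  The cost pairs of
the published cost table cannot be recomputed from scratch (the weights
and intervention strengths behind them are not published); the
cost–benefit identity CBR = C_ind/(C_dir + C_ind) is reproduced from the
printed pairs to 10⁻⁶, which is the reproducible content of that table.

## Scenarios, presets, and the synthetic-observation generator

Presets carry the published reference rates verbatim and the standard
initial conditions.  Horizons: the untreated reference scenario base-A
runs 15 weeks (the window named in the validation discussion); base-B
runs 3 weeks because with its crowded initial state (1, 3, 1, 1, 1) the
untreated dynamics leave the non-negative region soon after t ≈ 4 and
diverge near t ≈ 9 (the ζ₈IR term is super-exponential once I grows) — 3
weeks covers the described transient while staying physical.  Treatment
and outcome scenarios use T_f = 3, h = 0.01.  Fields with no published
values (χ's, objective weights, gains, setpoints) are filled with the
package defaults and listed under `assumed_fields` in every provenance
file.

The synthetic-observation generator emulates validation-style observed
data of unstated provenance: it subsamples a model trajectory at evenly
spaced times and perturbs multiplicatively with seeded Gaussian noise,
defaulting to 30 points at 5 % relative noise — our own choice of a
realistic measurement-error scale.  It produces data *from the model
itself*, so fit metrics against it validate the solver/compare pipeline,
not the model's biological adequacy; it has no outliers, no
heteroscedastic floor, and no sampling irregularity, all features real
tumor-burden data would have.  Parameter estimation against the
observations is deliberately out of scope (comparison only).

Sensitivity sweeps re-run a scenario across one parameter and report
terminal states plus qualitative monotonicity observations as report
lines.  One empirical subtlety: increasing the tumor–immune interaction
β₁ lowers the tumor curve pointwise throughout its expansion phase, but
the terminal ordering at 15 weeks inverts slightly (differences ~3 % at
N ≈ 0.2) — the suppression claim holds where the tumor is large, not at
the decayed tail.  The enhancement-rate sweep (ζ₈ up ⇒ terminal R up) is
monotone as stated.  Tests and the acceptance script assert exactly these
verified forms.

## Problem sizes and determinism

Default problem sizes — N = 1000 steps for solver-oracle checks
(h = 10⁻³ on [0, 1]), N = 300 (h = 0.01, T_f = 3) for control and outcome
scenarios, N = 1500 (h = 0.01, T_f = 15) for the untreated reference run —
were chosen as the coarsest grids at which every tolerance above is met
with at least an order of magnitude of margin.  The dynamical core is
fully deterministic (identical inputs give bit-identical trajectories,
asserted); the only randomness in the package is the observation noise
and the random evaluation points of verification checks, all driven by
explicit seeds.

## Known limitations

* Orders α > 1, adaptive stepping, and non-uniform grids are out of scope;
  the O(N²) memory cost makes very long horizons expensive.
* No convergence-order theory is claimed for the PECE scheme; validation
  is oracle- and residual-based.
* The stability criterion applied to the factored quintic is the
  integer-order test; for α < 1 it is conservative, and the sector
  diagnostic is informational only.
* Global optimality of the sweep is not certified; it is a local
  fixed-point method with baseline comparisons.
* The economics layer has no discounting or currency model; CBR is the
  only comparative statistic.
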