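"""Scenario presets, config serialization, synthetic observations and sweeps.

The shipped presets carry the published reference parameterization of the
untreated system (growth 0.3, carrying capacity 1e4, mutation pressure 0.9,
immune source 0.03*0.7, ... -- see ``REFERENCE_PARAMS``) together with the
initial conditions of the standard scenarios.  Fields the reference source
never fixes (objective weights, intervention strengths, PID gains, setpoint
policy) are filled with this package's documented defaults and flagged
"assumed" in every provenance report.

All randomness (synthetic observations only) flows from one explicit seed;
the dynamical core is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .model import (STATE_NAMES, ModelParameters, InterventionStrengths,
                    alpha_scale, rhs_base)
from .pece import FDEProblem, TimeGrid, Trajectory, pece_solve
from .control import ObjectiveWeights
from .pid import PIDGains, SetpointPolicy
from .outcomes import OutcomeParameters

__all__ = [
    "REFERENCE_PARAMS",
    "PRESETS",
    "ScenarioConfig",
    "ObservationSet",
    "reference_scenario",
    "simulate_scenario",
    "synthetic_observations",
    "fit_comparison",
    "parameter_sweep",
    "trajectory_frame",
]

# Published reference rates of the untreated system (base values, before any
# fractional-order exponentiation).
REFERENCE_PARAMS = dict(
    lambda_=0.3, mu=0.01, beta1=0.01, zeta1=0.9, phi1=0.03, phi2=0.004,
    phi3=0.1, beta2=0.01, zeta2=0.458, K=10000.0, zeta3=0.8, gamma_=0.003,
    delta_=0.03, beta3=0.4, zeta4=0.045, zeta5=0.5, zeta6=0.6, zeta7=0.5,
    zeta8=0.6,
)

# Fields without published values; always flagged "assumed".
_ASSUMED = ("strengths", "weights", "gains", "policy")

PRESETS: dict[str, dict] = {
    "base-A": {"initial_state": (1.5, 0.7, 0.3, 0.1, 0.1), "t_final": 15.0, "n_steps": 1500},
    # base-B is run on a 3-week window: with its crowded initial state the
    # untreated dynamics leave the physical (non-negative) region soon after
    # and eventually diverge, so the preset covers the meaningful transient.
    "base-B": {"initial_state": (1.0, 3.0, 1.0, 1.0, 1.0), "t_final": 3.0, "n_steps": 300},
    "optimal-C": {"initial_state": (5.0, 1.0, 1.0, 1.0, 1.0), "t_final": 3.0, "n_steps": 300},
    "pid-D": {"initial_state": (2.0, 3.0, 1.0, 1.0, 1.0), "t_final": 3.0, "n_steps": 300},
    "cost-benefit": {"initial_state": (1.0, 3.0, 1.0, 1.0, 1.0), "t_final": 3.0, "n_steps": 300},
    "toxicity": {"initial_state": (1.5, 0.7, 0.3, 0.1, 0.1), "t_final": 3.0, "n_steps": 300},
}


@dataclass
class ScenarioConfig:
    """A fully serializable simulation/control scenario."""

    name: str = "custom"
    orders: tuple = (1.0,)
    initial_state: tuple = (1.5, 0.7, 0.3, 0.1, 0.1)
    t_final: float = 15.0
    n_steps: int = 1500
    params: ModelParameters = field(default_factory=ModelParameters)
    strengths: InterventionStrengths = field(default_factory=InterventionStrengths)
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    gains: PIDGains = field(default_factory=PIDGains)
    policy: SetpointPolicy = field(default_factory=SetpointPolicy)
    outcome_params: OutcomeParameters = field(default_factory=OutcomeParameters)
    alpha_convention: str = "power"
    seed: int = 0
    assumed_fields: tuple = _ASSUMED

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(self.n_steps, self.t_final)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["orders"] = list(self.orders)
        d["initial_state"] = list(self.initial_state)
        d["assumed_fields"] = list(self.assumed_fields)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key, typ in (("params", ModelParameters), ("strengths", InterventionStrengths),
                         ("weights", ObjectiveWeights), ("gains", PIDGains),
                         ("policy", SetpointPolicy), ("outcome_params", OutcomeParameters)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        for key in ("orders", "initial_state", "assumed_fields"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def provenance(self) -> dict:
        """Distinguishes published reference values from assumed defaults."""
        return {
            "reference_parameters": dict(REFERENCE_PARAMS),
            "assumed_fields": {name: getattr(self, name).as_dict() for name in self.assumed_fields},
            "alpha_convention": self.alpha_convention,
            "seed": self.seed,
        }


@dataclass
class ObservationSet:
    """Noisy subsamples of a trajectory, reproducible from (config, seed)."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_components)
    components: tuple
    noise_rel: float
    seed: int


def reference_scenario(name: str, orders: tuple = (1.0,)) -> ScenarioConfig:
    """A shipped preset by label; unknown labels raise with the option list.

    The immune source baseline I0 follows the preset's immune initial
    condition (the source constant and the initial condition share one
    symbol by convention in this model).
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    spec = PRESETS[name]
    params = ModelParameters(**REFERENCE_PARAMS,
                             immune_source_baseline=spec["initial_state"][1])
    return ScenarioConfig(name=name, orders=tuple(orders),
                          initial_state=tuple(spec["initial_state"]),
                          t_final=spec["t_final"], n_steps=spec["n_steps"],
                          params=params)


def simulate_scenario(config: ScenarioConfig, order: float | None = None) -> Trajectory:
    """Solve the untreated system for one fractional order of the scenario."""
    if order is None:
        order = config.orders[0]
    params = alpha_scale(config.params, order, config.alpha_convention)
    prob = FDEProblem(order, lambda t, y: rhs_base(y, params),
                      config.initial_state, config.t_final)
    traj = pece_solve(prob, config.grid)
    traj.meta.update({"scenario": config.name, "alpha_convention": config.alpha_convention})
    return traj


def synthetic_observations(trajectory: Trajectory, n_points: int = 30,
                           noise_rel: float = 0.05, seed: int = 0,
                           components: tuple = STATE_NAMES) -> ObservationSet:
    """Multiplicative-Gaussian perturbed samples of a model trajectory.

    Emulates validation-style observed data of otherwise unstated
    provenance: the trajectory is subsampled at ``n_points`` evenly spaced
    times and each sample is scaled by ``1 + noise_rel * N(0,1)``.  Zero
    noise returns exact samples; a fixed seed reproduces the set exactly.
    """
    if noise_rel < 0:
        raise ValueError("noise scale must be non-negative")
    rng = np.random.default_rng(seed)
    idx = np.linspace(0, len(trajectory.grid) - 1, n_points).round().astype(int)
    comp_idx = [STATE_NAMES.index(c) for c in components]
    clean = trajectory.values[np.ix_(idx, comp_idx)]
    noisy = clean * (1.0 + noise_rel * rng.standard_normal(clean.shape))
    return ObservationSet(times=trajectory.grid.nodes[idx], values=noisy,
                          components=tuple(components), noise_rel=noise_rel, seed=seed)


def fit_comparison(observations: ObservationSet, trajectory: Trajectory) -> dict:
    """RMSE / max-abs agreement between observations and a model trajectory.

    The trajectory is interpolated linearly to the observation times;
    metrics are reported per component and pooled.
    """
    if observations.times.size == 0:
        raise ValueError("empty observation set")
    comp_idx = [STATE_NAMES.index(c) for c in observations.components]
    nodes = trajectory.grid.nodes
    pred = np.column_stack([
        np.interp(observations.times, nodes, trajectory.values[:, k]) for k in comp_idx
    ])
    err = observations.values - pred
    per_comp = {
        c: {"rmse": float(np.sqrt(np.mean(err[:, j] ** 2))),
            "max_abs": float(np.abs(err[:, j]).max())}
        for j, c in enumerate(observations.components)
    }
    return {
        "rmse": float(np.sqrt(np.mean(err ** 2))),
        "max_abs": float(np.abs(err).max()),
        "per_component": per_comp,
    }


def parameter_sweep(config: ScenarioConfig, parameter: str, values, order: float | None = None) -> dict:
    """Re-run the scenario once per parameter value, all else fixed.

    Returns the batch of trajectories plus a summary table of terminal
    states and qualitative report lines (monotonicity observations are
    reported, not asserted).
    """
    base = config.params.as_dict()
    if parameter not in base:
        raise KeyError(f"unknown parameter {parameter!r}; options: {sorted(base)}")
    runs = []
    rows = []
    for v in values:
        p = dict(base)
        p[parameter] = float(v)
        cfg = ScenarioConfig.from_dict({**config.to_dict(), "params": p})
        traj = simulate_scenario(cfg, order)
        runs.append(traj)
        rows.append({parameter: float(v),
                     **{f"{n}_final": float(traj.values[-1, j]) for j, n in enumerate(STATE_NAMES)}})
    summary = pd.DataFrame(rows)
    report = []
    for j, n in enumerate(STATE_NAMES):
        finals = summary[f"{n}_final"].to_numpy()
        if len(finals) > 1:
            if np.all(np.diff(finals) >= 0):
                report.append(f"terminal {n} non-decreasing in {parameter}")
            elif np.all(np.diff(finals) <= 0):
                report.append(f"terminal {n} non-increasing in {parameter}")
    return {"trajectories": runs, "summary": summary, "report": report}


def trajectory_frame(trajectory: Trajectory, columns: tuple = STATE_NAMES) -> pd.DataFrame:
    """Trajectory as a tidy frame with a leading time column (CSV-ready)."""
    data = {"t": trajectory.grid.nodes}
    for j, name in enumerate(columns):
        data[name] = trajectory.values[:, j]
    return pd.DataFrame(data)
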