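"""Time integration of the model with invariant enforcement and trajectory IO."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _kernels
from .params import ModelParameters, StateVector

__all__ = [
    "SolverConfig",
    "Trajectory",
    "IntegrationError",
    "simulate",
    "detect_extinction",
    "write_trajectory",
    "read_trajectory",
]

logger = logging.getLogger(__name__)

ADAPTIVE = "adaptive-RK"
FIXED_RK4 = "fixed-step-RK4"

COMPARTMENTS = ("S", "I", "P")


class IntegrationError(RuntimeError):
    """Solver failure; carries the approximate failure time."""

    def __init__(self, message: str, t_fail: Optional[float] = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass
class SolverConfig:
    """Integrator settings.

    method selects an adaptive embedded Runge–Kutta pair (scipy RK45) or a
    classical fixed-step RK4. Reported states are sampled on a uniform grid
    of n_report points regardless of internal steps, which downstream peak
    detection relies on. Components dipping below −abs_tol are clamped to
    zero (x to [0,1]) with a logged event when clamp_negative is set.
    """

    method: str = ADAPTIVE
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    dt_fixed: float = 1e-3
    t_end: float = 500.0
    n_report: int = 2001
    transient: float = 250.0
    extinction_eps: float = 1e-8
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.method not in (ADAPTIVE, FIXED_RK4):
            raise ValueError(f"method must be {ADAPTIVE!r} or {FIXED_RK4!r}, "
                             f"got {self.method!r}")
        for name in ("rel_tol", "abs_tol", "dt_fixed", "t_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_report < 2:
            raise ValueError("n_report must be >= 2")
        if not 0 <= self.transient < self.t_end:
            raise ValueError("transient must lie in [0, t_end)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SolverConfig":
        return cls(**d)


@dataclass
class Trajectory:
    """Solution sampled on a uniform time grid, plus provenance."""

    t: np.ndarray
    y: np.ndarray  # shape (n_report, 4): columns S, I, P, x
    events: List[Tuple[float, str]]
    params_used: ModelParameters
    solver_used: SolverConfig

    @property
    def S(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def I(self) -> np.ndarray:
        return self.y[:, 1]

    @property
    def P(self) -> np.ndarray:
        return self.y[:, 2]

    @property
    def x(self) -> np.ndarray:
        return self.y[:, 3]

    def component(self, name: str) -> np.ndarray:
        return self.y[:, ("S", "I", "P", "x").index(name)]

    def final_state(self) -> StateVector:
        return StateVector.from_array(self.y[-1])

    def post_transient(self, transient: Optional[float] = None) -> "Trajectory":
        """Restrict to t >= transient (default: the solver config's cut)."""
        cut = self.solver_used.transient if transient is None else transient
        mask = self.t >= cut
        return Trajectory(self.t[mask], self.y[mask], self.events,
                          self.params_used, self.solver_used)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "S": self.S, "I": self.I, "P": self.P, "x": self.x}
        )


def _clamp(y: np.ndarray, abs_tol: float, t_grid: np.ndarray,
           events: List[Tuple[float, str]]) -> np.ndarray:
    """Clamp populations at 0 and x to [0,1]; log first violation per column."""
    y = y.copy()
    for j, name in enumerate(("S", "I", "P")):
        bad = y[:, j] < -abs_tol
        if bad.any():
            events.append((float(t_grid[np.argmax(bad)]), f"clamp_{name}"))
        np.maximum(y[:, j], 0.0, out=y[:, j])
    low, high = y[:, 3] < -abs_tol, y[:, 3] > 1.0 + abs_tol
    if low.any() or high.any():
        t_bad = t_grid[np.argmax(low | high)]
        events.append((float(t_bad), "clamp_x"))
    np.clip(y[:, 3], 0.0, 1.0, out=y[:, 3])
    return y


def simulate(params: ModelParameters, state0: StateVector,
             solver: Optional[SolverConfig] = None) -> Trajectory:
    """Integrate the model from t=0 to solver.t_end.

    Deterministic given (params, state0, solver). Raises IntegrationError on
    solver failure or a non-finite state.
    """
    solver = solver or SolverConfig()
    y0 = state0.to_array()
    p_arr = params.to_array()
    t_grid = np.linspace(0.0, solver.t_end, solver.n_report)
    events: List[Tuple[float, str]] = []

    if solver.method == FIXED_RK4:
        y = _kernels.rk4_integrate(y0, p_arr, t_grid, solver.dt_fixed)
        if not np.all(np.isfinite(y)):
            i_bad = int(np.argmax(~np.isfinite(y).all(axis=1)))
            raise IntegrationError("non-finite state in fixed-step integration",
                                   t_fail=float(t_grid[i_bad]))
    else:
        sol = solve_ivp(
            lambda t, y: _kernels.rhs(y, p_arr),
            (0.0, solver.t_end), y0, method="RK45",
            t_eval=t_grid, rtol=solver.rel_tol, atol=solver.abs_tol,
        )
        if not sol.success:
            raise IntegrationError(f"adaptive solver failed: {sol.message}",
                                   t_fail=float(sol.t[-1]) if sol.t.size else 0.0)
        y = sol.y.T

    if solver.clamp_negative:
        y = _clamp(y, solver.abs_tol, t_grid, events)

    return Trajectory(t=t_grid, y=y, events=events,
                      params_used=params, solver_used=solver)


def detect_extinction(traj: Trajectory, eps: Optional[float] = None
                      ) -> List[Tuple[str, float, bool]]:
    """First crossing below eps per compartment, and whether it stays below.

    Returns a list of (compartment, first time below eps, stayed-below flag)
    for each of S, I, P that ever drops below eps.
    """
    if eps is None:
        eps = traj.solver_used.extinction_eps
    out: List[Tuple[str, float, bool]] = []
    for name in COMPARTMENTS:
        v = traj.component(name)
        below = v < eps
        if below.any():
            first = int(np.argmax(below))
            stayed = bool(below[first:].all())
            out.append((name, float(traj.t[first]), stayed))
    return out


def extinct_compartments(traj: Trajectory, eps: Optional[float] = None,
                         ) -> List[str]:
    """Compartments that drop below eps and stay below until t_end."""
    return [name for name, _, stayed in detect_extinction(traj, eps) if stayed]


# ---------------------------------------------------------------------------
# trajectory IO: tidy CSV + JSON sidecar, bit-exact round trip
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def write_trajectory(traj: Trajectory, csv_path: str | Path) -> Path:
    """Write tidy CSV (t,S,I,P,x) plus a JSON sidecar with provenance."""
    csv_path = Path(csv_path)
    traj.to_frame().to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "params": traj.params_used.to_dict(),
        "solver": traj.solver_used.to_dict(),
        "events": [[t, label] for t, label in traj.events],
    }
    side_path = csv_path.with_suffix(csv_path.suffix + ".json")
    side_path.write_text(json.dumps(sidecar, indent=1))
    return side_path


def read_trajectory(csv_path: str | Path) -> Trajectory:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    side = json.loads(csv_path.with_suffix(csv_path.suffix + ".json").read_text())
    return Trajectory(
        t=df["t"].to_numpy(),
        y=df[["S", "I", "P", "x"]].to_numpy(),
        events=[(float(t), str(label)) for t, label in side["events"]],
        params_used=ModelParameters.from_dict(side["params"]),
        solver_used=SolverConfig.from_dict(side["solver"]),
    )
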