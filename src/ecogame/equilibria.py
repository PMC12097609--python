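"""Equilibria of the model and their linear stability.

Equilibria of the (S, I, P) subsystem (x held fixed) or of the full 4-D
system are located from closed forms where available plus damped Newton
iterations from a deterministic multi-start grid, then classified by the
eigenvalues of the analytic Jacobian.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Literal, Optional

import numpy as np

from .model import payoff_gain, rhs_array, transmission_rate
from .params import ModelParameters, StateVector, X_DYNAMIC, X_FIXED

__all__ = [
    "Equilibrium",
    "jacobian",
    "find_equilibria",
    "classify_equilibrium",
]

RESIDUAL_TOL = 1e-10
HYPERBOLIC_BAND = 1e-7
MERGE_DIST = 1e-6

Label = Literal["stable_node", "stable_focus", "unstable", "saddle",
                "non_hyperbolic"]


@dataclass
class Equilibrium:
    state: StateVector
    kind: str                      # trivial | axial | coexistence | boundary-x
    eigenvalues: np.ndarray
    label: Label
    residual: float
    mode: str                      # "x-fixed" (3-D subsystem) or "full" (4-D)

    @property
    def is_interior(self) -> bool:
        return self.state.S > 0 and self.state.I > 0 and self.state.P > 0

    def to_dict(self) -> dict:
        return {
            "state": {"S": self.state.S, "I": self.state.I,
                      "P": self.state.P, "x": self.state.x},
            "kind": self.kind,
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "label": self.label,
            "residual": self.residual,
            "mode": self.mode,
        }


def jacobian(state: StateVector, params: ModelParameters,
             mode: str = "auto") -> np.ndarray:
    """Analytic Jacobian of the RHS.

    mode="x-fixed" returns the 3×3 block over (S, I, P); mode="full" the
    4×4 matrix including the replicator row/column; "auto" follows
    params.x_mode. Raises if a structural denominator vanishes.
    """
    if mode == "auto":
        mode = "full" if params.x_dynamic else "x-fixed"
    S, I, P, x = state.S, state.I, state.P, state.x
    p = params
    for name, den in (("a+S", p.a + S), ("sigma+S", p.sigma + S),
                      ("d+I", p.d + I), ("theta+P", p.theta + P)):
        if den == 0 and not (name == "theta+P" and p.theta == 0.0):
            raise ValueError(f"Jacobian undefined: denominator {name} vanishes")

    beta = transmission_rate(x, p)
    aS, sS, dI = p.a + S, p.sigma + S, p.d + I

    J = np.zeros((4, 4))
    # susceptible prey row
    J[0, 0] = (p.r - 2 * p.b * S - p.c * I
               - beta * I * p.a / aS**2 - p.alpha1 * P * p.sigma / sS**2)
    J[0, 1] = -(p.c + beta / aS) * S
    J[0, 2] = -p.alpha1 * S / sS
    # infected prey row
    J[1, 0] = beta * I * p.a / aS**2
    J[1, 1] = beta * S / aS - p.mu - p.alpha2 * P * p.d / dI**2
    J[1, 2] = -p.alpha2 * I / dI
    # predator row; g is the total per-capita intake
    g = p.c1 * p.alpha1 * S / sS + p.c2 * p.alpha2 * I / dI
    if p.theta == 0.0:
        allee_P, dAP_dP = P, 1.0  # A(P)≡1 in the Allee-free limit
    else:
        tP = p.theta + P
        allee_P, dAP_dP = P * P / tP, P * (2 * p.theta + P) / tP**2
    J[2, 0] = p.c1 * p.alpha1 * p.sigma / sS**2 * allee_P
    J[2, 1] = p.c2 * p.alpha2 * p.d / dI**2 * allee_P
    J[2, 2] = g * dAP_dP - p.m

    if mode == "x-fixed":
        return J[:3, :3]

    # strategy column (β depends on x unless the floor is active)
    dbeta_dx = -p.beta0 * p.e if p.beta0 * (1 - p.e * x) > 0 else 0.0
    J[0, 3] = -dbeta_dx * I * S / aS
    J[1, 3] = dbeta_dx * S * I / aS
    # replicator row
    xf = x * (1.0 - x)
    J[3, 0] = xf * (-p.CS)
    J[3, 1] = xf
    J[3, 2] = xf * p.CP
    J[3, 3] = (1.0 - 2.0 * x) * payoff_gain(S, I, P, p)
    return J


def classify_equilibrium(eigenvalues: np.ndarray,
                         band: float = HYPERBOLIC_BAND) -> Label:
    """Map eigenvalues to a stability label.

    Eigenvalues with |Re λ| inside the hyperbolicity band make the
    equilibrium non_hyperbolic rather than forcing a guess — bifurcation
    scans probe exactly those boundaries.
    """
    re = eigenvalues.real
    if np.any(np.abs(re) < band):
        return "non_hyperbolic"
    if np.all(re < 0):
        return "stable_focus" if np.any(np.abs(eigenvalues.imag) > band) \
            else "stable_node"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def _residual(y: np.ndarray, p_arr: np.ndarray, n: int) -> float:
    return float(np.max(np.abs(rhs_array(y, p_arr)[:n])))


def _newton(y0: np.ndarray, params: ModelParameters, n: int,
            max_iter: int = 100, tol: float = 1e-13) -> Optional[np.ndarray]:
    """Damped Newton on the first n components (x frozen when n=3)."""
    p_arr = params.to_array()
    y = y0.copy()
    for _ in range(max_iter):
        f = rhs_array(y, p_arr)[:n]
        if np.max(np.abs(f)) < tol:
            return y
        try:
            st = StateVector(max(y[0], 0), max(y[1], 0), max(y[2], 0),
                             min(max(y[3], 0), 1))
            J = jacobian(st, params, mode="x-fixed" if n == 3 else "full")
            step = np.linalg.solve(J, -f)
        except (np.linalg.LinAlgError, ValueError):
            return None
        lam = 1.0
        f0 = np.max(np.abs(f))
        for _ in range(30):  # backtracking line search
            y_new = y.copy()
            y_new[:n] = y[:n] + lam * step
            f_new = rhs_array(y_new, p_arr)[:n]
            if np.all(np.isfinite(f_new)) and np.max(np.abs(f_new)) < f0:
                y = y_new
                break
            lam *= 0.5
        else:
            return None
    f = rhs_array(y, p_arr)[:n]
    return y if np.max(np.abs(f)) < tol else None


def _kind_of(y: np.ndarray, mode: str) -> str:
    S, I, P, x = y
    if S <= MERGE_DIST and I <= MERGE_DIST and P <= MERGE_DIST:
        return "trivial"
    if S > MERGE_DIST and I > MERGE_DIST and P > MERGE_DIST:
        if mode == "full" and (x <= MERGE_DIST or x >= 1 - MERGE_DIST):
            return "boundary-x"
        return "coexistence"
    return "axial"


def _make_equilibrium(y: np.ndarray, params: ModelParameters,
                      mode: str) -> Optional[Equilibrium]:
    n = 3 if mode == "x-fixed" else 4
    # drop tiny negatives from Newton noise; reject genuinely negative roots
    if np.any(y[:3] < -1e-9) or (n == 4 and not -1e-9 <= y[3] <= 1 + 1e-9):
        return None
    y = y.copy()
    y[:3] = np.maximum(y[:3], 0.0)
    y[3] = min(max(y[3], 0.0), 1.0)
    res = _residual(y, params.to_array(), n)
    if res > RESIDUAL_TOL:
        return None
    state = StateVector.from_array(y)
    eig = np.linalg.eigvals(jacobian(state, params, mode=mode))
    return Equilibrium(state=state, kind=_kind_of(y, mode), eigenvalues=eig,
                       label=classify_equilibrium(eig), residual=res, mode=mode)


def _closed_form_seeds(params: ModelParameters, x: float) -> List[np.ndarray]:
    """Trivial, logistic, and planar (P=0) equilibria in closed form."""
    p = params
    seeds = [np.array([0.0, 0.0, 0.0, x])]
    if p.b > 0:
        seeds.append(np.array([p.r / p.b, 0.0, 0.0, x]))
    beta = p.beta0 * max(1.0 - p.e * x, 0.0)
    if beta > p.mu:  # predator-free endemic equilibrium
        S = p.mu * p.a / (beta - p.mu)
        I = (p.r - p.b * S) / (p.c + beta / (p.a + S))
        if I > 0:
            seeds.append(np.array([S, I, 0.0, x]))
    return seeds


def find_equilibria(params: ModelParameters, mode: str = "x-fixed",
                    x_fixed: Optional[float] = None,
                    grid_n: int = 8) -> List[Equilibrium]:
    """All equilibria found from closed forms + a deterministic multi-start.

    mode="x-fixed" treats x as the constant x_fixed (default: 0) and works
    in the 3-D (S, I, P) subsystem; mode="full" also seeks interior-x roots
    and the x∈{0,1} faces. Newton starts span a grid over [0, r/b]³ (the
    disease- and predator-free carrying capacity bounds the seed box);
    duplicates are merged at distance 1e-6.
    """
    if mode not in ("x-fixed", "full"):
        raise ValueError(f"mode must be 'x-fixed' or 'full', got {mode!r}")
    n = 3 if mode == "x-fixed" else 4
    K = params.r / params.b if params.b > 0 else 1.0
    axis = np.linspace(0.0, K, grid_n)[1:]  # interior seeds only

    x_values: List[float]
    if mode == "x-fixed":
        x_values = [0.0 if x_fixed is None else float(x_fixed)]
    else:
        x_values = [0.0, 0.5, 1.0]

    found: List[Equilibrium] = []

    def push(y: Optional[np.ndarray]) -> None:
        if y is None:
            return
        eq = _make_equilibrium(y, params, mode)
        if eq is None:
            return
        key = eq.state.to_array()[:n]
        for other in found:
            if np.linalg.norm(other.state.to_array()[:n] - key) < MERGE_DIST:
                return
        found.append(eq)

    for x in x_values:
        for seed in _closed_form_seeds(params, x):
            push(_newton(seed, params, n))
        for S0, I0, P0 in itertools.product(axis, axis, axis):
            push(_newton(np.array([S0, I0, P0, x]), params, n))

    order = {"trivial": 0, "axial": 1, "coexistence": 2, "boundary-x": 3}
    found.sort(key=lambda eq: (order[eq.kind], eq.state.S, eq.state.I))
    return found


def coexistence_equilibrium(params: ModelParameters, x: float = 0.0,
                            seed: Optional[np.ndarray] = None,
                            ) -> Optional[Equilibrium]:
    """Interior (S, I, P > 0) equilibrium of the x-fixed subsystem.

    With ``seed`` given, a single Newton run tracks a known branch (used by
    the Hopf bisection); otherwise a multi-start search is performed.
    """
    if seed is not None:
        y = _newton(np.array([seed[0], seed[1], seed[2], x]), params, 3)
        if y is not None:
            eq = _make_equilibrium(y, params, "x-fixed")
            if eq is not None and eq.is_interior:
                return eq
        return None
    for eq in find_equilibria(params, mode="x-fixed", x_fixed=x):
        if eq.kind == "coexistence":
            return eq
    return None
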