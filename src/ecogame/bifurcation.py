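"""Bifurcation scans, Hopf thresholds, Lyapunov exponents, attractor labels.

The reproduction surface of this model is qualitative regimes — steady
coexistence, limit cycles, period-doubled cycles, chaos, and extinctions —
as parameters such as the fixed strategy x, the controlling cost CS, or the
cooperation constant e vary. This module turns trajectories into those
labels and sweeps parameters in one and two dimensions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import _kernels
from .equilibria import coexistence_equilibrium
from .params import ModelParameters, StateVector, X_DYNAMIC
from .simulate import (FIXED_RK4, IntegrationError, SolverConfig, Trajectory,
                       extinct_compartments, simulate)

__all__ = [
    "ClassifierConfig",
    "AttractorSummary",
    "ScanResult",
    "classify_attractor",
    "largest_lyapunov",
    "scan_1d",
    "scan_2d",
    "hopf_threshold",
    "HopfBracketError",
]

logger = logging.getLogger(__name__)

REGIMES = ("stable_point", "limit_cycle", "period_doubled", "chaotic",
           "extinct_I", "extinct_P", "extinct_I_and_P")


@dataclass
class ClassifierConfig:
    """Thresholds for attractor classification.

    point_tol: post-transient amplitude below which a compartment is at a
    steady point. peak_cluster_rtol: relative tolerance for clustering local
    maxima; a cycle whose maxima collapse to one cluster is period-1, more
    clusters signal period doubling. chaos_tol separates the neutral
    direction along a limit cycle (Lyapunov exponent ≈ 0) from genuine
    exponential divergence.
    """

    point_tol: float = 1e-4
    peak_cluster_rtol: float = 1e-3
    chaos_tol: float = 0.005
    lyapunov_d0: float = 1e-8
    lyapunov_renorm_dt: float = 1.0
    lyapunov_dt: float = 0.01


@dataclass
class AttractorSummary:
    """Post-transient characterisation of one trajectory."""

    minima: Dict[str, float]
    maxima: Dict[str, float]
    peak_values: Dict[str, np.ndarray]
    distinct_peak_count: Dict[str, int]
    lyapunov: Optional[float]
    regime: str
    extinct: Tuple[str, ...] = ()
    dynamics: Optional[str] = None   # regime of the surviving compartments
    settled: bool = True

    def amplitude(self, name: str) -> float:
        return self.maxima[name] - self.minima[name]


def _cluster_peaks(peaks: np.ndarray, rtol: float) -> int:
    """Number of distinct peak levels after relative-tolerance clustering."""
    if peaks.size == 0:
        return 0
    vals = np.sort(peaks)
    scale = max(abs(vals[-1]), 1e-12)
    clusters = 1
    for prev, cur in zip(vals[:-1], vals[1:]):
        if cur - prev > rtol * scale:
            clusters += 1
    return clusters


def largest_lyapunov(params: ModelParameters, state0: StateVector,
                     config: Optional[ClassifierConfig] = None,
                     transient: float = 250.0, window: float = 250.0,
                     ) -> Optional[float]:
    """Largest Lyapunov exponent by two-trajectory Benettin renormalisation.

    A companion trajectory perturbed by d0=1e-8 is advanced with the
    reference and renormalised every renorm_dt=1 time units over the
    post-transient window; the averaged log-separation rate is returned.
    Returns None when the reference trajectory collapses (extinct system),
    where the exponent is not meaningful. Deterministic given the config.
    """
    config = config or ClassifierConfig()
    lam, ok = _kernels.lyapunov_benettin(
        state0.to_array(), params.to_array(), config.lyapunov_dt,
        transient, window, config.lyapunov_renorm_dt, config.lyapunov_d0,
    )
    return float(lam) if ok else None


def classify_attractor(traj: Trajectory,
                       config: Optional[ClassifierConfig] = None,
                       compute_lyapunov: bool = True) -> AttractorSummary:
    """Label the post-transient dynamics of a trajectory.

    Order of precedence: extinction flags first (a compartment below the
    extinction eps that stays below), then steady point (all surviving
    amplitudes below point_tol), then chaos (Lyapunov exponent above
    chaos_tol), then limit cycle vs period-doubled by the number of
    distinct peak levels. The trajectory must extend well past its
    transient cut (at least twice).
    """
    config = config or ClassifierConfig()
    solver = traj.solver_used
    if solver.t_end < 2 * solver.transient and solver.transient > 0:
        raise ValueError("trajectory must be at least twice its transient cut")

    post = traj.post_transient()
    extinct = tuple(extinct_compartments(traj))

    minima = {n: float(post.component(n).min()) for n in "SIP"}
    maxima = {n: float(post.component(n).max()) for n in "SIP"}

    # settledness: compare last-10% to preceding-10% amplitude
    n = len(post.t)
    tail, prev = post.y[-n // 10:], post.y[-2 * (n // 10):-n // 10]
    settled = True
    for j in range(3):
        a_tail = tail[:, j].max() - tail[:, j].min()
        a_prev = prev[:, j].max() - prev[:, j].min()
        ref = max(a_prev, config.point_tol)
        if abs(a_tail - a_prev) > 0.2 * ref:
            settled = False
    if not settled:
        warnings.warn("transient may not be settled: tail amplitude differs "
                      "from preceding window by > 20%", stacklevel=2)

    peak_values: Dict[str, np.ndarray] = {}
    peak_counts: Dict[str, int] = {}
    for j, name in enumerate("SIP"):
        v = post.y[:, j]
        idx, _ = find_peaks(v)
        pv = v[idx]
        peak_values[name] = pv
        peak_counts[name] = _cluster_peaks(pv, config.peak_cluster_rtol)

    surviving = [c for c in "SIP" if c not in extinct]
    amp = max((maxima[c] - minima[c]) for c in surviving) if surviving else 0.0

    lyap: Optional[float] = None
    if amp < config.point_tol:
        dynamics = "stable_point"
    else:
        if compute_lyapunov:
            lyap = largest_lyapunov(
                traj.params_used, StateVector.from_array(traj.y[0]), config,
                transient=solver.transient, window=solver.t_end - solver.transient)
        if lyap is not None and lyap > config.chaos_tol:
            dynamics = "chaotic"
        else:
            n_peaks = max((peak_counts[c] for c in surviving), default=0)
            dynamics = "limit_cycle" if n_peaks <= 1 else "period_doubled"

    if "I" in extinct and "P" in extinct:
        regime = "extinct_I_and_P"
    elif "I" in extinct:
        regime = "extinct_I"
    elif "P" in extinct:
        regime = "extinct_P"
    else:
        regime = dynamics

    return AttractorSummary(minima=minima, maxima=maxima,
                            peak_values=peak_values,
                            distinct_peak_count=peak_counts,
                            lyapunov=lyap, regime=regime, extinct=extinct,
                            dynamics=dynamics, settled=settled)


# ---------------------------------------------------------------------------
# parameter scans
# ---------------------------------------------------------------------------

@dataclass
class ScanPolicy:
    """Initial-condition policy for scans.

    By default every grid point starts from the same state (the study's
    fixed (0.99, 0.01, 0.01), x0 per run mode); continuation mode reuses
    the previous grid point's final state, which exposes hysteresis.
    """

    state0: StateVector = field(
        default_factory=lambda: StateVector(0.99, 0.01, 0.01, 0.0))
    continuation: bool = False


@dataclass
class ScanResult:
    param_names: Tuple[str, ...]
    grids: Tuple[np.ndarray, ...]
    summaries: Dict[tuple, Optional[AttractorSummary]]
    failures: Dict[tuple, str]
    base_params: ModelParameters
    solver: SolverConfig

    def regime_at(self, *values: float) -> Optional[str]:
        s = self.summaries.get(tuple(values))
        return None if s is None else s.regime

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (grid point, compartment, peak)."""
        rows = []
        for key, s in self.summaries.items():
            coord = dict(zip(self.param_names, key))
            if s is None:
                rows.append({**coord, "compartment": None, "peak": np.nan,
                             "regime": "integration_failed"})
                continue
            for comp in "SIP":
                pv = s.peak_values[comp]
                if pv.size == 0:
                    rows.append({**coord, "compartment": comp,
                                 "peak": s.maxima[comp], "regime": s.regime})
                else:
                    for v in pv:
                        rows.append({**coord, "compartment": comp,
                                     "peak": float(v), "regime": s.regime})
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "grids": [g.tolist() for g in self.grids],
            "regimes": {",".join(f"{v:.10g}" for v in k):
                        (None if s is None else s.regime)
                        for k, s in self.summaries.items()},
            "lyapunov": {",".join(f"{v:.10g}" for v in k):
                         (None if s is None else s.lyapunov)
                         for k, s in self.summaries.items()},
            "failures": {",".join(f"{v:.10g}" for v in k): msg
                         for k, msg in self.failures.items()},
            "base_params": self.base_params.to_dict(),
            "solver": self.solver.to_dict(),
        }

    def write(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
        csv_path.with_suffix(csv_path.suffix + ".json").write_text(
            json.dumps(self.summary_dict(), indent=1))


def _set_param(base: ModelParameters, name: str, value: float,
               ) -> ModelParameters:
    if name == "x":
        raise ValueError("sweep x through the scan policy's state0, or use "
                         "scan_1d's special handling via param_name='x'")
    return base.with_updates(**{name: value})


_DEFAULT_SCAN_SOLVER = SolverConfig(method=FIXED_RK4, dt_fixed=0.005,
                                    t_end=1000.0, transient=500.0,
                                    n_report=4001)


def _run_point(params: ModelParameters, state0: StateVector,
               solver: SolverConfig, config: ClassifierConfig,
               ) -> Tuple[Optional[AttractorSummary], Optional[str],
                          Optional[StateVector]]:
    try:
        traj = simulate(params, state0, solver)
    except IntegrationError as exc:
        return None, str(exc), None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = classify_attractor(traj, config)
    return summary, None, traj.final_state()


def scan_1d(base: ModelParameters, param_name: str,
            grid: Sequence[float], policy: Optional[ScanPolicy] = None,
            solver: Optional[SolverConfig] = None,
            config: Optional[ClassifierConfig] = None) -> ScanResult:
    """One-parameter bifurcation scan.

    param_name may be any ModelParameters field, or "x" to sweep the fixed
    strategy level (the bifurcation diagrams' abscissa). Per-point
    integration failures are recorded in .failures, not raised.
    """
    policy = policy or ScanPolicy()
    solver = solver or _DEFAULT_SCAN_SOLVER
    config = config or ClassifierConfig()
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")

    summaries: Dict[tuple, Optional[AttractorSummary]] = {}
    failures: Dict[tuple, str] = {}
    state0 = policy.state0
    for v in grid:
        if param_name == "x":
            params = base
            s0 = StateVector(state0.S, state0.I, state0.P, float(v))
        else:
            params = _set_param(base, param_name, float(v))
            s0 = state0
        summary, err, final = _run_point(params, s0, solver, config)
        summaries[(float(v),)] = summary
        if err is not None:
            failures[(float(v),)] = err
        elif policy.continuation and final is not None:
            floor = solver.extinction_eps
            state0 = StateVector(max(final.S, floor), max(final.I, floor),
                                 max(final.P, floor), final.x)
    return ScanResult(param_names=(param_name,), grids=(grid,),
                      summaries=summaries, failures=failures,
                      base_params=base, solver=solver)


def scan_2d(base: ModelParameters, names: Tuple[str, str],
            grids: Tuple[Sequence[float], Sequence[float]],
            policy: Optional[ScanPolicy] = None,
            solver: Optional[SolverConfig] = None,
            config: Optional[ClassifierConfig] = None) -> ScanResult:
    """Two-parameter outcome scan (e.g. over CS and e with dynamic x)."""
    policy = policy or ScanPolicy(state0=StateVector(0.99, 0.01, 0.01, 0.5))
    solver = solver or _DEFAULT_SCAN_SOLVER
    config = config or ClassifierConfig()
    g1 = np.asarray(grids[0], dtype=float)
    g2 = np.asarray(grids[1], dtype=float)
    for g in (g1, g2):
        if g.size > 1 and not np.all(np.diff(g) > 0):
            raise ValueError("grids must be strictly increasing")

    summaries: Dict[tuple, Optional[AttractorSummary]] = {}
    failures: Dict[tuple, str] = {}
    for v1 in g1:
        for v2 in g2:
            params = _set_param(_set_param(base, names[0], float(v1)),
                                names[1], float(v2))
            summary, err, _ = _run_point(params, policy.state0, solver, config)
            summaries[(float(v1), float(v2))] = summary
            if err is not None:
                failures[(float(v1), float(v2))] = err
    return ScanResult(param_names=tuple(names), grids=(g1, g2),
                      summaries=summaries, failures=failures,
                      base_params=base, solver=solver)


# ---------------------------------------------------------------------------
# Hopf threshold by eigenvalue bisection
# ---------------------------------------------------------------------------

class HopfBracketError(ValueError):
    """Bracket endpoints do not straddle an eigenvalue sign change."""


class EquilibriumLostError(RuntimeError):
    """Newton tracking of the coexistence equilibrium failed in the bracket."""


def _max_re_at(base: ModelParameters, param_name: str, value: float,
               seed: Optional[np.ndarray],
               ) -> Tuple[Optional[float], Optional[np.ndarray]]:
    """(max Re λ, equilibrium coords) at the coexistence equilibrium.

    Returns (None, None) when no interior equilibrium exists at this
    parameter value — treated by the bisection as the non-oscillatory side,
    since past the invasion boundary the interior branch has merged away
    and the attractor is an equilibrium.
    """
    if param_name == "x":
        params, x = base, float(value)
    else:
        params, x = _set_param(base, param_name, float(value)), 0.0
    eq = coexistence_equilibrium(params, x=x, seed=seed)
    if eq is None and seed is not None:  # retry with a full multi-start
        eq = coexistence_equilibrium(params, x=x)
    if eq is None:
        return None, None
    return float(np.max(eq.eigenvalues.real)), eq.state.to_array()[:3]


def hopf_threshold(base: ModelParameters, param_name: str,
                   bracket: Tuple[float, float], tol: float = 1e-8,
                   max_iter: int = 200) -> float:
    """Parameter value where the coexistence equilibrium loses stability.

    Bisects on the maximum real part of the Jacobian eigenvalues at the
    interior coexistence equilibrium of the (S, I, P) subsystem, tracking
    the equilibrium branch by Newton continuation from the previous point.
    param_name="x" sweeps the fixed strategy level; any other name sweeps
    that model constant at x=0.

    A bracket endpoint where the interior equilibrium does not exist counts
    as the stable (non-oscillatory) side: the branch there has merged with
    a boundary equilibrium, so no interior oscillation can be born beyond
    it. If the branch disappears before its eigenvalues cross zero, the
    value returned is the existence boundary rather than a Hopf point.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    f_lo, seed_lo = _max_re_at(base, param_name, lo, None)
    f_hi, seed_hi = _max_re_at(base, param_name, hi, seed_lo)
    if f_lo is None and f_hi is None:
        raise EquilibriumLostError(
            f"no coexistence equilibrium at either bracket endpoint "
            f"({lo}, {hi}) of {param_name!r}")

    def sgn(f: Optional[float]) -> float:
        return -1.0 if f is None else np.sign(f)

    if sgn(f_lo) == sgn(f_hi):
        raise HopfBracketError(
            f"no stability change in bracket ({lo}, {hi}): "
            f"max Re = {f_lo} and {f_hi}")
    seed = seed_lo if seed_lo is not None else seed_hi
    s_lo = sgn(f_lo)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid, seed_mid = _max_re_at(base, param_name, mid, seed)
        if seed_mid is not None:
            seed = seed_mid
        if f_mid is not None and abs(f_mid) < tol:
            return mid
        if sgn(f_mid) == s_lo:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)
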