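"""Right-hand side of the eco-epidemiological model.

Susceptible prey S grow logistically, lose to infection through a saturated
incidence β(x)·I/(a+S) and to predation through a Holling type-II response.
Infected prey I gain from new infections and lose to predation and disease
mortality. Predators P convert both prey classes into growth, damped at low
predator density by the weak Allee factor P/(θ+P). The cooperation level x
follows replicator dynamics: ẋ = x(1−x)·G(S, I, P).
"""

from __future__ import annotations

import logging

import numpy as np

from . import _kernels
from .params import ModelParameters, StateVector

__all__ = [
    "transmission_rate",
    "allee_factor",
    "payoff_gain",
    "strategy_rhs",
    "ode_rhs",
]

logger = logging.getLogger(__name__)


def transmission_rate(x: float, params: ModelParameters) -> float:
    """Effective disease transmission rate β(x) = β0·(1 − e·x).

    Higher cooperation x means stronger compliance with disease-control
    behaviour, hence lower transmission. The result is floored at zero:
    for e·x > 1 the linear form would turn negative, which is biologically
    meaningless; a warning is logged when the floor activates.
    """
    raw = params.beta0 * (1.0 - params.e * x)
    if raw < 0.0:
        logger.warning(
            "transmission rate clamped to 0 (beta0=%g, e=%g, x=%g gives %g)",
            params.beta0, params.e, x, raw,
        )
        return 0.0
    return raw


def allee_factor(P: float, theta: float) -> float:
    """Weak Allee (mate-finding) factor P/(θ+P).

    It is zero at zero population, increases with P, and approaches 1 for
    large P. θ=0 returns exactly 1 (the Allee-free limit), including the
    degenerate P=0, θ=0 case — any finite convention is harmless there
    because the factor is always multiplied by P.
    """
    if P < 0 or theta < 0:
        raise ValueError(f"allee_factor requires P >= 0 and theta >= 0, "
                         f"got P={P}, theta={theta}")
    if theta == 0.0:
        return 1.0
    return P / (theta + P)


def payoff_gain(S: float, I: float, P: float, params: ModelParameters) -> float:
    """Payoff gain G(S, I, P) of cooperation in the strategy game.

    G = −CS·S + I + CP·P: abundant healthy prey makes costly cooperation
    unattractive (−CS·S), while infection prevalence (I) and predation
    pressure (CP·P) both favour it. Kept as a single seam so alternative
    payoff readings can be swapped in without touching the replicator form.
    """
    return -params.CS * S + I + params.CP * P


def strategy_rhs(state: StateVector, params: ModelParameters) -> float:
    """Replicator dynamics ẋ = x(1−x)·G(S, I, P).

    The logistic prefactor pins x=0 and x=1 as fixed points, so x can never
    leave [0, 1] under the exact flow.
    """
    x = state.x
    return x * (1.0 - x) * payoff_gain(state.S, state.I, state.P, params)


def ode_rhs(state: StateVector, params: ModelParameters) -> np.ndarray:
    """Derivative vector (dS/dt, dI/dt, dP/dt, dx/dt).

    dx/dt follows replicator dynamics when params.x_mode == "dynamic" and is
    identically zero otherwise. Raises on non-finite input components.
    """
    y = state.to_array()
    if not np.all(np.isfinite(y)):
        bad = ("S", "I", "P", "x")[int(np.argmax(~np.isfinite(y)))]
        raise ValueError(f"non-finite state component {bad!r}: {y}")
    return _kernels.rhs(y, params.to_array())


def rhs_array(y: np.ndarray, p_arr: np.ndarray) -> np.ndarray:
    """Array-in/array-out RHS for integrators (no validation)."""
    return _kernels.rhs(y, p_arr)
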