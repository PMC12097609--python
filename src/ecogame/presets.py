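"""Named scenario presets.

All study scenarios share one base parameter set
(a=0.3636, b=1.0, α1=0.01, σ=15, c=0.01, r=1.0, α2=0.05, d=0.5, μ=0.4,
c1=2, c2=1.0, e=1.0, m=0.01) and the initial state (S, I, P) =
(0.99, 0.01, 0.01); scenarios differ in β0, θ, the strategy mode, and which
parameter(s) are swept. The registry is immutable: get_preset returns deep
copies, and a test pins every numeric value against a frozen serialisation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .params import ModelParameters, StateVector, X_DYNAMIC, X_FIXED

__all__ = ["Preset", "get_preset", "list_presets", "BASE_PARAMS"]

# shared constants of every scenario
BASE_PARAMS = dict(
    a=0.3636, b=1.0, alpha1=0.01, sigma=15.0, c=0.01, r=1.0,
    alpha2=0.05, d=0.5, mu=0.4, c1=2.0, c2=1.0, e=1.0, m=0.01,
)

STATE0 = dict(S=0.99, I=0.01, P=0.01)
X0_DYNAMIC = 0.5  # interior starting strategy for dynamic runs


@dataclass
class Preset:
    """A registered scenario: parameters, initial state, and its sweep."""

    name: str
    description: str
    params: ModelParameters
    state0: StateVector
    sweep: Optional[dict] = None        # {"params": (...), "values": (...)}
    variants: Optional[dict] = None     # param -> list of alternative values
    notes: str = ""


def _state0(x: float) -> StateVector:
    return StateVector(x=x, **STATE0)


def _mk(name, description, sweep=None, variants=None, notes="",
        x_mode=X_FIXED, x0=0.0, **overrides) -> Preset:
    params = ModelParameters(x_mode=x_mode, **{**BASE_PARAMS, **overrides})
    return Preset(name=name, description=description, params=params,
                  state0=_state0(x0), sweep=sweep, variants=variants,
                  notes=notes)


_REGISTRY: Dict[str, Preset] = {}


def _register(p: Preset) -> None:
    _REGISTRY[p.name] = p


_register(_mk(
    "fig1",
    "Time series varying the baseline transmission rate beta0 "
    "(x=0 fixed, no Allee effect)",
    beta0=0.5, theta=0.0,
    sweep={"params": ("beta0",), "values": ((0.5, 0.6, 0.8, 0.95),)},
    notes="beta0 in {0.5, 0.6, 0.8, 0.95}. Effectiveness e=1.0 throughout; "
          "only sigma takes the value 15 (e=15 would clamp beta(x) to 0 for "
          "x > 1/15 and is not a meaningful effectiveness).",
))

_register(_mk(
    "fig2",
    "Time series varying the Allee parameter theta at beta0=0.7 (x=0 fixed)",
    beta0=0.7, theta=0.0,
    sweep={"params": ("theta",), "values": ((0.0, 0.01, 0.3, 0.5),)},
))

_register(_mk(
    "fig3",
    "Time series varying the Allee parameter theta at beta0=0.95 (x=0 fixed)",
    beta0=0.95, theta=0.0,
    sweep={"params": ("theta",), "values": ((0.0, 0.01, 0.3, 0.5),)},
))

_register(_mk(
    "fig4",
    "Time series varying the fixed strategy level x at beta0=0.95, theta=0",
    beta0=0.95, theta=0.0,
    sweep={"params": ("x",), "values": ((0.0, 0.01, 0.1, 0.3),)},
    notes="x is held fixed (not dynamic) in this scenario.",
))

_register(_mk(
    "fig5",
    "One-parameter bifurcation diagram along the fixed strategy x "
    "(beta0=0.95), Allee variants theta in {0, 0.01, 0.03}",
    beta0=0.95, theta=0.0,
    sweep={"params": ("x",), "values": (tuple(i / 100 for i in range(101)),)},
    variants={"theta": [0.0, 0.01, 0.03]},
    notes="beta0=0.95 matches the fixed-x time-series scenario so the sweep "
          "crosses the full regime ladder: beta(x)=0.95(1-x) spans (0, 0.95] "
          "and the stability flip of the beta0 sweep falls inside it.",
))

_register(_mk(
    "fig5_text_variant",
    "Bifurcation along x with the larger Allee value theta=0.3 discussed "
    "alongside the theta=0.03 variant",
    beta0=0.95, theta=0.3,
    sweep={"params": ("x",), "values": (tuple(i / 100 for i in range(101)),)},
))

_register(_mk(
    "fig6",
    "Time series with dynamic strategy for cost combinations "
    "CS, CP in {0.1, 0.5, 0.9} (beta0=0.95, theta=0)",
    beta0=0.95, theta=0.0, CS=0.1, CP=0.1,
    x_mode=X_DYNAMIC, x0=X0_DYNAMIC,
    sweep={"params": ("CS", "CP"),
           "values": ((0.1, 0.5, 0.9), (0.1, 0.5, 0.9))},
    notes="beta0=0.95 as in the other strategy scenarios (see fig5).",
))

_register(_mk(
    "fig7",
    "Bifurcation along the susceptible-prey controlling cost CS for "
    "CP in {0.1, 0.5, 0.9} (dynamic strategy, beta0=0.95, theta=0)",
    beta0=0.95, theta=0.0, CS=0.1, CP=0.1,
    x_mode=X_DYNAMIC, x0=X0_DYNAMIC,
    sweep={"params": ("CS",), "values": (tuple(i / 100 for i in range(101)),)},
    variants={"CP": [0.1, 0.5, 0.9]},
    notes="beta0=0.95 as in the other strategy scenarios (see fig5).",
))

_register(_mk(
    "fig8",
    "Bifurcation along CS for Allee variants theta in {0, 0.1, 0.5} "
    "(dynamic strategy, CP=0.5, beta0=0.95)",
    beta0=0.95, theta=0.0, CS=0.1, CP=0.5,
    x_mode=X_DYNAMIC, x0=X0_DYNAMIC,
    sweep={"params": ("CS",), "values": (tuple(i / 100 for i in range(101)),)},
    variants={"theta": [0.0, 0.1, 0.5]},
    notes="beta0=0.95 as in the other strategy scenarios (see fig5).",
))

_register(_mk(
    "fig9",
    "Two-parameter (CS, e) outcome phase diagram at beta0=0.7 "
    "(dynamic strategy, CP=0.5), Allee variants theta in {0, 0.1}",
    beta0=0.7, theta=0.0, CS=0.1, CP=0.5,
    x_mode=X_DYNAMIC, x0=X0_DYNAMIC,
    sweep={"params": ("CS", "e"),
           "values": (tuple(i / 10 for i in range(11)),
                      tuple(i / 10 for i in range(11)))},
    variants={"theta": [0.0, 0.1]},
))

_register(_mk(
    "fig10",
    "Two-parameter (CS, e) outcome phase diagram at beta0=0.95 "
    "(dynamic strategy, CP=0.5), Allee variants theta in {0, 0.1}",
    beta0=0.95, theta=0.0, CS=0.1, CP=0.5,
    x_mode=X_DYNAMIC, x0=X0_DYNAMIC,
    sweep={"params": ("CS", "e"),
           "values": (tuple(i / 10 for i in range(11)),
                      tuple(i / 10 for i in range(11)))},
    variants={"theta": [0.0, 0.1]},
))


def get_preset(name: str) -> Preset:
    """Deep copy of a registered preset (caller mutation is harmless)."""
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(_REGISTRY))}")
    return copy.deepcopy(_REGISTRY[name])


def list_presets() -> List[Tuple[str, str]]:
    """Deterministically ordered (name, description) catalogue."""
    return [(name, _REGISTRY[name].description)
            for name in sorted(_REGISTRY)]
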