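"""Model state and parameter containers.

The model couples three populations — susceptible prey S, infected prey I and
a predator P — with a behavioural strategy level x in [0, 1] that measures how
strongly the prey population cooperates with disease-control measures.
Transmission follows a saturated incidence β(x)·I/(a+S), predation a Holling
type-II response, and predator recruitment is damped at low density by a weak
Allee factor P/(θ+P).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable

import numpy as np

__all__ = ["StateVector", "ModelParameters", "X_FIXED", "X_DYNAMIC"]

X_FIXED = "fixed"
X_DYNAMIC = "dynamic"


@dataclass
class StateVector:
    """Instantaneous system state (S, I, P, x).

    Densities are in arbitrary biomass units and must be non-negative; the
    cooperation level x lives in [0, 1].
    """

    S: float
    I: float
    P: float
    x: float = 0.0

    def __post_init__(self) -> None:
        for name in ("S", "I", "P", "x"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"state component {name!r} is not finite: {v}")
        if self.S < 0 or self.I < 0 or self.P < 0:
            raise ValueError(
                f"population densities must be non-negative, got "
                f"(S={self.S}, I={self.I}, P={self.P})"
            )
        if not 0.0 <= self.x <= 1.0:
            raise ValueError(f"cooperation level x must lie in [0, 1], got {self.x}")

    def to_array(self) -> np.ndarray:
        return np.array([self.S, self.I, self.P, self.x], dtype=float)

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "StateVector":
        S, I, P, x = (float(v) for v in y)
        return cls(S=S, I=I, P=P, x=x)


# order matters: _to_array/_kernels rely on it
_PARAM_FIELDS = (
    "r", "b", "c", "beta0", "e", "a",
    "alpha1", "alpha2", "sigma", "d", "c1", "c2",
    "mu", "m", "theta", "CS", "CP",
)


@dataclass
class ModelParameters:
    """All model constants plus the strategy-mode switch.

    Parameters
    ----------
    r, b, c : float
        Susceptible-prey growth rate, intra-class competition, and the
        inter-class effect of infected on susceptible prey.
    beta0, e, a : float
        Baseline transmission rate, cooperator proportionality constant in
        β(x)=β0(1−e·x), and the half-saturation constant of the saturated
        incidence term.
    alpha1, alpha2, sigma, d : float
        Predator attack rates on susceptible/infected prey and the matching
        Holling type-II half-saturation constants.
    c1, c2 : float
        Transfer efficacies converting consumed susceptible/infected prey
        into predator growth.
    mu, m : float
        Infected-prey and predator death rates.
    theta : float
        Allee parameter; theta=0 recovers the Allee-free model exactly.
    CS, CP : float
        Controlling costs of susceptible prey and predator in the strategy
        payoff.
    x_mode : {"fixed", "dynamic"}
        Whether x is held constant or evolves by replicator dynamics.
    """

    r: float = 1.0
    b: float = 1.0
    c: float = 0.01
    beta0: float = 0.5
    e: float = 1.0
    a: float = 0.3636
    alpha1: float = 0.01
    alpha2: float = 0.05
    sigma: float = 15.0
    d: float = 0.5
    c1: float = 2.0
    c2: float = 1.0
    mu: float = 0.4
    m: float = 0.01
    theta: float = 0.0
    CS: float = 0.5
    CP: float = 0.5
    x_mode: str = X_FIXED

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("a", "sigma", "d"):
            if getattr(self, name) <= 0:
                raise ValueError(
                    f"half-saturation constant {name!r} must be strictly "
                    f"positive (it appears in a denominator), got {getattr(self, name)}"
                )
        if self.theta < 0:
            raise ValueError(f"Allee parameter theta must be >= 0, got {self.theta}")
        for name in ("r", "b", "c", "beta0", "alpha1", "alpha2",
                     "c1", "c2", "mu", "m", "CS", "CP"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"rate parameter {name!r} must be a finite "
                                 f"non-negative number, got {v}")
        if self.e < 0 or not math.isfinite(self.e):
            raise ValueError(f"parameter 'e' must be finite and >= 0, got {self.e}")
        if self.x_mode not in (X_FIXED, X_DYNAMIC):
            raise ValueError(
                f"x_mode must be {X_FIXED!r} or {X_DYNAMIC!r}, got {self.x_mode!r}"
            )

    @property
    def x_dynamic(self) -> bool:
        return self.x_mode == X_DYNAMIC

    def to_array(self) -> np.ndarray:
        """Numeric parameter vector (fixed field order) + dynamic-x flag."""
        vals = [float(getattr(self, n)) for n in _PARAM_FIELDS]
        vals.append(1.0 if self.x_dynamic else 0.0)
        return np.array(vals, dtype=float)

    def with_updates(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced (validates)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**d)

    @staticmethod
    def field_names() -> tuple:
        return _PARAM_FIELDS + ("x_mode",)
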