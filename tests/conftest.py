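import numpy as np
import pytest

from ecogame import ModelParameters, SolverConfig, StateVector
from ecogame.presets import BASE_PARAMS
from ecogame.simulate import FIXED_RK4


@pytest.fixture
def base_params() -> ModelParameters:
    """The shared study parameter set (x fixed at zero, no Allee effect)."""
    return ModelParameters(beta0=0.5, theta=0.0, **BASE_PARAMS)


@pytest.fixture
def standard_ic() -> StateVector:
    return StateVector(0.99, 0.01, 0.01, 0.0)


@pytest.fixture
def fast_rk4() -> SolverConfig:
    """Quick fixed-step solver for regime checks (not accuracy checks)."""
    return SolverConfig(method=FIXED_RK4, dt_fixed=0.01, t_end=1000.0,
                        transient=500.0, n_report=2001)


def random_params_near(base: ModelParameters, rng: np.random.Generator,
                       spread: float = 0.15) -> ModelParameters:
    """Jitter every rate of a parameter set multiplicatively (seeded)."""
    jitter = {
        name: getattr(base, name) * float(rng.uniform(1 - spread, 1 + spread))
        for name in ("r", "b", "c", "beta0", "a", "alpha1", "alpha2",
                     "sigma", "d", "c1", "c2", "mu", "m")
    }
    return base.with_updates(**jitter)
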