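import numpy as np
import pytest

from hemolysim import DamageParams, StressHistory, ThresholdLaw


@pytest.fixture
def params() -> DamageParams:
    return DamageParams()


@pytest.fixture
def law() -> ThresholdLaw:
    return ThresholdLaw()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230412)


def random_history(rng: np.random.Generator, n_min: int = 3, n_max: int = 10,
                   low: float = 0.5, high: float = 400.0) -> StressHistory:
    """Random piecewise-constant history with n_min..n_max intervals."""
    n = int(rng.integers(n_min, n_max + 1))
    durations = rng.uniform(1e-3, 0.5, n)
    stresses = rng.uniform(low, high, n)
    return StressHistory(times=np.cumsum(durations), stresses=stresses)
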