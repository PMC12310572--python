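import numpy as np
import pytest

from trigov import GameParameters, PARAM_NAMES, StrategyState, baseline_scenarios


@pytest.fixture(scope="session")
def scenario1() -> GameParameters:
    s1, _, _ = baseline_scenarios()
    return s1


@pytest.fixture(scope="session")
def scenario2() -> GameParameters:
    _, s2, _ = baseline_scenarios()
    return s2


@pytest.fixture(scope="session")
def center() -> StrategyState:
    _, _, init = baseline_scenarios()
    return init


def random_parameters(rng: np.random.Generator, low: float = 0.0, high: float = 20.0) -> GameParameters:
    values = rng.uniform(low, high, size=len(PARAM_NAMES))
    return GameParameters(**dict(zip(PARAM_NAMES, values)))


def random_state(rng: np.random.Generator) -> StrategyState:
    return StrategyState(*rng.uniform(0.0, 1.0, size=3))
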