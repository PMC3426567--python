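import numpy as np
import pytest

from collrisk import EvoConfig, GameConfig, behavior_to_strategy


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def default_game():
    """The standard six-player, ten-round game (E=20, T=60, cap 2)."""
    return GameConfig(risk_prob=0.9)


@pytest.fixture
def quick_evo():
    """Short evolutionary run for smoke-level dynamics tests."""
    return EvoConfig(population_size=40, generations=60, burn_in=20, seed=7)


@pytest.fixture
def fair_rational():
    return behavior_to_strategy((0, 0, 0, 0, 0, 2, 2, 2, 2, 2))
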