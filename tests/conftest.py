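import numpy as np
import pytest

from spingroups import FREE, SimConfig, SpinPopulation


@pytest.fixture
def homogeneous_pop():
    """Twenty agents sharing one spin vector: any group has payoff 1."""
    spins = np.tile(np.array([1, -1, 1], dtype=np.int8), (20, 1))
    return SpinPopulation(spins=spins, membership=np.full(20, FREE))


@pytest.fixture
def small_config():
    return SimConfig(n_agents=20, group_size=2, vec_len=3,
                     pi_individual=0.0, horizon=200, seed=7)


class ScriptedRNG:
    """Stand-in random generator with scripted uniform draws; selection
    calls fall back to a real seeded generator."""

    def __init__(self, uniforms, seed=0):
        self._uniforms = list(uniforms)
        self._rng = np.random.default_rng(seed)

    def random(self):
        return self._uniforms.pop(0)

    def choice(self, a, size=None, replace=True):
        return self._rng.choice(a, size=size, replace=replace)

    def integers(self, *args, **kwargs):
        return self._rng.integers(*args, **kwargs)


@pytest.fixture
def scripted_rng():
    return ScriptedRNG
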