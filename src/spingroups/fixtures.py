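"""Deterministic population generators for tests and worked examples.

Four kinds are provided:

* ``random`` — i.i.d. +/-1 spins (delegates to
  :func:`~spingroups.dynamics.init_population`);
* ``homogeneous`` — all agents share one spin vector, so any group
  attains the maximal payoff 1;
* ``anti-aligned-pairs`` — rows alternate ``s, -s``; any even-sized group
  drawn as consecutive pairs has payoff exactly 0;
* ``example-vector`` — agents perturbed around the length-6 showcase
  vector ``[+1, -1, -1, -1, +1, +1]``, with the first agent carrying it
  exactly.

All kinds are bit-reproducible from their spec, and together they bracket
the full payoff range [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import init_population
from .model import FREE, SpinPopulation

__all__ = ["EXAMPLE_VECTOR", "FixtureSpec", "make_fixture",
           "load_population_txt", "save_population_txt"]

#: The length-6 showcase spin vector used in the worked examples.
EXAMPLE_VECTOR = np.array([+1, -1, -1, -1, +1, +1], dtype=np.int8)

_KINDS = ("random", "homogeneous", "anti-aligned-pairs", "example-vector")

#: Per-entry flip probability for the ``example-vector`` perturbation.
_FLIP_P = 0.1


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a deterministic population fixture."""

    kind: str
    n_agents: int = 10
    vec_len: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"choose one of {_KINDS}")
        if self.n_agents < 2 or self.vec_len < 1:
            raise ValueError("need n_agents >= 2 and vec_len >= 1")


def make_fixture(spec: FixtureSpec) -> SpinPopulation:
    """Build the population described by ``spec`` (all agents free)."""
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_agents, spec.vec_len
    if spec.kind == "random":
        return init_population(n, L, spec.seed)
    if spec.kind == "homogeneous":
        row = (rng.integers(0, 2, size=L) * 2 - 1).astype(np.int8)
        spins = np.tile(row, (n, 1))
    elif spec.kind == "anti-aligned-pairs":
        row = (rng.integers(0, 2, size=L) * 2 - 1).astype(np.int8)
        spins = np.tile(row, (n, 1))
        spins[1::2] *= -1
    else:  # example-vector
        if L != EXAMPLE_VECTOR.size:
            raise ValueError(
                f"example-vector fixture requires vec_len={EXAMPLE_VECTOR.size}")
        spins = np.tile(EXAMPLE_VECTOR, (n, 1))
        flips = rng.random(size=(n, L)) < _FLIP_P
        flips[0] = False  # first agent carries the exact vector
        spins[flips] *= -1
    return SpinPopulation(spins=spins, membership=np.full(n, FREE))


def save_population_txt(pop: SpinPopulation, path) -> None:
    """Write spins as plain text: one agent per line, space-separated +/-1."""
    np.savetxt(path, pop.spins, fmt="%+d")


def load_population_txt(path) -> SpinPopulation:
    """Read a plain-text spin matrix back into a (fully free) population."""
    spins = np.atleast_2d(np.loadtxt(path, dtype=np.int8))
    return SpinPopulation(spins=spins,
                          membership=np.full(spins.shape[0], FREE))
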