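"""Asynchronous population dynamics: one formation and one breaking
attempt per step, repeated for T steps.

Two engines share the same semantics:

* ``engine="fast"`` — the numba loop in :mod:`spingroups._engine`; used for
  sweeps and anything at production scale.
* ``engine="reference"`` — a literal composition of
  :func:`attempt_formation` and :func:`attempt_breaking` in Python; slow,
  readable, and used by the tests as an independent cross-check.

Both engines initialise the population from the same derived seed, so a
run's initial spins do not depend on the engine; the dynamic random
streams differ between engines, and reproducibility (same seed, same
engine -> bit-identical trajectory) holds for each.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import _engine
from .model import (FREE, Group, SimConfig, SpinPopulation,
                    breaking_probability, formation_probability, group_payoff)

__all__ = [
    "Trajectory",
    "attempt_breaking",
    "attempt_formation",
    "init_population",
    "run",
]


def _derive_seeds(seed: int) -> Tuple[int, int]:
    """Split a base seed into (population seed, dynamics seed), both < 2**31."""
    ss = np.random.SeedSequence(seed)
    s_init, s_dyn = (int(s % 2**31) for s in ss.generate_state(2))
    return s_init, s_dyn


def init_population(n_agents: int, vec_len: int, seed: int) -> SpinPopulation:
    """Draw a fresh population: each spin entry independently +/-1 with
    probability 1/2, every agent free.  Deterministic given the seed."""
    if n_agents < 2 or vec_len < 1:
        raise ValueError("need n_agents >= 2 and vec_len >= 1")
    rng = np.random.default_rng(seed)
    spins = (rng.integers(0, 2, size=(n_agents, vec_len)) * 2 - 1).astype(np.int8)
    return SpinPopulation(spins=spins, membership=np.full(n_agents, FREE))


def attempt_formation(pop: SpinPopulation, config: SimConfig,
                      rng: np.random.Generator, step: int = 0) -> Optional[Group]:
    """Try to form one group of G uniformly chosen free agents.

    With fewer than G free agents this is a no-op.  Otherwise the
    candidates' homogeneity payoff pi_g is computed and the group forms
    with probability ``formation_probability(pi_i, pi_g, K)``; on success
    the members' membership is updated atomically and the new
    :class:`~spingroups.model.Group` is registered and returned.
    """
    free = pop.free_agents()
    if free.size < config.group_size:
        return None
    members = rng.choice(free, size=config.group_size, replace=False)
    pi_g = group_payoff(pop.spins[members])
    w = formation_probability(config.pi_individual, pi_g, config.noise)
    if rng.random() >= w:
        return None
    gid = pop._next_gid
    pop._next_gid += 1
    group = Group(members=tuple(int(m) for m in members), payoff=pi_g,
                  birth_step=step)
    pop.membership[members] = gid
    pop.groups[gid] = group
    return group


def attempt_breaking(pop: SpinPopulation, config: SimConfig,
                     rng: np.random.Generator,
                     step: Optional[int] = None) -> Optional[Tuple[int, Group]]:
    """Try to dissolve one existing group.

    A group is drawn uniformly among those born before ``step`` (pass
    ``None`` to make every live group eligible) and breaks with
    probability ``breaking_probability(pi_i, pi_g, K)``; on success all
    members revert to free atomically.  Returns ``(gid, group)`` for the
    broken group, or ``None``.
    """
    if step is None:
        eligible = list(pop.groups)
    else:
        eligible = [gid for gid, grp in pop.groups.items() if grp.birth_step < step]
    if not eligible:
        return None
    gid = eligible[int(rng.integers(len(eligible)))]
    group = pop.groups[gid]
    w = breaking_probability(config.pi_individual, group.payoff, config.noise)
    if rng.random() >= w:
        return None
    pop.membership[np.array(group.members)] = FREE
    del pop.groups[gid]
    return gid, group


@dataclass
class Trajectory:
    """Full record of one run.

    ``group_count[t]`` is the number of live groups after step ``t``; the
    event arrays log every formation (step, payoff) and every breaking
    (step, payoff, group age in steps).  ``final`` is the end-of-run
    population snapshot.
    """

    config: SimConfig
    group_count: np.ndarray
    formation_steps: np.ndarray
    formation_payoffs: np.ndarray
    breaking_steps: np.ndarray
    breaking_payoffs: np.ndarray
    breaking_ages: np.ndarray
    final: SpinPopulation

    @property
    def steps(self) -> int:
        return self.group_count.size

    def density_series(self) -> np.ndarray:
        """Fraction of agents in groups after each step."""
        return self.group_count * (self.config.group_size / self.config.n_agents)

    def mean_density(self, burn_in: Optional[int] = None) -> float:
        """Time-averaged group density over the post-burn-in steps."""
        burn = self.config.burn_in if burn_in is None else burn_in
        if self.steps == 0:
            return 0.0
        if not 0 <= burn < self.steps:
            raise ValueError("burn_in outside the recorded trajectory")
        return float(self.density_series()[burn:].mean())


def _run_reference(config: SimConfig) -> Trajectory:
    s_init, s_dyn = _derive_seeds(config.seed)
    pop = init_population(config.n_agents, config.vec_len, s_init)
    rng = np.random.default_rng(s_dyn)
    n = config.horizon
    counts = np.empty(n, dtype=np.int32)
    f_steps, f_payoffs = [], []
    b_steps, b_payoffs, b_ages = [], [], []
    for t in range(n):
        formed = attempt_formation(pop, config, rng, step=t)
        if formed is not None:
            f_steps.append(t)
            f_payoffs.append(formed.payoff)
        broken = attempt_breaking(pop, config, rng, step=t)
        if broken is not None:
            _, grp = broken
            b_steps.append(t)
            b_payoffs.append(grp.payoff)
            b_ages.append(t - grp.birth_step)
        counts[t] = pop.n_groups
    return Trajectory(
        config=config,
        group_count=counts,
        formation_steps=np.array(f_steps, dtype=np.int64),
        formation_payoffs=np.array(f_payoffs, dtype=np.float64),
        breaking_steps=np.array(b_steps, dtype=np.int64),
        breaking_payoffs=np.array(b_payoffs, dtype=np.float64),
        breaking_ages=np.array(b_ages, dtype=np.int64),
        final=pop,
    )


def _run_fast(config: SimConfig) -> Trajectory:
    s_init, s_dyn = _derive_seeds(config.seed)
    pop = init_population(config.n_agents, config.vec_len, s_init)
    (counts, f_steps, f_payoffs, b_steps, b_payoffs, b_ages,
     membership, members, payoffs, births) = _engine.simulate(
        pop.spins, config.group_size, config.pi_individual, config.noise,
        config.horizon, s_dyn)
    pop.membership = membership
    pop.groups = {
        gi: Group(members=tuple(int(m) for m in members[gi]),
                  payoff=float(payoffs[gi]), birth_step=int(births[gi]))
        for gi in range(members.shape[0])
    }
    pop._next_gid = members.shape[0]
    return Trajectory(
        config=config,
        group_count=counts,
        formation_steps=f_steps,
        formation_payoffs=f_payoffs,
        breaking_steps=b_steps,
        breaking_payoffs=b_payoffs,
        breaking_ages=b_ages,
        final=pop,
    )


def run(config: SimConfig, engine: str = "fast") -> Trajectory:
    """Simulate one full trajectory of T steps from a fresh population.

    Each step attempts one formation and then one breaking; a group born
    in the current step only becomes breakable at the next step.  Fully
    reproducible from ``config.seed`` for a given engine.
    """
    if engine == "fast":
        return _run_fast(config)
    if engine == "reference":
        return _run_reference(config)
    raise ValueError(f"unknown engine {engine!r}; use 'fast' or 'reference'")
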