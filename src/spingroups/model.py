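"""Core domain types and payoff/probability primitives.

The population is a set of ``N`` agents, each carrying a quenched spin
vector of length ``L`` with entries in {-1, +1}.  Agents either act alone
(receiving a fixed *individual payoff* ``pi_i`` in [-1, +1]) or belong to
exactly one group of fixed size ``G`` (receiving the *group payoff*
``pi_g`` in [0, 1], a homogeneity score of the members' spin vectors).
Group formation and breaking are stochastic, driven by a Fermi (logistic)
comparison of the two payoffs at decision noise ``K``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "FREE",
    "Group",
    "SimConfig",
    "SpinPopulation",
    "breaking_probability",
    "formation_probability",
    "group_payoff",
]

#: Sentinel group id for agents that are not in any group.
FREE: int = -1


def group_payoff(member_spins: np.ndarray) -> float:
    """Homogeneity payoff of a prospective group.

    For a ``G x L`` matrix of member spin vectors the payoff is the
    normalised length of the average spin vector,

    .. math::

        \\pi_g = \\frac{1}{L}\\,\\frac{1}{G} \\sum_{j=1}^{L}
                 \\Bigl|\\sum_{i=1}^{G} v_{ij}\\Bigr| ,

    which is 1 for a perfectly homogeneous group (all rows identical) and 0
    when every feature column sums to zero.  The value is invariant under
    permuting members and under globally flipping the sign of any feature
    column.

    Parameters
    ----------
    member_spins
        ``G x L`` array with entries in {-1, +1}, one row per member,
        ``G >= 2``, ``L >= 1``.

    Returns
    -------
    float
        Payoff in ``[0, 1]``.
    """
    spins = np.asarray(member_spins)
    if spins.ndim != 2 or spins.size == 0:
        raise ValueError("member_spins must be a non-empty G x L matrix")
    n_members, vec_len = spins.shape
    if n_members < 2:
        raise ValueError(f"a group needs at least 2 members, got {n_members}")
    if not np.isin(spins, (-1, 1)).all():
        raise ValueError("spin entries must be exactly -1 or +1")
    return float(np.abs(spins.sum(axis=0)).sum()) / (n_members * vec_len)


def formation_probability(pi_i, pi_g, noise: float):
    """Fermi-rule probability of forming a group.

    ``W_G = (1 + exp[(pi_i - pi_g) / K])^{-1}``: strictly decreasing in the
    individual payoff, strictly increasing in the group payoff, and equal
    to 1/2 when the two payoffs coincide.  ``noise`` (``K > 0``) sets the
    decision uncertainty; ``K = 0.5`` models near-rational agents.

    Accepts scalars or broadcastable arrays for the payoffs.
    """
    if not noise > 0:
        raise ValueError(f"noise K must be positive, got {noise}")
    pi_i = np.asarray(pi_i, dtype=float)
    pi_g = np.asarray(pi_g, dtype=float)
    w = 1.0 / (1.0 + np.exp((pi_i - pi_g) / noise))
    return float(w) if w.ndim == 0 else w


def breaking_probability(pi_i, pi_g, noise: float):
    """Probability of dissolving an existing group.

    The complement of :func:`formation_probability`; by logistic symmetry
    it equals the Fermi rule with the payoffs swapped,
    ``(1 + exp[(pi_g - pi_i) / K])^{-1}``, so formation + breaking = 1
    exactly for every argument pair.
    """
    if not noise > 0:
        raise ValueError(f"noise K must be positive, got {noise}")
    pi_i = np.asarray(pi_i, dtype=float)
    pi_g = np.asarray(pi_g, dtype=float)
    w = 1.0 / (1.0 + np.exp((pi_g - pi_i) / noise))
    return float(w) if w.ndim == 0 else w


@dataclass(frozen=True)
class Group:
    """A live group: member indices plus the payoff quenched at formation.

    Spins never change during a run, so the payoff stored at formation is
    exact for the group's whole lifetime.
    """

    members: Tuple[int, ...]
    payoff: float
    birth_step: int = 0

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members) or len(self.members) < 2:
            raise ValueError("group members must be >= 2 distinct agent indices")
        if not 0.0 <= self.payoff <= 1.0:
            raise ValueError(f"group payoff must lie in [0, 1], got {self.payoff}")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SpinPopulation:
    """N agents with quenched +/-1 spin vectors and group membership state.

    ``membership[i]`` is the id of the group agent ``i`` belongs to, or
    :data:`FREE`.  ``groups`` maps live group ids to :class:`Group`
    records; the two views are kept consistent by the dynamics layer.
    """

    spins: np.ndarray
    membership: np.ndarray
    groups: Dict[int, Group] = field(default_factory=dict)
    _next_gid: int = 0

    def __post_init__(self) -> None:
        self.spins = np.asarray(self.spins)
        if self.spins.ndim != 2 or self.spins.size == 0:
            raise ValueError("spins must be a non-empty N x L matrix")
        if not np.isin(self.spins, (-1, 1)).all():
            raise ValueError("spin entries must be exactly -1 or +1")
        self.spins = self.spins.astype(np.int8)
        self.membership = np.asarray(self.membership, dtype=np.int64)
        if self.membership.shape != (self.spins.shape[0],):
            raise ValueError("membership must have one entry per agent")

    @property
    def n_agents(self) -> int:
        return self.spins.shape[0]

    @property
    def vec_len(self) -> int:
        return self.spins.shape[1]

    @property
    def n_free(self) -> int:
        return int(np.count_nonzero(self.membership == FREE))

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def free_agents(self) -> np.ndarray:
        """Indices of agents currently in no group."""
        return np.flatnonzero(self.membership == FREE)

    def validate(self) -> None:
        """Check the partition invariant: each agent in at most one group,
        membership consistent with the registry, free + grouped = N."""
        grouped = 0
        for gid, group in self.groups.items():
            members = np.array(group.members)
            if not (self.membership[members] == gid).all():
                raise AssertionError(f"membership inconsistent for group {gid}")
            expected = group_payoff(self.spins[members])
            if abs(expected - group.payoff) > 1e-12:
                raise AssertionError(f"cached payoff stale for group {gid}")
            grouped += group.size
        if grouped + self.n_free != self.n_agents:
            raise AssertionError("free + grouped agents do not partition the population")
        live = set(self.groups)
        seen = set(int(g) for g in self.membership if g != FREE)
        if seen != live:
            raise AssertionError("membership refers to dead or unknown groups")


@dataclass(frozen=True)
class SimConfig:
    """All parameters of a single simulation run.

    Parameters
    ----------
    n_agents
        Population size N.
    group_size
        Fixed group size G (>= 2).
    vec_len
        Spin-vector length L (>= 1).
    pi_individual
        Individual payoff pi_i in [-1, +1]; the control parameter.
    noise
        Decision noise K > 0 in the Fermi rule.
    horizon
        Number of asynchronous steps T.  Defaults to ``100 * n_agents``,
        large enough relative to N for the asynchronous dynamics to
        equilibrate.
    burn_in
        Steps discarded before measuring; defaults to ``horizon // 2``.
    window
        Width (in steps) of the disjoint windows used for breaking-event
        counts <B(dT)>.  Defaults to 1000 steps, clipped to the
        post-burn-in length.
    seed
        Base seed; replicate r of a replicated estimate uses derived seeds.
    replicates
        Default number of independent runs for averaged observables.
    """

    n_agents: int = 1000
    group_size: int = 2
    vec_len: int = 3
    pi_individual: float = 0.0
    noise: float = 0.5
    horizon: Optional[int] = None
    burn_in: Optional[int] = None
    window: Optional[int] = None
    seed: int = 0
    replicates: int = 10

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        if not 2 <= self.group_size <= self.n_agents:
            raise ValueError("group_size must satisfy 2 <= G <= N")
        if self.vec_len < 1:
            raise ValueError("vec_len must be >= 1")
        if not -1.0 <= self.pi_individual <= 1.0:
            raise ValueError("pi_individual must lie in [-1, +1]")
        if not self.noise > 0:
            raise ValueError("noise K must be positive")
        if self.horizon is None:
            object.__setattr__(self, "horizon", 100 * self.n_agents)
        if self.horizon < 0:
            raise ValueError("horizon must be non-negative")
        if self.burn_in is None:
            object.__setattr__(self, "burn_in", self.horizon // 2)
        if not 0 <= self.burn_in <= self.horizon:
            raise ValueError("burn_in must lie in [0, horizon]")
        if self.burn_in == self.horizon and self.horizon > 0:
            raise ValueError("burn_in must be smaller than horizon")
        if self.window is None:
            object.__setattr__(
                self, "window", max(1, min(1000, self.horizon - self.burn_in))
            )
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.horizon > 0 and self.window > self.horizon - self.burn_in:
            raise ValueError("window must not exceed horizon - burn_in")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def with_(self, **changes) -> "SimConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)
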