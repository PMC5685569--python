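"""Numba-compiled inner loop of the asynchronous form/break dynamics.

One step = one formation attempt on G uniformly drawn free agents,
followed by one breaking attempt on a uniformly drawn pre-existing group
(a group born this very step is not yet eligible).  The loop keeps the
free agents in a swap-list so both attempts are O(G) regardless of N.

Seeds passed here must be non-negative and below 2**31.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate"]


@njit(cache=True)
def _core(spins, group_size, pi_i, noise, n_steps, seed):
    np.random.seed(seed)
    n_agents, vec_len = spins.shape
    g = group_size

    free_list = np.arange(n_agents)
    pos = np.arange(n_agents)  # position of each agent in free_list, -1 if grouped
    free_count = n_agents

    max_groups = n_agents // g
    members = np.empty((max_groups, g), dtype=np.int64)
    payoffs = np.empty(max_groups, dtype=np.float64)
    births = np.empty(max_groups, dtype=np.int64)
    n_groups = 0

    counts = np.empty(n_steps, dtype=np.int32)
    form_steps = np.empty(n_steps, dtype=np.int64)
    form_payoffs = np.empty(n_steps, dtype=np.float64)
    n_form = 0
    break_steps = np.empty(n_steps, dtype=np.int64)
    break_payoffs = np.empty(n_steps, dtype=np.float64)
    break_ages = np.empty(n_steps, dtype=np.int64)
    n_break = 0

    for t in range(n_steps):
        formed = False
        if free_count >= g:
            # draw G distinct free agents into the tail of free_list
            for k in range(g):
                j = np.random.randint(0, free_count - k)
                tail = free_count - 1 - k
                a, b = free_list[j], free_list[tail]
                free_list[j], free_list[tail] = b, a
                pos[a], pos[b] = tail, j
            acc = 0.0
            for col in range(vec_len):
                s = 0
                for k in range(g):
                    s += spins[free_list[free_count - g + k], col]
                acc += abs(s)
            pg = acc / (g * vec_len)
            w = 1.0 / (1.0 + np.exp((pi_i - pg) / noise))
            if np.random.random() < w:
                gi = n_groups
                for k in range(g):
                    agent = free_list[free_count - g + k]
                    members[gi, k] = agent
                    pos[agent] = -1
                free_count -= g
                payoffs[gi] = pg
                births[gi] = t
                n_groups += 1
                formed = True
                form_steps[n_form] = t
                form_payoffs[n_form] = pg
                n_form += 1
        # the group formed this step is stored last; exclude it from the draw
        eligible = n_groups - 1 if formed else n_groups
        if eligible > 0:
            gi = np.random.randint(0, eligible)
            pg = payoffs[gi]
            wb = 1.0 / (1.0 + np.exp((pg - pi_i) / noise))
            if np.random.random() < wb:
                break_steps[n_break] = t
                break_payoffs[n_break] = pg
                break_ages[n_break] = t - births[gi]
                n_break += 1
                for k in range(g):
                    agent = members[gi, k]
                    pos[agent] = free_count
                    free_list[free_count] = agent
                    free_count += 1
                n_groups -= 1
                if gi != n_groups:
                    for k in range(g):
                        members[gi, k] = members[n_groups, k]
                    payoffs[gi] = payoffs[n_groups]
                    births[gi] = births[n_groups]
        counts[t] = n_groups

    membership = np.full(n_agents, -1, dtype=np.int64)
    for gi in range(n_groups):
        for k in range(g):
            membership[members[gi, k]] = gi

    return (
        counts,
        form_steps[:n_form].copy(),
        form_payoffs[:n_form].copy(),
        break_steps[:n_break].copy(),
        break_payoffs[:n_break].copy(),
        break_ages[:n_break].copy(),
        membership,
        members[:n_groups].copy(),
        payoffs[:n_groups].copy(),
        births[:n_groups].copy(),
    )


def simulate(spins: np.ndarray, group_size: int, pi_individual: float,
             noise: float, n_steps: int, seed: int):
    """Run the compiled dynamics on a fixed spin matrix.

    Returns the per-step group-count series, formation and breaking event
    logs (step, payoff[, group age]), the final membership vector and the
    final group table (members, payoffs, birth steps).
    """
    if not (0 <= seed < 2**31):
        raise ValueError("engine seed must lie in [0, 2**31)")
    spins = np.ascontiguousarray(spins, dtype=np.int8)
    return _core(spins, int(group_size), float(pi_individual), float(noise),
                 int(n_steps), int(seed))
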