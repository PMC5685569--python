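"""Order parameter, breaking statistics, threshold estimation and sweeps.

The order parameter is the group density ``rho_g``: the fraction of agents
currently organized in groups (``G * n_groups / N``).  Sweeping the
individual payoff ``pi_i`` yields a density curve whose collapse locates
the critical threshold ``pi_hat`` separating the group phase from the
individual phase; the average number of breaking events per time window,
``<B(dT)>``, peaks at that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _engine
from .dynamics import Trajectory, _derive_seeds, init_population
from .model import FREE, SimConfig, SpinPopulation

__all__ = [
    "NO_TRANSITION",
    "SweepResult",
    "breaking_rate",
    "critical_threshold",
    "density_curve",
    "equilibrium_density",
    "group_density",
    "phase_diagram",
    "sweep",
]

#: Sentinel returned by :func:`critical_threshold` when the density curve
#: never falls below half its reference value.
NO_TRANSITION = None


def group_density(pop: SpinPopulation, group_size: int) -> float:
    """Fraction of agents currently in groups, ``G * n_groups / N``.

    Equals 1 when every agent is grouped (possible only if G divides N)
    and 0 when the population is entirely free.
    """
    return float(np.count_nonzero(pop.membership != FREE)) / pop.n_agents


def breaking_rate(traj: Trajectory, window: Optional[int] = None,
                  burn_in: Optional[int] = None) -> float:
    """Mean number of breaking events per disjoint window of ``window``
    steps, averaged over the post-burn-in part of the trajectory."""
    win = traj.config.window if window is None else window
    burn = traj.config.burn_in if burn_in is None else burn_in
    span = traj.steps - burn
    if win < 1 or win > span:
        raise ValueError(
            f"window ({win}) must lie in [1, {span}] for this trajectory")
    n_windows = span // win
    steps = traj.breaking_steps
    n_events = int(((steps >= burn) & (steps < burn + n_windows * win)).sum())
    return n_events / n_windows


def _replicate_stats(config: SimConfig, seeds: Sequence[int]
                     ) -> Tuple[float, float, float, float]:
    """Mean/SE of post-burn-in density and of breaks-per-window over
    replicate runs with the given seeds (fast engine, no Trajectory
    objects allocated)."""
    rhos, brates = [], []
    n_windows = max(1, (config.horizon - config.burn_in) // config.window)
    scale = config.group_size / config.n_agents
    for s in seeds:
        s_init, s_dyn = _derive_seeds(int(s))
        pop = init_population(config.n_agents, config.vec_len, s_init)
        out = _engine.simulate(pop.spins, config.group_size,
                               config.pi_individual, config.noise,
                               config.horizon, s_dyn)
        counts, b_steps = out[0], out[3]
        rhos.append(float(counts[config.burn_in:].mean()) * scale
                    if config.horizon > config.burn_in else 0.0)
        in_win = ((b_steps >= config.burn_in) &
                  (b_steps < config.burn_in + n_windows * config.window))
        brates.append(int(in_win.sum()) / n_windows)
    rhos = np.asarray(rhos)
    brates = np.asarray(brates)
    n = len(seeds)
    se = lambda x: float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(rhos.mean()), se(rhos), float(brates.mean()), se(brates)


def equilibrium_density(config: SimConfig,
                        replicates: Optional[int] = None) -> Tuple[float, float]:
    """Cross-replicate mean and standard error of the time-averaged
    post-burn-in group density.

    Replicate ``r`` runs with seed ``config.seed + r``, so the estimate is
    fully reproducible from the config alone.
    """
    reps = config.replicates if replicates is None else replicates
    if reps < 2:
        raise ValueError("equilibrium_density needs replicates >= 2")
    seeds = [config.seed + r for r in range(reps)]
    rho_mean, rho_se, _, _ = _replicate_stats(config, seeds)
    return rho_mean, rho_se


def critical_threshold(density_curve) -> Optional[float]:
    """Half-maximum crossing estimator of the critical individual payoff.

    Scanning the curve upward in ``pi_i``, returns the first grid point at
    which the mean density falls below one half of its value at the lowest
    ``pi_i`` in the curve (the deep group-phase reference, ``pi_i = -1``
    for a full sweep).  Returns :data:`NO_TRANSITION` if the curve never
    crosses.  The grid point itself is reported, without interpolation.

    Accepts a sequence of ``(pi_i, rho)`` pairs or a DataFrame with
    ``pi_i`` and ``rho_mean`` columns, sorted by ``pi_i``.
    """
    if isinstance(density_curve, pd.DataFrame):
        pis = density_curve["pi_i"].to_numpy(dtype=float)
        rhos = density_curve["rho_mean"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(density_curve), dtype=float)
        if arr.size == 0:
            raise ValueError("density curve is empty")
        pis, rhos = arr[:, 0], arr[:, 1]
    if pis.size == 0:
        raise ValueError("density curve is empty")
    if np.any(np.diff(pis) <= 0):
        raise ValueError("density curve must be sorted by strictly increasing pi_i")
    below = rhos < 0.5 * rhos[0]
    if not below.any():
        return NO_TRANSITION
    return float(pis[np.argmax(below)])


@dataclass
class SweepResult:
    """Tidy grid of equilibrium observables over (G, L, pi_i) cells.

    ``table`` has one row per cell with columns ``G, L, pi_i, rho_mean,
    rho_se, breaks_mean, breaks_se, replicates, seed``; ``base`` is the
    config template every cell shares (N, K, horizon, ...).
    """

    table: pd.DataFrame
    base: SimConfig
    replicates: int
    seed: int

    def curve(self, G: int, L: int) -> pd.DataFrame:
        """Density/breaking curve for one (G, L) combination, sorted by pi_i."""
        sel = self.table[(self.table.G == G) & (self.table.L == L)]
        if sel.empty:
            raise KeyError(f"no cells for G={G}, L={L}")
        return sel.sort_values("pi_i").reset_index(drop=True)

    def thresholds(self) -> pd.DataFrame:
        """Estimated pi_hat per (G, L); NaN marks no transition."""
        rows = []
        for (G, L), _ in self.table.groupby(["G", "L"]):
            th = critical_threshold(self.curve(G, L))
            rows.append({"G": int(G), "L": int(L),
                         "pi_hat": np.nan if th is NO_TRANSITION else th})
        return pd.DataFrame(rows).sort_values(["L", "G"]).reset_index(drop=True)

    def phase_map(self, L: int, cut: float = 0.5) -> pd.DataFrame:
        """Binary phase classification per (G, pi_i) cell at one L:
        True = group phase (rho_g > cut), False = individual phase."""
        sel = self.table[self.table.L == L]
        if sel.empty:
            raise KeyError(f"no cells for L={L}")
        return sel.pivot(index="G", columns="pi_i", values="rho_mean") > cut

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _cell_seeds(base_seed: int, n_cells: int, replicates: int) -> np.ndarray:
    """Independent replicate seeds per sweep cell via SeedSequence spawns
    (all below 2**31)."""
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(n_cells)
    return np.array([c.generate_state(replicates) % 2**31 for c in children],
                    dtype=np.int64)


def sweep(G_grid: Iterable[int], L_grid: Iterable[int],
          pi_grid: Iterable[float], base: SimConfig,
          replicates: Optional[int] = None, progress: bool = False
          ) -> SweepResult:
    """Fill every (G, L, pi_i) cell with replicate-averaged equilibrium
    density and breaking rate.

    Each cell runs ``replicates`` independent trajectories; cell seeds are
    spawned deterministically from ``base.seed``, so the whole sweep is
    reproducible bit-for-bit.
    """
    G_grid = [int(g) for g in G_grid]
    L_grid = [int(l) for l in L_grid]
    pi_grid = [float(p) for p in pi_grid]
    if not G_grid or not L_grid or not pi_grid:
        raise ValueError("sweep grids must be non-empty")
    if max(G_grid) > base.n_agents:
        raise ValueError("every G in the grid must be <= n_agents")
    reps = base.replicates if replicates is None else replicates
    cells = [(G, L, pi) for G in G_grid for L in L_grid for pi in pi_grid]
    seeds = _cell_seeds(base.seed, len(cells), reps)
    rows = []
    for idx, (G, L, pi) in enumerate(cells):
        cfg = base.with_(group_size=G, vec_len=L, pi_individual=pi)
        rho_m, rho_se, b_m, b_se = _replicate_stats(cfg, seeds[idx])
        rows.append({"G": G, "L": L, "pi_i": pi, "rho_mean": rho_m,
                     "rho_se": rho_se, "breaks_mean": b_m, "breaks_se": b_se,
                     "replicates": reps, "seed": base.seed})
        if progress and (idx + 1) % max(1, len(cells) // 20) == 0:
            print(f"sweep: {idx + 1}/{len(cells)} cells", flush=True)
    return SweepResult(table=pd.DataFrame(rows), base=base,
                       replicates=reps, seed=base.seed)


def density_curve(pi_grid: Iterable[float], base: SimConfig,
                  replicates: Optional[int] = None) -> pd.DataFrame:
    """Equilibrium density (and breaking rate) versus pi_i for the G and L
    of ``base``; a single-(G, L) convenience wrapper around :func:`sweep`."""
    res = sweep([base.group_size], [base.vec_len], pi_grid, base,
                replicates=replicates)
    return res.curve(base.group_size, base.vec_len)


def phase_diagram(G_grid: Iterable[int], pi_grid: Iterable[float],
                  base: SimConfig, replicates: Optional[int] = None,
                  progress: bool = False) -> SweepResult:
    """Equilibrium density over a (G, pi_i) grid at the vec_len of
    ``base``; classification into group/individual phase is available via
    :meth:`SweepResult.phase_map`."""
    return sweep(G_grid, [base.vec_len], pi_grid, base,
                 replicates=replicates, progress=progress)


def pi_grid_default(step: float = 0.05, lo: float = -1.0, hi: float = 1.0
                    ) -> np.ndarray:
    """The standard individual-payoff grid, rounded to two decimals."""
    return np.round(np.arange(lo, hi + step / 2, step), 2)
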