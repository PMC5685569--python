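"""Configuration files, result serialization and canned experiments.

Configs are YAML (or JSON) mappings of :class:`~spingroups.model.SimConfig`
fields, optionally extended with sweep grids (``G_grid``, ``L_grid`` and
either ``pi_grid`` or ``pi_min``/``pi_max``/``pi_step``).  An empty config
yields the standard study defaults: N = 1000 agents, K = 0.5,
G grid [2, 4, 5, 10, 25, 50, 100], L grid [3, 10, 25], a 0.05-step
individual-payoff grid on [-1, 1] and 10 replicates.

``run_experiment`` reproduces each headline experiment (phase diagram,
density curves, vec-length comparison, breaking-rate curves) at full or
reduced scale and records a manifest sufficient to re-run it bit-exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .dynamics import Trajectory
from .model import SimConfig
from .observables import SweepResult, pi_grid_default, sweep

__all__ = [
    "ConfigError",
    "RunManifest",
    "SweepSpec",
    "DEFAULT_G_GRID",
    "DEFAULT_L_GRID",
    "load_config",
    "write_config",
    "run_experiment",
    "trajectory_events_csv",
]

DEFAULT_G_GRID: List[int] = [2, 4, 5, 10, 25, 50, 100]
DEFAULT_L_GRID: List[int] = [3, 10, 25]

_CONFIG_KEYS = {f.name for f in dataclasses.fields(SimConfig)}
_SWEEP_KEYS = {"G_grid", "L_grid", "pi_grid", "pi_min", "pi_max", "pi_step"}
EXPERIMENTS = ("phase_diagram", "density_curves", "length_comparison",
               "breaking_rates")


class ConfigError(ValueError):
    """Raised for malformed configuration files."""


@dataclass(frozen=True)
class SweepSpec:
    """A parameter sweep: a shared base config plus (G, L, pi_i) grids."""

    base: SimConfig
    G_grid: Sequence[int] = field(default_factory=lambda: list(DEFAULT_G_GRID))
    L_grid: Sequence[int] = field(default_factory=lambda: list(DEFAULT_L_GRID))
    pi_grid: Sequence[float] = field(
        default_factory=lambda: pi_grid_default().tolist())

    def run(self, progress: bool = False) -> SweepResult:
        return sweep(self.G_grid, self.L_grid, self.pi_grid, self.base,
                     progress=progress)


def _build_sim_config(mapping: Dict) -> SimConfig:
    try:
        return SimConfig(**mapping)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path):
    """Parse a YAML/JSON config into a :class:`SimConfig` or, if any grid
    key is present (or the file is empty), a :class:`SweepSpec` with the
    standard defaults filled in.

    Unknown or invalid keys raise :class:`ConfigError` naming the key.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping of parameter names")
    unknown = set(data) - _CONFIG_KEYS - _SWEEP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    base_keys = {k: v for k, v in data.items() if k in _CONFIG_KEYS}
    if not (set(data) & _SWEEP_KEYS) and base_keys:
        return _build_sim_config(base_keys)
    if "pi_grid" in data:
        pi_grid = [float(p) for p in data["pi_grid"]]
    else:
        pi_grid = pi_grid_default(
            step=float(data.get("pi_step", 0.05)),
            lo=float(data.get("pi_min", -1.0)),
            hi=float(data.get("pi_max", 1.0))).tolist()
    base = _build_sim_config(base_keys)
    spec = SweepSpec(
        base=base,
        G_grid=[int(g) for g in data.get("G_grid", DEFAULT_G_GRID)],
        L_grid=[int(l) for l in data.get("L_grid", DEFAULT_L_GRID)],
        pi_grid=pi_grid,
    )
    if max(spec.G_grid) > base.n_agents:
        raise ConfigError("G_grid contains a group size larger than n_agents")
    return spec


def write_config(config, path) -> None:
    """Serialize a :class:`SimConfig` or :class:`SweepSpec` to YAML such
    that ``load_config`` round-trips it exactly."""
    if isinstance(config, SimConfig):
        data = dataclasses.asdict(config)
    elif isinstance(config, SweepSpec):
        data = dataclasses.asdict(config.base)
        data.update({"G_grid": list(config.G_grid),
                     "L_grid": list(config.L_grid),
                     "pi_grid": [float(p) for p in config.pi_grid]})
    else:
        raise TypeError("expected SimConfig or SweepSpec")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def trajectory_events_csv(traj: Trajectory, path) -> None:
    """Write the formation/breaking event log as tidy CSV with columns
    step, event_type, pi_g, group_size."""
    frames = [
        pd.DataFrame({"step": traj.formation_steps, "event_type": "formation",
                      "pi_g": traj.formation_payoffs}),
        pd.DataFrame({"step": traj.breaking_steps, "event_type": "breaking",
                      "pi_g": traj.breaking_payoffs}),
    ]
    events = pd.concat(frames, ignore_index=True)
    events["group_size"] = traj.config.group_size
    events = events.sort_values(["step", "event_type"],
                                kind="stable").reset_index(drop=True)
    events.to_csv(path, index=False)


@dataclass
class RunManifest:
    """Provenance record for one canned experiment: the exact grids, base
    config and seed reproduce the outputs bit-for-bit."""

    name: str
    scale: str
    seed: int
    base_config: Dict
    G_grid: List[int]
    L_grid: List[int]
    pi_grid: List[float]
    version: str
    started: str
    finished: str
    outputs: List[str]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _experiment_grids(name: str, scale: str):
    if scale == "full":
        step, n_agents, reps = 0.05, 1000, 10
    elif scale == "reduced":
        step, n_agents, reps = 0.1, 200, 5
    else:
        raise ValueError(f"unknown scale {scale!r}; use 'full' or 'reduced'")
    pi_grid = pi_grid_default(step=step).tolist()
    if name == "phase_diagram":
        G_grid, L_grid = DEFAULT_G_GRID, [3, 10]
    elif name == "density_curves":
        G_grid, L_grid = [2, 10, 25], DEFAULT_L_GRID
    elif name == "length_comparison":
        G_grid, L_grid = [2, 10, 25, 50], DEFAULT_L_GRID
    elif name == "breaking_rates":
        G_grid, L_grid = [2, 10, 25, 50], [3, 25]
    else:
        raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
    return G_grid, L_grid, pi_grid, n_agents, reps


def run_experiment(name: str, scale: str = "reduced", outdir=".",
                   seed: int = 0, progress: bool = False) -> RunManifest:
    """Run one canned experiment and write its CSV table, JSON threshold
    summary and manifest into ``outdir``.

    ``phase_diagram`` sweeps the full G grid at two vec lengths;
    ``density_curves`` produces density curves and threshold estimates;
    ``length_comparison`` compares densities across vec lengths;
    ``breaking_rates`` produces the breaking-rate curves.  Identical
    (name, scale, seed) invocations produce byte-identical CSV/JSON
    outputs.
    """
    G_grid, L_grid, pi_grid, n_agents, reps = _experiment_grids(name, scale)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = SimConfig(n_agents=n_agents, seed=seed, replicates=reps)
    started = _dt.datetime.now().isoformat(timespec="seconds")
    result = sweep(G_grid, L_grid, pi_grid, base, progress=progress)
    csv_path = outdir / f"{name}_{scale}.csv"
    result.to_csv(csv_path)
    th = result.thresholds()
    summary = {
        "thresholds": [
            {"G": int(r.G), "L": int(r.L),
             "pi_hat": None if np.isnan(r.pi_hat) else float(r.pi_hat)}
            for r in th.itertuples()
        ]
    }
    json_path = outdir / f"{name}_{scale}_summary.json"
    json_path.write_text(json.dumps(summary, indent=2))
    from . import __version__
    manifest = RunManifest(
        name=name, scale=scale, seed=seed,
        base_config=dataclasses.asdict(base),
        G_grid=list(G_grid), L_grid=list(L_grid),
        pi_grid=[float(p) for p in pi_grid],
        version=__version__, started=started,
        finished=_dt.datetime.now().isoformat(timespec="seconds"),
        outputs=[csv_path.name, json_path.name],
    )
    manifest.to_json(outdir / f"{name}_{scale}_manifest.json")
    return manifest


def plot_density_curves(result: SweepResult, path, L: Optional[int] = None) -> None:
    """Plot rho_g(pi_i) for every (G, L) in the sweep (one L if given)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    tab = result.table if L is None else result.table[result.table.L == L]
    for (G, Lv), _ in tab.groupby(["G", "L"]):
        c = result.curve(int(G), int(Lv))
        ax.errorbar(c.pi_i, c.rho_mean, yerr=c.rho_se,
                    label=f"G={int(G)}, L={int(Lv)}", lw=1)
    ax.set_xlabel(r"individual payoff $\pi_i$")
    ax.set_ylabel(r"group density $\rho_g$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_phase_diagram(result: SweepResult, path, L: int) -> None:
    """Binary group/individual phase map over (pi_i, G) at one vec length."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pm = result.phase_map(L)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.pcolormesh(pm.columns.to_numpy(dtype=float),
                  np.arange(len(pm.index)), pm.to_numpy(dtype=float),
                  cmap="viridis", shading="nearest")
    ax.set_yticks(np.arange(len(pm.index)), [str(g) for g in pm.index])
    ax.set_xlabel(r"individual payoff $\pi_i$")
    ax.set_ylabel("group size G")
    ax.set_title(f"L = {L} (yellow: group phase)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
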