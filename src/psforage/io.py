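"""Configuration, serialisation and run manifests.

Formats are deliberately plain: YAML configs, JSON for ECM weight stacks and
fit reports, CSV for learning curves and metric series, one-integer-per-line
text for step samples, and HDF5 for long trajectory logs (CSV for short
ones).  Every pipeline command writes a manifest tying its outputs to the
config snapshot and seed that produced them.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ecm import ACTION_NAMES, N_ACTIONS, N_PERCEPTS, index_to_percept
from .world import TrajectoryArray, WorldConfig

__all__ = [
    "load_config",
    "save_config",
    "save_ecm_stack",
    "load_ecm_stack",
    "save_trajectory",
    "load_trajectory",
    "save_steps",
    "load_steps",
    "save_learning_curves",
    "write_manifest",
]

_CONFIG_EXTRAS = {"seed", "n_ensembles"}


def load_config(path: str | Path):
    """Read a YAML config; returns ``(WorldConfig, extras)``.

    Unknown keys raise, listing the offenders, so typos do not silently run
    a different simulation.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fields = set(WorldConfig.__dataclass_fields__)
    unknown = set(raw) - fields - _CONFIG_EXTRAS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    extras = {k: raw.pop(k) for k in list(raw) if k in _CONFIG_EXTRAS}
    return WorldConfig(**raw), extras


def save_config(path: str | Path, cfg: WorldConfig, **extras) -> None:
    data = asdict(cfg)
    data.update(extras)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def save_ecm_stack(path: str | Path, h: np.ndarray, eta: float, reward_R: float = 1.0) -> None:
    """Persist an ensemble's weight matrices with the percept enumeration."""
    h = np.asarray(h, dtype=float)
    if h.ndim != 3 or h.shape[1:] != (N_PERCEPTS, N_ACTIONS):
        raise ValueError(f"expected (N, {N_PERCEPTS}, {N_ACTIONS}) stack, got {h.shape}")
    payload = {
        "h": h.tolist(),
        "eta": eta,
        "reward_R": reward_R,
        "enumeration": [f"{f},{b}" for f, b in map(index_to_percept, range(N_PERCEPTS))],
        "actions": list(ACTION_NAMES),
    }
    Path(path).write_text(json.dumps(payload))


def load_ecm_stack(path: str | Path):
    d = json.loads(Path(path).read_text())
    expected = [f"{f},{b}" for f, b in map(index_to_percept, range(N_PERCEPTS))]
    if d.get("enumeration", expected) != expected:
        raise ValueError("percept enumeration in file does not match this build")
    return np.array(d["h"], dtype=float), float(d["eta"]), float(d.get("reward_R", 1.0))


def save_trajectory(path: str | Path, traj: TrajectoryArray) -> None:
    """HDF5 for ``.h5``/``.hdf5`` paths, long-format CSV otherwise."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("unwrapped", data=traj.unwrapped, compression="gzip")
            f.create_dataset("orient", data=traj.orient, compression="gzip")
            f.attrs["W"] = traj.W
        return
    T, N = traj.unwrapped.shape
    df = pd.DataFrame(
        {
            "agent": np.repeat(np.arange(N), T),
            "round": np.tile(np.arange(T), N),
            "unwrapped_pos": traj.unwrapped.T.ravel(),
            "pos": np.mod(traj.unwrapped.T.ravel(), traj.W),
            "orient": traj.orient.T.ravel(),
        }
    )
    df.attrs["W"] = traj.W
    with open(path, "w") as fh:
        fh.write(f"# W={traj.W}\n")
        df.to_csv(fh, index=False)


def load_trajectory(path: str | Path) -> TrajectoryArray:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            return TrajectoryArray(
                unwrapped=f["unwrapped"][...],
                orient=f["orient"][...],
                W=int(f.attrs["W"]),
            )
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# W="):
            raise ValueError("trajectory CSV must start with a '# W=' header line")
        W = int(first.strip().split("=")[1])
        df = pd.read_csv(fh)
    n_agents = df["agent"].nunique()
    T = df["round"].max() + 1
    unw = df.sort_values(["agent", "round"])["unwrapped_pos"].to_numpy().reshape(n_agents, T).T
    ori = df.sort_values(["agent", "round"])["orient"].to_numpy().reshape(n_agents, T).T
    return TrajectoryArray(unwrapped=unw, orient=ori.astype(np.int8), W=W)


def save_steps(path: str | Path, steps) -> None:
    np.savetxt(path, np.asarray(steps, dtype=np.int64), fmt="%d")


def load_steps(path: str | Path) -> np.ndarray:
    steps = np.loadtxt(path, dtype=np.int64, ndmin=1)
    if steps.size and steps.min() < 1:
        raise ValueError("step lengths must be positive integers")
    return steps


def save_learning_curves(path: str | Path, result) -> None:
    """Per-trial curves of one training run as tidy CSV."""
    data = {"trial": np.arange(result.rewarded_fraction.size), "rewarded_fraction": result.rewarded_fraction}
    if result.order_parameter is not None:
        data["order_parameter"] = result.order_parameter
    if result.mean_neighbors is not None:
        data["mean_neighbors"] = result.mean_neighbors
    pd.DataFrame(data).to_csv(path, index=False)


def write_manifest(path: str | Path, cfg: WorldConfig, seed, outputs, **extra) -> None:
    manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": asdict(cfg),
        "seed": seed,
        "outputs": [str(o) for o in outputs],
    }
    manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
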