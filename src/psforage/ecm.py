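"""Projective Simulation agent memory.

A Projective Simulation (PS) agent deliberates over an *episodic and
compositional memory* (ECM): a two-layer weighted graph connecting percept
clips to action clips.  For the foraging agents modelled here the percept
space is the Cartesian product of a front and a back visual-region class
(5 x 5 = 25 percepts) and there are exactly two actions, ``GO`` (keep the
current heading) and ``TURN`` (reverse it).

The policy is the row-normalised weight matrix ``h``: the probability of
action *j* given percept *i* is ``h[i, j] / sum_k h[i, k]``.  Learning is a
reward-modulated Hebbian update ``h <- h + R * g`` where the *glow* matrix
``g`` is an eligibility trace over recently traversed percept-action edges,
damped by a factor ``(1 - eta)`` every interaction round.

This module is the single-agent reference implementation; the vectorised
simulation kernel in :mod:`psforage.world` operates on stacked copies of the
same matrices and is tested against this one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# Ordered alphabet of visual-region classes: empty region, fewer than three
# neighbours mostly receding / approaching, three or more mostly receding /
# approaching.  The order is load-bearing: percept indices are row-major over
# (front, back) in this order and persisted files record it to guard drift.
ALPHABET: tuple[str, ...] = ("0", "<3_r", ">=3_r", "<3_a", ">=3_a")

N_PERCEPTS = len(ALPHABET) ** 2
GO, TURN = 0, 1
N_ACTIONS = 2
ACTION_NAMES = ("GO", "TURN")

_CLASS_INDEX = {label: i for i, label in enumerate(ALPHABET)}
# Tolerated aliases for the "three or more" classes (unicode >= sign).
_CLASS_INDEX.update({"≥3_r": 2, "≥3_a": 4, 0: 0, "0": 0})


def percept_index(percept: tuple[str, str]) -> int:
    """Map a (front, back) percept to its index in ``0..24``.

    The enumeration is row-major over (s_f, s_b) with the class order of
    :data:`ALPHABET`; it is a fixed bijection, stable across runs.
    """
    s_f, s_b = percept
    try:
        return len(ALPHABET) * _CLASS_INDEX[s_f] + _CLASS_INDEX[s_b]
    except KeyError as exc:  # pragma: no cover - message matters, not path
        raise ValueError(f"unknown percept class: {exc.args[0]!r}") from exc


def index_to_percept(index: int) -> tuple[str, str]:
    """Inverse of :func:`percept_index`."""
    if not 0 <= index < N_PERCEPTS:
        raise ValueError(f"percept index out of range: {index}")
    return ALPHABET[index // len(ALPHABET)], ALPHABET[index % len(ALPHABET)]


@dataclass
class ECM:
    """Episodic memory of one PS agent: weights, glow and learning constants.

    Parameters
    ----------
    eta:
        Glow damping in ``[0, 1]``; each round every glow entry is scaled by
        ``1 - eta`` before the traversed edge is incremented.
    reward_R:
        Non-negative reward magnitude delivered when the agent reaches food.
    """

    eta: float = 0.2
    reward_R: float = 1.0
    h: np.ndarray = field(default_factory=lambda: np.ones((N_PERCEPTS, N_ACTIONS)))
    g: np.ndarray = field(default_factory=lambda: np.zeros((N_PERCEPTS, N_ACTIONS)))

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.h.shape != (N_PERCEPTS, N_ACTIONS):
            raise ValueError(f"h must be {(N_PERCEPTS, N_ACTIONS)}, got {self.h.shape}")
        if self.g.shape != (N_PERCEPTS, N_ACTIONS):
            raise ValueError(f"g must be {(N_PERCEPTS, N_ACTIONS)}, got {self.g.shape}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.reward_R < 0:
            raise ValueError("reward_R must be non-negative")
        if np.any(self.h < 1.0):
            raise ValueError("all h entries must be >= 1 (h starts at 1 and only grows)")

    # -- policy ---------------------------------------------------------

    def action_probabilities(self, percept: tuple[str, str] | int) -> tuple[float, float]:
        """Return ``(P_go, P_turn)`` for a percept (row-normalised weights)."""
        i = percept if isinstance(percept, (int, np.integer)) else percept_index(percept)
        row = self.h[i]
        total = row[GO] + row[TURN]
        return row[GO] / total, row[TURN] / total

    def policy(self) -> np.ndarray:
        """The full 25-vector of GO probabilities."""
        return self.h[:, GO] / self.h.sum(axis=1)

    def sample_action(self, percept: tuple[str, str] | int, rng: np.random.Generator) -> int:
        """Draw ``GO`` or ``TURN`` for a percept; the caller records the edge."""
        i = percept if isinstance(percept, (int, np.integer)) else percept_index(percept)
        p_go, _ = self.action_probabilities(i)
        return GO if rng.random() < p_go else TURN

    # -- learning -------------------------------------------------------

    def update_glow(self, traversed: tuple[int, int] | None) -> None:
        """Damp every glow entry by ``1 - eta``; then mark the traversed edge.

        ``traversed`` is a ``(percept_index, action)`` pair, or ``None`` for a
        round in which no edge was walked (e.g. bookkeeping updates).
        """
        self.g *= 1.0 - self.eta
        if traversed is not None:
            self.g[traversed] += 1.0

    def apply_reward(self, R: float | None = None) -> None:
        """Reinforce glowing edges: ``h <- h + R * g`` (no-op when ``R = 0``)."""
        R = self.reward_R if R is None else R
        if R < 0:
            raise ValueError("rewards are non-negative in this model")
        self.h += R * self.g

    def reset_glow(self) -> None:
        """Zero the eligibility trace (used at the start of every trial)."""
        self.g[:] = 0.0

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "h": self.h.tolist(),
            "eta": self.eta,
            "reward_R": self.reward_R,
            "enumeration": [f"{f},{b}" for f, b in map(index_to_percept, range(N_PERCEPTS))],
            "actions": list(ACTION_NAMES),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ECM":
        expected = [f"{f},{b}" for f, b in map(index_to_percept, range(N_PERCEPTS))]
        if d.get("enumeration", expected) != expected:
            raise ValueError("percept enumeration in file does not match this build")
        return cls(eta=d["eta"], reward_R=d.get("reward_R", 1.0), h=np.array(d["h"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ECM":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fresh_ensemble_h(n_agents: int) -> np.ndarray:
    """Stacked all-ones weight matrices for ``n_agents`` untrained agents."""
    return np.ones((n_agents, N_PERCEPTS, N_ACTIONS))
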