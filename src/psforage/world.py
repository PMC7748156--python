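"""1D circular foraging world for ensembles of PS agents.

The world is a ring of ``W`` discrete positions.  ``N`` agents move at speed
one position per interaction round, each carrying its own ECM policy.  Every
round each agent, in a fixed label order, (1) possibly has its orientation
re-randomised (reorientation noise with period ``s_r``), (2) perceives the
neighbour count and majority motion class in its front and back visual
regions (radius ``V_R``), (3) samples GO or TURN from its policy, (4) moves
one position, (5) updates its glow, and (6) during training is rewarded once
per trial if it stands on a food position.

Trials start with all agents placed uniformly in the initial region (the
first ``2 V_R + 1`` positions, centred on ``C = V_R``) with random
orientations and fresh glow.  Food sits at ``F = C + d_F`` and
``F' = C - d_F`` (mod ``W``).  Training repeats trials with persistent
weights; *free runs* propagate trained, frozen policies with no food or
learning, which is how the long trajectories for the movement-pattern
analysis are produced.

The hot loop is JIT-compiled with numba and consumes a
``numpy.random.Generator`` directly, so compiled and pure-Python executions
of the same seed are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit

from .ecm import N_ACTIONS, N_PERCEPTS, fresh_ensemble_h

__all__ = [
    "WorldConfig",
    "TrialLog",
    "TrajectoryArray",
    "TrainResult",
    "initialize_trial",
    "compute_percept_index",
    "run_trial",
    "train_ensemble",
    "free_run",
    "policy_table",
]


@dataclass(frozen=True)
class WorldConfig:
    """Simulation parameters (defaults are the standard training setting)."""

    W: int = 500  # world size (number of ring positions)
    N: int = 60  # agents per ensemble
    V_R: int = 6  # visual range (positions, each side)
    s_r: int = 5  # reorientation period (rounds); 0 disables the noise
    n_rounds: int = 50  # interaction rounds per trial
    d_F: int = 21  # distance from initial-region centre to each food site
    eta: float = 0.2  # glow damping
    reward_R: float = 1.0  # reward magnitude
    n_trials: int = 10_000  # training length

    def __post_init__(self) -> None:
        if self.W < 3 or self.N < 1:
            raise ValueError("need W >= 3 and N >= 1")
        if self.V_R < 0 or 2 * self.V_R >= self.W:
            raise ValueError("need 0 <= V_R and 2*V_R < W")
        if not 0 <= self.d_F < self.W / 2:
            raise ValueError("need 0 <= d_F < W/2")
        if self.s_r < 0 or self.n_rounds < 1:
            raise ValueError("need s_r >= 0 and n_rounds >= 1")
        if not 0.0 <= self.eta <= 1.0 or self.reward_R < 0:
            raise ValueError("need eta in [0,1] and reward_R >= 0")

    @property
    def C(self) -> int:
        """Centre of the initial region."""
        return self.V_R

    @property
    def F(self) -> int:
        return (self.C + self.d_F) % self.W

    @property
    def F_prime(self) -> int:
        return (self.C - self.d_F) % self.W

    def with_world(self, W: int) -> "WorldConfig":
        return replace(self, W=W)


@dataclass
class TrialLog:
    """One trial: per-round snapshots plus the reward outcome.

    ``unwrapped`` has shape ``(n_rounds + 1, N)``; row 0 is the initial
    placement, row ``t`` the state after global round ``t``.  Wrapped
    positions are ``unwrapped % W``.
    """

    unwrapped: np.ndarray
    orient: np.ndarray
    rewarded: np.ndarray
    W: int

    @property
    def positions(self) -> np.ndarray:
        return np.mod(self.unwrapped, self.W)

    @property
    def rewarded_fraction(self) -> float:
        return float(np.mean(self.rewarded))


@dataclass
class TrajectoryArray:
    """Unwrapped positions/orientations of a reward-free run.

    Shape ``(T + 1, N)`` with the initial snapshot in row 0; consecutive rows
    differ by exactly +-1 per agent (speed 1).
    """

    unwrapped: np.ndarray
    orient: np.ndarray
    W: int

    @property
    def positions(self) -> np.ndarray:
        return np.mod(self.unwrapped, self.W)

    @property
    def n_rounds(self) -> int:
        return self.unwrapped.shape[0] - 1

    @property
    def n_agents(self) -> int:
        return self.unwrapped.shape[1]


@dataclass
class TrainResult:
    """Outcome of a training run: final weights and per-trial curves."""

    h: np.ndarray  # (N, 25, 2) final weights
    config: WorldConfig
    rewarded_fraction: np.ndarray  # (n_trials,) learning curve
    order_parameter: Optional[np.ndarray] = None  # per-trial round-mean phi
    mean_neighbors: Optional[np.ndarray] = None  # per-trial round-mean M
    seed_info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# JIT kernel
# ---------------------------------------------------------------------------


@njit(cache=False)
def _percept_index(pos, orient, i, W, V_R):
    """Percept index of agent ``i`` given current positions/orientations.

    Front region = circular displacements +1..+V_R along the focal heading,
    back region = -1..-V_R.  Agents co-located with the focal agent are
    inside the visual radius but on the boundary between the two regions, so
    they are counted in both, classified by their orientation exactly as a
    neighbour of that region would be (same heading = receding in front,
    approaching behind).  A region's class encodes the neighbour count
    threshold (<3 vs >=3) and whether the majority is receding or
    approaching; an exact tie counts as approaching.
    """
    n_others = pos.shape[0]
    pi = pos[i]
    oi = orient[i]
    f_rec = 0
    f_app = 0
    b_rec = 0
    b_app = 0
    for j in range(n_others):
        if j == i:
            continue
        d = (pos[j] - pi) % W
        if d == 0:
            if V_R < 1:  # zero radius: no perception at all
                continue
            if orient[j] == oi:
                f_rec += 1
                b_app += 1
            else:
                f_app += 1
                b_rec += 1
            continue
        if oi == 1:
            in_front = 1 <= d <= V_R
            in_back = d >= W - V_R
        else:
            in_front = d >= W - V_R
            in_back = 1 <= d <= V_R
        if in_front:
            if orient[j] == oi:
                f_rec += 1
            else:
                f_app += 1
        elif in_back:
            if orient[j] == oi:
                b_app += 1
            else:
                b_rec += 1
    # class codes: 0 empty, 1 "<3_r", 2 ">=3_r", 3 "<3_a", 4 ">=3_a"
    nf = f_rec + f_app
    if nf == 0:
        cf = 0
    elif f_rec > f_app:
        cf = 1 if nf < 3 else 2
    else:
        cf = 3 if nf < 3 else 4
    nb = b_rec + b_app
    if nb == 0:
        cb = 0
    elif b_rec > b_app:
        cb = 1 if nb < 3 else 2
    else:
        cb = 3 if nb < 3 else 4
    return 5 * cf + cb


@njit(cache=False)
def _run_rounds(
    h,
    g,
    pos,
    unw,
    orient,
    phase,
    rewarded,
    W,
    V_R,
    s_r,
    eta,
    R,
    F1,
    F2,
    n_rounds,
    learn,
    record,
    unw_log,
    orient_log,
    rng,
):
    """Advance the ensemble ``n_rounds`` global rounds, sequentially per agent."""
    N = pos.shape[0]
    damp = 1.0 - eta
    for t in range(n_rounds):
        for i in range(N):
            # reorientation noise, applied right before the agent's round
            if s_r > 0 and (t - phase[i]) % s_r == 0:
                orient[i] = 1 if rng.random() < 0.5 else -1
            idx = _percept_index(pos, orient, i, W, V_R)
            h_go = h[i, idx, 0]
            a = 0 if rng.random() < h_go / (h_go + h[i, idx, 1]) else 1
            if a == 1:
                orient[i] = -orient[i]
            pos[i] = (pos[i] + orient[i]) % W
            unw[i] += orient[i]
            # glow: damp everything, then mark the traversed edge
            for p in range(N_PERCEPTS):
                g[i, p, 0] *= damp
                g[i, p, 1] *= damp
            g[i, idx, a] += 1.0
            # at most one reward per agent per trial
            if learn and not rewarded[i] and (pos[i] == F1 or pos[i] == F2):
                for p in range(N_PERCEPTS):
                    h[i, p, 0] += R * g[i, p, 0]
                    h[i, p, 1] += R * g[i, p, 1]
                rewarded[i] = True
        if record:
            for i in range(N):
                unw_log[t + 1, i] = unw[i]
                orient_log[t + 1, i] = orient[i]


# ---------------------------------------------------------------------------
# Python-level API
# ---------------------------------------------------------------------------


def initialize_trial(cfg: WorldConfig, rng: np.random.Generator):
    """Fresh per-trial agent state.

    Positions are uniform on the inclusive initial window ``{0 .. 2 V_R}``
    (centre ``C = V_R``), orientations uniform +-1, reorientation phases
    uniform in ``{0 .. s_r - 1}``, reward flags cleared.
    """
    pos = rng.integers(0, 2 * cfg.V_R + 1, size=cfg.N)
    orient = rng.integers(0, 2, size=cfg.N) * 2 - 1
    phase = rng.integers(0, cfg.s_r, size=cfg.N) if cfg.s_r > 0 else np.zeros(cfg.N, np.int64)
    rewarded = np.zeros(cfg.N, dtype=np.bool_)
    return pos.astype(np.int64), orient.astype(np.int64), phase.astype(np.int64), rewarded


def compute_percept_index(positions, orientations, focal: int, cfg: WorldConfig) -> int:
    """Percept index of ``focal`` given the current ensemble state."""
    pos = np.asarray(positions, dtype=np.int64)
    ori = np.asarray(orientations, dtype=np.int64)
    return int(_percept_index(pos, ori, focal, cfg.W, cfg.V_R))


def run_trial(
    h: np.ndarray,
    cfg: WorldConfig,
    rng: np.random.Generator,
    learn: bool = True,
    record: bool = True,
) -> TrialLog:
    """One trial of ``cfg.n_rounds`` global rounds; mutates ``h`` if learning."""
    h = np.ascontiguousarray(h, dtype=np.float64)
    g = np.zeros_like(h)  # glow is trial-scoped
    pos, orient, phase, rewarded = initialize_trial(cfg, rng)
    unw = pos.copy()
    T = cfg.n_rounds
    unw_log = np.zeros((T + 1, cfg.N), dtype=np.int64)
    orient_log = np.zeros((T + 1, cfg.N), dtype=np.int8)
    unw_log[0] = unw
    orient_log[0] = orient
    _run_rounds(
        h, g, pos, unw, orient, phase, rewarded,
        cfg.W, cfg.V_R, cfg.s_r, cfg.eta, cfg.reward_R,
        cfg.F, cfg.F_prime, T, learn, record, unw_log, orient_log, rng,
    )
    return TrialLog(unwrapped=unw_log, orient=orient_log, rewarded=rewarded, W=cfg.W)


def train_ensemble(
    cfg: WorldConfig,
    rng: np.random.Generator,
    n_trials: Optional[int] = None,
    h: Optional[np.ndarray] = None,
    record_metrics: bool = False,
) -> TrainResult:
    """Train one ensemble for ``n_trials`` trials with persistent weights.

    With ``record_metrics`` the per-trial round-averaged order parameter and
    mean-neighbour count are computed from the trial logs as well (slower,
    but this is what the learning-dynamics plots are made of).
    """
    from . import metrics as _metrics

    n_trials = cfg.n_trials if n_trials is None else n_trials
    h = fresh_ensemble_h(cfg.N) if h is None else np.ascontiguousarray(h, dtype=np.float64)
    curve = np.empty(n_trials)
    phi = np.empty(n_trials) if record_metrics else None
    mneigh = np.empty(n_trials) if record_metrics else None
    for k in range(n_trials):
        log = run_trial(h, cfg, rng, learn=True, record=record_metrics)
        curve[k] = log.rewarded_fraction
        if record_metrics:
            ori = log.orient[1:].astype(np.int64)
            phi[k] = float(np.mean(np.abs(ori.mean(axis=1))))
            mneigh[k] = float(
                np.mean(_metrics.mean_neighbors_series(log.positions[1:], cfg.V_R, cfg.W))
            )
    return TrainResult(
        h=h, config=cfg, rewarded_fraction=curve, order_parameter=phi, mean_neighbors=mneigh
    )


def free_run(
    h: np.ndarray,
    cfg: WorldConfig,
    T_rounds: int,
    rng: np.random.Generator,
    W_override: Optional[int] = None,
) -> TrajectoryArray:
    """Reward-free run of trained (frozen) policies for ``T_rounds`` rounds.

    Reorientation noise stays active; there is no food and no learning.
    ``W_override`` reruns the ensemble in a different world size (e.g. a
    world too large to circle within the run, which emulates an open
    environment).
    """
    W = cfg.W if W_override is None else int(W_override)
    run_cfg = replace(cfg, W=W, n_rounds=1)  # n_rounds unused below
    h = np.ascontiguousarray(h, dtype=np.float64)
    g = np.zeros_like(h)
    pos, orient, phase, rewarded = initialize_trial(run_cfg, rng)
    unw = pos.copy()
    unw_log = np.zeros((T_rounds + 1, cfg.N), dtype=np.int64)
    orient_log = np.zeros((T_rounds + 1, cfg.N), dtype=np.int8)
    unw_log[0] = unw
    orient_log[0] = orient
    _run_rounds(
        h, g, pos, unw, orient, phase, rewarded,
        W, cfg.V_R, cfg.s_r, cfg.eta, 0.0,
        -1, -1, T_rounds, False, True, unw_log, orient_log, rng,
    )
    return TrajectoryArray(unwrapped=unw_log, orient=orient_log, W=W)


def policy_table(h: np.ndarray) -> np.ndarray:
    """Mean GO probability per percept as a 5x5 table (rows: front class).

    ``h`` is one stacked ensemble ``(N, 25, 2)`` or a list/array of such
    stacks; the average runs over all agents of all ensembles.
    """
    h = np.asarray(h, dtype=float)
    h = h.reshape(-1, N_PERCEPTS, N_ACTIONS)
    p_go = h[:, :, 0] / h.sum(axis=2)
    return p_go.mean(axis=0).reshape(5, 5)
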