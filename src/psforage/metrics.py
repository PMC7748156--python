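"""Swarm-level and trajectory-level summary statistics.

Alignment and cohesion observables for the ensemble (order parameter, local
alignment, mean neighbour count, swarm extent, swarm velocity, exploration
coverage) and diffusion observables for individual trajectories (mean
squared displacement and its power-law exponent).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = [
    "order_parameter",
    "local_alignment",
    "mean_neighbors",
    "mean_neighbors_series",
    "largest_circular_gap",
    "swarm_extent",
    "swarm_velocity",
    "exploration_coverage",
    "msd",
    "fit_diffusion_exponent",
]


def order_parameter(orientations) -> float:
    """Global alignment ``phi = |mean orientation|`` in ``[0, 1]``."""
    v = np.asarray(orientations, dtype=float)
    if v.size == 0:
        raise ValueError("order_parameter of an empty ensemble is undefined")
    return float(np.abs(v.mean()))


def _pair_within(positions, V_R: int, W: int) -> np.ndarray:
    """Boolean (N, N) matrix: j within visual range of i (diagonal False)."""
    pos = np.asarray(positions, dtype=np.int64)
    d = np.mod(pos[None, :] - pos[:, None], W)
    d = np.minimum(d, W - d)
    within = (d >= 1) & (d <= V_R)
    # co-located distinct agents (d == 0 off-diagonal) are within range of
    # each other for neighbour counting, though they feed neither percept
    # region; Eq-style neighbour counts use plain circular distance <= V_R.
    n = pos.shape[0]
    off_diag = ~np.eye(n, dtype=bool)
    within |= (d == 0) & off_diag
    return within


def local_alignment(positions, orientations, V_R: int, W: int) -> float:
    """Mean over agents of ``phi_i = |mean orientation of i's neighbours|``.

    Agents with no neighbour inside the visual range are excluded from the
    average; if no agent has neighbours the value is NaN.
    """
    ori = np.asarray(orientations, dtype=float)
    within = _pair_within(positions, V_R, W)
    counts = within.sum(axis=1)
    has = counts > 0
    if not np.any(has):
        return float("nan")
    sums = within @ ori
    phi_i = np.abs(sums[has] / counts[has])
    return float(phi_i.mean())


def mean_neighbors(positions, V_R: int, W: int) -> float:
    """Average number of agents within circular distance ``V_R`` of each agent."""
    return float(_pair_within(positions, V_R, W).sum(axis=1).mean())


def mean_neighbors_series(positions_2d, V_R: int, W: int) -> np.ndarray:
    """Per-round mean neighbour count for a (T, N) position log."""
    pos = np.asarray(positions_2d, dtype=np.int64)
    d = np.mod(pos[:, None, :] - pos[:, :, None], W)
    d = np.minimum(d, W - d)
    n = pos.shape[1]
    off_diag = ~np.eye(n, dtype=bool)
    within = ((d <= V_R) & off_diag[None, :, :])
    return within.sum(axis=2).mean(axis=1)


def largest_circular_gap(positions, W: int) -> int:
    """Largest run of empty positions between occupied sites on the ring."""
    occ = np.unique(np.mod(np.asarray(positions, dtype=np.int64), W))
    if occ.size == 1:
        return W - 1
    gaps = np.diff(occ) - 1
    wrap = W - occ[-1] + occ[0] - 1
    return int(max(gaps.max(initial=0), wrap))


def swarm_extent(positions, W: int, V_R: Optional[int] = None):
    """Extent of the occupied arc: max minus min occupied position, mod ``W``.

    Computed as ``W - 1 - largest_circular_gap`` so the wrap-around case is
    handled.  If ``V_R`` is given, a second return value flags a fragmented
    configuration (largest gap smaller than the visual range means the
    agents do not form one well-separated contiguous swarm).
    """
    gap = largest_circular_gap(positions, W)
    occ = np.unique(np.mod(np.asarray(positions, dtype=np.int64), W))
    extent = 0 if occ.size == 1 else W - 1 - gap
    if V_R is None:
        return extent
    return extent, gap < V_R


def swarm_velocity(positions_log, W: int) -> float:
    """Normalised net displacement ``<xi>`` of a trial, in ``[0, 1]``.

    ``positions_log`` is the (T+1, N) wrapped-position log of one trial; the
    per-agent net distance is the shorter circular arc between the first and
    last snapshot, divided by the number of rounds, then averaged.
    """
    pos = np.asarray(positions_log, dtype=np.int64)
    n_rounds = pos.shape[0] - 1
    fwd = np.mod(pos[-1] - pos[0], W)
    s = np.minimum(fwd, W - fwd)
    return float(np.mean(s / n_rounds))


def exploration_coverage(positions_log, C: int, W: int, d_max: Optional[int] = None):
    """Fraction of agents visiting distance ``d`` from ``C``, for each ``d``.

    An agent counts for distance ``d`` if it visited position ``(C + d) % W``
    or ``(C - d) % W`` at any round of the log.  Returns ``(d, fraction)``.
    """
    pos = np.mod(np.asarray(positions_log, dtype=np.int64), W)
    if d_max is None:
        d_max = pos.shape[0] - 1 + 2 * 6  # run length + a generous margin
        d_max = min(d_max, W // 2)
    ds = np.arange(d_max + 1)
    frac = np.empty(ds.shape, dtype=float)
    for k, d in enumerate(ds):
        a = (C + d) % W
        b = (C - d) % W
        visited = np.any((pos == a) | (pos == b), axis=0)
        frac[k] = visited.mean()
    return ds, frac


def msd(unwrapped, origin_stride: int = 0) -> np.ndarray:
    """Mean squared displacement over lag, averaged across trajectories.

    ``unwrapped`` is (T+1, N).  By default one time origin per trajectory
    (the run start) is used.  ``origin_stride > 0`` switches to a
    multi-origin estimate with origins every ``origin_stride`` rounds.
    """
    x = np.asarray(unwrapped, dtype=np.float64)
    T = x.shape[0] - 1
    if origin_stride <= 0:
        disp = x - x[0]
        return np.mean(disp**2, axis=1)
    out = np.zeros(T + 1)
    counts = np.zeros(T + 1)
    for t0 in range(0, T, origin_stride):
        seg = x[t0:] - x[t0]
        m = seg.shape[0]
        out[:m] += np.mean(seg**2, axis=1)
        counts[:m] += 1
    return out / counts


def fit_diffusion_exponent(msd_values, lags: Optional[Sequence[int]] = None) -> float:
    """Slope ``alpha`` of ``log2 MSD`` vs ``log2 lag`` over a lag window.

    The default window is the dyadic lags ``2, 4, ..., 1024`` (clipped to
    the available range).  MSD values must be positive over the window.
    """
    m = np.asarray(msd_values, dtype=float)
    if lags is None:
        lags = [2**k for k in range(1, 11)]
    lags = np.asarray([t for t in lags if t < m.size], dtype=int)
    if lags.size < 2:
        raise ValueError("need at least two lags inside the MSD series")
    vals = m[lags]
    if np.any(vals <= 0):
        raise ValueError("MSD must be positive over the fitting window")
    slope, _ = np.polyfit(np.log2(lags), np.log2(vals), 1)
    return float(slope)
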