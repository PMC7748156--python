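"""Synthetic inputs with known ground truth.

Exact samplers for the four step-length models (used to validate the MLE
and model-selection machinery against known parameters) and hand-crafted
deterministic ECM policies (used to exercise the world and the collective
metrics without any training).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .ecm import ALPHABET, N_ACTIONS, N_PERCEPTS

__all__ = ["sample_steps", "make_policy", "POLICY_LABELS"]

# "probability ~1" fixture edges: Eq-1 policies have no exact 1 with finite
# weights on both edges, so a 1e6:1 weight ratio stands in.
_BIG = 1.0e6

POLICY_LABELS = ("uniform", "always_go", "pure_aligner", "pure_cohesive")


def sample_steps(model: str, params: dict, S: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an ordered step-length sample of size ``S`` from a named model.

    BW and the CRW components are geometric draws; the CCRW simulates its
    two-state mode chain and emits geometric lengths in order; the discrete
    power law uses the zipf sampler (same Hurwitz-zeta normalisation).
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if model == "bw":
        lam = params["lambda"]
        if lam <= 0:
            raise ValueError("lambda must be positive")
        return rng.geometric(-np.expm1(-lam), size=S).astype(np.int64)
    if model == "crw":
        p, bI, bE = params["p"], params["beta_I"], params["beta_E"]
        if not 0 <= p <= 1 or bI <= 0 or bE <= 0:
            raise ValueError("invalid CRW parameters")
        intensive = rng.random(S) < p
        out = np.empty(S, dtype=np.int64)
        out[intensive] = rng.geometric(-np.expm1(-bI), size=int(intensive.sum()))
        out[~intensive] = rng.geometric(-np.expm1(-bE), size=int((~intensive).sum()))
        return out
    if model == "ccrw":
        d = params["delta"]
        lI, lE = params["lambda_I"], params["lambda_E"]
        gII, gEE = params["gamma_II"], params["gamma_EE"]
        if not (0 <= d <= 1 and 0 <= gII <= 1 and 0 <= gEE <= 1) or lI <= 0 or lE <= 0:
            raise ValueError("invalid CCRW parameters")
        modes = np.empty(S, dtype=np.int64)  # 0 = intensive, 1 = extensive
        modes[0] = 0 if rng.random() < d else 1
        stay = rng.random(S)  # pre-drawn transition uniforms
        for t in range(1, S):
            if modes[t - 1] == 0:
                modes[t] = 0 if stay[t] < gII else 1
            else:
                modes[t] = 1 if stay[t] < gEE else 0
        out = np.empty(S, dtype=np.int64)
        is_I = modes == 0
        out[is_I] = rng.geometric(-np.expm1(-lI), size=int(is_I.sum()))
        out[~is_I] = rng.geometric(-np.expm1(-lE), size=int((~is_I).sum()))
        return out
    if model == "pl":
        mu = params["mu"]
        if mu <= 1:
            raise ValueError("mu must exceed 1")
        return stats.zipf.rvs(mu, size=S, random_state=rng).astype(np.int64)
    raise ValueError(f"unknown model: {model!r}")


def _class_direction(label: str, region: str) -> int:
    """+1 if the class signals same-orientation neighbours, -1 opposite, 0 empty.

    In front, receding neighbours share the focal heading; at the back,
    approaching neighbours do.
    """
    if label == "0":
        return 0
    receding = label.endswith("_r")
    if region == "front":
        return 1 if receding else -1
    return -1 if receding else 1


def _class_density(label: str) -> int:
    if label == "0":
        return 0
    return 1 if label.startswith("<3") else 2


def make_policy(label: str, n_agents: int = 1) -> np.ndarray:
    """Deterministic fixture weight tables, stacked for ``n_agents``.

    ``uniform``
        all GO probabilities 1/2 (the untrained policy).
    ``always_go``
        GO with probability ~1 for every percept (straight movers).
    ``pure_aligner``
        follow the net orientation signal of the neighbours: GO when the
        majority shares the focal heading, TURN when it opposes it, 1/2 when
        the signals cancel or no neighbour is visible.
    ``pure_cohesive``
        move towards the denser region: GO when the front class is denser,
        TURN when the back is denser, 1/2 on ties.
    """
    if label not in POLICY_LABELS:
        raise ValueError(f"unknown policy label: {label!r}")
    h = np.ones((N_PERCEPTS, N_ACTIONS))
    for i_f, s_f in enumerate(ALPHABET):
        for i_b, s_b in enumerate(ALPHABET):
            idx = 5 * i_f + i_b
            if label == "always_go":
                h[idx] = (_BIG, 1.0)
            elif label == "pure_aligner":
                score = _class_direction(s_f, "front") + _class_direction(s_b, "back")
                if score > 0:
                    h[idx] = (_BIG, 1.0)
                elif score < 0:
                    h[idx] = (1.0, _BIG)
            elif label == "pure_cohesive":
                diff = _class_density(s_f) - _class_density(s_b)
                if diff > 0:
                    h[idx] = (_BIG, 1.0)
                elif diff < 0:
                    h[idx] = (1.0, _BIG)
    return np.repeat(h[None, :, :], n_agents, axis=0)
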