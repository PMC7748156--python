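"""Step-length extraction and movement-pattern model fitting.

A trajectory of a speed-1 agent on the ring decomposes uniquely into *steps*:
maximal runs of consecutive rounds moved in the same direction.  Four
candidate models for the step-length distribution are fitted by maximum
likelihood and compared:

``BW``
    Brownian walk — a single discrete exponential (geometric) pmf
    ``p(l) = (1 - e^-lambda) e^-lambda (l - 1)``, ``l >= 1``.
``CRW``
    Composite random walk — an iid two-component mixture of geometrics with
    intensive rate ``beta_I``, extensive rate ``beta_E`` (``beta_I >=
    beta_E``) and intensive weight ``p``.
``CCRW``
    Composite *correlated* random walk — a two-state hidden Markov model
    whose states (intensive/extensive) emit geometric step lengths; the
    sequence order matters.  Parameters: initial intensive probability
    ``delta``, rates ``lambda_I >= lambda_E`` and self-transition
    probabilities ``gamma_II``, ``gamma_EE``.
``PL``
    Discrete power law (Levy walk for ``1 < mu <= 3``):
    ``p(l) = l^-mu / zeta(mu, 1)`` with the Hurwitz zeta normalisation and
    no lower-bound parameter.

Model comparison uses AIC ``2k - 2 ln L``, Akaike weights and BIC
``k ln S - 2 ln L``; a model is declared the BIC winner only when its BIC
undercuts every rival by more than 10.

Goodness of fit: for the iid models a likelihood-ratio (G) statistic against
the fitted pmf, calibrated by parametric bootstrap; for the CCRW,
Kolmogorov-Smirnov uniformity of one-step-ahead mid-pseudo-residuals from
the forward recursion (the standard HMM construction for discrete data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy import optimize, special, stats

__all__ = [
    "RATE_MIN",
    "RATE_MAX",
    "extract_steps",
    "bw_pmf",
    "crw_pmf",
    "pl_pmf",
    "ccrw_marginal_weight",
    "FitResult",
    "ModelComparison",
    "fit_bw",
    "fit_crw",
    "loglik_ccrw",
    "fit_ccrw",
    "fit_pl",
    "fit_model",
    "fit_all_models",
    "compare_models",
    "gof_iid",
    "gof_ccrw",
    "survival_curves",
]

RATE_MIN = 1e-6
RATE_MAX = 10.0
PROB_MIN = 1e-6
MODEL_K = {"bw": 1, "crw": 3, "pl": 1, "ccrw": 5}


# ---------------------------------------------------------------------------
# Step extraction
# ---------------------------------------------------------------------------


def extract_steps(series, kind: str = "auto") -> np.ndarray:
    """Run-length encode a trajectory into ordered step lengths.

    ``series`` is either a per-round orientation sequence (+-1 values) or an
    unwrapped position series (one more entry than rounds); ``kind`` may be
    ``"orientations"``, ``"positions"`` or ``"auto"``.  The first and last
    (boundary-truncated) runs are included; the step lengths always sum to
    the number of rounds.
    """
    x = np.asarray(series)
    if x.ndim != 1:
        raise ValueError("extract_steps expects a single 1D series")
    if kind == "auto":
        kind = "orientations" if np.all(np.isin(x, (-1, 1))) else "positions"
    if kind == "positions":
        moves = np.diff(x.astype(np.int64))
        if moves.size == 0:
            raise ValueError("position series shorter than one round")
        if not np.all(np.abs(moves) == 1):
            raise ValueError("not a speed-1 position series")
    elif kind == "orientations":
        moves = x.astype(np.int64)
        if moves.size == 0:
            raise ValueError("empty orientation series")
    else:
        raise ValueError(f"unknown kind: {kind!r}")
    change = np.flatnonzero(moves[1:] != moves[:-1])
    bounds = np.concatenate(([0], change + 1, [moves.size]))
    return np.diff(bounds).astype(np.int64)


# ---------------------------------------------------------------------------
# pmfs and survival functions
# ---------------------------------------------------------------------------


def bw_pmf(l, lam: float) -> np.ndarray:
    """Discrete exponential pmf on ``l >= 1``."""
    l = np.asarray(l, dtype=float)
    return -np.expm1(-lam) * np.exp(-lam * (l - 1.0))


def bw_logpmf(l, lam: float) -> np.ndarray:
    l = np.asarray(l, dtype=float)
    return np.log(-np.expm1(-lam)) - lam * (l - 1.0)


def crw_pmf(l, p: float, beta_I: float, beta_E: float) -> np.ndarray:
    return p * bw_pmf(l, beta_I) + (1.0 - p) * bw_pmf(l, beta_E)


def pl_pmf(l, mu: float) -> np.ndarray:
    """Discrete power law on ``l >= 1`` with Hurwitz-zeta normalisation."""
    l = np.asarray(l, dtype=float)
    return l ** (-mu) / special.zeta(mu, 1.0)


def bw_survival(l, lam: float) -> np.ndarray:
    """P(step > l) = exp(-lambda * l) for the geometric model."""
    return np.exp(-lam * np.asarray(l, dtype=float))


def crw_survival(l, p: float, beta_I: float, beta_E: float) -> np.ndarray:
    return p * bw_survival(l, beta_I) + (1.0 - p) * bw_survival(l, beta_E)


def pl_survival(l, mu: float) -> np.ndarray:
    l = np.asarray(l, dtype=np.int64)
    return np.array([special.zeta(mu, li + 1.0) for li in np.atleast_1d(l)]) / special.zeta(
        mu, 1.0
    )


def ccrw_marginal_weight(gamma_II: float, gamma_EE: float) -> float:
    """Intensive-mode weight of the iid mixture approximating a CCRW.

    Weights the two geometric components by the mean dwell time of each mode,
    ``p' = (1/(1-gamma_II)) / (1/(1-gamma_II) + 1/(1-gamma_EE))``.
    """
    tI = 1.0 / (1.0 - gamma_II)
    tE = 1.0 / (1.0 - gamma_EE)
    return tI / (tI + tE)


# ---------------------------------------------------------------------------
# Fit containers
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """MLE outcome for one model on one step sample."""

    model: str
    params: dict
    loglik: float
    n: int
    k: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.k:
            self.k = MODEL_K[self.model]

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n) - 2.0 * self.loglik

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {k: float(v) for k, v in self.params.items()},
            "loglik": float(self.loglik),
            "n": int(self.n),
            "k": int(self.k),
            "aic": float(self.aic),
            "bic": float(self.bic),
        }


@dataclass
class ModelComparison:
    """AIC/BIC comparison of fits computed on one identical sample."""

    fits: dict  # model -> FitResult
    akaike_weights: dict
    aic_best: str
    bic_best: Optional[str]  # None when no model clears the delta-BIC > 10 bar
    delta_bic: dict

    def to_dict(self) -> dict:
        return {
            "akaike_weights": {m: float(w) for m, w in self.akaike_weights.items()},
            "aic_best": self.aic_best,
            "bic_best": self.bic_best,
            "delta_bic": {m: float(d) for m, d in self.delta_bic.items()},
            "fits": {m: f.to_dict() for m, f in self.fits.items()},
        }


def _as_sample(steps) -> np.ndarray:
    s = np.asarray(steps, dtype=np.int64)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("step sample must be a nonempty 1D sequence")
    if np.any(s < 1):
        raise ValueError("step lengths must be >= 1")
    return s


def _geom_rate_from_mean(m: float) -> float:
    """Closed-form geometric MLE ``lambda = ln(m / (m - 1))``, clipped."""
    if m <= 1.0:
        return np.inf
    return float(np.clip(np.log(m / (m - 1.0)), RATE_MIN, RATE_MAX))


# ---------------------------------------------------------------------------
# BW
# ---------------------------------------------------------------------------


def fit_bw(steps) -> FitResult:
    """Closed-form MLE of the single-geometric model."""
    s = _as_sample(steps)
    m = float(s.mean())
    if m <= 1.0:
        warnings.warn("all steps have length 1: BW rate is at the +inf boundary")
        return FitResult("bw", {"lambda": np.inf}, 0.0, s.size)
    lam = _geom_rate_from_mean(m)
    ll = float(np.sum(bw_logpmf(s, lam)))
    return FitResult("bw", {"lambda": lam}, ll, s.size)


# ---------------------------------------------------------------------------
# CRW (iid mixture) via EM on the count representation
# ---------------------------------------------------------------------------


def _crw_em(values, counts, p, bI, bE, tol, max_iter):
    S = counts.sum()
    ll_old = -np.inf
    for _ in range(max_iter):
        lI = np.log(p) + bw_logpmf(values, bI)
        lE = np.log1p(-p) + bw_logpmf(values, bE)
        ltot = np.logaddexp(lI, lE)
        ll = float(np.sum(counts * ltot))
        r = np.exp(lI - ltot)
        w = counts * r
        wI = w.sum()
        wE = S - wI
        p = float(np.clip(wI / S, PROB_MIN, 1.0 - PROB_MIN))
        if wI > 0:
            bI = _geom_rate_from_mean(float(np.sum(w * values) / wI))
            bI = min(bI, RATE_MAX)
        if wE > 0:
            bE = _geom_rate_from_mean(float(np.sum(counts * (1 - r) * values) / wE))
            bE = min(bE, RATE_MAX)
        if ll - ll_old < tol and ll >= ll_old:
            break
        ll_old = ll
    return p, bI, bE, ll


def fit_crw(steps, n_restarts: int = 10, rng=None, tol: float = 1e-8, max_iter: int = 2000) -> FitResult:
    """MLE of the iid two-geometric mixture by multi-restart EM.

    The likelihood depends on the sample only through the length counts, so
    EM runs on the count representation.  The intensive mode is the larger
    rate (labels swapped at the end if needed).
    """
    s = _as_sample(steps)
    rng = np.random.default_rng(0) if rng is None else rng
    values, counts = np.unique(s, return_counts=True)
    values = values.astype(float)
    counts = counts.astype(float)
    m = float(s.mean())
    if m <= 1.0:
        warnings.warn("all steps have length 1: CRW collapses to the BW boundary")
        return FitResult("crw", {"p": 1.0, "beta_I": np.inf, "beta_E": np.inf}, 0.0, s.size)
    # informed start: split sample at the mean
    lam0 = _geom_rate_from_mean(m)
    short = s[s <= m]
    long_ = s[s > m]
    starts = []
    if short.size and long_.size:
        starts.append(
            (
                short.size / s.size,
                _geom_rate_from_mean(max(float(short.mean()), 1.0 + 1e-9)),
                _geom_rate_from_mean(float(long_.mean())),
            )
        )
    starts.append((0.5, min(4.0 * lam0, RATE_MAX), max(0.25 * lam0, RATE_MIN)))
    while len(starts) < n_restarts:
        starts.append(
            (
                rng.uniform(0.05, 0.95),
                float(np.exp(rng.uniform(np.log(1e-3), np.log(2.0)))),
                float(np.exp(rng.uniform(np.log(1e-3), np.log(2.0)))),
            )
        )
    best = None
    for p0, b1, b2 in starts:
        bI0, bE0 = max(b1, b2), min(b1, b2)
        try:
            p, bI, bE, ll = _crw_em(values, counts, p0, bI0, bE0, tol, max_iter)
        except (FloatingPointError, ValueError):  # pragma: no cover - guard
            continue
        if best is None or ll > best[-1]:
            best = (p, bI, bE, ll)
    if best is None:  # pragma: no cover
        raise RuntimeError("CRW EM failed on all restarts")
    p, bI, bE, ll = best
    if bI < bE:  # identifiability: intensive = larger decay rate
        bI, bE, p = bE, bI, 1.0 - p
    return FitResult(
        "crw", {"p": p, "beta_I": bI, "beta_E": bE}, ll, s.size, extras={"restarts": len(starts)}
    )


# ---------------------------------------------------------------------------
# CCRW (two-state HMM with geometric emissions)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _ccrw_forward_ll(steps, delta, lI, lE, gII, gEE):
    """Scaled forward recursion; returns the exact log-likelihood."""
    qI = np.exp(-lI)
    qE = np.exp(-lE)
    cI = 1.0 - qI
    cE = 1.0 - qE
    l0 = steps[0]
    a0 = delta * cI * qI ** (l0 - 1)
    a1 = (1.0 - delta) * cE * qE ** (l0 - 1)
    c = a0 + a1
    if c <= 0.0:
        return -np.inf
    ll = np.log(c)
    a0 /= c
    a1 /= c
    for t in range(1, steps.shape[0]):
        lt = steps[t]
        eI = cI * qI ** (lt - 1)
        eE = cE * qE ** (lt - 1)
        b0 = (a0 * gII + a1 * (1.0 - gEE)) * eI
        b1 = (a0 * (1.0 - gII) + a1 * gEE) * eE
        c = b0 + b1
        if c <= 0.0:
            return -np.inf
        ll += np.log(c)
        a0 = b0 / c
        a1 = b1 / c
    return ll


@njit(cache=False)
def _ccrw_em_once(steps, delta, lI, lE, gII, gEE, tol, max_iter, rate_min, rate_max, prob_min):
    """Baum-Welch with closed-form geometric M-step. Returns params + loglik."""
    S = steps.shape[0]
    alpha = np.empty((S, 2))
    scale = np.empty(S)
    beta = np.empty((S, 2))
    ll_old = -np.inf
    ll = -np.inf
    for _ in range(max_iter):
        qI = np.exp(-lI)
        qE = np.exp(-lE)
        cI = 1.0 - qI
        cE = 1.0 - qE
        # forward
        e0 = cI * qI ** (steps[0] - 1)
        e1 = cE * qE ** (steps[0] - 1)
        a0 = delta * e0
        a1 = (1.0 - delta) * e1
        c = a0 + a1
        if c <= 0.0:
            return delta, lI, lE, gII, gEE, -np.inf
        alpha[0, 0] = a0 / c
        alpha[0, 1] = a1 / c
        scale[0] = c
        ll = np.log(c)
        for t in range(1, S):
            eI = cI * qI ** (steps[t] - 1)
            eE = cE * qE ** (steps[t] - 1)
            b0 = (alpha[t - 1, 0] * gII + alpha[t - 1, 1] * (1.0 - gEE)) * eI
            b1 = (alpha[t - 1, 0] * (1.0 - gII) + alpha[t - 1, 1] * gEE) * eE
            c = b0 + b1
            if c <= 0.0:
                return delta, lI, lE, gII, gEE, -np.inf
            alpha[t, 0] = b0 / c
            alpha[t, 1] = b1 / c
            scale[t] = c
            ll += np.log(c)
        # backward (scaled with the forward scales)
        beta[S - 1, 0] = 1.0
        beta[S - 1, 1] = 1.0
        for t in range(S - 2, -1, -1):
            eI = cI * qI ** (steps[t + 1] - 1)
            eE = cE * qE ** (steps[t + 1] - 1)
            bI = eI * beta[t + 1, 0]
            bE = eE * beta[t + 1, 1]
            beta[t, 0] = (gII * bI + (1.0 - gII) * bE) / scale[t + 1]
            beta[t, 1] = ((1.0 - gEE) * bI + gEE * bE) / scale[t + 1]
        # E-step accumulators
        wI = 0.0
        wE = 0.0
        wIl = 0.0
        wEl = 0.0
        aII = 0.0
        aIE = 0.0
        aEI = 0.0
        aEE = 0.0
        for t in range(S):
            gI = alpha[t, 0] * beta[t, 0]
            gE = alpha[t, 1] * beta[t, 1]
            z = gI + gE
            gI /= z
            gE /= z
            wI += gI
            wE += gE
            wIl += gI * steps[t]
            wEl += gE * steps[t]
            if t == 0:
                delta_new = gI
        for t in range(1, S):
            eI = cI * qI ** (steps[t] - 1)
            eE = cE * qE ** (steps[t] - 1)
            denom = scale[t]
            xII = alpha[t - 1, 0] * gII * eI * beta[t, 0] / denom
            xIE = alpha[t - 1, 0] * (1.0 - gII) * eE * beta[t, 1] / denom
            xEI = alpha[t - 1, 1] * (1.0 - gEE) * eI * beta[t, 0] / denom
            xEE = alpha[t - 1, 1] * gEE * eE * beta[t, 1] / denom
            z = xII + xIE + xEI + xEE
            aII += xII / z
            aIE += xIE / z
            aEI += xEI / z
            aEE += xEE / z
        # M-step
        delta = min(max(delta_new, prob_min), 1.0 - prob_min)
        if aII + aIE > 0:
            gII = min(max(aII / (aII + aIE), prob_min), 1.0 - prob_min)
        if aEI + aEE > 0:
            gEE = min(max(aEE / (aEI + aEE), prob_min), 1.0 - prob_min)
        if wI > 0:
            mI = wIl / wI
            if mI > 1.0:
                lI = min(max(np.log(mI / (mI - 1.0)), rate_min), rate_max)
            else:
                lI = rate_max
        if wE > 0:
            mE = wEl / wE
            if mE > 1.0:
                lE = min(max(np.log(mE / (mE - 1.0)), rate_min), rate_max)
            else:
                lE = rate_max
        if ll - ll_old < tol and ll >= ll_old:
            break
        ll_old = ll
    return delta, lI, lE, gII, gEE, ll


def loglik_ccrw(steps, params: dict) -> float:
    """Exact CCRW log-likelihood via the scaled forward recursion."""
    s = _as_sample(steps)
    delta = params["delta"]
    lI = params["lambda_I"]
    lE = params["lambda_E"]
    gII = params["gamma_II"]
    gEE = params["gamma_EE"]
    for name, v in (("delta", delta), ("gamma_II", gII), ("gamma_EE", gEE)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if lI <= 0 or lE <= 0:
        raise ValueError("decay rates must be positive")
    return float(_ccrw_forward_ll(s.astype(np.float64), delta, lI, lE, gII, gEE))


def fit_ccrw(
    steps,
    n_restarts: int = 10,
    rng=None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> FitResult:
    """MLE of the two-state HMM by multi-restart Baum-Welch.

    Restarts draw rates log-uniformly in ``[1e-3, 2]`` and the probabilities
    uniformly; one informed start reuses the CRW mixture fit.  The intensive
    state is the larger rate; labels are swapped at the end if needed.
    """
    s = _as_sample(steps).astype(np.float64)
    rng = np.random.default_rng(0) if rng is None else rng
    if float(s.mean()) <= 1.0:
        warnings.warn("all steps have length 1: CCRW collapses to the BW boundary")
        return FitResult(
            "ccrw",
            {"delta": 0.5, "lambda_I": np.inf, "lambda_E": np.inf, "gamma_II": 0.5, "gamma_EE": 0.5},
            0.0,
            s.size,
        )
    crw = fit_crw(steps, n_restarts=4, rng=rng)
    starts = [
        (0.5, max(crw.params["beta_I"], RATE_MIN), max(crw.params["beta_E"], RATE_MIN), 0.85, 0.85),
        (0.5, 0.5, 0.02, 0.9, 0.9),
    ]
    while len(starts) < n_restarts:
        r1 = float(np.exp(rng.uniform(np.log(1e-3), np.log(2.0))))
        r2 = float(np.exp(rng.uniform(np.log(1e-3), np.log(2.0))))
        starts.append(
            (
                rng.uniform(0.1, 0.9),
                max(r1, r2),
                min(r1, r2),
                rng.uniform(0.5, 0.99),
                rng.uniform(0.5, 0.99),
            )
        )
    best = None
    # cheap pass on a prefix of the ordered sequence, tight polish on the
    # full sample from the best start (EM is monotone, so the polish can
    # only improve the likelihood it is handed)
    prefix = s[: min(s.size, 5000)]
    for st in starts:
        out = _ccrw_em_once(prefix, *st, 1e-3, 150, RATE_MIN, RATE_MAX, PROB_MIN)
        if np.isfinite(out[-1]) and (best is None or out[-1] > best[-1]):
            best = out
    if best is None:  # pragma: no cover
        raise RuntimeError("CCRW EM failed on all restarts")
    out = _ccrw_em_once(s, *best[:-1], tol, max_iter, RATE_MIN, RATE_MAX, PROB_MIN)
    delta, lI, lE, gII, gEE, ll = out if np.isfinite(out[-1]) else best
    if lI < lE:  # identifiability
        lI, lE = lE, lI
        gII, gEE = gEE, gII
        delta = 1.0 - delta
    params = {"delta": delta, "lambda_I": lI, "lambda_E": lE, "gamma_II": gII, "gamma_EE": gEE}
    return FitResult("ccrw", params, float(ll), s.size, extras={"restarts": len(starts)})


# ---------------------------------------------------------------------------
# PL
# ---------------------------------------------------------------------------


def fit_pl(steps, mu_max: float = 20.0) -> FitResult:
    """MLE of the discrete power law by 1D bounded likelihood maximisation."""
    s = _as_sample(steps)
    log_sum = float(np.sum(np.log(s)))
    S = s.size
    if log_sum == 0.0:
        warnings.warn("all steps have length 1: PL exponent is at the +inf boundary")
        return FitResult("pl", {"mu": np.inf}, 0.0, S)

    def neg_ll(mu):
        return mu * log_sum + S * np.log(special.zeta(mu, 1.0))

    res = optimize.minimize_scalar(
        neg_ll, bounds=(1.0 + 1e-9, mu_max), method="bounded", options={"xatol": 1e-10}
    )
    mu = float(res.x)
    return FitResult("pl", {"mu": mu}, -float(res.fun), S)


# ---------------------------------------------------------------------------
# Model comparison and GOF
# ---------------------------------------------------------------------------

_FITTERS = {"bw": fit_bw, "crw": fit_crw, "ccrw": fit_ccrw, "pl": fit_pl}


def fit_model(model: str, steps, **kwargs) -> FitResult:
    if model not in _FITTERS:
        raise ValueError(f"unknown model: {model!r}")
    return _FITTERS[model](steps, **kwargs)


def fit_all_models(steps, models: Sequence[str] = ("bw", "crw", "ccrw", "pl"), rng=None) -> dict:
    out = {}
    for m in models:
        kwargs = {"rng": rng} if m in ("crw", "ccrw") else {}
        out[m] = _FITTERS[m](steps, **kwargs)
    return out


def compare_models(fits, delta_bic_threshold: float = 10.0) -> ModelComparison:
    """AIC weights and the conservative delta-BIC winner rule."""
    if not isinstance(fits, dict):
        fits = {f.model: f for f in fits}
    sizes = {f.n for f in fits.values()}
    if len(sizes) != 1:
        raise ValueError("fits must all be computed on the identical sample")
    aics = {m: f.aic for m, f in fits.items()}
    amin = min(aics.values())
    raw = {m: np.exp(-0.5 * (a - amin)) for m, a in aics.items()}
    z = sum(raw.values())
    weights = {m: r / z for m, r in raw.items()}
    bics = {m: f.bic for m, f in fits.items()}
    bic_best = min(bics, key=bics.get)
    delta = {m: b - bics[bic_best] for m, b in bics.items()}
    rivals = [d for m, d in delta.items() if m != bic_best]
    winner = bic_best if (not rivals or min(rivals) > delta_bic_threshold) else None
    return ModelComparison(
        fits=fits,
        akaike_weights=weights,
        aic_best=min(aics, key=aics.get),
        bic_best=winner,
        delta_bic=delta,
    )


def _model_pmf(fit: FitResult):
    if fit.model == "bw":
        return lambda l: bw_pmf(l, fit.params["lambda"])
    if fit.model == "crw":
        return lambda l: crw_pmf(l, fit.params["p"], fit.params["beta_I"], fit.params["beta_E"])
    if fit.model == "pl":
        return lambda l: pl_pmf(l, fit.params["mu"])
    raise ValueError(f"{fit.model} is not an iid model")


def _g_statistic(sample: np.ndarray, fit: FitResult, min_expected: float = 5.0) -> float:
    """Likelihood-ratio statistic of binned counts vs the fitted pmf.

    Bins are single lengths ``1..L`` pooled from the right until every bin's
    expected count reaches ``min_expected``; the open tail is one bin.
    """
    pmf = _model_pmf(fit)
    S = sample.size
    lmax = int(sample.max())
    probs = pmf(np.arange(1, lmax + 1))
    tail = max(1.0 - probs.sum(), 0.0)
    obs = np.bincount(sample, minlength=lmax + 1)[1:].astype(float)
    # pool from the right so sparse tail bins merge with the open tail
    exp_bins = [tail * S]
    obs_bins = [0.0]
    for l in range(lmax, 0, -1):
        if exp_bins[-1] < min_expected:
            exp_bins[-1] += probs[l - 1] * S
            obs_bins[-1] += obs[l - 1]
        else:
            exp_bins.append(probs[l - 1] * S)
            obs_bins.append(obs[l - 1])
    e = np.asarray(exp_bins)
    o = np.asarray(obs_bins)
    mask = o > 0
    return float(2.0 * np.sum(o[mask] * np.log(o[mask] / e[mask])))


def gof_iid(steps, fit: FitResult, n_boot: int = 200, rng=None):
    """Parametric-bootstrap G-test for the iid models (BW, CRW, PL).

    Simulates ``n_boot`` samples from the fitted model, refits the model on
    each and compares the observed G statistic with the bootstrap null
    distribution.  Returns ``(g_observed, p_value)``.
    """
    from .synth import sample_steps

    s = _as_sample(steps)
    rng = np.random.default_rng(0) if rng is None else rng
    g_obs = _g_statistic(s, fit)
    if n_boot <= 0:
        return g_obs, float("nan")
    exceed = 0
    for _ in range(n_boot):
        sim = sample_steps(fit.model, fit.params, s.size, rng)
        if fit.model == "crw":
            refit = fit_crw(sim, n_restarts=3, rng=rng)
        else:
            refit = _FITTERS[fit.model](sim)
        if _g_statistic(sim, refit) >= g_obs:
            exceed += 1
    p = (exceed + 1.0) / (n_boot + 1.0)
    return g_obs, float(p)


def gof_ccrw(steps, fit: FitResult):
    """KS uniformity test of CCRW one-step-ahead mid-pseudo-residuals.

    For each step the forward recursion yields the forecast distribution
    given the past; the discrete mid-pseudo-residual is
    ``u_t = (F_t(l_t) + F_t(l_t - 1)) / 2``, uniform under a correct model.
    Returns ``(D_KS, p_value)``.
    """
    s = _as_sample(steps).astype(np.float64)
    delta = fit.params["delta"]
    lI, lE = fit.params["lambda_I"], fit.params["lambda_E"]
    gII, gEE = fit.params["gamma_II"], fit.params["gamma_EE"]
    qI, qE = np.exp(-lI), np.exp(-lE)
    cI, cE = 1.0 - qI, 1.0 - qE
    S = s.size
    u = np.empty(S)
    wI = delta
    for t in range(S):
        lt = s[t]
        # forecast cdf at lt and lt-1 under the mode mixture
        FI_hi = 1.0 - qI**lt
        FE_hi = 1.0 - qE**lt
        FI_lo = 1.0 - qI ** (lt - 1.0)
        FE_lo = 1.0 - qE ** (lt - 1.0)
        hi = wI * FI_hi + (1.0 - wI) * FE_hi
        lo = wI * FI_lo + (1.0 - wI) * FE_lo
        u[t] = 0.5 * (hi + lo)
        # condition on the observed step, then propagate one mode transition
        aI = wI * cI * qI ** (lt - 1.0)
        aE = (1.0 - wI) * cE * qE ** (lt - 1.0)
        z = aI + aE
        if z <= 0:
            aI, aE, z = wI, 1.0 - wI, 1.0
        aI /= z
        aE /= z
        wI = aI * gII + aE * (1.0 - gEE)
    res = stats.kstest(u, "uniform")
    return float(res.statistic), float(res.pvalue)


def survival_curves(steps, fits: Optional[dict] = None):
    """Empirical and fitted survival functions ``P(step > l)``.

    Returns a dict with ``"l"`` (0..max), ``"empirical"`` and one entry per
    fitted model.  The CCRW entry uses the dwell-time-weighted iid mixture
    approximation with weight :func:`ccrw_marginal_weight`.
    """
    s = _as_sample(steps)
    lmax = int(s.max())
    grid = np.arange(0, lmax + 1)
    emp = np.array([(s > l).mean() for l in grid])
    out = {"l": grid, "empirical": emp}
    for m, f in (fits or {}).items():
        pr = f.params
        if m == "bw":
            out[m] = bw_survival(grid, pr["lambda"])
        elif m == "crw":
            out[m] = crw_survival(grid, pr["p"], pr["beta_I"], pr["beta_E"])
        elif m == "pl":
            out[m] = pl_survival(grid, pr["mu"])
        elif m == "ccrw":
            w = ccrw_marginal_weight(pr["gamma_II"], pr["gamma_EE"])
            out[m] = crw_survival(grid, w, pr["lambda_I"], pr["lambda_E"])
    return out
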