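"""Stochastic model of seeded ribbon growth and its analytic solution.

A seeded ribbon elongates at intrinsic velocity ``v`` (nm/s) while in the
*growing* state, pauses in a *stalled* state, and stops permanently on
*termination* (e.g. poisoning of the growth front by truncated slats):

* growing -> stalled at rate ``k_stall``; stalled -> growing at ``k_resume``
  (a reversible two-state pause process, started at stationarity);
* termination is absorbing and runs at rate ``k_term`` in both states.

Because the pause process is stationary and independent of termination, the
mean contour length has the exact closed form

    E[L(t)] = (v_eff / k_term) * (1 - exp(-k_term * t)),
    v_eff   = v * k_resume / (k_resume + k_stall),

with the linear limit ``v_eff * t`` as ``k_term -> 0``: growth looks linear
early and saturates at ``v_eff / k_term`` once termination catches up —
the non-linear profiles seen for fast, high-temperature growth.

Interface units: hours for time, nm for length, seconds inside the rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GrowthParams",
    "LengthSample",
    "GrowthFit",
    "simulate_ribbons",
    "analytic_mean_length",
    "fit_growth_model",
    "polydispersity_index",
    "rate_constant_from_velocity",
    "velocity_from_rate_constant",
    "ribbon_count_from_seeds",
]

HOUR = 3600.0


@dataclass(frozen=True)
class GrowthParams:
    """Kinetic parameters of the seeded-growth model.

    v : intrinsic growth velocity, nm/s
    k_stall, k_resume : pause entry/exit rates, 1/s
    k_term : absorbing termination rate, 1/s
    J : spontaneous nucleation rate, mol/L/s (unseeded background)
    seed_conc, slat_conc : mol/L
    delta : ribbon extension per slat, nm (two new half-turn columns)
    """

    v: float
    k_stall: float = 0.0
    k_resume: float = 1.0
    k_term: float = 0.0
    J: float = 0.0
    seed_conc: float = 0.0
    slat_conc: float = 1e-6
    delta: float = 1.5

    def __post_init__(self) -> None:
        for name in ("v", "k_stall", "k_resume", "k_term", "J"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.k_stall > 0 and self.k_resume <= 0:
            raise ValueError("k_resume must be positive when stalling is on")

    @property
    def v_eff(self) -> float:
        """Effective velocity: v times the stationary growing fraction."""
        if self.k_stall == 0:
            return self.v
        return self.v * self.k_resume / (self.k_resume + self.k_stall)


@dataclass(frozen=True)
class LengthSample:
    """Ribbon contour lengths (nm) measured at one timepoint."""

    time_h: float
    lengths: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        if (lengths < 0).any():
            raise ValueError("lengths must be non-negative")
        object.__setattr__(self, "lengths", lengths)

    @property
    def n(self) -> int:
        return len(self.lengths)

    @property
    def mean(self) -> float:
        return float(self.lengths.mean())

    @property
    def sem(self) -> float:
        return float(self.lengths.std(ddof=1) / math.sqrt(self.n))


def simulate_ribbons(
    params: GrowthParams,
    times_h: Sequence[float],
    n_ribbons: int,
    rng_seed: int,
    condition: str = "",
) -> List[LengthSample]:
    """Simulate ``n_ribbons`` seeded ribbons, sampled at each time (hours).

    Each ribbon follows the continuous-time Markov dynamics above; the same
    ribbons are observed at every requested time (a longitudinal sample, as
    when a single reaction is imaged at successive times).  Reproducible for
    fixed ``rng_seed``.
    """
    times_h = list(times_h)
    if n_ribbons < 1:
        raise ValueError("n_ribbons must be >= 1")
    if any(b <= a for a, b in zip(times_h, times_h[1:])):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(rng_seed)
    times_s = np.asarray(times_h) * HOUR
    out = np.empty((len(times_s), n_ribbons))
    for i in range(n_ribbons):
        t_term = (
            rng.exponential(1.0 / params.k_term) if params.k_term > 0 else math.inf
        )
        if params.k_stall > 0:
            out[:, i] = _growing_time_profile(params, times_s, t_term, rng)
        else:
            out[:, i] = np.minimum(times_s, t_term)
    lengths = params.v * out
    return [
        LengthSample(time_h=th, lengths=lengths[j], condition=condition)
        for j, th in enumerate(times_h)
    ]


def _growing_time_profile(
    params: GrowthParams,
    times_s: np.ndarray,
    t_term: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cumulative growing time at each observation time for one ribbon."""
    ks, kr = params.k_stall, params.k_resume
    growing = rng.random() < kr / (kr + ks)
    horizon = min(float(times_s[-1]), t_term)
    t = 0.0
    grow = 0.0
    marks: List[Tuple[float, float]] = [(0.0, 0.0)]  # (time, growing time)
    while t < horizon:
        rate = ks if growing else kr
        dwell = rng.exponential(1.0 / rate)
        seg = min(dwell, horizon - t)
        if growing:
            grow += seg
        t += seg
        marks.append((t, grow))
        growing = not growing
    mt = np.array([m[0] for m in marks])
    mg = np.array([m[1] for m in marks])
    # piecewise-linear interpolation is exact: growth is linear within a state
    out = np.empty(len(times_s))
    for j, tq in enumerate(times_s):
        tq = min(float(tq), t_term)
        out[j] = np.interp(tq, mt, mg)
    return out


def analytic_mean_length(params: GrowthParams, t_h: float) -> Tuple[float, float]:
    """Exact mean and (no-stall) standard deviation of ribbon length at t.

    Mean: ``(v_eff/k_term)(1 - e^(-k_term t))``; limit ``v_eff*t`` for
    ``k_term -> 0``.  The standard deviation is exact when ``k_stall = 0``
    (length = ``v * min(t, T_term)`` with exponential ``T_term``); with
    stalling it uses the same expression with ``v_eff`` and slightly
    understates the true spread.
    """
    if t_h < 0:
        raise ValueError("t must be >= 0")
    t = t_h * HOUR
    v, k = params.v_eff, params.k_term
    if k == 0:
        return v * t, 0.0
    e = math.exp(-k * t)
    m1 = (1.0 - e) / k  # E[min(t, T)]
    m2 = 2.0 * (1.0 - e) / k**2 - 2.0 * t * e / k  # E[min(t, T)^2]
    mean = v * m1
    var = v * v * max(m2 - m1 * m1, 0.0)
    return mean, math.sqrt(var)


def _mean_model(t_s: np.ndarray, v_eff: float, k_term: float) -> np.ndarray:
    with np.errstate(over="ignore"):
        kt = k_term * t_s
        out = np.where(
            kt > 1e-12, v_eff * (1.0 - np.exp(-kt)) / np.maximum(k_term, 1e-300),
            v_eff * t_s,
        )
    return out


@dataclass(frozen=True)
class GrowthFit:
    """Fitted effective growth parameters with bootstrap confidence bands."""

    v_eff: float  # nm/s
    k_term: float  # 1/s
    ci: Dict[str, Tuple[float, float]]
    n_bootstrap: int
    J: float | None = None  # mol/L/s, only with unseeded ribbon counts


def _fit_means(
    t_s: np.ndarray, means: np.ndarray, sems: np.ndarray
) -> Tuple[float, float]:
    v0 = max(means[0] / t_s[0], 1e-9)
    k0 = 1.0 / t_s[-1]
    popt, _ = curve_fit(
        _mean_model,
        t_s,
        means,
        p0=(v0, k0),
        sigma=np.maximum(sems, 1e-9),
        absolute_sigma=True,
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=20000,
    )
    return float(popt[0]), float(popt[1])


def fit_growth_model(
    samples: Sequence[LengthSample],
    n_bootstrap: int = 200,
    rng_seed: int = 1729,
    unseeded_counts: Sequence[Tuple[float, float]] | None = None,
) -> GrowthFit:
    """Fit (v_eff, k_term) to mean length versus time.

    Weighted least squares on the per-timepoint means (weights = standard
    error of the mean); confidence intervals by case-resampling bootstrap
    within each timepoint, using the basic (reflected) interval, which
    corrects the small upward skew of the nonlinear estimates.  If
    ``unseeded_counts`` (pairs of hours, mol/L of spontaneously nucleated
    ribbons) are given, the nucleation rate ``J`` is fitted as the
    zero-intercept slope of concentration versus time.
    """
    samples = sorted(samples, key=lambda s: s.time_h)
    if len({s.time_h for s in samples}) < 3:
        raise ValueError("need at least 3 distinct timepoints")
    if all(np.all(s.lengths == 0) for s in samples):
        raise ValueError("all lengths are zero; nothing to fit")
    t_s = np.array([s.time_h for s in samples]) * HOUR
    means = np.array([s.mean for s in samples])
    sems = np.array([s.sem for s in samples])
    v_eff, k_term = _fit_means(t_s, means, sems)

    rng = np.random.default_rng(rng_seed)
    boots = []
    for _ in range(n_bootstrap):
        bm, bs = [], []
        for s in samples:
            idx = rng.integers(0, s.n, s.n)
            ls = s.lengths[idx]
            bm.append(ls.mean())
            bs.append(ls.std(ddof=1) / math.sqrt(s.n))
        try:
            boots.append(_fit_means(t_s, np.array(bm), np.array(bs)))
        except RuntimeError:  # rare non-convergence on a resample
            continue
    boots_arr = np.array(boots) if boots else np.empty((0, 2))
    ci = {}
    for i, (name, hat) in enumerate((("v_eff", v_eff), ("k_term", k_term))):
        if len(boots_arr):
            q_lo, q_hi = np.percentile(boots_arr[:, i], [2.5, 97.5])
            lo, hi = 2 * hat - q_hi, 2 * hat - q_lo  # basic bootstrap
        else:
            lo = hi = math.nan
        ci[name] = (float(lo), float(hi))

    J = None
    if unseeded_counts is not None:
        pts = np.asarray(unseeded_counts, dtype=float)
        tt = pts[:, 0] * HOUR
        cc = pts[:, 1]
        J = float((tt @ cc) / (tt @ tt))  # zero-intercept least squares
    return GrowthFit(v_eff=v_eff, k_term=k_term, ci=ci, n_bootstrap=len(boots), J=J)


def polydispersity_index(lengths: Sequence[float]) -> float:
    """PDI = weight-average over number-average length = E[L^2]/E[L]^2.

    1.0 for a monodisperse sample; 2.0 in expectation for exponentially
    distributed lengths.  Always >= 1 (Cauchy-Schwarz).
    """
    ls = np.asarray(lengths, dtype=float)
    if ls.size == 0:
        raise ValueError("lengths must be non-empty")
    if (ls < 0).any():
        raise ValueError("lengths must be non-negative")
    if not (ls > 0).any():
        raise ValueError("at least one length must be positive")
    m1 = ls.mean()
    return float((ls**2).mean() / m1**2)


def rate_constant_from_velocity(
    v_eff: float, slat_conc: float, delta: float = 1.5
) -> float:
    """Second-order on-rate (1/(M s)) from effective velocity.

    ``k_on = v_eff / (delta * slat_conc)``: each slat addition advances the
    ribbon by ``delta`` nm and consumes one monomer at ``slat_conc``.
    """
    if slat_conc <= 0:
        raise ValueError("slat_conc must be positive")
    if delta <= 0:
        raise ValueError("delta must be positive")
    return v_eff / (delta * slat_conc)


def velocity_from_rate_constant(
    k_on: float, slat_conc: float, delta: float = 1.5
) -> float:
    """Inverse of :func:`rate_constant_from_velocity`."""
    if slat_conc <= 0:
        raise ValueError("slat_conc must be positive")
    return k_on * delta * slat_conc


def ribbon_count_from_seeds(seed_conc: float, conversion_fraction: float = 1.0) -> float:
    """Ribbon molar concentration from seeds at a given conversion fraction."""
    if not 0.0 <= conversion_fraction <= 1.0:
        raise ValueError("conversion_fraction must be in [0, 1]")
    if seed_conc < 0:
        raise ValueError("seed_conc must be non-negative")
    return seed_conc * conversion_fraction
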