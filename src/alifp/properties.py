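"""Response-property measures derived from a fitted parameter set.

Seven scalar measures summarize a fiber's behaviour:

* ``dynamic_range_db``: amplitude ratio (20*log10) between 10 % and 90 %
  single-pulse spike probability;
* ``latency50_ms`` / ``jitter50_ms``: spike latency mean / sd at 50 % spike
  probability for a single pulse;
* ``refractory_ms``: time after a spike at which 1.5x the resting threshold
  can again evoke a spike;
* ``facilitation_ms``: duration of the post-failed-pulse threshold decrease;
* ``accommodation_ms``: from the threshold's first rise above rest until it
  last falls below 1.01x rest;
* ``adaptation_db``: threshold increase (dB re. rest) 10 ms after one spike.

dB conversions use 20*log10 throughout (currents and thresholds are field
quantities; a factor of 2 is about 6 dB).

``correlation_analysis`` computes the fiber-by-fiber Pearson correlation
matrix of these measures with Bonferroni-corrected significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy import optimize, stats

from .model import pulse_shape_factor, refractory_factor, subthreshold_factor
from .params import ALIFPParams

__all__ = [
    "PropertyMeasures",
    "CorrelationReport",
    "dynamic_range",
    "latency_jitter_at_50",
    "refractory_measure",
    "facilitation_duration",
    "accommodation_duration",
    "adaptation_amplitude",
    "measures_from_params",
    "critical_r",
    "correlation_analysis",
]

_Z10 = stats.norm.ppf(0.1)
_Z90 = stats.norm.ppf(0.9)


@dataclass
class PropertyMeasures:
    dynamic_range_db: float
    latency50_ms: float
    jitter50_ms: float
    refractory_ms: float
    facilitation_ms: float
    accommodation_ms: float
    adaptation_db: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


def threshold_amplitude(params: ALIFPParams, prob: float = 0.5) -> float:
    """Stimulus amplitude giving the requested single-pulse spike probability."""
    kappa = pulse_shape_factor(tau_m_us=params.tau_m_us)
    return (params.theta0 + params.s_sigma * stats.norm.ppf(prob)) / (
        params.r_m * kappa
    )


def dynamic_range(params: ALIFPParams) -> float:
    """20*log10 of the amplitude ratio between 90 % and 10 % spike probability."""
    if params.s_sigma <= 0:
        return 0.0
    a10 = params.theta0 + params.s_sigma * _Z10
    a90 = params.theta0 + params.s_sigma * _Z90
    if a10 <= 0:
        return float("inf")
    return 20.0 * math.log10(a90 / a10)


def latency_jitter_at_50(params: ALIFPParams) -> tuple[float, float]:
    """Latency and jitter at the drive giving 50 % spike probability.

    With the curve midpoints pinned to zero supra-threshold drive these are
    the logistic midpoints ``l4 + l3/2`` and ``j3/2``.
    """
    return params.l4 + params.l3 / 2.0, params.j3 / 2.0


def refractory_measure(params: ALIFPParams) -> float:
    """Time after a spike at which 1.5x the resting threshold evokes a spike.

    Root of ``refractory_factor(t) = 1.5``; the factor falls from infinity
    at the end of the absolute refractory period towards 1.
    """
    target = 1.5

    def f(dt: float) -> float:
        return refractory_factor(dt, params) - target

    lo = params.t_arp * (1 + 1e-12) + 1e-12
    hi = params.t_arp + params.tau_rrp
    if f(lo) <= 0.0:
        return params.t_arp
    for _ in range(200):
        if f(hi) < 0.0:
            break
        hi += params.tau_rrp
    else:  # pragma: no cover - factor never recovers below 1.5
        return params.t_arp
    return float(optimize.brentq(f, lo, hi, xtol=1e-9))


def _subthreshold_grid(params: ALIFPParams, dt_ms: float = 1e-3):
    horizon = max(12.0 * params.f1, 30.0 * params.f4, 5.0)
    t = np.arange(1, int(horizon / dt_ms) + 1) * dt_ms
    return t, subthreshold_factor(t, params)


def facilitation_duration(params: ALIFPParams) -> float:
    """Length of the initial interval where the sub-threshold factor is < 1."""
    if params.f2 == 0.0:
        return 0.0
    t, g = _subthreshold_grid(params)
    above = np.flatnonzero(g >= 1.0)
    if above.size == 0:
        # curve approaches 1 from below; take the point of near-complete return
        near = np.flatnonzero(g >= 1.0 - 1e-3)
        return float(t[near[0]]) if near.size else float(t[-1])
    i = above[0]
    if i == 0:
        return 0.0
    f = lambda dt: subthreshold_factor(dt, params) - 1.0
    return float(optimize.brentq(f, t[i - 1], t[i], xtol=1e-9))


def accommodation_duration(params: ALIFPParams) -> float:
    """From the first up-crossing of 1 to the last down-crossing of 1.01."""
    t, g = _subthreshold_grid(params)
    above = np.flatnonzero(g > 1.01)
    if above.size == 0:
        return 0.0
    start = facilitation_duration(params)
    i = above[-1]
    if i + 1 >= len(t):
        end = float(t[-1])
    else:
        f = lambda dt: subthreshold_factor(dt, params) - 1.01
        end = float(optimize.brentq(f, t[i], t[i + 1], xtol=1e-9))
    return max(end - start, 0.0)


def adaptation_amplitude(params: ALIFPParams) -> float:
    """Threshold increase in dB 10 ms after a single spike."""
    if params.c_a == 0.0 or params.tau_a <= 0.0:
        return 0.0
    factor = 1.0 + params.c_a * math.exp(-0.010 / params.tau_a)
    return 20.0 * math.log10(min(factor, params.a_max))


def measures_from_params(params: ALIFPParams) -> PropertyMeasures:
    lat, jit = latency_jitter_at_50(params)
    return PropertyMeasures(
        dynamic_range_db=dynamic_range(params),
        latency50_ms=lat,
        jitter50_ms=jit,
        refractory_ms=refractory_measure(params),
        facilitation_ms=facilitation_duration(params),
        accommodation_ms=accommodation_duration(params),
        adaptation_db=adaptation_amplitude(params),
    )


# ----------------------------------------------------------------------
# fiber-by-fiber correlation analysis


@dataclass
class CorrelationReport:
    names: list[str]
    r: np.ndarray
    p: np.ndarray
    alpha: float
    n_tests: int
    corrected_alpha: float
    critical_r: float
    n_fibers: int
    significant_pairs: list[tuple[str, str, float, float]]


def critical_r(alpha_two_sided: float, n: int) -> float:
    """Smallest |Pearson r| significant at the given two-sided level.

    Inverts the t transform ``t = r*sqrt(n-2)/sqrt(1-r^2)`` at the
    ``1 - alpha/2`` quantile with ``n - 2`` degrees of freedom.
    """
    if n <= 2:
        raise ValueError("need n > 2")
    t = stats.t.ppf(1.0 - alpha_two_sided / 2.0, n - 2)
    return float(t / math.sqrt(n - 2 + t * t))


def correlation_analysis(
    measures: list[PropertyMeasures],
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> CorrelationReport:
    """Pairwise Pearson correlations with Bonferroni correction.

    ``n_tests`` defaults to the number of distinct pairs (7 choose 2 = 21);
    pass it explicitly to reproduce a different correction base.
    """
    if len(measures) < 3:
        raise ValueError("need at least 3 fibers")
    mat = np.array([m.as_array() for m in measures])
    names = PropertyMeasures.names()
    k = len(names)
    if n_tests is None:
        n_tests = k * (k - 1) // 2
    corrected = alpha / n_tests
    n = mat.shape[0]

    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = mat[:, i], mat[:, j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue

    crit = critical_r(corrected, n)
    sig = [
        (names[i], names[j], float(r[i, j]), float(p[i, j]))
        for i in range(k)
        for j in range(i + 1, k)
        if np.isfinite(p[i, j]) and p[i, j] < corrected
    ]
    return CorrelationReport(
        names=names,
        r=r,
        p=p,
        alpha=alpha,
        n_tests=n_tests,
        corrected_alpha=corrected,
        critical_r=crit,
        n_fibers=n,
        significant_pairs=sig,
    )
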