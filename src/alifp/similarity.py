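"""Similarity terms between recorded and simulated responses, and their cost.

Three terms quantify how well a model trace matches a recorded condition:

* ``xcorr``: zero-lag normalized cross-correlation between windowed rate
  series of data and model over the *first part* of the response (where
  spike counts are high enough for the fine temporal structure to be
  meaningful);
* ``delta_cvs``: the modulus of the difference between the complex vector
  strengths of model and data over the whole response -- sensitive to both
  phase-locking strength and phase position, bounded by 2;
* ``delta_sqrt_rate``: the absolute difference of the square roots of the
  mean rates in the remaining (steady-state) part of the response.

The per-condition cost is ``log(r_total) * [c_x*(1-xcorr) + c_v*dcVS +
c_r*dsqrt]`` with the natural logarithm of the whole-response data rate as a
reliability weight; the total cost is the mean over conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import SpikeResponseSet
from .model import ProbabilityTrace

__all__ = [
    "WindowSpec",
    "CostWeights",
    "SimilarityBreakdown",
    "STEP_WEIGHTS",
    "window_weight",
    "first_part_end",
    "windowed_rate_data",
    "windowed_rate_model",
    "normalized_xcorr",
    "complex_vector_strength",
    "delta_cvs",
    "delta_sqrt_rate",
    "data_psth",
    "compare",
    "condition_cost",
    "total_cost",
]


@dataclass(frozen=True)
class WindowSpec:
    """Trapezoidal analysis window: linear rise, plateau, linear fall."""

    length_ms: float = 0.6
    rise_ms: float = 0.2
    plateau_ms: float = 0.2

    @property
    def step_ms(self) -> float:
        """Window stride; consecutive windows overlap by 2/3 of the length."""
        return self.length_ms / 3.0


DEFAULT_WINDOW = WindowSpec()


@dataclass(frozen=True)
class CostWeights:
    c_xcorr: float
    c_cvs: float
    c_rate: float


#: cost weights of the optimization steps that use the combined cost
STEP_WEIGHTS: dict[int, CostWeights] = {
    3: CostWeights(1.0, 0.0, 0.0),
    4: CostWeights(1.0, 0.5, 0.0),
    5: CostWeights(3.0, 0.75, 0.1),
}


@dataclass
class SimilarityBreakdown:
    xcorr: float
    delta_cvs: float
    delta_sqrt_rate: float
    first_part_end_ms: float
    r_d_total: float
    x_data: complex
    x_model: complex


def window_weight(t_ms, spec: WindowSpec = DEFAULT_WINDOW):
    """Trapezoid weight at offset ``t`` from the window start."""
    t = np.asarray(t_ms, dtype=float)
    up = spec.rise_ms
    flat_end = spec.rise_ms + spec.plateau_ms
    w = np.zeros_like(t)
    m = (t >= 0) & (t < up)
    w[m] = t[m] / up
    m = (t >= up) & (t <= flat_end)
    w[m] = 1.0
    fall = spec.length_ms - flat_end
    m = (t > flat_end) & (t < spec.length_ms)
    w[m] = (spec.length_ms - t[m]) / fall
    return w if w.shape else float(w)


def first_part_end(
    response: SpikeResponseSet,
    window_ms: float = 10.0,
    min_count: int = 10,
    min_end_ms: float = 20.0,
    max_end_ms: float = 50.0,
) -> float:
    """End of the high-rate first part of a response.

    Spikes across all repetitions are counted in non-overlapping 10 ms
    windows from t = 0; the first part ends where the count first drops
    below ``min_count``, clamped to [20, 50] ms.
    """
    max_end_ms = min(max_end_ms, response.train_duration_ms)
    spikes = response.all_spikes()
    end = 0.0
    k = 0
    while end < max_end_ms:
        lo, hi = k * window_ms, (k + 1) * window_ms
        count = int(np.sum((spikes >= lo) & (spikes < hi)))
        if count < min_count:
            break
        end = hi
        k += 1
    return float(np.clip(end, min_end_ms, max_end_ms))


def _n_windows(span_ms: float, spec: WindowSpec) -> int:
    if span_ms < spec.length_ms:
        return 0
    return int(np.floor((span_ms - spec.length_ms) / spec.step_ms + 1e-9)) + 1


def windowed_rate_data(
    response: SpikeResponseSet,
    span_ms: float,
    spec: WindowSpec = DEFAULT_WINDOW,
) -> np.ndarray:
    """Weighted spike rate (spikes/s) in overlapping windows of the data.

    ``r(i) = sum_n w(s_n - i*step) / (length * rep_count)``, windows placed
    on the step grid starting at t = 0.
    """
    if response.rep_count == 0:
        raise ValueError("response has no repetitions")
    n_win = _n_windows(span_ms, spec)
    r = np.zeros(n_win)
    spikes = response.all_spikes()
    if n_win == 0 or spikes.size == 0:
        return r
    step = spec.step_ms
    n_span = int(np.ceil(spec.length_ms / step))
    base = np.floor(spikes / step).astype(int)
    for j in range(n_span):
        i = base - j
        off = spikes - i * step
        m = (i >= 0) & (i < n_win) & (off >= 0) & (off < spec.length_ms)
        if np.any(m):
            np.add.at(r, i[m], window_weight(off[m], spec))
    return r * 1000.0 / (spec.length_ms * response.rep_count)


def windowed_rate_model(
    trace: ProbabilityTrace,
    span_ms: float,
    spec: WindowSpec = DEFAULT_WINDOW,
) -> np.ndarray:
    """Windowed rate (spikes/s) of the model trace via quadrature on its grid."""
    n_win = _n_windows(span_ms, spec)
    if n_win == 0:
        return np.zeros(0)
    dt = trace.dt_ms
    n_w = int(round(spec.length_ms / dt))
    offsets = (np.arange(n_w) + 0.5) * dt
    w_samp = window_weight(offsets, spec)
    corr = np.correlate(trace.p_inst, w_samp, mode="full")[n_w - 1 :] * dt
    stride = spec.step_ms / dt
    idx = np.round(np.arange(n_win) * stride).astype(int)
    out = np.zeros(n_win)
    valid = idx < len(corr)
    out[valid] = corr[idx[valid]]
    return out * 1000.0 / spec.length_ms


def normalized_xcorr(r_d: np.ndarray, r_m: np.ndarray) -> float:
    """Zero-lag normalized cross-correlation in [0, 1]; 0 if a series is silent."""
    r_d = np.asarray(r_d, dtype=float)
    r_m = np.asarray(r_m, dtype=float)
    if r_d.shape != r_m.shape:
        raise ValueError("rate series must have equal length")
    nd = np.sqrt(np.sum(r_d**2))
    nm = np.sqrt(np.sum(r_m**2))
    if nd == 0.0 or nm == 0.0:
        return 0.0
    return float(np.sum(r_d * r_m) / (nd * nm))


def complex_vector_strength(spike_times_ms, period_ms: float) -> complex:
    """Mean unit phasor of spike phases; the modulus is the vector strength."""
    if period_ms <= 0:
        raise ValueError("period must be positive")
    s = np.asarray(spike_times_ms, dtype=float)
    if s.size == 0:
        return 0.0 + 0.0j
    return complex(np.mean(np.exp(2j * np.pi * s / period_ms)))


def delta_cvs(x_m: complex, x_d: complex) -> float:
    """Modulus of the complex vector-strength difference, in [0, 2]."""
    return float(abs(x_m - x_d))


def _end_rate_data(response: SpikeResponseSet, end_ms: float, duration_ms: float) -> float:
    spikes = response.all_spikes()
    n = int(np.sum((spikes >= end_ms) & (spikes <= duration_ms)))
    return 1000.0 * n / ((duration_ms - end_ms) * response.rep_count)


def _end_rate_model(trace: ProbabilityTrace, end_ms: float, duration_ms: float) -> float:
    return 1000.0 * trace.mass_between(end_ms, duration_ms) / (duration_ms - end_ms)


def delta_sqrt_rate(
    response: SpikeResponseSet,
    trace: ProbabilityTrace,
    end_ms: float,
    duration_ms: float | None = None,
) -> float:
    """|sqrt(data rate) - sqrt(model rate)| over the steady-state segment."""
    dur = response.train_duration_ms if duration_ms is None else duration_ms
    if end_ms >= dur:
        raise ValueError("steady-state segment is empty")
    rd = _end_rate_data(response, end_ms, dur)
    rm = _end_rate_model(trace, end_ms, dur)
    return float(abs(math.sqrt(rd) - math.sqrt(rm)))


def data_psth(response: SpikeResponseSet, bin_ms: float = 0.1,
              t_max_ms: float | None = None) -> np.ndarray:
    """Per-bin spike probability of the data (count / repetitions)."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    t_max = (response.train_duration_ms + 5.0) if t_max_ms is None else t_max_ms
    n_bins = int(round(t_max / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(response.all_spikes(), bins=edges)
    return counts / response.rep_count


# ----------------------------------------------------------------------
# combined cost


def compare(
    response: SpikeResponseSet,
    trace: ProbabilityTrace,
    span_ms: float | None = None,
    spec: WindowSpec = DEFAULT_WINDOW,
) -> SimilarityBreakdown:
    """All three similarity terms for one condition.

    ``span_ms`` overrides the detected first-part end (it is still clamped
    to the response duration for the steady-state rate).
    """
    end = first_part_end(response) if span_ms is None else float(span_ms)
    r_d = windowed_rate_data(response, end, spec)
    r_m = windowed_rate_model(trace, end, spec)
    x_d = complex_vector_strength(response.all_spikes(), response.period_ms)
    x_m = trace.complex_vs(response.period_ms)
    dur = response.train_duration_ms
    dsr = delta_sqrt_rate(response, trace, end, dur) if end < dur else 0.0
    r_total = 1000.0 * response.n_spikes / (dur * response.rep_count)
    return SimilarityBreakdown(
        xcorr=normalized_xcorr(r_d, r_m),
        delta_cvs=delta_cvs(x_m, x_d),
        delta_sqrt_rate=dsr,
        first_part_end_ms=end,
        r_d_total=r_total,
        x_data=x_d,
        x_model=x_m,
    )


def condition_cost(breakdown: SimilarityBreakdown, weights: CostWeights) -> float:
    """Log-rate-weighted combination of the three terms for one condition.

    Conditions with a whole-response rate at or below 1 spike/s get the
    weight floor ln(2) so silent conditions neither vanish from nor flip the
    sign of the total cost.
    """
    r = breakdown.r_d_total
    w = math.log(r) if r > 1.0 else math.log(2.0)
    return w * (
        weights.c_xcorr * (1.0 - breakdown.xcorr)
        + weights.c_cvs * breakdown.delta_cvs
        + weights.c_rate * breakdown.delta_sqrt_rate
    )


def total_cost(breakdowns: list[SimilarityBreakdown], weights: CostWeights) -> float:
    """Mean per-condition cost across conditions."""
    if not breakdowns:
        raise ValueError("no conditions to score")
    return float(np.mean([condition_cost(b, weights) for b in breakdowns]))
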