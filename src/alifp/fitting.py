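"""Five-step parameter-fitting procedure for single-fiber recordings.

The steps, each constraining a subset of the parameters:

1. rate-level: membrane resistance and threshold spread from the first-pulse
   spike probability of the lowest-rate data, by bounded least squares;
2. latency/jitter: the four timing-curve parameters from first-pulse spike
   times, by bounded least squares;
3. short-term interaction (refractoriness, facilitation, accommodation) on
   the first part of all conditions, cross-correlation cost only, multi-start
   bounded derivative-free search (six archetype starting points);
4. latency/jitter refit on the same slice with the complex vector-strength
   term added (cross-correlation kept as a regularizer);
5. short-term refit plus adaptation on the full response, four amplitudes
   spread across the dynamic range.

The optimizer behind steps 3-5 is pluggable: any bounded derivative-free
minimizer with a (function, start, bounds, budget) contract works; the
default is Powell's method, which is deterministic.  Every step returns the
better of its entry and exit points, so the active-weight cost never
increases across a step.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import ndtr
from scipy.stats import norm

from .data import FiberDataset, SpikeResponseSet
from .model import pulse_shape_factor
from .params import ALIFPParams, BOUNDS
from .similarity import (
    STEP_WEIGHTS,
    CostWeights,
    SimilarityBreakdown,
    compare,
    complex_vector_strength,
    condition_cost,
    first_part_end,
    normalized_xcorr,
    windowed_rate_data,
    windowed_rate_model,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "NonIdentifiableError",
    "DEFAULT_STARTS",
    "minimize_bounded",
    "step1_rate_level",
    "step2_latency_jitter",
    "step3_short_term",
    "step4_latency_jitter_refit",
    "step5_full",
    "fit_fiber",
    "default_params_for_fiber",
    "score_fiber",
    "refit_with_perturbed_starts",
]


class NonIdentifiableError(ValueError):
    """Raised when a deterministic fitting step has no information to fit."""


_SHORT_TERM = ("f1", "f3", "t_arp", "tau_rrp", "q")
_TIMING = ("l2", "l3", "j2", "j3")
# step 5 explores its fresh dimensions (adaptation) first: the short-term
# parameters enter near their step-3 optimum, so a budget-limited
# direction-set search should spend its early sweeps on c_a and tau_a
_STEP5 = ("c_a", "tau_a") + _SHORT_TERM

#: six starting points for step 3 spanning response archetypes
#: (short/long refractoriness x weak/strong accommodation x facilitation)
DEFAULT_STARTS: tuple[dict[str, float], ...] = (
    {"f1": 0.25, "f3": 1.0, "t_arp": 0.5, "tau_rrp": 0.7, "q": 1.0},
    {"f1": 0.1, "f3": 0.1, "t_arp": 0.3, "tau_rrp": 0.3, "q": 1.0},
    {"f1": 0.1, "f3": 2.0, "t_arp": 0.3, "tau_rrp": 0.5, "q": 2.0},
    {"f1": 1.0, "f3": 0.3, "t_arp": 1.0, "tau_rrp": 2.0, "q": 1.0},
    {"f1": 2.0, "f3": 1.5, "t_arp": 2.0, "tau_rrp": 10.0, "q": 0.5},
    {"f1": 0.5, "f3": 0.5, "t_arp": 0.1, "tau_rrp": 1.0, "q": 5.0},
)


@dataclass
class FitConfig:
    """Tunables of the fitting procedure.

    Budgets are function evaluations per optimizer start.  ``scale``
    presets: "full" mirrors the study conditions, "test" is sized for quick
    recovery experiments.
    """

    rates: tuple[float, ...] = (200.0, 1000.0, 2000.0)
    base_rate: float = 200.0
    first_pulse_window_ms: float = 4.0
    step3_budget: int = 2000
    step4_budget: int = 1000
    step5_budget: int = 2000
    starts: tuple[dict[str, float], ...] = DEFAULT_STARTS
    step5_quantiles: tuple[float, ...] = (0.10, 0.37, 0.63, 0.90)
    branch_cap: int = 512
    prune_mass: float = 1e-6
    grid_dt_ms: float = 0.01
    perturb_scale: float = 0.25
    seed: int = 0

    @classmethod
    def test_scale(cls, **overrides) -> "FitConfig":
        """Reduced-budget preset for recovery experiments on synthetic data.

        The coarser 0.02 ms cost grid still oversamples the 0.2 ms analysis
        window slopes by 10x.
        """
        base = dict(
            step3_budget=120,
            step4_budget=30,
            step5_budget=220,
            branch_cap=96,
            grid_dt_ms=0.02,
        )
        base.update(overrides)
        return cls(**base)

    def digest(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class FitResult:
    params: ALIFPParams
    step_costs: dict[int, tuple[float, float]] = field(default_factory=dict)
    step3_candidate_costs: list[float] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    seed: int = 0
    config_digest: str = ""


# ----------------------------------------------------------------------
# optimizer contract

#: parameters searched on a log scale (they span >= 2 decades)
_LOG_SCALE = {"t_arp", "tau_rrp", "f3"}


class _ParamTransform:
    """Map the unit cube to parameter space (log scale where appropriate).

    Normalizing the search space makes the coordinate sweeps of a
    direction-set optimizer comparable across parameters.
    """

    def __init__(self, names: tuple[str, ...]):
        self.names = names
        self.lo = np.array([BOUNDS[n][0] for n in names])
        self.hi = np.array([BOUNDS[n][1] for n in names])
        self.log = np.array([n in _LOG_SCALE and BOUNDS[n][0] > 0 for n in names])
        self.llo = np.where(self.log, np.log10(np.maximum(self.lo, 1e-300)), self.lo)
        self.lhi = np.where(self.log, np.log10(np.maximum(self.hi, 1e-300)), self.hi)

    def to_params(self, u: np.ndarray) -> np.ndarray:
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        val = self.llo + u * (self.lhi - self.llo)
        return np.where(self.log, 10.0**val, val)

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        val = np.where(self.log, np.log10(np.clip(x, 1e-300, None)), x)
        return np.clip((val - self.llo) / (self.lhi - self.llo), 0.0, 1.0)


def minimize_bounded(fun, x0, bounds, budget: int):
    """Bounded derivative-free minimization; returns (x_best, f_best).

    Default backend: Powell's method with box bounds and an evaluation
    budget.  Never returns a point worse than the start.
    """
    x0 = np.asarray(x0, dtype=float)
    f0 = fun(x0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            fun,
            x0,
            method="Powell",
            bounds=bounds,
            options={"maxfev": int(budget), "xtol": 1e-3, "ftol": 1e-4},
        )
    if np.isfinite(res.fun) and res.fun < f0:
        return np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds]), float(res.fun)
    return x0, float(f0)


# ----------------------------------------------------------------------
# first-pulse statistics


def _first_pulse_stats(
    fiber: FiberDataset, rate: float, window_ms: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[np.ndarray]]:
    """Per-amplitude first-pulse spike probability, latency mean/sd, count."""
    responses = fiber.conditions_at(rate)
    if not responses:
        raise NonIdentifiableError(f"no {rate} pps conditions available")
    amps, probs, lat_mean, lat_sd, counts = [], [], [], [], []
    for resp in responses:
        w = min(window_ms, resp.period_ms)
        hits = 0
        times = []
        for rep in resp.spike_times_ms:
            first = rep[(rep >= 0) & (rep < w)]
            if len(first):
                hits += 1
                times.append(first[0])
        amps.append(resp.amplitude)
        probs.append(hits / resp.rep_count)
        times = np.asarray(times)
        counts.append(len(times))
        lat_mean.append(times.mean() if len(times) else np.nan)
        lat_sd.append(times.std(ddof=1) if len(times) > 1 else np.nan)
    return (
        np.asarray(amps),
        np.asarray(probs),
        np.asarray(lat_mean),
        np.asarray(lat_sd),
        np.asarray(counts),
    )


def step1_rate_level(
    fiber: FiberDataset,
    params: ALIFPParams | None = None,
    config: FitConfig | None = None,
) -> ALIFPParams:
    """Fit membrane resistance and threshold spread to the rate-level function.

    The first-pulse spike probability versus amplitude is fitted by
    ``Phi((A * r_m * kappa - theta0) / s_sigma)``.  If the resulting dynamic
    range is narrower than the amplitude spacing, the threshold spread is
    inflated afterwards to the widest value that the spacing can resolve,
    leaving the predicted rate-level points unchanged within their spacing.
    """
    params = params or ALIFPParams()
    config = config or FitConfig()
    amps, probs, *_ = _first_pulse_stats(fiber, config.base_rate, config.first_pulse_window_ms)
    if len(amps) < 3:
        raise NonIdentifiableError("need >= 3 amplitudes for the rate-level fit")
    if np.all(probs <= 0.0) or np.all(probs >= 1.0) or np.ptp(probs) == 0.0:
        raise NonIdentifiableError("first-pulse probabilities carry no slope")

    kappa = pulse_shape_factor(tau_m_us=params.tau_m_us)
    theta0 = params.theta0

    # initial guess: threshold near the 50 % crossing, spread from the 10-90 span
    order = np.argsort(amps)
    a_sorted, p_sorted = amps[order], probs[order]
    a50 = float(np.interp(0.5, np.clip(p_sorted, 0, 1), a_sorted)) if np.any(
        p_sorted >= 0.5
    ) and np.any(p_sorted <= 0.5) else float(np.median(a_sorted))
    r_m0 = theta0 / (kappa * a50)
    s0 = max(0.05 * theta0, 1e-4)

    def residuals(x):
        r_m, s_sigma = x
        return ndtr((amps * r_m * kappa - theta0) / s_sigma) - probs

    res = optimize.least_squares(
        residuals,
        x0=[r_m0, s0],
        bounds=([1e-9, 1e-6], [np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
    )
    r_m, s_sigma = res.x

    spacing = float(np.median(np.diff(np.unique(a_sorted)))) if len(a_sorted) > 1 else 0.0
    z_span = norm.ppf(0.9) - norm.ppf(0.1)
    width = z_span * s_sigma / (r_m * kappa)
    if spacing > 0 and width < spacing:
        s_sigma = spacing * r_m * kappa / z_span
    return params.replace(r_m=float(r_m), s_sigma=float(s_sigma))


def step2_latency_jitter(
    fiber: FiberDataset,
    params: ALIFPParams,
    config: FitConfig | None = None,
) -> ALIFPParams:
    """Fit the latency and jitter curves to first-pulse spike times."""
    config = config or FitConfig()
    amps, _, lat_mean, lat_sd, counts = _first_pulse_stats(
        fiber, config.base_rate, config.first_pulse_window_ms
    )
    have_lat = counts > 0
    if have_lat.sum() < 2:
        raise NonIdentifiableError("need first-pulse spikes at >= 2 amplitudes")
    if counts.sum() < 5:
        warnings.warn(
            "fewer than 5 first-pulse spikes: latency/jitter estimates are "
            "wide-uncertainty",
            stacklevel=2,
        )
    kappa = pulse_shape_factor(tau_m_us=params.tau_m_us)
    dv = amps * params.r_m * kappa - params.theta0

    from .model import jitter_curve, latency_curve  # local import avoids cycle

    w_lat = np.sqrt(counts[have_lat])
    mean_lat = float(np.average(lat_mean[have_lat], weights=counts[have_lat]))
    l3_0 = float(np.clip(2.0 * (mean_lat - params.l4), *BOUNDS["l3"]))

    def lat_res(x):
        p = params.replace(l2=x[0], l3=x[1])
        return w_lat * (latency_curve(dv[have_lat], p) - lat_mean[have_lat])

    res = optimize.least_squares(
        lat_res,
        x0=[max(params.l2, 1e-3), max(l3_0, 1e-3)],
        bounds=(
            [BOUNDS["l2"][0], BOUNDS["l3"][0]],
            [BOUNDS["l2"][1], BOUNDS["l3"][1]],
        ),
    )
    l2, l3 = res.x

    have_jit = counts > 1
    if have_jit.sum() >= 2:
        w_jit = np.sqrt(counts[have_jit])
        j3_0 = float(np.clip(2.0 * np.nanmean(lat_sd[have_jit]), 1e-3, BOUNDS["j3"][1]))

        def jit_res(x):
            p = params.replace(j2=x[0], j3=x[1])
            return w_jit * (jitter_curve(dv[have_jit], p) - lat_sd[have_jit])

        res = optimize.least_squares(
            jit_res,
            x0=[max(params.j2, 1e-3), j3_0],
            bounds=(
                [BOUNDS["j2"][0], BOUNDS["j3"][0]],
                [BOUNDS["j2"][1], BOUNDS["j3"][1]],
            ),
        )
        j2, j3 = res.x
    else:
        j2, j3 = params.j2, params.j3
        warnings.warn("not enough repeated first-pulse spikes to fit jitter", stacklevel=2)
    return params.replace(l2=float(l2), l3=float(l3), j2=float(j2), j3=float(j3))


# ----------------------------------------------------------------------
# combined-cost objective for steps 3-5


@dataclass
class _Condition:
    response: SpikeResponseSet
    span_ms: float
    full: bool  # full response (step 5) vs first-part slice (steps 3/4)
    r_d: np.ndarray
    x_d: complex
    r_total: float


def _make_train(resp: SpikeResponseSet, span: float | None):
    from .stimulus import PulseTrain

    duration = resp.train_duration_ms if span is None else min(span, resp.train_duration_ms)
    full = PulseTrain(
        rate_pps=resp.rate_pps,
        amplitude=resp.amplitude,
        effective_rate_pps=resp.effective_rate_pps,
        train_duration_ms=resp.train_duration_ms,
    )
    return full.truncated(duration) if span is not None else full


def _sliced(resp: SpikeResponseSet, span: float) -> SpikeResponseSet:
    return SpikeResponseSet(
        rate_pps=resp.rate_pps,
        amplitude=resp.amplitude,
        effective_rate_pps=resp.effective_rate_pps,
        spike_times_ms=[rep[rep < span] for rep in resp.spike_times_ms],
        train_duration_ms=resp.train_duration_ms,
    )


def _prepare_conditions(
    fiber: FiberDataset,
    rates: tuple[float, ...],
    full: bool,
    amplitudes: dict[float, np.ndarray] | None = None,
) -> list[_Condition]:
    conds: list[_Condition] = []
    for rate in rates:
        for resp in fiber.conditions_at(rate):
            if amplitudes is not None and resp.amplitude not in amplitudes.get(rate, ()):
                continue
            span = first_part_end(resp)
            dur = resp.train_duration_ms
            r_total = 1000.0 * resp.n_spikes / (dur * resp.rep_count)
            if full:
                x_d = complex_vector_strength(resp.all_spikes(), resp.period_ms)
            else:
                sliced = _sliced(resp, span)
                x_d = complex_vector_strength(sliced.all_spikes(), sliced.period_ms)
            conds.append(
                _Condition(
                    response=resp,
                    span_ms=span,
                    full=full,
                    r_d=windowed_rate_data(resp, span),
                    x_d=x_d,
                    r_total=r_total,
                )
            )
    return conds


def _cost_for_params(
    params: ALIFPParams,
    conds: list[_Condition],
    weights: CostWeights,
    config: FitConfig,
) -> float:
    from .model import simulate_bank
    from .similarity import delta_sqrt_rate

    # bank conditions sharing pulse timing (same rate) into one propagation
    groups: dict[tuple[float, float], list[_Condition]] = {}
    for c in conds:
        key = (c.response.effective_rate_pps, c.response.train_duration_ms)
        groups.setdefault(key, []).append(c)

    costs = []
    for group in groups.values():
        full = group[0].full
        span = None if full else max(c.span_ms for c in group)
        trains = [_make_train(c.response, span) for c in group]
        traces = simulate_bank(
            params,
            trains,
            branch_cap=config.branch_cap,
            prune_mass=config.prune_mass,
            grid_dt_ms=config.grid_dt_ms,
        )
        for c, trace in zip(group, traces):
            resp = c.response
            r_m = windowed_rate_model(trace, c.span_ms)
            xcorr = normalized_xcorr(c.r_d, r_m)
            t_max = None if full else c.span_ms
            dcvs = abs(trace.complex_vs(resp.period_ms, t_max_ms=t_max) - c.x_d)
            if weights.c_rate > 0 and c.span_ms < resp.train_duration_ms and full:
                dsr = delta_sqrt_rate(resp, trace, c.span_ms)
            else:
                dsr = 0.0
            b = SimilarityBreakdown(
                xcorr=xcorr,
                delta_cvs=dcvs,
                delta_sqrt_rate=dsr,
                first_part_end_ms=c.span_ms,
                r_d_total=c.r_total,
                x_data=c.x_d,
                x_model=0j,
            )
            costs.append(condition_cost(b, weights))
    return float(np.mean(costs))


def _objective(base: ALIFPParams, names, conds, weights, config):
    def fun(x):
        p = base.replace(**dict(zip(names, (float(v) for v in x))))
        if not p.facilitation_ok():
            from .params import subthreshold_first_value

            return 1e3 * (1.0 + subthreshold_first_value(p))
        return _cost_for_params(p, conds, weights, config)

    return fun


def _run_step(
    fiber: FiberDataset,
    params: ALIFPParams,
    config: FitConfig,
    names: tuple[str, ...],
    weights: CostWeights,
    full: bool,
    budget: int,
    starts: list[dict[str, float]] | None = None,
    amplitudes: dict[float, np.ndarray] | None = None,
):
    conds = _prepare_conditions(fiber, config.rates, full, amplitudes)
    if not conds:
        raise NonIdentifiableError("no conditions available for this step")
    tf = _ParamTransform(names)
    fun = _objective(params, names, conds, weights, config)
    fun_unit = lambda u: fun(tf.to_params(u))
    entry_x = np.array([getattr(params, n) for n in names])
    entry = fun(entry_x)

    candidates = []
    start_dicts = starts if starts is not None else [
        {n: getattr(params, n) for n in names}
    ]
    unit_bounds = [(0.0, 1.0)] * len(names)
    for s in start_dicts:
        u0 = tf.to_unit(np.array([s.get(n, getattr(params, n)) for n in names]))
        try:
            u, fx = minimize_bounded(fun_unit, u0, unit_bounds, budget)
            candidates.append((fx, tf.to_params(u)))
        except Exception as exc:  # pragma: no cover - optimizer failure path
            warnings.warn(f"optimizer start failed: {exc}", stacklevel=2)
    if not candidates:
        raise RuntimeError("every optimizer start failed")
    candidates.sort(key=lambda c: c[0])
    best_cost, best_x = candidates[0]
    if entry <= best_cost:
        best_cost = entry
        best_x = entry_x
    out = params.replace(**dict(zip(names, (float(v) for v in best_x))))
    return out, entry, best_cost, [c[0] for c in candidates]


def step3_short_term(
    fiber: FiberDataset, params: ALIFPParams, config: FitConfig
):
    """Multi-start fit of refractoriness/facilitation/accommodation."""
    return _run_step(
        fiber,
        params,
        config,
        _SHORT_TERM,
        STEP_WEIGHTS[3],
        full=False,
        budget=config.step3_budget,
        starts=list(config.starts),
    )


def step4_latency_jitter_refit(
    fiber: FiberDataset, params: ALIFPParams, config: FitConfig
):
    """Refine the timing curves with the vector-strength term added."""
    return _run_step(
        fiber,
        params,
        config,
        _TIMING,
        STEP_WEIGHTS[4],
        full=False,
        budget=config.step4_budget,
    )


def _step5_amplitudes(
    fiber: FiberDataset, params: ALIFPParams, config: FitConfig
) -> dict[float, np.ndarray]:
    from .properties import threshold_amplitude

    targets = np.array([threshold_amplitude(params, q) for q in config.step5_quantiles])
    chosen: dict[float, np.ndarray] = {}
    for rate in config.rates:
        avail = fiber.amplitudes_at(rate)
        if len(avail) == 0:
            continue
        picks: list[float] = []
        for t in targets:
            order = np.argsort(np.abs(avail - t))
            for i in order:
                if avail[i] not in picks:
                    picks.append(float(avail[i]))
                    break
        chosen[rate] = np.array(sorted(picks))
    return chosen


def step5_full(fiber: FiberDataset, params: ALIFPParams, config: FitConfig):
    """Joint refit of short-term interaction and adaptation on full responses."""
    defaults = ALIFPParams()
    start = {n: getattr(params, n) for n in _SHORT_TERM}
    start.update({"c_a": defaults.c_a, "tau_a": defaults.tau_a})
    params5 = params.replace(c_a=defaults.c_a, tau_a=defaults.tau_a)
    return _run_step(
        fiber,
        params5,
        config,
        _STEP5,
        STEP_WEIGHTS[5],
        full=True,
        budget=config.step5_budget,
        starts=[start],
        amplitudes=_step5_amplitudes(fiber, params, config),
    )


def fit_fiber(fiber: FiberDataset, config: FitConfig | None = None) -> FitResult:
    """Run the whole five-step procedure on one fiber."""
    config = config or FitConfig()
    result = FitResult(params=ALIFPParams(), seed=config.seed, config_digest=config.digest())

    params = step1_rate_level(fiber, ALIFPParams(), config)
    params = step2_latency_jitter(fiber, params, config)

    params, e3, x3, cand3 = step3_short_term(fiber, params, config)
    result.step_costs[3] = (e3, x3)
    result.step3_candidate_costs = cand3

    params, e4, x4, _ = step4_latency_jitter_refit(fiber, params, config)
    result.step_costs[4] = (e4, x4)

    params, e5, x5, _ = step5_full(fiber, params, config)
    result.step_costs[5] = (e5, x5)

    params.validate()
    result.params = params
    return result


def default_params_for_fiber(
    fiber: FiberDataset, config: FitConfig | None = None
) -> ALIFPParams:
    """Baseline: model defaults with only the rate-level parameters adapted.

    Mirrors the comparison baseline in which only the membrane resistance and
    threshold spread are adjusted so the default model responds over the
    fiber's amplitude range.
    """
    return step1_rate_level(fiber, ALIFPParams(), config or FitConfig())


def score_fiber(
    fiber: FiberDataset,
    params: ALIFPParams,
    rates: tuple[float, ...] | None = None,
    branch_cap: int = 512,
) -> dict[float, list[SimilarityBreakdown]]:
    """Similarity breakdowns per rate across all amplitudes of a fiber."""
    from .model import simulate_bank

    rates = rates or tuple(fiber.rates)
    out: dict[float, list[SimilarityBreakdown]] = {}
    for rate in rates:
        responses = fiber.conditions_at(rate)
        if not responses:
            out[rate] = []
            continue
        trains = [_make_train(resp, None) for resp in responses]
        traces = simulate_bank(params, trains, branch_cap=branch_cap)
        out[rate] = [compare(resp, trace) for resp, trace in zip(responses, traces)]
    return out


def refit_with_perturbed_starts(
    fiber: FiberDataset,
    config: FitConfig,
    n_refits: int = 20,
    seed: int = 0,
) -> list[FitResult]:
    """Parameter-certainty protocol: refit with randomly shifted starts.

    A random vector (uniform, +-``perturb_scale`` of each bound range) is
    added to each of the six step-3 starting points, drawn anew per refit;
    steps 1-2 are deterministic and shared.
    """
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_refits):
        starts = []
        for s in config.starts:
            shifted = dict(s)
            for n in _SHORT_TERM:
                lo, hi = BOUNDS[n]
                delta = rng.uniform(-1, 1) * config.perturb_scale * (hi - lo)
                shifted[n] = float(np.clip(s[n] + delta, lo, hi))
            starts.append(shifted)
        cfg = FitConfig(**{**config.__dict__, "starts": tuple(starts)})
        results.append(fit_fiber(fiber, cfg))
    return results
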