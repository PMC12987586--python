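"""Deterministic aLIFP simulator and its stochastic twin.

The model turns a biphasic pulse train into an instantaneous spike
probability over time.  Each pulse depolarizes a leaky-integrator membrane
by ``amplitude * r_m * kappa`` mV, where ``kappa`` is the peak of the
membrane response to a unit-amplitude biphasic pulse.  The spike probability
of a pulse is the probability that this drive exceeds a Gaussian threshold
whose mean is the resting threshold multiplied by history-dependent factors:

* refractoriness after a spike (absolute period ``t_arp``, then a relative
  period decaying with ``tau_rrp``/``q``),
* facilitation then accommodation after a sub-threshold pulse,
* a slow cumulative adaptation after every spike.

Because a pulse may or may not evoke a spike, both futures are propagated as
weighted branches ("branching simulation"); the model output is the
probability-weighted mixture of per-pulse Gaussian spike-time components,
which can be multimodal.  Threshold spread scales with the effective
threshold (relative spread), so every modulation factor raises mean and
spread together and the single-pulse probability keeps its shape.

``sample_spikes`` is the stochastic twin: it draws a threshold per pulse and
a spike time per spike instead of propagating the distribution, and is used
to generate synthetic recordings.  For history bookkeeping both routes use
the mean spike time of the evoking pulse, so the twin's marginal statistics
match the deterministic trace up to Monte-Carlo error.

``simulate_bank`` propagates several trains that share the same pulse
timing (e.g. all amplitudes of one rate) in a single pass; the branch
populations of the different conditions are carried side by side and never
interact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtr

from .data import SpikeResponseSet
from .params import ALIFPParams
from .stimulus import PulseTrain

__all__ = [
    "pulse_shape_factor",
    "pulse_drive",
    "single_pulse_prob",
    "latency_curve",
    "jitter_curve",
    "refractory_factor",
    "subthreshold_factor",
    "adaptation_factor",
    "ProbabilityTrace",
    "simulate",
    "simulate_bank",
    "sample_spikes",
]

#: simulation grid step, 10x finer than the 0.1 ms analysis bin
GRID_DT_MS = 0.01
#: latency tail kept after the last pulse / train end
TAIL_MS = 5.0
#: padding value marking "no event" slots in history matrices; old enough
#: that every history factor evaluates to exactly 1
_NO_EVENT = -1.0e12
#: smallest spike-time spread used when depositing components on the grid
_SD_FLOOR = 1.0e-4


# ----------------------------------------------------------------------
# membrane drive


def pulse_shape_factor(
    phase_duration_us: float = 25.0,
    interphase_gap_us: float = 8.0,
    tau_m_us: float = 100.0,
) -> float:
    """Peak depolarization of the leaky integrator for a unit biphasic pulse.

    The membrane kernel is a first-order low-pass with time constant
    ``tau_m``; for a cathodic-first pulse the depolarization peaks at the end
    of the first phase, giving ``1 - exp(-phase/tau_m)``.  The gap and the
    anodic phase only pull the potential back down.
    """
    return 1.0 - math.exp(-phase_duration_us / tau_m_us)


def pulse_drive(params: ALIFPParams, train: PulseTrain) -> np.ndarray:
    """Per-pulse peak depolarization in mV (linear in amplitude)."""
    kappa = pulse_shape_factor(
        train.phase_duration_us, train.interphase_gap_us, params.tau_m_us
    )
    v = train.amplitude * params.r_m * kappa
    return np.full(train.n_pulses, v)


def single_pulse_prob(v: float, theta_eff: float, s_sigma_eff: float):
    """Probability that drive ``v`` exceeds a N(theta_eff, s_sigma_eff) threshold."""
    if np.any(np.asarray(s_sigma_eff) <= 0):
        raise ValueError("s_sigma_eff must be positive")
    return ndtr((np.asarray(v, dtype=float) - theta_eff) / s_sigma_eff)


# ----------------------------------------------------------------------
# threshold-modulation and spike-timing curves


def _falling_logistic(dv, x0: float, scale: float):
    """logistic(-(dv - x0)/scale), with the step-function limit at scale = 0."""
    dv = np.asarray(dv, dtype=float)
    if scale <= 0.0:
        return np.where(dv > x0, 0.0, np.where(dv < x0, 1.0, 0.5))
    return expit(-(dv - x0) / scale)


def latency_curve(dv, params: ALIFPParams):
    """Mean pulse-to-spike delay (ms) as a function of supra-threshold drive.

    Falls from ``l4 + l3`` far below threshold to ``l4`` far above; at the
    50 % spike-probability point (dv = 0 with l1 = 0) it equals
    ``l4 + l3/2``.
    """
    return params.l4 + params.l3 * _falling_logistic(dv, params.l1, params.l2)


def jitter_curve(dv, params: ALIFPParams):
    """Spike-time standard deviation (ms); ``j3/2`` at 50 % spike probability."""
    return params.j3 * _falling_logistic(dv, params.j1, params.j2)


def refractory_factor(dt_since_spike, params: ALIFPParams):
    """Threshold multiplier after a spike.

    Infinite during the absolute refractory period, then
    ``[1 - exp(-((dt - t_arp)/tau_rrp)^q)]^(-p)`` decaying to 1.
    """
    dt = np.asarray(dt_since_spike, dtype=float)
    out = np.full(dt.shape, np.inf)
    m = dt >= params.t_arp
    with np.errstate(divide="ignore", over="ignore"):
        u = ((dt[m] - params.t_arp) / params.tau_rrp) ** params.q
        out[m] = (1.0 - np.exp(-u)) ** (-params.p)
    return out if out.shape else float(out)


def subthreshold_factor(dt_since_failed_pulse, params: ALIFPParams):
    """Threshold multiplier after a pulse that failed to evoke a spike.

    Starts below 1 (facilitation), rises above 1 (accommodation, an
    alpha-function lobe scaled by ``f3 * f5``), and returns to 1.
    """
    dt = np.asarray(dt_since_failed_pulse, dtype=float)
    if params.f1 > 0.0:
        fac = params.f2 * np.exp(-dt / params.f1)
    else:
        fac = np.where(dt > 0, 0.0, params.f2)
    x = dt / params.f4
    with np.errstate(over="ignore", invalid="ignore"):
        acc = params.f3 * params.f5 * x * np.exp(-x)
    acc = np.where(x > 700.0, 0.0, acc)
    out = 1.0 - fac + acc
    return out if out.shape else float(out)


def adaptation_factor(spike_times_ms, t_ms: float, params: ALIFPParams) -> float:
    """Cumulative threshold multiplier from past spikes, capped at ``a_max``."""
    ts = np.asarray(spike_times_ms, dtype=float)
    if ts.size == 0 or params.c_a == 0.0:
        return 1.0
    tau_ms = params.tau_a * 1000.0
    if tau_ms <= 0.0:
        return 1.0
    prod = np.prod(1.0 + params.c_a * np.exp(-(t_ms - ts) / tau_ms))
    return float(min(prod, params.a_max))


# ----------------------------------------------------------------------
# probability trace


@dataclass
class ProbabilityTrace:
    """Instantaneous spike probability over time with per-pulse components.

    ``p_inst`` is a probability density per ms on a uniform grid;
    ``per_pulse_components`` holds, for each pulse, the Gaussian spike-time
    mixture (weights, means in ms, standard deviations in ms) it evoked.
    """

    dt_ms: float
    t_ms: np.ndarray
    p_inst: np.ndarray
    per_pulse_components: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    per_pulse_total_prob: np.ndarray
    pulse_onsets_ms: np.ndarray
    duration_ms: float
    period_ms: float

    @property
    def expected_spikes(self) -> float:
        """Expected spike count per repetition."""
        return float(self.per_pulse_total_prob.sum())

    def mass_between(self, t0_ms: float, t1_ms: float) -> float:
        """Expected spikes with spike time in [t0, t1), from the components."""
        total = 0.0
        for w, mu, sd in self.per_pulse_components:
            if w.size == 0:
                continue
            sd = np.maximum(sd, _SD_FLOOR)
            total += float(np.sum(w * (ndtr((t1_ms - mu) / sd) - ndtr((t0_ms - mu) / sd))))
        return total

    def psth(self, bin_ms: float = 0.1) -> np.ndarray:
        """Per-bin expected spike probability on [0, duration + tail)."""
        if bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        n_per = int(round(bin_ms / self.dt_ms))
        if abs(n_per * self.dt_ms - bin_ms) > 1e-9:
            raise ValueError("bin_ms must be a multiple of the grid step")
        cell_mass = self.p_inst * self.dt_ms
        n_bins = len(cell_mass) // n_per
        return cell_mass[: n_bins * n_per].reshape(n_bins, n_per).sum(axis=1)

    def complex_vs(
        self, period_ms: float | None = None, t_max_ms: float | None = None
    ) -> complex:
        """Probability-weighted complex vector strength of the trace."""
        T = self.period_ms if period_ms is None else period_ms
        mass = self.p_inst * self.dt_ms
        if t_max_ms is not None:
            n = int(round(t_max_ms / self.dt_ms))
            mass = mass[:n]
        total = mass.sum()
        if total <= 0:
            return 0.0 + 0.0j
        centers = self.t_ms[: len(mass)] + 0.5 * self.dt_ms
        phase = np.exp(2j * np.pi * centers / T)
        return complex(np.sum(mass * phase) / total)


# ----------------------------------------------------------------------
# history horizons (events older than these contribute < ~1e-9)


def _subthreshold_horizon_ms(params: ALIFPParams) -> float:
    h_fac = params.f1 * math.log(max(params.f2, 1e-12) * 1e9) if params.f1 > 0 else 0.0
    h_acc = 30.0 * params.f4 if params.f3 * params.f5 > 0 else 0.0
    return max(h_fac, h_acc, 1.0)


def _adaptation_horizon_ms(params: ALIFPParams) -> float:
    if params.c_a <= 0.0 or params.tau_a <= 0.0:
        return 0.0
    return params.tau_a * 1000.0 * math.log(params.c_a * 1e9 + math.e)


class _History:
    """Fixed-horizon matrix of past event times, one row per branch."""

    def __init__(self, n_rows: int, horizon_ms: float):
        self.mat = np.full((n_rows, 0), _NO_EVENT)
        self.col_times: list[float] = []
        self.horizon = horizon_ms

    def append(self, col: np.ndarray, t_now: float) -> None:
        keep = 0
        ct = self.col_times
        while keep < len(ct) and t_now - ct[keep] > self.horizon:
            keep += 1
        if keep:
            self.mat = self.mat[:, keep:]
            del ct[:keep]
        ct.append(t_now)
        self.mat = np.concatenate([self.mat, col[:, None]], axis=1)


# ----------------------------------------------------------------------
# deterministic branching simulation


def _merge_to_cap(mass, last_spike, cap):
    """Indices to keep and merged masses for one over-cap system.

    The lowest-mass branches are merged into their neighbour in
    last-spike-time order; the kept neighbour's state is retained.
    """
    order = np.argsort(last_spike, kind="stable")
    m_sorted = mass[order]
    n_drop = len(mass) - cap
    drop_pos = np.argpartition(m_sorted, n_drop)[:n_drop]
    kept = np.ones(len(m_sorted), dtype=bool)
    kept[drop_pos] = False
    if not kept[0]:
        first = int(np.argmax(kept))
        kept[0], kept[first] = True, False
    idx = np.arange(len(m_sorted))
    target = np.maximum.accumulate(np.where(kept, idx, -1))
    acc = np.zeros(len(m_sorted))
    np.add.at(acc, target, m_sorted)
    return order[kept], acc[kept]


def _propagate(
    params: ALIFPParams,
    onsets: np.ndarray,
    v_sys: np.ndarray,
    branch_cap: int,
    prune_mass: float,
):
    """Run the branching process for ``len(v_sys)`` independent conditions
    sharing the same pulse onsets.

    Returns per-pulse component tuples ``(sysid, weight, mean, sd)`` and the
    per-pulse total spike probability per system.
    """
    n_sys = len(v_sys)
    n_pulses = len(onsets)
    th0 = params.theta0
    s_rel = params.s_sigma / th0
    t_arp, tau_rrp, q, pw = params.t_arp, params.tau_rrp, params.q, params.p
    f1, f2, f3, f4, f5 = params.f1, params.f2, params.f3, params.f4, params.f5
    l1, l2, l3, l4 = params.l1, params.l2, params.l3, params.l4
    j1, j2, j3 = params.j1, params.j2, params.j3
    c_a = params.c_a
    tau_a_ms = params.tau_a * 1000.0
    use_adapt = c_a > 0.0 and tau_a_ms > 0.0

    sysid = np.arange(n_sys)
    mass = np.ones(n_sys)
    last_spike = np.full(n_sys, _NO_EVENT)
    spikes = _History(n_sys, _adaptation_horizon_ms(params))
    failed = _History(n_sys, _subthreshold_horizon_ms(params))

    comps: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    pulse_prob = np.zeros((n_pulses, n_sys))

    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        for k in range(n_pulses):
            t = float(onsets[k])
            v = v_sys[sysid]

            dts = t - last_spike
            u = (np.maximum(dts - t_arp, 0.0) / tau_rrp) ** q
            rho = (1.0 - np.exp(-u)) ** (-pw)  # inf at/inside the ARP

            if failed.mat.shape[1]:
                dtf = t - failed.mat  # padding -> huge dt -> factor exactly 1
                if f1 > 0.0:
                    fac = f2 * np.exp(-dtf / f1)
                else:
                    fac = 0.0
                x = dtf / f4
                g = np.prod(1.0 - fac + f3 * f5 * x * np.exp(-x), axis=1)
            else:
                g = 1.0

            if use_adapt and spikes.mat.shape[1]:
                a = np.prod(1.0 + c_a * np.exp(-(t - spikes.mat) / tau_a_ms), axis=1)
                adapt = np.minimum(a, params.a_max)
            else:
                adapt = 1.0

            theta = th0 * rho * g * adapt
            prob = ndtr((v - theta) / (s_rel * theta))
            blocked = dts < t_arp
            prob[blocked] = 0.0  # absolute refractory period (also clears NaN)

            dv = v - theta
            lat = l4 + (l3 * _falling_logistic(dv, l1, l2) if l3 != 0.0 else 0.0)
            jit = j3 * _falling_logistic(dv, j1, j2) if j3 != 0.0 else np.zeros_like(dv)
            mu = t + lat

            w = mass * prob
            sel = w > 0.0
            comps.append(
                (sysid[sel], w[sel], np.broadcast_to(mu, w.shape)[sel].copy(),
                 np.broadcast_to(jit, w.shape)[sel].copy())
            )
            np.add.at(pulse_prob[k], sysid, w)

            # children
            s_mask = sel
            n_mask = prob < 1.0
            spikes.append(np.where(s_mask, mu, _NO_EVENT), t)
            failed.append(np.full(len(mass), t), t)

            sp_rows = np.flatnonzero(s_mask)
            ns_rows = np.flatnonzero(n_mask)
            new_mass = np.concatenate([w[sp_rows], (mass * (1.0 - prob))[ns_rows]])
            new_last = np.concatenate([mu[sp_rows], last_spike[ns_rows]])
            new_sysid = np.concatenate([sysid[sp_rows], sysid[ns_rows]])
            sp_spk = spikes.mat[sp_rows]
            ns_spk = spikes.mat[ns_rows].copy()
            ns_spk[:, -1] = _NO_EVENT
            spikes.mat = np.concatenate([sp_spk, ns_spk], axis=0)
            n_cols_f = failed.mat.shape[1]
            failed.mat = np.concatenate(
                [np.full((len(sp_rows), n_cols_f), _NO_EVENT), failed.mat[ns_rows]],
                axis=0,
            )

            # prune per system, conserving per-system mass
            total = np.zeros(n_sys)
            np.add.at(total, new_sysid, new_mass)
            keep = new_mass >= prune_mass * total[new_sysid]
            if not np.all(keep):
                new_mass = new_mass[keep]
                new_last = new_last[keep]
                new_sysid = new_sysid[keep]
                spikes.mat = spikes.mat[keep]
                failed.mat = failed.mat[keep]
                kept_total = np.zeros(n_sys)
                np.add.at(kept_total, new_sysid, new_mass)
                scale = np.where(kept_total > 0, total / np.maximum(kept_total, 1e-300), 1.0)
                new_mass = new_mass * scale[new_sysid]

            # cap per system
            counts = np.bincount(new_sysid, minlength=n_sys)
            if counts.max() > branch_cap:
                keep_rows = []
                merged_mass = []
                for s in range(n_sys):
                    rows = np.flatnonzero(new_sysid == s)
                    if len(rows) <= branch_cap:
                        keep_rows.append(rows)
                        merged_mass.append(new_mass[rows])
                    else:
                        sub_keep, sub_mass = _merge_to_cap(
                            new_mass[rows], new_last[rows], branch_cap
                        )
                        keep_rows.append(rows[sub_keep])
                        merged_mass.append(sub_mass)
                rows = np.concatenate(keep_rows)
                new_mass = np.concatenate(merged_mass)
                new_last = new_last[rows]
                new_sysid = new_sysid[rows]
                spikes.mat = spikes.mat[rows]
                failed.mat = failed.mat[rows]

            mass, last_spike, sysid = new_mass, new_last, new_sysid

    return comps, pulse_prob


def simulate_bank(
    params: ALIFPParams,
    trains: list[PulseTrain],
    *,
    branch_cap: int = 512,
    prune_mass: float = 1e-6,
    grid_dt_ms: float = GRID_DT_MS,
    tail_ms: float = TAIL_MS,
) -> list[ProbabilityTrace]:
    """Simulate several trains that share pulse timing in one pass."""
    if not trains:
        return []
    ref = trains[0]
    onsets = np.asarray(ref.pulse_onsets_ms, dtype=float)
    for tr in trains[1:]:
        if len(tr.pulse_onsets_ms) != len(onsets) or not np.allclose(
            tr.pulse_onsets_ms, onsets
        ):
            raise ValueError("banked trains must share pulse onsets")
    kappa = pulse_shape_factor(
        ref.phase_duration_us, ref.interphase_gap_us, params.tau_m_us
    )
    v_sys = np.array([tr.amplitude * params.r_m * kappa for tr in trains])
    comps, pulse_prob = _propagate(params, onsets, v_sys, branch_cap, prune_mass)

    span = ref.train_duration_ms + tail_ms
    n_cells = int(round(span / grid_dt_ms))
    grids = _deposit(comps, len(trains), n_cells, grid_dt_ms)

    traces = []
    for s, tr in enumerate(trains):
        per_pulse = [
            (w[sid == s], mu[sid == s], sd[sid == s]) for sid, w, mu, sd in comps
        ]
        traces.append(
            ProbabilityTrace(
                dt_ms=grid_dt_ms,
                t_ms=np.arange(n_cells) * grid_dt_ms,
                p_inst=grids[s] / grid_dt_ms,
                per_pulse_components=per_pulse,
                per_pulse_total_prob=pulse_prob[:, s].copy(),
                pulse_onsets_ms=onsets,
                duration_ms=tr.train_duration_ms,
                period_ms=tr.period_ms,
            )
        )
    return traces


def simulate(
    params: ALIFPParams,
    train: PulseTrain,
    *,
    branch_cap: int = 512,
    prune_mass: float = 1e-6,
    grid_dt_ms: float = GRID_DT_MS,
    tail_ms: float = TAIL_MS,
) -> ProbabilityTrace:
    """Propagate the spike/no-spike branching process over a pulse train.

    Branches with probability mass below ``prune_mass`` are dropped (mass
    renormalized); if more than ``branch_cap`` branches survive a pulse, the
    lowest-mass branches are merged into their nearest neighbour in
    last-spike-time order.
    """
    return simulate_bank(
        params,
        [train],
        branch_cap=branch_cap,
        prune_mass=prune_mass,
        grid_dt_ms=grid_dt_ms,
        tail_ms=tail_ms,
    )[0]


def _deposit(comps, n_sys: int, n_cells: int, dt: float) -> np.ndarray:
    """Gaussian components -> per-system grid of per-cell probability mass.

    Exact per cell (CDF differences).  Components are first compacted by
    rounding mean and sd to the grid, then deposited bucket-by-bucket in sd
    so each bucket has a fixed stencil width.
    """
    if comps:
        sid = np.concatenate([c[0] for c in comps])
        w = np.concatenate([c[1] for c in comps])
        mu = np.concatenate([c[2] for c in comps])
        sd = np.maximum(np.concatenate([c[3] for c in comps]), _SD_FLOOR)
    else:
        sid = np.zeros(0, dtype=int)
        w = mu = sd = np.zeros(0)
    grids = np.zeros((n_sys, n_cells))
    if len(w) == 0:
        return grids

    mu_i = np.round(mu / dt).astype(np.int64)
    sd_i = np.maximum(np.round(sd / dt).astype(np.int64), 0)
    key = (sid.astype(np.int64) * 2_000_003 + mu_i) * 4003 + sd_i
    uniq, inv = np.unique(key, return_inverse=True)
    cw = np.zeros(len(uniq))
    cmu = np.zeros(len(uniq))
    csd = np.zeros(len(uniq))
    csid = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(cw, inv, w)
    np.add.at(cmu, inv, w * mu)
    np.add.at(csd, inv, w * sd)
    csid[inv] = sid
    cmu /= cw
    csd /= cw

    flat = grids.reshape(-1)
    csd_i = np.round(csd / dt).astype(np.int64)
    for b in np.unique(csd_i):
        m = csd_i == b
        bmu, bsd, bw, bsid = cmu[m], csd[m], cw[m], csid[m]
        h = int(6 * max(b, 1)) + 1
        lo = np.floor(bmu / dt).astype(np.int64) - h
        offs = np.arange(2 * h + 2)
        edges = (lo[:, None] + offs[None, :]) * dt
        cdf = ndtr((edges - bmu[:, None]) / bsd[:, None])
        masses = bw[:, None] * np.diff(cdf, axis=1)
        # tails beyond the stencil and the grid are clipped into the edge
        # cells, mirroring how sampled spike times are clipped into range
        masses[:, 0] += bw * cdf[:, 0]
        masses[:, -1] += bw * (1.0 - cdf[:, -1])
        cells = np.clip(lo[:, None] + offs[None, :-1], 0, n_cells - 1)
        idx = bsid[:, None] * n_cells + cells
        np.add.at(flat, idx, masses)
    return grids


# ----------------------------------------------------------------------
# stochastic twin


def sample_spikes(
    params: ALIFPParams,
    train: PulseTrain,
    n_repetitions: int,
    seed: int | np.random.Generator = 0,
) -> SpikeResponseSet:
    """Draw spike trains from the model (threshold drawn per pulse).

    Vectorized over repetitions; reproducible under a fixed seed.  Spike
    times are drawn from the per-pulse Gaussian (mean latency, sd jitter);
    history bookkeeping uses the mean spike time, matching the deterministic
    branch propagation.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    onsets = np.asarray(train.pulse_onsets_ms, dtype=float)
    v = float(pulse_drive(params, train)[0]) if train.n_pulses else 0.0
    tau_a_ms = params.tau_a * 1000.0
    use_adapt = params.c_a > 0.0 and tau_a_ms > 0.0
    th0 = params.theta0
    s_rel = params.s_sigma / th0
    R = n_repetitions

    last_spike = np.full(R, _NO_EVENT)
    spikes_hist = _History(R, _adaptation_horizon_ms(params))
    failed_hist = _History(R, _subthreshold_horizon_ms(params))
    out_times: list[list[float]] = [[] for _ in range(R)]

    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        for k in range(len(onsets)):
            t = float(onsets[k])
            dts = t - last_spike
            u = (np.maximum(dts - params.t_arp, 0.0) / params.tau_rrp) ** params.q
            rho = (1.0 - np.exp(-u)) ** (-params.p)

            if failed_hist.mat.shape[1]:
                dtf = t - failed_hist.mat
                if params.f1 > 0.0:
                    fac = params.f2 * np.exp(-dtf / params.f1)
                else:
                    fac = 0.0
                x = dtf / params.f4
                g = np.prod(1.0 - fac + params.f3 * params.f5 * x * np.exp(-x), axis=1)
            else:
                g = 1.0

            if use_adapt and spikes_hist.mat.shape[1]:
                a = np.prod(
                    1.0 + params.c_a * np.exp(-(t - spikes_hist.mat) / tau_a_ms), axis=1
                )
                adapt = np.minimum(a, params.a_max)
            else:
                adapt = 1.0

            theta = th0 * rho * g * adapt
            can = dts >= params.t_arp
            thr = rng.normal(theta, s_rel * np.abs(theta))
            spike = can & (v > thr)

            dv = v - theta
            lat = np.asarray(latency_curve(dv, params), dtype=float)
            jit = np.asarray(jitter_curve(dv, params), dtype=float)
            mu = t + lat
            drawn = rng.normal(mu, np.maximum(jit, 0.0))
            for r in np.flatnonzero(spike):
                out_times[r].append(float(drawn[r]))

            last_spike = np.where(spike, mu, last_spike)
            spikes_hist.append(np.where(spike, mu, _NO_EVENT), t)
            failed_hist.append(np.full(R, t), t)
            failed_hist.mat[spike] = _NO_EVENT

    limit = train.train_duration_ms + TAIL_MS
    reps = [np.sort(np.clip(np.asarray(ts), 0.0, limit)) for ts in out_times]
    return SpikeResponseSet(
        rate_pps=train.rate_pps,
        amplitude=train.amplitude,
        effective_rate_pps=train.effective_rate_pps,
        spike_times_ms=reps,
        train_duration_ms=train.train_duration_ms,
    )
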