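"""The five-step fitting procedure on constructed and synthetic data."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from alifp import ALIFPParams, build_pulse_train, sample_spikes
from alifp.data import FiberDataset, SpikeResponseSet
from alifp.fitting import (
    DEFAULT_STARTS,
    FitConfig,
    NonIdentifiableError,
    _ParamTransform,
    fit_fiber,
    minimize_bounded,
    refit_with_perturbed_starts,
    step1_rate_level,
    step2_latency_jitter,
    step3_short_term,
    step4_latency_jitter_refit,
    step5_full,
)
from alifp.model import jitter_curve, latency_curve, pulse_shape_factor, single_pulse_prob
from alifp.params import BOUNDS


def _rate_level_fiber(
    r_m: float, s_sigma: float, amplitudes: np.ndarray, reps: int = 400
) -> FiberDataset:
    """Fiber whose first-pulse response realizes the rate-level curve exactly
    (up to count rounding)."""
    kappa = pulse_shape_factor()
    fiber = FiberDataset(fiber_id="RL-000")
    for amp in amplitudes:
        p = float(single_pulse_prob(amp * r_m * kappa, 1.0, s_sigma))
        n_hit = int(round(p * reps))
        spikes = [[0.7]] * n_hit + [[]] * (reps - n_hit)
        fiber.add(
            SpikeResponseSet(rate_pps=200.0, amplitude=float(amp), spike_times_ms=spikes)
        )
    return fiber


class TestStep1:
    def test_noiseless_recovery(self):
        amps = np.arange(4.2, 4.95, 0.1)
        fiber = _rate_level_fiber(1.0, 0.05, amps)
        p = step1_rate_level(fiber)
        assert p.r_m == pytest.approx(1.0, rel=0.01)
        assert p.s_sigma == pytest.approx(0.05, rel=0.01)

    def test_scale_equivariance(self):
        amps = np.arange(4.2, 4.95, 0.1)
        p1 = step1_rate_level(_rate_level_fiber(1.0, 0.05, amps))
        p2 = step1_rate_level(_rate_level_fiber(0.5, 0.05, 2 * amps))
        assert p2.r_m == pytest.approx(p1.r_m / 2.0, rel=0.01)

    def test_degenerate_probabilities_flagged(self):
        fiber = FiberDataset(fiber_id="D-000")
        for amp in (1.0, 2.0, 3.0):
            fiber.add(
                SpikeResponseSet(
                    rate_pps=200.0, amplitude=amp, spike_times_ms=[[0.7], []]
                )
            )
        with pytest.raises(NonIdentifiableError):
            step1_rate_level(fiber)

    def test_spread_inflated_to_amplitude_spacing(self):
        # three widely spaced amplitudes around a narrow threshold: the
        # spacing cannot resolve the true spread, so it is widened to it
        fiber = _rate_level_fiber(1.0, 0.01, np.array([3.0, 4.5, 6.0]))
        p = step1_rate_level(fiber)
        kappa = pulse_shape_factor()
        from scipy.stats import norm

        width = (norm.ppf(0.9) - norm.ppf(0.1)) * p.s_sigma / (p.r_m * kappa)
        assert width == pytest.approx(1.5, rel=1e-6)


def _timing_fiber(true: ALIFPParams, amplitudes: np.ndarray) -> FiberDataset:
    """First-pulse spike times with exactly the curve's mean and sd."""
    kappa = pulse_shape_factor()
    z = np.array([-1.2, -np.sqrt(0.06), np.sqrt(0.06), 1.2])  # mean 0, sd 1 (ddof=1)
    fiber = FiberDataset(fiber_id="TM-000")
    for amp in amplitudes:
        dv = amp * true.r_m * kappa - true.theta0
        mu = float(latency_curve(dv, true))
        sd = float(jitter_curve(dv, true))
        times = [[float(mu + sd * zz)] for zz in z]
        fiber.add(
            SpikeResponseSet(rate_pps=200.0, amplitude=float(amp), spike_times_ms=times)
        )
    return fiber


class TestStep2:
    def test_noiseless_recovery(self):
        true = ALIFPParams(l2=0.06, l3=1.2, j2=0.05, j3=0.3)
        amps = np.linspace(4.2, 4.9, 8)
        fiber = _timing_fiber(true, amps)
        p = step2_latency_jitter(fiber, true)
        assert p.l3 == pytest.approx(true.l3, rel=0.05)
        assert p.l2 == pytest.approx(true.l2, rel=0.05)
        assert p.j3 == pytest.approx(true.j3, rel=0.05)

    def test_constant_latency_degenerates_to_flat_curve(self):
        true = ALIFPParams(l2=0.06, l3=0.0, j2=0.05, j3=0.3)
        amps = np.linspace(4.2, 4.9, 6)
        fiber = _timing_fiber(true, amps)
        p = step2_latency_jitter(fiber, true)
        # a flat latency profile is explained by a vanishing latency span
        assert p.l3 * 0.5 < 0.05 or p.l2 >= BOUNDS["l2"][1] * 0.9

    def test_sparse_spikes_warn(self):
        true = ALIFPParams()
        fiber = FiberDataset(fiber_id="SP-000")
        for amp in (4.4, 4.8):
            fiber.add(
                SpikeResponseSet(
                    rate_pps=200.0, amplitude=amp, spike_times_ms=[[0.7], [0.8]]
                )
            )
        with pytest.warns(UserWarning):
            step2_latency_jitter(fiber, true)


class TestOptimizerContract:
    def test_never_worse_than_start(self):
        fun = lambda x: float((x[0] - 0.3) ** 2 + (x[1] + 1) ** 2)
        x, fx = minimize_bounded(fun, [0.9, 0.9], [(0.0, 1.0), (0.0, 1.0)], budget=100)
        assert fx <= fun(np.array([0.9, 0.9]))
        assert x[0] == pytest.approx(0.3, abs=1e-2)
        assert x[1] == pytest.approx(0.0, abs=1e-2)

    def test_transform_round_trip(self):
        tf = _ParamTransform(("f1", "tau_rrp", "t_arp"))
        x = np.array([0.7, 3.3, 0.25])
        np.testing.assert_allclose(tf.to_params(tf.to_unit(x)), x, rtol=1e-12)
        assert tf.log[1] and tf.log[2] and not tf.log[0]


@pytest.fixture(scope="module")
def tiny_cfg():
    return FitConfig.test_scale(
        step3_budget=8, step4_budget=8, step5_budget=8, starts=DEFAULT_STARTS[:2]
    )


@pytest.fixture(scope="module")
def tiny_prepared(tiny_fiber_module, tiny_cfg):
    fiber, truth = tiny_fiber_module
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = step2_latency_jitter(fiber, step1_rate_level(fiber, config=tiny_cfg), tiny_cfg)
    return fiber, truth, p


@pytest.fixture(scope="module")
def tiny_fiber_module():
    from alifp.synth import CohortSpec, generate_fiber

    spec = CohortSpec(seed=7, train_duration_ms=30.0, deviation_prob=0.0)
    rng = np.random.default_rng(spec.seed)
    return generate_fiber(spec, "TINY-000", rng, n_amplitudes=3, n_repetitions=10)


class TestSearchSteps:
    def test_step3_best_of_starts_and_descent(self, tiny_prepared, tiny_cfg):
        fiber, truth, p = tiny_prepared
        out, entry, exit_cost, candidates = step3_short_term(fiber, p, tiny_cfg)
        assert exit_cost <= entry + 1e-12
        assert exit_cost <= min(candidates) + 1e-12
        assert out.bounds_ok() and out.facilitation_ok()

    def test_step3_retains_truth_start(self, tiny_prepared, tiny_cfg):
        fiber, truth, p = tiny_prepared
        from alifp.fitting import _SHORT_TERM, _objective, _prepare_conditions
        from alifp.similarity import STEP_WEIGHTS

        truth_start = {n: getattr(truth.params, n) for n in _SHORT_TERM}
        cfg = FitConfig.test_scale(
            step3_budget=8, starts=(truth_start,) + DEFAULT_STARTS[:1]
        )
        base = p.replace(**truth_start)
        conds = _prepare_conditions(fiber, cfg.rates, False)
        cost_at_truth = _objective(p, _SHORT_TERM, conds, STEP_WEIGHTS[3], cfg)(
            [truth_start[n] for n in _SHORT_TERM]
        )
        _, _, exit_cost, _ = step3_short_term(fiber, p, cfg)
        assert exit_cost <= cost_at_truth + 1e-9

    def test_step4_descent(self, tiny_prepared, tiny_cfg):
        fiber, truth, p = tiny_prepared
        out, entry, exit_cost, _ = step4_latency_jitter_refit(fiber, p, tiny_cfg)
        assert exit_cost <= entry + 1e-12
        assert out.bounds_ok()

    def test_step5_descent_and_bounds(self, tiny_prepared, tiny_cfg):
        fiber, truth, p = tiny_prepared
        out, entry, exit_cost, _ = step5_full(fiber, p, tiny_cfg)
        assert exit_cost <= entry + 1e-12
        assert out.bounds_ok() and out.facilitation_ok()


class TestStep5Adaptation:
    def test_zero_adaptation_ground_truth_recovered_low(self):
        from alifp.synth import CohortSpec, generate_fiber

        spec = CohortSpec(seed=13, deviation_prob=0.0)
        rng = np.random.default_rng(spec.seed)
        from alifp.synth import sample_fiber_params

        true = sample_fiber_params(spec, rng).replace(c_a=0.0)
        fiber, _ = generate_fiber(
            spec, "NOAD-000", rng, params=true, n_amplitudes=3, n_repetitions=15
        )
        cfg = FitConfig.test_scale(step5_budget=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = step2_latency_jitter(fiber, step1_rate_level(fiber, config=cfg), cfg)
        # start step 5 from the true short-term values
        p = p.replace(
            **{n: getattr(true, n) for n in ("f1", "f3", "t_arp", "tau_rrp", "q")}
        )
        out, _, _, _ = step5_full(fiber, p, cfg)
        assert out.c_a < 0.05


class TestFitFiber:
    def test_reproducible_under_fixed_config(self, tiny_fiber_module, tiny_cfg):
        fiber, _ = tiny_fiber_module
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_fiber(fiber, tiny_cfg)
            b = fit_fiber(fiber, tiny_cfg)
        assert a.params.as_dict() == b.params.as_dict()
        assert a.step_costs == b.step_costs

    def test_perturbed_starts_protocol(self, tiny_fiber_module):
        fiber, _ = tiny_fiber_module
        cfg = FitConfig.test_scale(
            step3_budget=5, step4_budget=5, step5_budget=5, starts=DEFAULT_STARTS[:2]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = refit_with_perturbed_starts(fiber, cfg, n_refits=2, seed=1)
        assert len(results) == 2
        for res in results:
            assert res.params.bounds_ok() and res.params.facilitation_ok()
        from alifp.properties import measures_from_params

        spread = np.array(
            [measures_from_params(r.params).as_array() for r in results]
        )
        assert spread.shape == (2, 7)
        assert np.all(np.isfinite(spread))
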