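"""Model curves, drive, branching simulation, and the stochastic twin."""

from __future__ import annotations

import math

import numpy as np
import pytest

from alifp import (
    ALIFPParams,
    adaptation_factor,
    build_pulse_train,
    jitter_curve,
    latency_curve,
    pulse_drive,
    pulse_shape_factor,
    refractory_factor,
    sample_spikes,
    simulate,
    simulate_bank,
    single_pulse_prob,
    subthreshold_factor,
)
from alifp.similarity import complex_vector_strength, data_psth


def _ode_peak(phase_us: float, gap_us: float, tau_us: float) -> float:
    """Fine-grid integration of the leaky membrane driven by a biphasic pulse."""
    dt = 0.001  # us
    t_end = 2 * phase_us + gap_us
    n = int(t_end / dt)
    v, peak = 0.0, 0.0
    for i in range(n):
        t = i * dt
        cur = 1.0 if t < phase_us else (-1.0 if t >= phase_us + gap_us else 0.0)
        v += (cur - v) * dt / tau_us
        peak = max(peak, v)
    return peak


class TestDrive:
    def test_shape_factor_matches_ode_oracle(self):
        kappa = pulse_shape_factor(25.0, 8.0, 100.0)
        oracle = _ode_peak(25.0, 8.0, 100.0)
        assert kappa == pytest.approx(oracle, rel=1e-4)

    def test_drive_linear_in_amplitude(self, default_params):
        t1 = build_pulse_train(200.0, 1.0, 20.0)
        t2 = build_pulse_train(200.0, 2.0, 20.0)
        np.testing.assert_allclose(
            2.0 * pulse_drive(default_params, t1), pulse_drive(default_params, t2)
        )

    def test_zero_amplitude_zero_drive(self, default_params):
        train = build_pulse_train(200.0, 0.0, 20.0)
        assert np.all(pulse_drive(default_params, train) == 0.0)


class TestSinglePulseProb:
    def test_midpoint(self):
        assert single_pulse_prob(1.0, 1.0, 0.1) == pytest.approx(0.5)

    def test_one_sigma(self):
        assert single_pulse_prob(1.1, 1.0, 0.1) == pytest.approx(0.8413, abs=1e-4)

    def test_saturation(self):
        assert single_pulse_prob(10.0, 1.0, 0.1) == pytest.approx(1.0)

    def test_monotone_in_drive(self):
        v = np.linspace(0.7, 1.3, 50)
        p = single_pulse_prob(v, 1.0, 0.1)
        assert np.all(np.diff(p) > 0)

    def test_invalid_spread(self):
        with pytest.raises(ValueError):
            single_pulse_prob(1.0, 1.0, 0.0)


class TestTimingCurves:
    def test_latency_midpoint(self):
        p = ALIFPParams(l3=2.0, l4=0.1)
        assert latency_curve(0.0, p) == pytest.approx(1.1)

    def test_jitter_midpoint(self):
        p = ALIFPParams(j3=0.28)
        assert jitter_curve(0.0, p) == pytest.approx(0.14)

    def test_strong_drive_limits(self):
        p = ALIFPParams(l3=2.0, l4=0.1, j3=0.28)
        assert latency_curve(1e3, p) == pytest.approx(p.l4, abs=1e-9)
        assert jitter_curve(1e3, p) == pytest.approx(0.0, abs=1e-9)

    def test_curves_decreasing(self):
        p = ALIFPParams()
        dv = np.linspace(-0.5, 0.5, 101)
        assert np.all(np.diff(latency_curve(dv, p)) < 0)
        assert np.all(np.diff(jitter_curve(dv, p)) < 0)

    def test_zero_slope_is_step(self):
        p = ALIFPParams(l2=0.0, l3=2.0, l4=0.1)
        assert latency_curve(-1.0, p) == pytest.approx(2.1)
        assert latency_curve(1.0, p) == pytest.approx(0.1)
        assert latency_curve(0.0, p) == pytest.approx(1.1)


class TestRefractory:
    def test_absolute_period_blocks(self):
        p = ALIFPParams(t_arp=0.5)
        assert refractory_factor(0.3, p) == math.inf

    def test_full_recovery(self):
        p = ALIFPParams(t_arp=0.5, tau_rrp=0.7, q=1.0)
        assert refractory_factor(1e4, p) == pytest.approx(1.0)

    def test_closed_form_crossing(self):
        # rho = 1.5 at t_arp + tau * ln 3 for q = p = 1
        p = ALIFPParams(t_arp=0.3, tau_rrp=0.5, q=1.0, p=1.0)
        dt = 0.3 + 0.5 * math.log(3.0)
        assert refractory_factor(dt, p) == pytest.approx(1.5, rel=1e-9)

    def test_monotone_non_increasing(self):
        p = ALIFPParams()
        dt = np.linspace(p.t_arp + 1e-6, 20.0, 500)
        rho = refractory_factor(dt, p)
        assert np.all(np.diff(rho) <= 1e-12)


class TestSubthreshold:
    def test_facilitation_at_onset(self):
        p = ALIFPParams(f2=0.5)
        assert subthreshold_factor(0.0, p) == pytest.approx(0.5)

    def test_returns_to_rest(self):
        p = ALIFPParams()
        assert subthreshold_factor(1e5, p) == pytest.approx(1.0)

    def test_accommodation_scales_with_f3(self):
        # dense-grid oracle: the accommodation lobe grows with f3
        t = np.linspace(0.0, 30.0, 30001)
        lo = np.max(subthreshold_factor(t, ALIFPParams(f3=0.01)))
        hi = np.max(subthreshold_factor(t, ALIFPParams(f3=2.5)))
        assert hi > lo

    def test_f1_zero_no_singularity(self):
        p = ALIFPParams(f1=0.0)
        g = subthreshold_factor(np.array([0.5, 1.0]), p)
        assert np.all(np.isfinite(g))


class TestAdaptation:
    def test_no_history(self):
        assert adaptation_factor([], 5.0, ALIFPParams()) == 1.0

    def test_single_spike_value(self):
        p = ALIFPParams(c_a=0.02, tau_a=0.1)  # tau_a 100 ms
        assert adaptation_factor([0.0], 10.0, p) == pytest.approx(1.01810, abs=1e-5)

    def test_zero_increment(self):
        p = ALIFPParams(c_a=0.0)
        assert adaptation_factor([0.0, 1.0, 2.0], 5.0, p) == 1.0

    def test_accumulates_and_caps(self):
        p = ALIFPParams(c_a=0.5, tau_a=10.0, a_max=2.0)
        many = np.arange(0.0, 50.0, 1.0)
        assert adaptation_factor(many, 50.0, p) == 2.0


class TestSimulate:
    def test_zero_amplitude_silent(self, default_params):
        train = build_pulse_train(200.0, 0.0, 50.0)
        trace = simulate(default_params, train)
        np.testing.assert_allclose(trace.p_inst, 0.0, atol=1e-30)
        assert trace.expected_spikes < 1e-30

    def test_isolated_strong_pulse(self, default_params):
        train = build_pulse_train(10.0, 100.0, 50.0)  # one pulse in 50 ms? no: 10pps
        train = train.truncated(train.period_ms)  # keep exactly one pulse
        trace = simulate(default_params, train)
        assert trace.expected_spikes == pytest.approx(1.0, abs=1e-9)
        w, mu, sd = trace.per_pulse_components[0]
        assert len(w) == 1
        assert mu[0] == pytest.approx(default_params.l4, abs=1e-3)

    def test_mass_bookkeeping(self, default_params):
        train = build_pulse_train(1000.0, 5.0, 30.0)
        trace = simulate(default_params, train)
        # integral of the density equals the summed per-pulse probability
        assert np.sum(trace.p_inst) * trace.dt_ms == pytest.approx(
            trace.expected_spikes, rel=1e-6
        )
        assert np.all(trace.per_pulse_total_prob <= 1.0 + 1e-12)

    def test_first_pulse_monotone_in_amplitude(self, default_params):
        probs = []
        for amp in np.linspace(3.0, 7.0, 6):
            train = build_pulse_train(200.0, amp, 10.0)
            probs.append(simulate(default_params, train).per_pulse_total_prob[0])
        assert np.all(np.diff(probs) >= -1e-12)

    def test_steady_rate_non_increasing_in_t_arp(self, default_params):
        rates = []
        for t_arp in (0.5, 2.0, 6.0):
            p = default_params.replace(t_arp=t_arp)
            train = build_pulse_train(200.0, 8.0, 100.0)
            rates.append(simulate(p, train).expected_spikes)
        assert rates[0] >= rates[1] >= rates[2]

    def test_alternating_response_with_long_refractoriness(self, default_params):
        # refractory period longer than the 5 ms inter-pulse interval at
        # 200 pps forces a response to every second pulse
        p = default_params.replace(t_arp=6.0, tau_rrp=0.5)
        train = build_pulse_train(200.0, 10.0, 100.0)
        per_pulse = simulate(p, train).per_pulse_total_prob
        np.testing.assert_allclose(per_pulse[0::2], 1.0, atol=1e-6)
        np.testing.assert_allclose(per_pulse[1::2], 0.0, atol=1e-6)

    def test_bank_matches_single(self, default_params):
        trains = [build_pulse_train(1000.0, a, 20.0) for a in (4.0, 5.0, 6.0)]
        banked = simulate_bank(default_params, trains)
        for train, tb in zip(trains, banked):
            ts = simulate(default_params, train)
            np.testing.assert_allclose(tb.p_inst, ts.p_inst)


class TestSampleSpikes:
    def test_zero_amplitude_silent(self, default_params):
        train = build_pulse_train(200.0, 0.0, 50.0)
        resp = sample_spikes(default_params, train, 20, seed=1)
        assert resp.n_spikes == 0

    def test_seed_determinism(self, default_params):
        train = build_pulse_train(1000.0, 5.0, 30.0)
        a = sample_spikes(default_params, train, 10, seed=42)
        b = sample_spikes(default_params, train, 10, seed=42)
        for ra, rb in zip(a.spike_times_ms, b.spike_times_ms):
            np.testing.assert_array_equal(ra, rb)

    def test_first_pulse_fraction_at_half_probability(self, default_params):
        from alifp.properties import threshold_amplitude

        amp = threshold_amplitude(default_params, 0.5)
        train = build_pulse_train(200.0, amp, 5.0)  # single pulse
        resp = sample_spikes(default_params, train, 10_000, seed=3)
        frac = np.mean([len(r) > 0 for r in resp.spike_times_ms])
        assert frac == pytest.approx(0.5, abs=0.015)


class TestTwinEquivalence:
    def test_psth_rate_and_vs_agree(self, default_params):
        """Deterministic trace vs Monte-Carlo twin on a short train."""
        n = 20_000
        train = build_pulse_train(200.0, 5.0, 15.0)  # 3 pulses
        trace = simulate(default_params, train)
        resp = sample_spikes(default_params, train, n, seed=5)

        model_p = trace.psth(0.1)
        data_p = data_psth(resp, 0.1, t_max_ms=20.0)
        counts = data_p * n
        mean = model_p * n
        sd = np.sqrt(np.maximum(mean * (1 - np.minimum(model_p, 1.0)), 0.0))
        assert np.all(np.abs(counts - mean) <= 4 * sd + 1)

        per_rep = np.array([len(r) for r in resp.spike_times_ms])
        se = per_rep.std(ddof=1) / math.sqrt(n)
        assert abs(per_rep.mean() - trace.expected_spikes) <= 4 * se + 1e-3

        x_d = complex_vector_strength(resp.all_spikes(), train.period_ms)
        x_m = trace.complex_vs()
        assert abs(x_m - x_d) <= 5.0 / math.sqrt(resp.n_spikes) + 2e-3
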