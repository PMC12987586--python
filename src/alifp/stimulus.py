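"""Pulse-train stimulus definition.

Stimuli are 100 ms constant-amplitude trains of charge-balanced biphasic
pulses (25 us phases, 8 us inter-phase gap).  The first pulse onset sits at
t = 0 and subsequent onsets are spaced by the period 1000/rate ms.  Recorded
trains can deviate slightly from the nominal rate; the effective rate is
carried explicitly so that phase-locking analyses use the true period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PulseTrain", "build_pulse_train"]

#: largest pulse-rate deviation observed in recordings
MAX_RATE_DEVIATION = 0.09


@dataclass(frozen=True)
class PulseTrain:
    """Deterministic stimulus timing and amplitude for one condition."""

    rate_pps: float
    amplitude: float
    effective_rate_pps: float
    phase_duration_us: float = 25.0
    interphase_gap_us: float = 8.0
    train_duration_ms: float = 100.0
    pulse_onsets_ms: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.pulse_onsets_ms is None:
            onsets = _onsets(self.effective_rate_pps, self.train_duration_ms)
            object.__setattr__(self, "pulse_onsets_ms", onsets)

    @property
    def period_ms(self) -> float:
        """Stimulus period T used for phase-locking measures."""
        return 1000.0 / self.effective_rate_pps

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_onsets_ms)

    @property
    def condition(self) -> tuple[float, float]:
        return (self.rate_pps, self.amplitude)

    def truncated(self, span_ms: float) -> "PulseTrain":
        """Train restricted to pulses with onset < ``span_ms``."""
        onsets = self.pulse_onsets_ms[self.pulse_onsets_ms < span_ms]
        return PulseTrain(
            rate_pps=self.rate_pps,
            amplitude=self.amplitude,
            effective_rate_pps=self.effective_rate_pps,
            phase_duration_us=self.phase_duration_us,
            interphase_gap_us=self.interphase_gap_us,
            train_duration_ms=min(span_ms, self.train_duration_ms),
            pulse_onsets_ms=onsets,
        )


def _onsets(rate_pps: float, duration_ms: float) -> np.ndarray:
    period = 1000.0 / rate_pps
    n = int(np.ceil(duration_ms / period))
    onsets = np.arange(n) * period
    return onsets[onsets < duration_ms]


def build_pulse_train(
    rate_pps: float,
    amplitude: float,
    duration_ms: float = 100.0,
    deviation_fraction: float = 0.0,
) -> PulseTrain:
    """Build a constant-amplitude biphasic pulse train.

    Parameters
    ----------
    rate_pps
        Nominal pulse rate in pulses/s.
    amplitude
        Current amplitude in (arbitrary) linear units, >= 0.
    duration_ms
        Train length; onsets strictly below this value.
    deviation_fraction
        Relative deviation of the delivered rate from the nominal one,
        |deviation| <= 0.09 as observed in recordings.
    """
    if rate_pps <= 0:
        raise ValueError("rate_pps must be positive")
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if abs(deviation_fraction) > MAX_RATE_DEVIATION:
        raise ValueError(
            f"|deviation_fraction| must be <= {MAX_RATE_DEVIATION}"
        )
    effective = rate_pps * (1.0 + deviation_fraction)
    return PulseTrain(
        rate_pps=rate_pps,
        amplitude=amplitude,
        effective_rate_pps=effective,
        train_duration_ms=duration_ms,
    )
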