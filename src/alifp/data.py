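"""Spike-time data containers and their CSV serialization.

A recording session yields, per fiber, spike times for several conditions
(pulse rate x amplitude), each repeated multiple times.  The on-disk form is
a flat CSV with one spike per row (columns: fiber_id, rate_pps,
effective_rate_pps, amplitude, repetition, spike_time_ms) -- diff-able and
loadable with any table reader.  Repetitions without spikes are kept as rows
with an empty spike_time_ms field so that repetition counts round-trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeResponseSet",
    "FiberDataset",
    "read_spike_table",
    "write_spike_table",
    "remaining_after_exclusions",
]

_COLUMNS = [
    "fiber_id",
    "rate_pps",
    "effective_rate_pps",
    "amplitude",
    "repetition",
    "spike_time_ms",
]

#: spike times are stored at 0.1 us resolution
_TIME_DECIMALS = 4


@dataclass
class SpikeResponseSet:
    """Spike times of one fiber for one condition across repetitions."""

    rate_pps: float
    amplitude: float
    spike_times_ms: list[np.ndarray]
    effective_rate_pps: float | None = None
    train_duration_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.effective_rate_pps is None:
            self.effective_rate_pps = self.rate_pps
        self.spike_times_ms = [
            np.sort(np.asarray(rep, dtype=float)) for rep in self.spike_times_ms
        ]

    @property
    def condition(self) -> tuple[float, float]:
        return (self.rate_pps, self.amplitude)

    @property
    def rep_count(self) -> int:
        return len(self.spike_times_ms)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(rep) for rep in self.spike_times_ms))

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.effective_rate_pps

    def all_spikes(self) -> np.ndarray:
        """Spike times pooled across repetitions (unsorted concatenation)."""
        if not self.spike_times_ms:
            return np.empty(0)
        return np.concatenate(self.spike_times_ms) if self.n_spikes else np.empty(0)

    def validate(self) -> None:
        limit = self.train_duration_ms + 5.0
        for i, rep in enumerate(self.spike_times_ms):
            if np.any(np.diff(rep) < 0):
                raise ValueError(f"repetition {i} not sorted")
            if len(rep) and (rep[0] < 0 or rep[-1] > limit):
                raise ValueError(
                    f"repetition {i} has spike times outside [0, {limit}] ms"
                )


@dataclass
class FiberDataset:
    """All recorded conditions of one fiber."""

    fiber_id: str
    responses: dict[tuple[float, float], SpikeResponseSet] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add(self, response: SpikeResponseSet) -> None:
        if response.condition in self.responses:
            raise ValueError(
                f"duplicate condition {response.condition} for fiber {self.fiber_id}"
            )
        self.responses[response.condition] = response

    @property
    def rates(self) -> list[float]:
        return sorted({r for r, _ in self.responses})

    def conditions_at(self, rate_pps: float) -> list[SpikeResponseSet]:
        """Responses at one nominal rate, ordered by amplitude."""
        out = [resp for (r, _), resp in self.responses.items() if r == rate_pps]
        return sorted(out, key=lambda s: s.amplitude)

    def amplitudes_at(self, rate_pps: float) -> np.ndarray:
        return np.array([s.amplitude for s in self.conditions_at(rate_pps)])


# ----------------------------------------------------------------------
# CSV serialization


def write_spike_table(datasets: list[FiberDataset], path) -> None:
    """Write fibers to CSV with a deterministic row order."""
    rows: list[tuple] = []
    for fiber in sorted(datasets, key=lambda f: f.fiber_id):
        for (rate, amp) in sorted(fiber.responses):
            resp = fiber.responses[(rate, amp)]
            for rep, spikes in enumerate(resp.spike_times_ms):
                if len(spikes) == 0:
                    rows.append(
                        (fiber.fiber_id, rate, resp.effective_rate_pps, amp, rep, np.nan)
                    )
                for t in np.sort(spikes):
                    rows.append(
                        (
                            fiber.fiber_id,
                            rate,
                            resp.effective_rate_pps,
                            amp,
                            rep,
                            round(float(t), _TIME_DECIMALS),
                        )
                    )
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    frame.to_csv(path, index=False)


def read_spike_table(path) -> list[FiberDataset]:
    """Read a spike table CSV back into :class:`FiberDataset` objects."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas names the line
        raise ValueError(f"malformed spike table {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"spike table {path} lacks columns {missing}")

    datasets: list[FiberDataset] = []
    for fiber_id, per_fiber in frame.groupby("fiber_id", sort=True):
        fiber = FiberDataset(fiber_id=str(fiber_id))
        for (rate, amp), grp in per_fiber.groupby(["rate_pps", "amplitude"], sort=True):
            eff = float(grp["effective_rate_pps"].iloc[0])
            n_rep = int(grp["repetition"].max()) + 1
            reps: list[np.ndarray] = [np.empty(0) for _ in range(n_rep)]
            for rep, rep_grp in grp.groupby("repetition"):
                times = rep_grp["spike_time_ms"].dropna().to_numpy(dtype=float)
                if np.any(np.diff(times) < 0):
                    warnings.warn(
                        f"unsorted spike times for fiber {fiber_id}, "
                        f"condition ({rate}, {amp}), repetition {rep}; sorting",
                        stacklevel=2,
                    )
                    times = np.sort(times)
                reps[int(rep)] = times
            fiber.add(
                SpikeResponseSet(
                    rate_pps=float(rate),
                    amplitude=float(amp),
                    effective_rate_pps=eff,
                    spike_times_ms=reps,
                )
            )
        datasets.append(fiber)
    return datasets


def remaining_after_exclusions(n_recorded: int, exclusions: dict[str, int]) -> int:
    """Cohort bookkeeping: fibers left after applying exclusion counts.

    ``exclusions`` maps a reason label to the number of fibers removed for
    that reason; reasons are assumed disjoint.
    """
    removed = sum(exclusions.values())
    remaining = n_recorded - removed
    if remaining < 0:
        raise ValueError("exclusions exceed the number of recorded fibers")
    return remaining
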