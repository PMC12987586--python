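"""Parameter set of the adaptive leaky-integrate and firing-probability (aLIFP) model.

The model describes the response of a single electrically stimulated nerve
fiber as a deterministic spike probability over time.  Its parameters fall
into four groups:

* threshold / drive: membrane resistance ``r_m`` (current -> mV gain),
  resting threshold mean ``theta0`` (mV, fixed scale anchor) and standard
  deviation ``s_sigma`` (mV);
* spike timing: the latency curve (``l1``..``l4``) and jitter curve
  (``j1``..``j3``), both logistic functions of the supra-threshold drive;
* short-term pulse interaction: refractoriness (``t_arp``, ``tau_rrp``,
  ``p``, ``q``) after a spike and facilitation/accommodation
  (``f1``..``f5``) after a sub-threshold pulse;
* long-term interaction: adaptation (``c_a``, ``tau_a``, ``a_max``), a small
  cumulative threshold increase after every spike.

All times are in ms except ``tau_a`` (seconds) and ``tau_m_us``
(microseconds), mirroring the scales on which the phenomena act.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Any, Mapping

__all__ = [
    "ALIFPParams",
    "BOUNDS",
    "FITTED_NAMES",
    "FIRST_SAMPLE_MS",
    "subthreshold_first_value",
]

#: bounds used during optimization for the fitted parameters (ms / mV / s as
#: documented on :class:`ALIFPParams`); ``r_m`` and ``s_sigma`` are fitted in
#: step 1 by least squares and carry no box bounds.
BOUNDS: dict[str, tuple[float, float]] = {
    "l2": (0.0, 40.0),
    "l3": (0.0, 40.0),
    "j2": (0.0, 4.0),
    "j3": (0.0, 4.0),
    "f1": (0.0, 5.0),
    "f3": (0.01, 2.5),
    "t_arp": (0.01, 10.0),
    "tau_rrp": (0.1, 100.0),
    "q": (0.0, 10.0),
    "c_a": (0.0, 1.0),
    "tau_a": (0.0, 10.0),
}

FITTED_NAMES: tuple[str, ...] = (
    "r_m",
    "s_sigma",
    "l2",
    "l3",
    "j2",
    "j3",
    "f1",
    "f3",
    "t_arp",
    "tau_rrp",
    "q",
    "c_a",
    "tau_a",
)

#: first sample of the sub-threshold (facilitation/accommodation) curve,
#: one simulation grid step after the failed pulse.  The fit constraint
#: "the first value of the facilitation function is below 1" is evaluated here.
FIRST_SAMPLE_MS = 0.01

_UNITS: dict[str, str] = {
    "r_m": "mV/unit",
    "s_sigma": "mV",
    "theta0": "mV",
    "l1": "mV",
    "l2": "mV",
    "l3": "ms",
    "l4": "ms",
    "j1": "mV",
    "j2": "mV",
    "j3": "ms",
    "t_arp": "ms",
    "tau_rrp": "ms",
    "p": "",
    "q": "",
    "f1": "ms",
    "f2": "",
    "f3": "",
    "f4": "ms",
    "f5": "",
    "c_a": "",
    "tau_a": "s",
    "a_max": "",
    "tau_m_us": "us",
}


@dataclass
class ALIFPParams:
    # threshold / drive
    r_m: float = 1.0
    s_sigma: float = 0.05
    theta0: float = 1.0
    # latency curve: l4 + l3 * logistic(-(dv - l1)/l2)
    l1: float = 0.0
    l2: float = 0.05
    l3: float = 0.9
    l4: float = 0.3
    # jitter curve: j3 * logistic(-(dv - j1)/j2)
    j1: float = 0.0
    j2: float = 0.05
    j3: float = 0.28
    # refractoriness
    t_arp: float = 0.5
    tau_rrp: float = 0.7
    p: float = 1.0
    q: float = 1.0
    # facilitation / accommodation
    f1: float = 0.25
    f2: float = 0.5
    f3: float = 1.0
    f4: float = 1.0
    f5: float = 0.1
    # adaptation
    c_a: float = 0.014
    tau_a: float = 0.1
    a_max: float = 2.0
    # membrane time constant of the leaky integrator
    tau_m_us: float = 100.0

    # ------------------------------------------------------------------
    def replace(self, **changes: float) -> "ALIFPParams":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    # ------------------------------------------------------------------
    def bounds_ok(self) -> bool:
        """True if every box-bounded fitted parameter is within its bounds."""
        vals = self.as_dict()
        return all(lo <= vals[k] <= hi for k, (lo, hi) in BOUNDS.items())

    def facilitation_ok(self) -> bool:
        """Fit constraint: the sub-threshold curve starts below 1."""
        return subthreshold_first_value(self) < 1.0

    def validate(self) -> None:
        vals = self.as_dict()
        for k, (lo, hi) in BOUNDS.items():
            if not lo <= vals[k] <= hi:
                raise ValueError(
                    f"parameter {k}={vals[k]!r} outside bounds [{lo}, {hi}]"
                )
        if not self.facilitation_ok():
            raise ValueError(
                "sub-threshold curve starts at or above 1 "
                "(facilitation constraint violated)"
            )

    # ------------------------------------------------------------------
    def to_schema(self) -> dict[str, dict[str, Any]]:
        """Serialize as ``{name: {value, unit, fitted, bounds}}``."""
        out: dict[str, dict[str, Any]] = {}
        for name, value in self.as_dict().items():
            entry: dict[str, Any] = {
                "value": value,
                "unit": _UNITS.get(name, ""),
                "fitted": name in FITTED_NAMES,
            }
            if name in BOUNDS:
                entry["bounds"] = list(BOUNDS[name])
            out[name] = entry
        return out

    @classmethod
    def from_schema(cls, schema: Mapping[str, Any]) -> "ALIFPParams":
        values = {}
        for name, entry in schema.items():
            values[name] = float(entry["value"] if isinstance(entry, Mapping) else entry)
        return cls(**values)

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_schema(), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "ALIFPParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_schema(json.load(fh))


def subthreshold_first_value(params: ALIFPParams, dt_ms: float = FIRST_SAMPLE_MS) -> float:
    """Sub-threshold threshold factor one grid step after a failed pulse."""
    if params.f1 > 0.0:
        fac = params.f2 * math.exp(-dt_ms / params.f1)
    else:
        fac = 0.0 if dt_ms > 0 else params.f2
    acc = params.f3 * params.f5 * (dt_ms / params.f4) * math.exp(-dt_ms / params.f4)
    return 1.0 - fac + acc
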