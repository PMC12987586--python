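# alifp

Single-fiber modelling of electrically stimulated nerve fibers, built for
cochlear-implant-style pulse-train stimulation.  The package implements

* the **aLIFP model** (adaptive leaky-integrate and firing-probability): a
  phenomenological neuron model whose output is the deterministic spike
  probability over time rather than sampled spikes,
* a **five-step fitting procedure** that finds fiber-specific model
  parameters from spike-train recordings,
* the **similarity terms** between recorded and simulated responses that
  drive the fit,
* extraction of seven **response-property measures** (dynamic range,
  latency, jitter, refractory period, facilitation, accommodation,
  adaptation) from fitted parameters, with a fiber-by-fiber Pearson
  correlation analysis,
* a **synthetic-data generator** — the model's stochastic twin — that
  produces cohorts with known ground truth for validation and parameter
  recovery experiments.

## The model

A biphasic pulse (25 µs phases, 8 µs gap) of amplitude *A* depolarizes a
leaky-integrator membrane by *v = A·R·κ* mV, with membrane resistance *R*
and pulse-shape factor *κ = 1 − exp(−t_phase/τ_m)*.  The pulse evokes a
spike with probability

    P = Φ((v − θ_eff) / s_σ,eff),

where Φ is the standard normal CDF and the effective threshold θ_eff is the
resting threshold θ₀ multiplied by history-dependent factors: refractoriness
after a spike (absolute period t_ARP, relative recovery with τ_RRP and shape
q), facilitation/accommodation after a sub-threshold pulse (f₁, f₃ fitted),
and cumulative adaptation after every spike (c_a, τ_a).  Spike times are
Gaussian around the pulse onset plus a drive-dependent latency, with a
drive-dependent jitter.  Spike and no-spike futures of every pulse are
propagated as weighted branches, so the output is an exact mixture
distribution — the instantaneous spike probability over time.

The fit minimizes, over conditions (pulse rate × amplitude),

    cost = ln(r_total) · [c_x·(1 − xcorr) + c_v·ΔcVS + c_r·Δ√rate]

with the normalized cross-correlation of windowed rates over the first part
of the response, the complex vector-strength difference (phase locking and
phase position, bounded by 2), and the difference of square-root
steady-state rates.

## Worked example

Generate a synthetic fiber, fit it, and compare recovered response
properties with the ground truth:

```python
import numpy as np
from alifp.synth import CohortSpec, generate_fiber
from alifp.fitting import FitConfig, fit_fiber
from alifp.properties import measures_from_params

spec = CohortSpec(seed=11, deviation_prob=0.0,
                  measure_floors={"accommodation_ms": 0.3,
                                  "facilitation_ms": 0.05})
rng = np.random.default_rng(spec.seed)
fiber, truth = generate_fiber(spec, "SYN-000", rng,
                              n_amplitudes=5, n_repetitions=30)
result = fit_fiber(fiber, FitConfig.test_scale())
for name, t, f in zip(truth.measures.names(),
                      truth.measures.as_array(),
                      measures_from_params(result.params).as_array()):
    print(f"{name:18s} true {t:7.4f}   fitted {f:7.4f}")
```

prints (seed 11, first fiber of the cohort):

```
dynamic_range_db   true  1.3371   fitted  1.4381
latency50_ms       true  0.5230   fitted  0.5027
jitter50_ms        true  0.2356   fitted  0.2187
refractory_ms      true  3.5472   fitted  2.6007
facilitation_ms    true  0.5341   fitted  0.4032
accommodation_ms   true  2.3186   fitted  2.5694
adaptation_db      true  0.2333   fitted  0.3200
```

i.e. the procedure recovers the fiber's response properties from 100 ms
pulse-train responses alone (dynamic range in dB, times in ms, adaptation in
dB threshold increase 10 ms after a spike).  Exact fitted values depend on
the optimizer budget; see `FitConfig`.

A command-line interface mirrors the library:

```bash
alifp synth --n-fibers 3 --seed 11 --out-dir data/
alifp fit --spikes data/spikes.csv --fiber SYN-000 --test-scale --seed 7 --out fit.json
alifp properties --params fit.json --out measures.csv
alifp correlate --measures measures.csv --alpha 0.05 --out report.json
```

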