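# Methods

This note documents the model, the numerical choices, and the scope of the
validation experiments, in the order a user meets them.

## Stimulus and data model

Stimuli are 100 ms constant-amplitude trains of charge-balanced biphasic
pulses (25 µs phases, 8 µs inter-phase gap).  The first pulse onset defines
t = 0 and onsets are spaced by the period of the *effective* pulse rate,
which may deviate from the nominal rate by up to 9 % — recordings show such
deviations, and phase-locking measures are computed against the effective
period.  Spike times are stored in ms from stimulus onset; times up to
5 ms past the train end are retained (latency tail of the last pulse).
Amplitudes are abstract linear current units; every dB conversion uses
20·log10 of an amplitude or threshold ratio (field quantities, so a factor
of 2 is ≈ 6 dB).

The on-disk format is a flat CSV with one spike per row and explicit empty
rows for spike-free repetitions, so repetition counts survive a round trip.
Times are stored at 0.1 µs resolution.

## The aLIFP model

The model is phenomenological: each response property is carried by its own
parametric curve, all acting multiplicatively on a resting threshold
θ₀ = 1 mV (the scale anchor; the membrane resistance absorbs the units).

* **Drive.**  A pulse of amplitude A depolarizes the membrane by
  A·R·κ, with κ the peak of the first-order membrane response
  (time constant τ_m = 100 µs) to the biphasic pulse.  For a
  cathodic-first pulse the peak sits at the end of the first phase,
  κ = 1 − exp(−25/100) ≈ 0.221.  This closed form is verified against
  fine-grid ODE integration in the tests.
* **Spike probability.**  P = Φ((v − θ_eff)/s_σ,eff).  The threshold spread
  is *relative*: s_σ,eff = s_σ·θ_eff/θ₀, so the modulation factors raise
  mean and spread together and the rate-level curve keeps its shape under
  modulation.  (Whether the spread is absolute or relative is genuinely
  open; the relative choice keeps the single-pulse behaviour
  shape-invariant and is isolated in one place.)
* **Latency and jitter.**  Logistic functions of the supra-threshold drive
  Δv = v − θ_eff: latency = l₄ + l₃·S(−Δv/l₂), jitter = j₃·S(−Δv/j₂), with
  the midpoint parameters l₁ = j₁ = 0 pinned so both curves are symmetric
  about the 50 % spike-probability point; latency(0) = l₄ + l₃/2 and
  jitter(0) = j₃/2 are the reported "at 50 %" measures.  l₂ = 0 degenerates
  to a step, handled explicitly.
* **Refractoriness.**  ρ(Δt) = [1 − exp(−((Δt − t_ARP)/τ_RRP)^q)]^(−p),
  infinite during the absolute period; p is fixed at 1.
* **Facilitation / accommodation.**  After a failed pulse,
  g(Δt) = 1 − f₂·e^(−Δt/f₁) + f₃·f₅·(Δt/f₄)·e^(−Δt/f₄): a threshold dip
  (facilitation) followed by an alpha-function lobe above 1
  (accommodation).  Only f₁ and f₃ are fitted; f₂ = 0.5, f₄ = 1 ms,
  f₅ = 0.1 are fixed.  A fit constraint requires g at the first grid sample
  (0.01 ms) to lie below 1.
* **Adaptation.**  Each spike multiplies the threshold by
  1 + c_a·e^(−Δt/τ_a) (τ_a in seconds); the product over past spikes is
  capped at a_max = 2.
* **Fixed defaults.**  The non-fitted parameters (τ_m, p, l₄, f₂, f₄, f₅,
  a_max, θ₀) are package defaults, surfaced in the parameter schema and
  never hard-coded in the simulation path.  The exact functional forms
  above are this package's binding definitions, chosen to satisfy the
  qualitative contracts of the response-property curves (shapes, parameter
  roles, limits); they are confined to the curve functions in
  `alifp.model`, so alternative forms can be swapped without touching the
  fitter.

### Branching simulation

Each pulse splits every live branch into a spike and a no-spike future,
weighted by the pulse's spike probability under that branch's history.  The
output trace is the probability-weighted mixture of per-pulse Gaussian
spike-time components; multimodal per-pulse distributions arise naturally.
Numerical policy:

* per-branch history keeps failed-pulse times since the last spike and all
  spike times, truncated at horizons where the respective factor differs
  from 1 by < 1e−9;
* branch bookkeeping collapses each spike-time distribution to its mean;
* branches below 1e−6 of their condition's mass are pruned and the mass
  renormalized; above 512 branches (96 at test scale) the lowest-mass
  branches are merged into their neighbour in last-spike-time order;
* the trace is deposited on a 0.01 ms grid by exact per-cell Gaussian CDF
  differences (0.02 ms inside the fitting loop, still 10× finer than the
  0.2 ms analysis-window slopes);
* several conditions that share pulse timing (the amplitudes of one rate)
  are propagated side by side in one pass (`simulate_bank`); their branch
  populations never interact.

The stochastic twin (`sample_spikes`) draws a threshold per pulse and a
spike time per spike but keeps the *mean* spike time for history
bookkeeping, so its marginal statistics match the deterministic trace
exactly; the test suite verifies PSTH, total rate, and vector strength
agreement at n = 20 000 repetitions within Monte-Carlo error.

## Similarity terms and cost

* Windowed rates use 0.6 ms trapezoid windows (0.2 ms rise, plateau, fall)
  on a 0.2 ms step grid starting at t = 0; the data-side rate weights each
  spike by the window amplitude, the model side integrates the trace.
* The first part of a response ends where the pooled spike count in
  non-overlapping 10 ms windows first drops below 10, clamped to
  [20, 50] ms (and to the train duration for short test stimuli).
* The cross-correlation is zero-lag and normalized; an all-zero series
  scores 0 (a silent model against a firing fiber is maximally dissimilar),
  not NaN.
* The complex vector strength keeps the mean phase; the model-side
  estimator weights the trace grid by probability mass.  During the
  first-part-only fitting steps both model and data are restricted to the
  same span so the two estimators see the same window.
* The steady-state rate term compares *square roots* of the rates (Poisson
  discriminability scaling).
* The per-condition cost uses the natural logarithm of the whole-response
  data rate (spikes/s over the full 100 ms) as a reliability weight, with a
  floor of ln 2 for conditions at or below 1 spike/s so silent conditions
  cannot zero out or flip the cost; the total is the mean over conditions.

## Fitting procedure

Five steps, each releasing a subset of the 13 fitted parameters:

1. **Rate-level** (deterministic least squares): R and s_σ from first-pulse
   spike probabilities of the lowest-rate data, first-pulse spikes counted
   in a 4 ms window.  If the fitted 10–90 % width is narrower than the
   median amplitude spacing, s_σ is inflated to the widest value the
   spacing can resolve (the sampled rate-level points are in the saturated
   region either way).
2. **Latency/jitter** (least squares): per-amplitude first-pulse latency
   means and SDs, weighted by spike counts, fitted by the two curves.
3. **Short-term interaction** (f₁, f₃, t_ARP, τ_RRP, q): multi-start
   bounded derivative-free search on the first part of all conditions,
   cross-correlation cost only.  Six starting points span response
   archetypes (short/long refractoriness × weak/strong accommodation ×
   weak/strong facilitation); the best of the six candidate results is
   kept.
4. **Latency/jitter refit** on the same slice with the vector-strength term
   added (weights 1, 0.5, 0); the cross-correlation acts as a regularizer.
5. **Short-term + adaptation** on the full 100 ms (weights 3, 0.75, 0.1),
   restricted to four amplitudes at the 10/37/63/90 % points of the fitted
   rate-level function.  The search explores the adaptation dimensions
   first, since the short-term parameters enter near their step-3 optimum
   and a budget-limited direction-set search sweeps coordinates in order.

The optimizer contract is minimal — bounds, budget, start point → best
point and cost — so any bounded derivative-free minimizer fits; the default
backend is Powell's method, which is deterministic.  The search runs in a
normalized unit cube with log scaling for parameters spanning ≥ 2 decades
(t_ARP, τ_RRP, f₃).  Every step returns the better of its entry and exit
point, so the active-weight cost never increases across a step, and bounds
plus the facilitation constraint are enforced after every step (constraint
violations are penalized inside the objective).

The parameter-certainty protocol refits a fiber repeatedly with a random
vector added to each step-3 starting point, uniform within ±25 % of each
parameter's bound range (the magnitude is this package's choice), and
reports the spread of the property measures.

## Response-property measures

* dynamic range: 20·log10 of the amplitude ratio between 90 % and 10 %
  single-pulse spike probability;
* latency/jitter at 50 % spike probability (curve midpoints);
* refractory period: time after a spike at which 1.5× the resting threshold
  can again evoke a spike (root of ρ = 1.5, bracketed bisection);
* facilitation: initial interval with g < 1; accommodation: from the first
  up-crossing of 1 to the *last* down-crossing of 1.01 (robust to
  non-monotone shapes); both by 1 µs-refined root finding on a dense grid;
* adaptation: threshold increase in dB 10 ms after one spike.

The correlation analysis computes pairwise Pearson r with two-sided t-test
p-values; the Bonferroni base defaults to the 21 distinct pairs of seven
measures but can be set explicitly, and the critical |r| at the corrected
level is reported by inverting the t transform.

## Synthetic cohorts and what the tests show

The generator emulates the structure of the targeted recordings: rates
{200, 1000, 2000} pps (optionally 5000), ~11 ± 5 amplitudes per fiber
placed linearly between the 2 % and 98 % points of the true rate-level
curve, ~24 ± 16 repetitions (truncated normals, floored at 3 and 5), and a
small minority of fibers with a pulse-rate deviation up to ±9 %.  Parameter
priors are uniform; the "realistic" preset narrows them to ranges whose
property measures sit near published single-fiber values (dynamic range
≈ 1 dB, latency < 1.5 ms, refractory period a few ms, adaptation ≈ 0.1 dB).

The recovery and fitted-versus-default experiments in the test suite run on
one shared cohort of 5 fibers with 5 amplitudes and 30 repetitions each,
fitted at reduced optimizer budget (60/30/90 evaluations per start for
steps 3/4/5, branch cap 96, 0.02 ms cost grid) — sizes chosen so the whole
suite runs on one CPU in well under half an hour.  The recovery cohort's
priors additionally require strictly positive true measures
(accommodation ≥ 0.3 ms, facilitation ≥ 0.05 ms): a factor-of-2 (ratio)
comparison is undefined at a true value of zero, which the 1.01-threshold
accommodation criterion would otherwise produce for weakly accommodating
parameter draws.

What passing these tests does *not* show: the generator draws from the
model itself, so recovery says the procedure can invert the model under the
study's data structure — it cannot reveal model misspecification, electrode
artifacts, recording noise, fiber-health drift over repetitions, or
two-fiber contamination, all of which real recordings contain and which the
exclusion bookkeeping is there to remove.

## Known limitations

* The branching simulation collapses spike-time distributions to their
  means for history bookkeeping; with large jitter relative to the
  refractory recovery this slightly sharpens history effects (the twin
  shares the approximation, so the two routes stay comparable).
* Sequential (step-wise) optimization can settle in globally sub-optimal
  parameter sets; joint optimization of all 13 parameters is out of scope.
* Fitted parameter sets are known to be ambiguous — different sets can
  produce near-identical responses; the property *measures* are the stable
  quantities, and the certainty protocol quantifies exactly that.
* Phase-duration effects and deafness-duration differences are not
  modelled.
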