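# Methods

## Model

One extension neuron E with `n` dendritic branches receives synapses from
an input neuron I and an attention neuron A on every branch. All dynamics
are computed on a fixed 1 ms grid over one run of `duration` ms (default
120 ms, one SMO cycle).

Per branch `j`, the absolute membrane potential is

```
V_j(t) = R + h·sin(0.002 π f (t − j·ph)) + Σ EPSP + Σ BsP
```

with resting potential `R = −65 mV`, SMO amplitude `h = 6 mV`, frequency
`f = 8.33 Hz` and phase step `ph = 10 ms` (`j = −2 … 9` in the regular
12-branch layout, giving one SMO maximum per 10 ms attention slot at
t = 10 … 120 ms). Each presynaptic spike at `t0` adds an alpha kernel
`k·W·δt·g^(−δt/τ)` (`δt = t − t0`; `k = 39`, `g = 2`, `τ = 1 ms`;
`W_IE = 0.15`, `W_AE = 0.40` initially). A dendritic spike is registered
on an upward crossing of `φ_dend = −48.7 mV` outside a 10 ms refractory
window, and adds the same alpha kernel with `k = 40` to its own branch.

The soma sits at `R` plus `u_pass = 0.08` times the summed branch EPSPs
plus `u_B = 1.0` times the summed branch-spike potentials; branch SMOs do
not reach the soma (their phases are assumed to cancel). A somatic spike
is an upward crossing of `S = −50 mV`: the potential is forced to +30 mV
for 1 ms, then relaxes from −70 mV back to rest with a 3 ms time
constant. `S`, the hyperpolarization depth and its time constant are not
constrained by the source material; the values above satisfy the two
structural requirements — the passive EPSP sum alone (≤ ~11 mV at 12
branches) can never fire the soma, while a single dendritic spike
(20.9 mV at its on-grid peak) always does — and recover fast enough that
somatic spikes 10 ms apart are all emitted (tested).

Learning (between encoding and recall) potentiates exactly the branches
that fired a dendritic spike: either `W_AE → W_AE_max = 0.55` (one-shot
saturating STDP; `W_IE` never changes, somatic spikes never modify
weights) or `h → 1.5·h = 9 mV` (SMO amplification). Recall restarts the
clock at t = 0 with the identical attention burst and SMO phases and a
silent input neuron, so encoding and recall somatic trains are compared
at identical absolute times with 0 ms tolerance.

## Why recall is exact, and how thin the margins are

All depolarizations below are relative to rest; the dendritic threshold
gap is `φ_dend − R = 16.3 mV`.

* Coincident A + I at a branch peak: EPSP `(0.40+0.15)·39/2 = 10.725 mV`
  plus SMO ≈ 5.99 mV → 16.72 mV > 16.3 → spike, 1 ms after the input
  slot.
* A alone, unpotentiated: `7.8 + 6.0 = 13.8 mV` < 16.3 → silent.
* A alone, potentiated (STDP): `10.725` + SMO at peak → fires at the
  encoded slot. Since `W_IE + W_AE = W_AE_max` and the kernel is linear
  in `W`, the potentiated branch's recall potential is sample-for-sample
  identical to its encoding potential — recall cannot differ from
  encoding at the regular layout.
* One slot off-peak, potentiated: the largest depolarization is
  `10.725 + 6·sin(0.0523·22) + 0.063 (EPSP tail) = 16.265 mV`, i.e.
  **0.035 mV below threshold**. On the adjacent slot's first sample the
  margin is 0.116 mV.

These sub-0.1 mV margins exist only on the 1 ms grid: the continuous-time
maximum of the same depolarization is ≈ 16.8 mV > 16.3, so a finer grid
would make every potentiated branch fire one slot early. The grid is
therefore a model assumption, not a numerical setting (`dt` is fixed and
a regression test pins the off-peak margin).

The same margin bounds parameter robustness: an adjacent-slot recall
crossing appears once `19.614·W_AE_max + 5.478 ≥ 16.3`, i.e.
`W_AE_max ≥ 0.5518`. With `W_AE_max = W_IE + W_AE` co-varied, exact
recall is robust for `W_AE ∈ [~0.373, ~0.402]` — asymmetric around the
default 0.40, and much narrower above than below (tested at 0.38–0.40).

## Studies and the synthetic input generator

Input patterns emulate the randomized protocol: a spike count drawn
uniformly from {1, …, 11} (or fixed), positions drawn uniformly without
replacement from the servable slots (t = 10 … 110 ms — attention times
coinciding with a branch SMO maximum; slot 0 is excluded, matching the
11-slot capacity of a 120 ms cycle). The generator emulates only the
protocol's timing statistics; it does not model jitter, failures, or rate
variation of real spike trains, so passing studies demonstrate the
mechanism's arithmetic, not robustness to biological noise.

* **Exact-recall study** (default layout): 100 random trials, and an
  exhaustive mode enumerating all 2^11 − 1 = 2047 nonempty patterns.
  Both give 100 % exact recall under either learning rule.
* **Delta–beta study**: SMO at 1 Hz, input alignment on the
  cumulative-rounded 12 Hz grid (round(i·83.33) → intervals 83/84 ms, 12
  slots per second), branches peaked at the 11 slots after t = 0,
  patterns of exactly 10 spikes over one second. Before running, three
  feasibility inequalities are re-verified by micro-simulation
  (coincidence fires; A alone does not; a potentiated branch recalls its
  slot and only its slot). 100 % exact over 100 trials.
* **Random-phase study**: `n = 48` branches with offsets drawn uniformly
  over one SMO period (continuous offsets; decisions stay on the grid),
  patterns on the canonical slots, phases redrawn per pattern (each trial
  an independent neuron) or fixed once per study — both modes are
  provided because the original protocol is underdetermined. The passive
  factor is rescaled as `u_pass · 12/n` so the summed electrotonic load
  on the soma does not grow with branch count; without this, 48 branches
  would fire the soma on attention EPSPs alone and the variant would
  store nothing.

### Known divergence: random-phase exact-train percentage

Earlier reported values for this variant are ~96 % of spikes and ~85 % of
whole trains correctly recalled. This implementation reproduces the
per-spike figure (≈ 99 %) but not the train-level one (≈ 0 %), and the
discrepancy is structural, not numerical: a potentiated branch crosses
threshold whenever its SMO is within ≈ 0.9 mV of peak at an EPSP arrival,
an excitability window of ~14–16 ms — wider than the 10 ms slot spacing.
A randomly phased learned branch therefore usually also fires one slot
away from its encoded slot during the recall burst, adding extra somatic
spikes to almost every trial. The regular layout escapes this only
through the sub-0.1 mV on-grid margins described above. A train-level
accuracy of ~85 % would require each branch to serve at most one slot
(window < 10 ms), which the printed amplitudes, kernels and thresholds do
not produce under threshold-crossing dynamics; we report the measured
value rather than alter the firing rule. Consequences, both measured:
the exact-train percentage *decreases* with branch count (more learned
branches, more off-slot windows), and the per-spike percentage is
non-monotone at large counts (at ~96 branches, stacked branch-spike
potentials hold the soma above threshold across a following slot and
block its upward crossing). Encoding coverage — the fraction of input
spikes that get encoded at all — is the quantity that grows monotonically
and saturates with branch count.

## Numerical choices

* Alpha kernels are truncated at `δt > 20 ms` (< 0.005 % of peak);
  protocol traces are bit-identical to the untruncated sum within
  0.01 mV, verified against a naive-summation oracle.
* Upward-crossing semantics: a spike requires the potential to have been
  below threshold on the previous grid step; a potential that stays above
  threshold (EPSP plateau, spike kernel) is never double-counted.
* Dendritic refractoriness is one gamma period (10 ms) — irrelevant
  within a single regular cycle (each peak occurs once) but required for
  multi-cycle bursts and active in the random-phase variant.
* Ties and degenerate inputs: empty input trains encode and recall
  nothing (vacuously exact); studies with zero trials flag their
  percentages as NaN; off-grid or out-of-run spike times are rejected.
* Study sizes (100 trials, 1000 random-phase patterns, 2047-pattern
  enumeration) follow the original protocols; each completes in seconds
  on one CPU.

## Limitations

Point-kernel dynamics only: no conductances, cable properties,
dendro-somatic back-propagation, noise currents, or inhibition. The
somatic threshold and hyperpolarization shape are package choices
(configurable) constrained only by the structural requirements above.
Multi-item chaining of cycles via sequences of bursting neurons is out of
scope; the engine supports multi-cycle runs but the studies cover single
cycles.
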