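# phasemem

A simulator of single-neuron memory for temporally precise spike trains:
**time is stored as space**. A grid-aligned input spike train is converted
into a spatial pattern of dendritic-branch spikes by phase-shifted
subthreshold membrane-potential oscillations (SMOs), stored by a one-shot
unsupervised learning rule, and replayed by a plain spike burst — all
within one model neuron.

The package is aimed at computational neuroscientists who want a tested,
scriptable implementation of this theta–gamma phase-coding mechanism: to
reproduce its headline behaviour, to probe its parameter margins, or to
use it as a building block for oscillation-based memory models.

## The model

Three neurons: an **input neuron I** carrying the pattern to be stored, an
**attention neuron A** firing a continuous burst on a fast (gamma, 100 Hz)
grid, and an **extension neuron E** with `n` dendritic branches. Every
branch has a slow (theta, 8.33 Hz) sinusoidal subthreshold oscillation

```
SMO_j(t) = h · sin(0.002 π f (t − j·ph)),      h = 6 mV, f = 8.33 Hz, ph = 10 ms
```

so branch `j` is maximally excitable at a different slot of the fast grid.
Presynaptic spikes deposit alpha-kernel EPSPs on every branch,

```
EPSP(δt) = k · W · δt · g^(−δt/τ),             k = 39, g = 2, τ = 1 ms
```

with fixed input weight `W_IE = 0.15` and initial attention weight
`W_AE = 0.40`. A branch fires a local dendritic spike (alpha kernel with
`k = 40`) when rest + SMO + EPSPs crosses `φ_dend = −48.7 mV` — which, at
these parameters, happens **only** when A and I coincide while the
branch's SMO is at its peak. Dendritic spikes propagate to the soma
without attenuation (`u_B = 1`), EPSPs electrotonically (`u_pass = 0.08`);
the soma fires 1 ms after any dendritic spike, i.e. 2 ms after the input
spike.

Storage uses one of two rules, applied to every branch that fired during
encoding:

* **STDP** — one-shot saturating potentiation `W_AE: 0.40 → 0.55`;
* **SMO amplification** — oscillation amplitude `h: 6.0 → 9.0 mV`.

Either rule lets the attention burst alone re-fire exactly the encoded
branches at exactly the encoded times: recall reproduces the encoding
somatic train. Because `W_IE + W_AE = W_AE_max` and the EPSP kernel is
linear in `W`, a potentiated branch driven by A alone sees the identical
depolarization it saw from A + I during encoding — the structural reason
recall is exact. The simulation runs on a fixed 1 ms grid; the grid is
part of the model definition (see `docs/methods.md`).

## Worked example

```bash
phasemem demo --input 20,50,90 --out demo-out
```

prints

```
input train:          [20, 50, 90]
encoding somatic:     [22, 52, 92]
recall somatic:       [22, 52, 92]
recall vs encoding:   exact
traces and manifest in demo-out/
```

The input spikes at 20, 50, 90 ms fire the branches whose SMO peaks sit at
those slots (dendritic spikes at 21, 51, 91 ms), the soma follows 1 ms
later — the somatic train is the input train shifted by 2 ms. After
learning, the attention burst alone replays the identical somatic train.
`demo-out/` contains per-branch CSV traces (`time_ms, smo_mV, epsp_A_mV,
epsp_I_mV, bsp_mV, net_mV`) and the somatic trace, from which the classic
membrane-potential figures can be re-plotted.

The same protocol from Python:

```python
import phasemem as pm

cfg = pm.default_config()                    # 12 branches, 100 Hz grid, 8.33 Hz SMO
enc, rec = pm.encode_learn_recall(cfg, (20, 50, 90))
assert rec.somatic_spikes == enc.somatic_spikes == (22, 52, 92)

summary = pm.run_exact_recall_study(n_trials=100, seed=1)
print(summary.percent_trains_exact)          # 100.0
```

Other entry points: `phasemem study-exact` (randomized or `--exhaustive`
enumeration of all 2047 patterns), `phasemem study-random-phase` (48
branches with uniformly random SMO phases), `phasemem study-delta-beta`
(1 Hz SMO with a ~12 Hz grid storing one-second trains), and
`phasemem capacity` (storable time-points per cycle, e.g. 12 for
8.33 Hz / 10 ms).

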