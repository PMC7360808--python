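"""Time-stepped simulation engine: encoding, learning, and recall.

One run (:func:`run_phase`) steps the neuron over a discrete 1 ms grid.
At every step, spikes of the attention neuron A and the input neuron I
deposit EPSP kernels on *every* dendritic branch (A with weight ``w_AE``,
I with ``w_IE``; there are no conduction delays).  Each branch sums rest +
SMO + EPSPs + its own past dendritic-spike potentials; an upward crossing
of the dendritic threshold outside the refractory window registers a
dendritic spike.  The soma receives the branch EPSPs passively and the
dendritic spike potentials actively, and fires on upward crossings of its
own threshold, after which the stereotyped action-potential /
hyperpolarization waveform is imposed.

The two unsupervised learning rules operate between phases:

* :func:`apply_stdp` -- one-shot saturating potentiation: every branch that
  fired a dendritic spike during encoding gets ``w_AE`` set to
  ``w_AE_max``;
* :func:`apply_smo_amplification` -- every such branch has its SMO
  amplitude multiplied by ``smo_amp_factor`` (6.0 -> 9.0 mV at defaults).

:func:`encode_learn_recall` chains the full protocol: encode with A + I,
learn, reset the clock, and recall with the attention burst alone.

The 1 ms grid is part of the model, not a numerical convenience: on the
grid, the depolarization of a potentiated branch one slot away from its SMO
peak stays a few hundredths of a millivolt below threshold, while in
continuous time it would cross.  Do not refine the step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Literal, Optional, Sequence, Tuple

import numpy as np

from .kernels import (
    AlphaKernelParams,
    SMOParams,
    SomaParams,
    SynapticWeights,
)
from .patterns import SpikeTrain, as_spike_train

__all__ = [
    "BranchState",
    "NetworkConfig",
    "BranchTrace",
    "SimulationResult",
    "regular_branches",
    "random_phase_branches",
    "default_config",
    "default_attention",
    "servable_slots",
    "run_phase",
    "apply_stdp",
    "apply_smo_amplification",
    "encode_learn_recall",
]

logger = logging.getLogger(__name__)

Mode = Literal["encoding", "recall"]


@dataclass(frozen=True)
class BranchState:
    """One dendritic branch: oscillation, synapses, learning state, spikes."""

    branch_id: int
    smo: SMOParams
    weights: SynapticWeights = SynapticWeights()
    learned: bool = False
    smo_amplified: bool = False
    dendritic_spikes: SpikeTrain = ()
    refractory_until: float = -math.inf


@dataclass(frozen=True)
class NetworkConfig:
    """Full parameter set of one simulated neuron.

    ``branches`` are templates: :func:`run_phase` never mutates them, it
    returns post-run snapshots inside the :class:`SimulationResult`.
    ``attention_train``/``input_train`` may carry inline spike trains loaded
    from a configuration file; when ``attention_train`` is ``None`` the
    attention neuron fires at every multiple of ``gamma_period`` within the
    run, i.e. a continuous burst on the fast grid.
    """

    branches: Tuple[BranchState, ...]
    soma: SomaParams = SomaParams()
    epsp_kernel: AlphaKernelParams = AlphaKernelParams(k=39.0)
    bsp_kernel: AlphaKernelParams = AlphaKernelParams(k=40.0)
    gamma_period: int = 10
    duration: int = 120
    learning_rule: str = "stdp"
    smo_amp_factor: float = 1.5
    dt: int = 1
    dendritic_refractory: int = 10
    kernel_cutoff: int = 20
    seed: int = 0
    attention_train: Optional[SpikeTrain] = None
    input_train: Optional[SpikeTrain] = None

    def __post_init__(self) -> None:
        if self.dt != 1:
            raise ValueError("the 1 ms grid is model-defining; dt must be 1")
        if len(self.branches) == 0:
            raise ValueError("at least one dendritic branch is required")
        if self.gamma_period <= 0 or self.gamma_period % self.dt:
            raise ValueError("gamma_period must be a positive multiple of dt")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.learning_rule not in ("stdp", "smo_amp"):
            raise ValueError(f"unknown learning rule {self.learning_rule!r}")
        if not self.smo_amp_factor > 1:
            raise ValueError("smo_amp_factor must exceed 1")
        if self.dendritic_refractory < 0:
            raise ValueError("dendritic refractory period must be >= 0")


@dataclass(frozen=True)
class BranchTrace:
    """Per-branch potential decomposition over one run (mV per grid step)."""

    smo: np.ndarray
    epsp_A: np.ndarray
    epsp_I: np.ndarray
    bsp: np.ndarray
    net: np.ndarray


@dataclass(frozen=True)
class SimulationResult:
    """Traces and spike trains of one encoding or recall run."""

    mode: Mode
    dt: int
    duration: int
    attention: SpikeTrain
    input_train: SpikeTrain
    somatic_trace: np.ndarray
    somatic_spikes: SpikeTrain
    branch_traces: Dict[int, BranchTrace]
    branches: Tuple[BranchState, ...]

    @property
    def dendritic_spikes(self) -> Dict[int, SpikeTrain]:
        """Dendritic spike train of each branch, keyed by branch id."""
        return {b.branch_id: b.dendritic_spikes for b in self.branches}


def regular_branches(
    n_branches: int = 12,
    j_start: int = -2,
    h: float = 6.0,
    fq: float = 8.33,
    ph: float = 10.0,
    weights: SynapticWeights = SynapticWeights(),
) -> Tuple[BranchState, ...]:
    """Regular phase layout: branches ``j = j_start .. j_start + n - 1``.

    At the defaults this yields 12 branches (j = -2 .. 9) whose SMO maxima
    fall at t ~= 10, 20, ..., 120 ms within one theta cycle, one per slot of
    the 100 Hz attention grid.
    """
    return tuple(
        BranchState(branch_id=i, smo=SMOParams(h=h, fq=fq, ph=ph, j=j_start + i), weights=weights)
        for i in range(n_branches)
    )


def random_phase_branches(
    n_branches: int,
    rng: np.random.Generator,
    h: float = 6.0,
    fq: float = 8.33,
    weights: SynapticWeights = SynapticWeights(),
) -> Tuple[BranchState, ...]:
    """Branches with phase offsets drawn uniformly over one SMO period.

    Offsets are continuous; spike decisions still happen on the 1 ms grid.
    """
    period = 1000.0 / fq
    offsets = rng.uniform(0.0, period, size=n_branches)
    return tuple(
        BranchState(branch_id=i, smo=SMOParams.with_offset(float(off), h=h, fq=fq), weights=weights)
        for i, off in enumerate(offsets)
    )


def default_config(**overrides) -> NetworkConfig:
    """The reference configuration: 12 regular branches, 100 Hz grid, 8.33 Hz SMO."""
    kwargs = dict(branches=regular_branches())
    kwargs.update(overrides)
    return NetworkConfig(**kwargs)


def default_attention(config: NetworkConfig) -> SpikeTrain:
    """Attention burst used when no explicit train is configured.

    A continuous sequence of spikes at every multiple of ``gamma_period``
    within the run: 12 spikes at t = 0, 10, ..., 110 ms at the defaults.
    """
    if config.attention_train is not None:
        return config.attention_train
    return tuple(range(0, config.duration, config.gamma_period))


def servable_slots(config: NetworkConfig, attention: Optional[SpikeTrain] = None) -> SpikeTrain:
    """Grid times at which an attention spike coincides with a branch SMO peak.

    Only these slots can be stored: an input spike anywhere else finds no
    branch near its excitability maximum.  Peaks are taken as each branch's
    first SMO maximum at ``t >= 0`` (no periodic wrap-around), matched to
    attention times within half a grid step.  At the defaults this yields
    the 11 slots t = 10, 20, ..., 110 ms.
    """
    attention = default_attention(config) if attention is None else attention
    slots = []
    tol = 0.5 * config.dt + 1e-9
    for s in attention:
        for b in config.branches:
            period = b.smo.period_ms
            quarter = period / 4.0
            peak = b.smo.offset_ms + quarter
            while peak < 0:
                peak += period
            while peak < config.duration:
                if abs(s - peak) <= tol:
                    slots.append(s)
                    break
                peak += period
            if slots and slots[-1] == s:
                break
    return tuple(sorted(set(slots)))


def _kernel_array(p: AlphaKernelParams, cutoff: int) -> np.ndarray:
    dt = np.arange(cutoff + 1, dtype=float)
    return p.k * dt * p.g ** (-dt / p.tau)


def _alpha_trace(train: SpikeTrain, kernel: np.ndarray, T: int) -> np.ndarray:
    """Unit-weight alpha-kernel trace of a spike train over T grid steps."""
    ind = np.zeros(T)
    for t in train:
        ind[t] = 1.0
    if not train:
        return ind
    return np.convolve(ind, kernel)[:T]


def _validate_train(train: SpikeTrain, config: NetworkConfig, name: str) -> SpikeTrain:
    train = as_spike_train(train)
    for t in train:
        if t % config.dt:
            raise ValueError(f"{name} spike at {t} ms is off the {config.dt} ms grid")
        if t >= config.duration:
            raise ValueError(
                f"{name} spike at {t} ms falls outside the {config.duration} ms run"
            )
    return train


def run_phase(
    config: NetworkConfig,
    attention: SpikeTrain,
    input_train: SpikeTrain,
    mode: Mode,
) -> SimulationResult:
    """Run one encoding or recall phase over the configured duration.

    Parameters
    ----------
    config : NetworkConfig
        Parameter set; ``config.branches`` provides the branch templates.
    attention, input_train : sequence of int
        Grid-aligned spike times of neurons A and I.  During recall the
        input neuron is silent, so a non-empty ``input_train`` is rejected.
    mode : {"encoding", "recall"}

    Returns
    -------
    SimulationResult
        Complete potential traces (somatic and per-branch decompositions),
        dendritic and somatic spike trains, and post-run branch snapshots.
    """
    if mode not in ("encoding", "recall"):
        raise ValueError(f"unknown mode {mode!r}")
    attention = _validate_train(attention, config, "attention")
    input_train = _validate_train(input_train, config, "input")
    if mode == "recall" and input_train:
        raise ValueError("the input neuron is silent during recall")

    T = config.duration
    soma = config.soma
    kern_e = _kernel_array(config.epsp_kernel, config.kernel_cutoff)
    kern_b = _kernel_array(config.bsp_kernel, config.kernel_cutoff)
    eA = _alpha_trace(attention, kern_e, T)  # unit-weight EPSP traces
    eI = _alpha_trace(input_train, kern_e, T)
    t_axis = np.arange(T, dtype=float)

    soma_epsp = np.zeros(T)
    soma_bsp = np.zeros(T)
    branch_traces: Dict[int, BranchTrace] = {}
    post_branches = []

    for b in config.branches:
        smo_tr = b.smo.h * np.sin(
            0.002 * math.pi * b.smo.fq * (t_axis - b.smo.offset_ms)
        )
        epsp_A = b.weights.w_AE * eA
        epsp_I = b.weights.w_IE * eI
        base = soma.resting + smo_tr + epsp_A + epsp_I
        bsp = np.zeros(T)
        spikes = []
        prev_above = False
        refr_until = -math.inf
        for t in range(T):
            above = base[t] + bsp[t] >= soma.phi_dend
            if above and not prev_above and t >= refr_until:
                spikes.append(t)
                refr_until = t + config.dendritic_refractory
                n = min(config.kernel_cutoff, T - 1 - t)
                bsp[t : t + n + 1] += kern_b[: n + 1]
            prev_above = above
        soma_epsp += epsp_A + epsp_I
        soma_bsp += bsp
        branch_traces[b.branch_id] = BranchTrace(
            smo=smo_tr, epsp_A=epsp_A, epsp_I=epsp_I, bsp=bsp, net=base + bsp
        )
        post_branches.append(
            replace(b, dendritic_spikes=tuple(spikes), refractory_until=refr_until)
        )

    contrib = soma.u_pass * soma_epsp + soma.u_B * soma_bsp
    trace = np.empty(T)
    somatic_spikes = []
    last_spike: Optional[int] = None
    prev_above = False
    for t in range(T):
        if last_spike is not None and t - last_spike < soma.spike_width:
            pot = soma.spike_peak
        else:
            hyper = 0.0
            if last_spike is not None:
                hyper = (soma.hyper_depth - soma.resting) * math.exp(
                    -(t - last_spike - soma.spike_width) / soma.hyper_tau
                )
            pot = soma.resting + hyper + contrib[t]
        above = pot >= soma.threshold
        if above and not prev_above:
            somatic_spikes.append(t)
            last_spike = t
            pot = soma.spike_peak
        trace[t] = pot
        prev_above = above

    n_dend = sum(len(b.dendritic_spikes) for b in post_branches)
    logger.info(
        "%s: %d attention / %d input spikes -> %d dendritic, %d somatic spikes",
        mode,
        len(attention),
        len(input_train),
        n_dend,
        len(somatic_spikes),
    )
    return SimulationResult(
        mode=mode,
        dt=config.dt,
        duration=T,
        attention=attention,
        input_train=input_train,
        somatic_trace=trace,
        somatic_spikes=tuple(somatic_spikes),
        branch_traces=branch_traces,
        branches=tuple(post_branches),
    )


def _require_encoding(result: SimulationResult, rule: str) -> None:
    if result.mode != "encoding":
        raise ValueError(f"{rule} must be applied to an encoding result, got {result.mode!r}")


def apply_stdp(result: SimulationResult, config: NetworkConfig) -> Tuple[BranchState, ...]:
    """One-shot saturating potentiation of the attention synapse.

    Every branch that fired at least one dendritic spike during encoding
    has ``w_AE`` set to ``w_AE_max`` and is flagged ``learned``; all other
    branches, and every ``w_IE``, stay untouched.  Somatic spikes never
    modify weights.  Spike records are cleared so the returned branches are
    fresh templates for the recall run.
    """
    _require_encoding(result, "STDP")
    updated = []
    for b in result.branches:
        if b.dendritic_spikes:
            b = replace(
                b,
                weights=replace(b.weights, w_AE=b.weights.w_AE_max),
                learned=True,
            )
        updated.append(replace(b, dendritic_spikes=(), refractory_until=-math.inf))
    return tuple(updated)


def apply_smo_amplification(
    result: SimulationResult, config: NetworkConfig
) -> Tuple[BranchState, ...]:
    """Amplitude learning: scale the SMO of every spiking branch.

    Branches with at least one encoding dendritic spike get their
    oscillation amplitude multiplied by ``config.smo_amp_factor`` (6.0 ->
    9.0 mV at the defaults); synaptic weights are untouched.
    """
    _require_encoding(result, "SMO amplification")
    updated = []
    for b in result.branches:
        if b.dendritic_spikes:
            b = replace(
                b,
                smo=replace(b.smo, h=b.smo.h * config.smo_amp_factor),
                smo_amplified=True,
            )
        updated.append(replace(b, dendritic_spikes=(), refractory_until=-math.inf))
    return tuple(updated)


_LEARNING_RULES = {"stdp": apply_stdp, "smo_amp": apply_smo_amplification}


def encode_learn_recall(
    config: NetworkConfig,
    input_train: SpikeTrain,
    learning_rule: Optional[str] = None,
) -> Tuple[SimulationResult, SimulationResult]:
    """Full protocol: encode with A + I, learn, then recall with A alone.

    The recall clock restarts at t = 0 with the identical attention burst
    and identical SMO phases, so encoding and recall trains are directly
    comparable at absolute times.  The run must span at least one full SMO
    cycle so that every branch sees an attention spike near its peak.

    Returns the ``(encoding, recall)`` result pair.
    """
    rule = config.learning_rule if learning_rule is None else learning_rule
    if rule not in _LEARNING_RULES:
        raise ValueError(f"unknown learning rule {rule!r}")
    period = config.branches[0].smo.period_ms
    if config.duration < period - config.gamma_period:
        raise ValueError(
            f"duration {config.duration} ms is shorter than one SMO cycle ({period:.1f} ms)"
        )
    attention = default_attention(config)
    encoding = run_phase(config, attention, input_train, "encoding")
    learned = _LEARNING_RULES[rule](encoding, config)
    n_learned = sum(b.learned or b.smo_amplified for b in learned)
    logger.info("learning (%s): %d of %d branches potentiated", rule, n_learned, len(learned))
    recall_config = replace(config, branches=learned)
    recall = run_phase(recall_config, attention, (), "recall")
    return encoding, recall
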