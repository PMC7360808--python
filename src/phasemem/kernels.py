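"""Membrane-potential primitives for a phase-coding dendritic memory neuron.

The model neuron converts the *timing* of grid-aligned input spikes into a
*spatial* pattern of dendritic-branch spikes.  Each dendritic branch carries
a sinusoidal subthreshold membrane-potential oscillation (SMO) with its own
phase offset, so every branch is maximally excitable in a different slot of
the fast (gamma) input grid.  A branch fires a local dendritic spike only
when excitatory postsynaptic potentials (EPSPs) from the attention neuron A
and the input neuron I arrive while its SMO is at (or within a fraction of
a millivolt of) its peak.

This module holds the pure, stateless potential arithmetic:

* :func:`smo_potential` -- the phase-shifted sine oscillation,
  ``h * sin(0.002 * pi * fq * (t - j*ph))``, an offset around rest;
* :func:`alpha_epsp` / :func:`branch_spike_potential` -- alpha-function
  kernels ``k * W * dt * g**(-dt/tau)`` for synaptic and dendritic-spike
  depolarizations;
* :func:`branch_net_potential` -- the summed absolute branch potential;
* :func:`soma_contribution` / :func:`soma_spike_waveform` -- passive/active
  propagation to the soma and the stereotyped action-potential shape.

Everything here is evaluated on (or between) the 1 ms simulation grid used
by :mod:`phasemem.simulate`; the grid itself is part of the model definition
(see ``docs/methods.md``), but these functions are total over real time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

__all__ = [
    "SMOParams",
    "AlphaKernelParams",
    "SomaParams",
    "SynapticWeights",
    "smo_potential",
    "alpha_epsp",
    "branch_spike_potential",
    "branch_net_potential",
    "soma_contribution",
    "soma_spike_waveform",
]

#: Angular-frequency conversion used by the SMO sine: radians per (Hz * ms).
#: ``0.002 * pi * fq * t`` equals ``2 * pi * fq * (t / 1000 ms)``.
_RAD_PER_HZ_MS = 0.002 * math.pi


@dataclass(frozen=True)
class SMOParams:
    """Subthreshold membrane-potential oscillation of one dendritic branch.

    Parameters
    ----------
    h : float
        Oscillation amplitude in mV (default 6.0 mV; raised to 9.0 mV by the
        amplitude-learning rule).
    fq : float
        Oscillation frequency in Hz (default 8.33 Hz, theta band).
    ph : float
        Phase step size in ms between neighbouring branches (default 10 ms,
        one gamma period).
    j : float
        Phase index; the branch's phase offset is ``j * ph`` ms.  Integer in
        the regular layout (j = -2 .. 9 for 12 branches), but real-valued
        offsets are allowed for the random-phase variant.
    """

    h: float = 6.0
    fq: float = 8.33
    ph: float = 10.0
    j: float = 0.0

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError(f"SMO amplitude h must be > 0, got {self.h}")
        if not self.fq > 0:
            raise ValueError(f"SMO frequency fq must be > 0, got {self.fq}")
        if not self.ph > 0:
            raise ValueError(f"SMO phase step ph must be > 0, got {self.ph}")

    @property
    def offset_ms(self) -> float:
        """Phase offset of this branch in ms (``j * ph``)."""
        return self.j * self.ph

    @property
    def period_ms(self) -> float:
        """Oscillation period in ms (``1000 / fq``)."""
        return 1000.0 / self.fq

    @classmethod
    def with_offset(cls, offset_ms: float, h: float = 6.0, fq: float = 8.33) -> "SMOParams":
        """Build parameters from an explicit (possibly fractional) phase offset."""
        return cls(h=h, fq=fq, ph=1.0, j=offset_ms)


@dataclass(frozen=True)
class AlphaKernelParams:
    """Alpha-function kernel ``k * dt * g**(-dt/tau)`` (times a weight for EPSPs).

    With the default ``g = 2, tau = 1 ms`` the kernel is exactly equal at
    ``dt = 1`` and ``dt = 2`` ms (both ``k/2``), which is also its maximum on
    the 1 ms grid; it is zero at onset and decays geometrically afterwards.
    """

    k: float
    g: float = 2.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"kernel scale k must be > 0, got {self.k}")
        if not self.g > 1:
            raise ValueError(f"kernel decay base g must be > 1, got {self.g}")
        if not self.tau > 0:
            raise ValueError(f"kernel time constant tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class SomaParams:
    """Somatic and dendritic threshold/propagation parameters.

    Attributes
    ----------
    resting : float
        Resting membrane potential in mV.
    phi_dend : float
        Dendritic spike threshold in mV (absolute).
    threshold : float
        Somatic spike threshold S in mV (absolute).
    u_pass : float
        Passive (electrotonic) attenuation factor for dendritic EPSPs
        propagating to the soma.
    u_B : float
        Active propagation factor for dendritic spike potentials (1.0 means
        no attenuation).
    spike_peak : float
        Potential imposed during a somatic action potential, in mV.
    spike_width : float
        Duration of the action-potential plateau, in ms.
    hyper_depth : float
        Potential floor immediately after the action potential, in mV.
    hyper_tau : float
        Exponential recovery time constant from ``hyper_depth`` back toward
        rest, in ms.
    """

    resting: float = -65.0
    phi_dend: float = -48.7
    threshold: float = -50.0
    u_pass: float = 0.08
    u_B: float = 1.0
    spike_peak: float = 30.0
    spike_width: float = 1.0
    hyper_depth: float = -70.0
    hyper_tau: float = 3.0

    def __post_init__(self) -> None:
        if not self.resting < self.phi_dend:
            raise ValueError("resting potential must lie below the dendritic threshold")
        if not self.resting < self.threshold < self.spike_peak:
            raise ValueError("somatic threshold must lie between rest and spike peak")
        if not 0 < self.u_pass < self.u_B <= 1:
            raise ValueError("propagation factors must satisfy 0 < u_pass < u_B <= 1")
        if not self.spike_width >= 1:
            raise ValueError("somatic spike width must be >= 1 ms")
        if not self.hyper_tau > 0:
            raise ValueError("hyperpolarization time constant must be > 0")

    @property
    def dend_gap(self) -> float:
        """Depolarization (mV above rest) needed to reach the dendritic threshold."""
        return self.phi_dend - self.resting


@dataclass(frozen=True)
class SynapticWeights:
    """Synaptic weights of one dendritic branch.

    ``w_IE`` (input -> branch) is fixed; ``w_AE`` (attention -> branch)
    starts at 0.40 and is potentiated to ``w_AE_max`` = 0.55 by the one-shot
    STDP rule.  At the defaults ``w_IE + w_AE == w_AE_max`` exactly; because
    the EPSP kernel is linear in the weight, a potentiated branch driven by
    the attention neuron alone then reproduces, sample for sample, the
    depolarization it received from the coincident A+I input during
    encoding.  That identity is what makes recall exact.
    """

    w_IE: float = 0.15
    w_AE: float = 0.40
    w_AE_max: float = 0.55

    def __post_init__(self) -> None:
        if not self.w_IE > 0:
            raise ValueError(f"w_IE must be > 0, got {self.w_IE}")
        if not self.w_AE <= self.w_AE_max:
            raise ValueError(
                f"w_AE ({self.w_AE}) must not exceed its ceiling w_AE_max ({self.w_AE_max})"
            )


def smo_potential(t: float, p: SMOParams) -> float:
    """Oscillation offset (mV, relative to rest) of a branch at time ``t`` ms.

    Evaluates ``h * sin(0.002 * pi * fq * (t - j*ph))``.  Bounded in
    ``[-h, +h]`` and periodic with period ``1000/fq`` ms.
    """
    return p.h * math.sin(_RAD_PER_HZ_MS * p.fq * (t - p.j * p.ph))


def alpha_epsp(dt: float, W: float, p: AlphaKernelParams) -> float:
    """EPSP depolarization (mV) at ``dt`` ms after a presynaptic spike.

    ``k * W * dt * g**(-dt/tau)``: zero at onset, single-peaked, decaying to
    zero.  ``dt < 0`` raises -- EPSPs have no acausal part, so a negative
    ``dt`` always indicates a caller bug.
    """
    if dt < 0:
        raise ValueError(f"EPSP evaluated at negative dt ({dt} ms)")
    return p.k * W * dt * p.g ** (-dt / p.tau)


def branch_spike_potential(dt: float, p: AlphaKernelParams) -> float:
    """Dendritic-spike depolarization (mV) at ``dt`` ms after spike onset."""
    if dt < 0:
        raise ValueError(f"branch spike potential evaluated at negative dt ({dt} ms)")
    return p.k * dt * p.g ** (-dt / p.tau)


def branch_net_potential(
    t: float,
    epsp_events: Iterable[Tuple[float, float]],
    spike_onsets: Iterable[float],
    smo: SMOParams,
    epsp_kernel: AlphaKernelParams,
    bsp_kernel: AlphaKernelParams,
    resting: float = -65.0,
    cutoff: float = 20.0,
) -> float:
    """Absolute net potential (mV) of one branch at time ``t``.

    Sums rest, the branch SMO, all active EPSPs and all active dendritic
    spike potentials.  ``epsp_events`` is an iterable of ``(onset_ms,
    weight)`` pairs; ``spike_onsets`` lists dendritic spike times.  Kernels
    are truncated to zero beyond ``cutoff`` ms after onset (where they are
    below 0.005 % of their peak); event onsets must not lie in the future.
    """
    total = resting + smo_potential(t, smo)
    for onset, w in epsp_events:
        dt = t - onset
        if dt < 0:
            raise ValueError(f"EPSP onset {onset} ms lies after evaluation time {t} ms")
        if dt <= cutoff:
            total += alpha_epsp(dt, w, epsp_kernel)
    for onset in spike_onsets:
        dt = t - onset
        if dt < 0:
            raise ValueError(f"spike onset {onset} ms lies after evaluation time {t} ms")
        if dt <= cutoff:
            total += branch_spike_potential(dt, bsp_kernel)
    return total


def soma_contribution(epsp_sum: float, bsp_sum: float, p: SomaParams) -> float:
    """Somatic depolarization (mV) contributed by one branch.

    EPSPs reach the soma electrotonically (scaled by ``u_pass``); dendritic
    spike potentials propagate actively (scaled by ``u_B``).  Branch SMOs do
    not contribute: their phase distribution is assumed to cancel at the
    soma.  The engine sums this quantity over all branches on top of rest.
    """
    return epsp_sum * p.u_pass + bsp_sum * p.u_B


def soma_spike_waveform(dt: float, p: SomaParams) -> float:
    """Stereotyped somatic action-potential shape (absolute mV).

    For ``dt < spike_width`` the potential sits at ``spike_peak``; it then
    drops to ``hyper_depth`` and relaxes exponentially back to rest with
    time constant ``hyper_tau``.
    """
    if dt < 0:
        raise ValueError(f"somatic waveform evaluated at negative dt ({dt} ms)")
    if dt < p.spike_width:
        return p.spike_peak
    return p.resting + (p.hyper_depth - p.resting) * math.exp(
        -(dt - p.spike_width) / p.hyper_tau
    )
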