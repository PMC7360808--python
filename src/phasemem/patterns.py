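"""Spike-train containers, synthetic input generation, and comparison metrics.

Spike trains are plain tuples of strictly increasing, non-negative integer
times in ms on the simulation grid (:func:`as_spike_train` validates and
normalises).  :func:`make_random_input_pattern` emulates the randomized
study protocol: a random number of up to 11 input spikes placed at random
servable slots of the attention grid within one SMO cycle.
:func:`compare_trains` scores a recalled somatic train against the encoding
reference, spike by spike.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "SpikeTrain",
    "as_spike_train",
    "TrialOutcome",
    "make_attention_train",
    "aligned_grid",
    "make_random_input_pattern",
    "compare_trains",
    "write_spike_trains",
    "read_spike_trains",
]

#: A spike train: sorted tuple of integer spike times in ms.
SpikeTrain = Tuple[int, ...]


def as_spike_train(times: Iterable[Union[int, float]]) -> SpikeTrain:
    """Validate and normalise spike times into a sorted integer tuple.

    Times must be non-negative integers (integral floats are accepted) with
    no duplicates.
    """
    out = []
    for t in times:
        if isinstance(t, float):
            if not t.is_integer():
                raise ValueError(f"spike time {t} is not an integer number of ms")
            t = int(t)
        elif isinstance(t, (np.integer,)):
            t = int(t)
        elif not isinstance(t, int) or isinstance(t, bool):
            raise TypeError(f"spike time {t!r} is not an integer")
        if t < 0:
            raise ValueError(f"spike time {t} is negative")
        out.append(t)
    if len(set(out)) != len(out):
        raise ValueError("duplicate spike times are forbidden")
    return tuple(sorted(out))


@dataclass(frozen=True)
class TrialOutcome:
    """Comparison of a recalled somatic train with its encoding reference.

    ``n_hits`` counts recalled spikes matched one-to-one to reference
    spikes; ``n_misses`` reference spikes left unmatched; ``n_extras``
    recalled spikes with no reference partner.  ``exact`` holds when
    nothing is missing and nothing is spurious.
    """

    n_input_spikes: int
    n_hits: int
    n_misses: int
    n_extras: int

    @property
    def exact(self) -> bool:
        return self.n_misses == 0 and self.n_extras == 0

    @property
    def n_reference(self) -> int:
        """Number of reference (encoding somatic) spikes."""
        return self.n_hits + self.n_misses


def make_attention_train(
    gamma_period: int, n_cycles: int = 1, cycle_length: int = 120
) -> SpikeTrain:
    """Regular attention burst covering ``n_cycles`` full SMO cycles.

    Spikes at 0, ``gamma_period``, 2 * ``gamma_period``, ...; the number of
    spikes is ``floor(n_cycles * cycle_length / gamma_period)``, so a
    period that does not divide the cycle (e.g. the 83 ms grid-rounded
    12 Hz beta period in a 1000 ms cycle) still yields a full burst (12
    spikes in that example).
    """
    if gamma_period <= 0:
        raise ValueError("gamma_period must be positive")
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    n = int(n_cycles * cycle_length // gamma_period)
    return tuple(i * gamma_period for i in range(n))


def aligned_grid(rate_hz: float, duration_ms: int) -> SpikeTrain:
    """Grid-rounded regular train at ``rate_hz`` over ``duration_ms``.

    Each spike time is ``round(i * 1000 / rate_hz)``, i.e. a
    cumulative-rounding schedule that keeps long-run timing exact on the
    1 ms grid: at 12 Hz the intervals alternate between 83 and 84 ms and 12
    spikes span one second.
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    times = []
    i = 0
    while True:
        t = round(i * 1000.0 / rate_hz)
        if t >= duration_ms:
            break
        times.append(int(t))
        i += 1
    return tuple(times)


def make_random_input_pattern(
    rng: Union[int, np.random.Generator],
    servable_slots: Sequence[int],
    max_spikes: int = 11,
    n_spikes: Optional[int] = None,
) -> SpikeTrain:
    """Draw one random input pattern on the servable attention slots.

    The spike count is drawn uniformly from ``{1, ..., max_spikes}``
    (or fixed to ``n_spikes``), then positions are drawn uniformly without
    replacement from ``servable_slots``.  Reproducible for a given seed or
    generator state.
    """
    if len(servable_slots) == 0:
        raise ValueError("servable_slots must not be empty")
    if max_spikes > len(servable_slots):
        raise ValueError(
            f"max_spikes ({max_spikes}) exceeds the number of servable slots "
            f"({len(servable_slots)})"
        )
    if max_spikes < 1:
        raise ValueError("max_spikes must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if n_spikes is None:
        n_spikes = int(rng.integers(1, max_spikes + 1))
    elif not 1 <= n_spikes <= len(servable_slots):
        raise ValueError(f"n_spikes ({n_spikes}) out of range for the slot list")
    chosen = rng.choice(len(servable_slots), size=n_spikes, replace=False)
    return as_spike_train(servable_slots[i] for i in chosen)


def compare_trains(
    reference: Sequence[int],
    recalled: Sequence[int],
    tolerance: int = 0,
    n_input_spikes: Optional[int] = None,
) -> TrialOutcome:
    """Score a recalled spike train against a reference train.

    Spikes are matched greedily in time order, one-to-one: a recalled spike
    within ``tolerance`` ms of the earliest unmatched reference spike is a
    hit.  The default tolerance is 0 ms (exact grid equality) because
    encoding and recall share the same clock and grid.  Unmatched reference
    spikes are misses, unmatched recalled spikes extras.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    ref = as_spike_train(reference)
    rec = as_spike_train(recalled)
    hits = 0
    i = j = 0
    while i < len(ref) and j < len(rec):
        if abs(ref[i] - rec[j]) <= tolerance:
            hits += 1
            i += 1
            j += 1
        elif rec[j] < ref[i]:
            j += 1
        else:
            i += 1
    return TrialOutcome(
        n_input_spikes=len(ref) if n_input_spikes is None else n_input_spikes,
        n_hits=hits,
        n_misses=len(ref) - hits,
        n_extras=len(rec) - hits,
    )


def write_spike_trains(path: Union[str, Path], trains: Dict[str, Sequence[int]]) -> None:
    """Write spike trains to a two-column CSV (``neuron_id,time_ms``)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["neuron_id", "time_ms"])
        for name, train in trains.items():
            for t in as_spike_train(train):
                writer.writerow([name, t])


def read_spike_trains(path: Union[str, Path]) -> Dict[str, SpikeTrain]:
    """Read spike trains from the two-column CSV written by :func:`write_spike_trains`."""
    path = Path(path)
    grouped: Dict[str, list] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["neuron_id", "time_ms"]:
            raise ValueError(f"unexpected header {header!r} in {path}")
        for name, t in reader:
            grouped.setdefault(name, []).append(int(t))
    return {name: as_spike_train(ts) for name, ts in grouped.items()}
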