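"""Batch studies: exact-recall trials, random-phase variant, capacity relations.

Each study runs the full encode-learn-recall protocol over many input
patterns and aggregates two quantities:

* ``percent_spikes_recalled`` -- hits divided by the total number of
  encoding somatic spikes, over all trials (extras are reported per trial
  but do not subtract from hits);
* ``percent_trains_exact`` -- share of trials whose recalled somatic train
  matches the encoding train completely (no misses, no extras).

The reference for every comparison is the *encoding somatic train*: the
model stores and recalls the somatic response it produced, which at the
default parameters equals the input train shifted by 2 ms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kernels import SMOParams
from .patterns import (
    SpikeTrain,
    TrialOutcome,
    aligned_grid,
    compare_trains,
    make_random_input_pattern,
)
from .simulate import (
    BranchState,
    NetworkConfig,
    default_attention,
    default_config,
    encode_learn_recall,
    random_phase_branches,
    run_phase,
    servable_slots,
)

__all__ = [
    "StudySummary",
    "storable_timepoints",
    "run_exact_recall_study",
    "run_random_phase_study",
    "run_delta_beta_study",
    "delta_beta_config",
    "check_feasibility",
]


@dataclass(frozen=True)
class StudySummary:
    """Aggregated outcome of a batch study.

    Percentages are ``nan`` (and ``valid`` is False) when the study ran no
    trials or produced no reference spikes; both can always be recomputed
    from the per-trial ``outcomes``.
    """

    n_trials: int
    percent_spikes_recalled: float
    percent_trains_exact: float
    outcomes: Tuple[TrialOutcome, ...]
    config: Dict
    seed: Optional[int]
    feasibility: Optional[Dict[str, bool]] = None

    @property
    def valid(self) -> bool:
        return self.n_trials > 0 and not math.isnan(self.percent_spikes_recalled)

    @property
    def n_exact(self) -> int:
        return sum(o.exact for o in self.outcomes)

    def to_frame(self) -> pd.DataFrame:
        """Per-trial table (one row per pattern)."""
        return pd.DataFrame(
            {
                "trial": range(len(self.outcomes)),
                "n_input_spikes": [o.n_input_spikes for o in self.outcomes],
                "n_reference_spikes": [o.n_reference for o in self.outcomes],
                "n_hits": [o.n_hits for o in self.outcomes],
                "n_misses": [o.n_misses for o in self.outcomes],
                "n_extras": [o.n_extras for o in self.outcomes],
                "exact": [o.exact for o in self.outcomes],
            }
        )

    def to_dict(self) -> Dict:
        return {
            "n_trials": self.n_trials,
            "n_exact": self.n_exact,
            "percent_spikes_recalled": self.percent_spikes_recalled,
            "percent_trains_exact": self.percent_trains_exact,
            "seed": self.seed,
            "feasibility": self.feasibility,
            "config": self.config,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def storable_timepoints(slow_freq: float, fast_period: float) -> int:
    """Number of storable time-points for a slow/fast frequency pairing.

    ``floor((1000 / slow_freq) / fast_period)``: how many fast-grid slots
    fit into one slow-oscillation cycle.  12 for the default 8.33 Hz SMO on
    the 10 ms attention grid, and likewise 12 for a 1 Hz SMO on an
    83.33 ms (12 Hz) grid.
    """
    if slow_freq <= 0:
        raise ValueError("slow_freq must be positive")
    if fast_period <= 0:
        raise ValueError("fast_period must be positive")
    return int(math.floor((1000.0 / slow_freq) / fast_period + 1e-9))


def _summarize(
    outcomes: Sequence[TrialOutcome],
    config: NetworkConfig,
    seed: Optional[int],
    feasibility: Optional[Dict[str, bool]] = None,
) -> StudySummary:
    from .readwrite import config_to_dict  # local import avoids a cycle

    n = len(outcomes)
    total_ref = sum(o.n_reference for o in outcomes)
    total_hits = sum(o.n_hits for o in outcomes)
    pct_spikes = 100.0 * total_hits / total_ref if total_ref else float("nan")
    pct_exact = 100.0 * sum(o.exact for o in outcomes) / n if n else float("nan")
    return StudySummary(
        n_trials=n,
        percent_spikes_recalled=pct_spikes,
        percent_trains_exact=pct_exact,
        outcomes=tuple(outcomes),
        config=config_to_dict(config),
        seed=seed,
        feasibility=feasibility,
    )


def _run_trial(config: NetworkConfig, pattern: SpikeTrain) -> TrialOutcome:
    encoding, recall = encode_learn_recall(config, pattern)
    return compare_trains(
        encoding.somatic_spikes, recall.somatic_spikes, n_input_spikes=len(pattern)
    )


def run_exact_recall_study(
    config: Optional[NetworkConfig] = None,
    n_trials: int = 100,
    seed: int = 0,
    exhaustive: bool = False,
    max_spikes: Optional[int] = None,
) -> StudySummary:
    """Randomized (or exhaustive) exact-recall study at a regular phase layout.

    Draws ``n_trials`` independent random input patterns on the servable
    slots, runs encode-learn-recall on each, and aggregates recall
    fidelity.  With ``exhaustive=True`` every nonempty subset of the
    servable slots is enumerated instead (2^11 - 1 = 2047 patterns at the
    defaults), superseding sampling.
    """
    config = default_config() if config is None else config
    slots = servable_slots(config)
    if max_spikes is None:
        max_spikes = len(slots)
    outcomes = []
    if exhaustive:
        for r in range(1, max_spikes + 1):
            for combo in combinations(slots, r):
                outcomes.append(_run_trial(config, combo))
        seed_used: Optional[int] = None
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_trials):
            pattern = make_random_input_pattern(rng, slots, max_spikes=max_spikes)
            outcomes.append(_run_trial(config, pattern))
        seed_used = seed
    return _summarize(outcomes, config, seed_used)


def run_random_phase_study(
    config: Optional[NetworkConfig] = None,
    n_branches: int = 48,
    n_patterns: int = 1000,
    seed: int = 0,
    redraw_phases: bool = True,
) -> StudySummary:
    """Random-phase variant: branch phases drawn uniformly over one SMO period.

    The regular one-peak-per-slot layout is replaced by ``n_branches``
    branches with uniformly random (continuous) phase offsets; input
    patterns are still drawn on the canonical servable slots of the regular
    layout.  With ``redraw_phases=True`` (default) every pattern gets a
    fresh phase draw -- each trial is an independent neuron; with
    ``redraw_phases=False`` one phase set is drawn for the whole study.

    The passive propagation factor is rescaled by ``len(base.branches) /
    n_branches`` so that the summed electrotonic load on the soma does not
    grow with the branch count.  Without this, many-branch neurons would
    fire somatically on the attention EPSPs alone, violating the model
    requirement that passive dendritic EPSPs cannot trigger somatic spikes
    (while a single dendritic spike must).
    """
    base = default_config() if config is None else config
    slots = servable_slots(default_config()) if config is None else servable_slots(base)
    base = replace(
        base,
        soma=replace(base.soma, u_pass=base.soma.u_pass * len(base.branches) / n_branches),
    )
    template = base.branches[0]
    h, fq = template.smo.h, template.smo.fq
    weights = template.weights
    rng = np.random.default_rng(seed)
    outcomes = []
    branches: Optional[Tuple[BranchState, ...]] = None
    for _ in range(n_patterns):
        if branches is None or redraw_phases:
            branches = random_phase_branches(n_branches, rng, h=h, fq=fq, weights=weights)
        trial_config = replace(base, branches=branches)
        pattern = make_random_input_pattern(rng, slots, max_spikes=len(slots))
        outcomes.append(_run_trial(trial_config, pattern))
    return _summarize(outcomes, replace(base, branches=branches), seed)


def delta_beta_config(
    slow_freq: float = 1.0,
    fast_rate: float = 12.0,
    duration: int = 1000,
    **overrides,
) -> NetworkConfig:
    """Rescaled configuration: 1 Hz (delta) SMO with a ~12 Hz (beta) grid.

    The fast grid is the cumulative-rounding schedule of ``fast_rate`` on
    the 1 ms grid (intervals alternate 83/84 ms at 12 Hz).  One branch is
    placed with its SMO maximum at each grid slot after t = 0, mirroring
    the servable-slot layout of the default configuration.
    """
    grid = aligned_grid(fast_rate, duration)
    quarter = (1000.0 / slow_freq) / 4.0
    branches = tuple(
        BranchState(branch_id=i, smo=SMOParams.with_offset(s - quarter, fq=slow_freq))
        for i, s in enumerate(grid[1:])
    )
    kwargs = dict(
        branches=branches,
        gamma_period=int(round(1000.0 / fast_rate)),
        duration=duration,
        attention_train=grid,
    )
    kwargs.update(overrides)
    return NetworkConfig(**kwargs)


def check_feasibility(config: NetworkConfig) -> Dict[str, bool]:
    """Verify the three firing inequalities of a (rescaled) configuration.

    1. ``coincidence_fires`` -- coincident A + I input at a branch SMO peak
       triggers a dendritic spike (and hence a somatic spike);
    2. ``attention_alone_silent`` -- an unpotentiated neuron driven by the
       attention burst alone stays silent everywhere;
    3. ``recall_selective`` -- after learning a single spike, the attention
       burst recalls exactly the encoding somatic train (the potentiated
       branch fires at its peak slot only).

    Each check is a direct micro-simulation of the configured neuron.
    """
    attention = default_attention(config)
    slots = servable_slots(config, attention)
    if not slots:
        return {
            "coincidence_fires": False,
            "attention_alone_silent": True,
            "recall_selective": False,
        }
    probe = (slots[0],)
    encoding = run_phase(config, attention, probe, "encoding")
    coincidence = sum(len(b.dendritic_spikes) for b in encoding.branches) >= 1
    silent_run = run_phase(config, attention, (), "encoding")
    silent = sum(len(b.dendritic_spikes) for b in silent_run.branches) == 0
    enc, rec = encode_learn_recall(config, probe)
    selective = rec.somatic_spikes == enc.somatic_spikes and len(enc.somatic_spikes) == 1
    return {
        "coincidence_fires": coincidence,
        "attention_alone_silent": silent,
        "recall_selective": selective,
    }


def run_delta_beta_study(
    config: Optional[NetworkConfig] = None,
    n_trials: int = 100,
    seed: int = 0,
    n_spikes: int = 10,
) -> StudySummary:
    """Exact-recall study under the delta-beta (1 Hz / ~12 Hz) configuration.

    Runs the standard protocol on random one-second patterns of exactly
    ``n_spikes`` spikes.  The three feasibility inequalities are checked by
    micro-simulation first and reported on the summary.
    """
    config = delta_beta_config() if config is None else config
    feas = check_feasibility(config)
    slots = servable_slots(config)
    rng = np.random.default_rng(seed)
    outcomes = []
    for _ in range(n_trials):
        pattern = make_random_input_pattern(
            rng, slots, max_spikes=len(slots), n_spikes=n_spikes
        )
        outcomes.append(_run_trial(config, pattern))
    return _summarize(outcomes, config, seed, feasibility=feas)
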