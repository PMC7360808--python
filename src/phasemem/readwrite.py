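"""Configuration files, trace export, and run manifests.

The canonical configuration dialect is YAML: a nested mapping whose
sections mirror the parameter dataclasses (``smo``, ``branches``,
``kernels``, ``weights``, ``soma``, ``grid``, ``learning``,
``refractory``), plus optional inline ``attention``/``input`` spike-time
lists.  Every omitted key falls back to the reference defaults; unknown
keys are rejected with their full key path, so typos cannot silently
change a run.

Trace export writes one CSV per branch with the potential decomposition
(SMO, EPSPs from A and I, dendritic spike potential, net) and one somatic
CSV, from which the classic trace figures can be regenerated with any
plotting tool.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .kernels import AlphaKernelParams, SMOParams, SomaParams, SynapticWeights
from .patterns import as_spike_train
from .simulate import BranchState, NetworkConfig, SimulationResult, regular_branches

__all__ = [
    "load_config",
    "write_config",
    "config_to_dict",
    "config_from_dict",
    "export_traces",
    "RunManifest",
    "write_manifest",
]

_FLOAT_FMT = "%.6g"


def _reject_unknown(section: Dict, allowed: Sequence[str], path: str) -> None:
    for key in section:
        if key not in allowed:
            raise ValueError(f"unknown configuration key {path}.{key}")


def _num(section: Dict, key: str, default: float, path: str) -> float:
    value = section.get(key, default)
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ValueError(f"configuration key {path}.{key} must be a number, got {value!r}")
    return value


def config_to_dict(config: NetworkConfig) -> Dict:
    """Serialize a configuration to the canonical nested mapping.

    Homogeneous regular layouts are written compactly as ``branches:
    {count, j_start}``; anything else (random phases, post-learning
    snapshots) is written as an explicit per-branch list.
    """
    branches = config.branches
    first = branches[0]
    js = [b.smo.j for b in branches]
    homogeneous = all(
        b.smo.h == first.smo.h
        and b.smo.fq == first.smo.fq
        and b.smo.ph == first.smo.ph
        and b.weights == first.weights
        and not b.learned
        and not b.smo_amplified
        for b in branches
    )
    regular = (
        homogeneous
        and all(float(j).is_integer() for j in js)
        and js == [js[0] + i for i in range(len(js))]
    )
    if regular:
        branch_section: Union[Dict, List] = {
            "count": len(branches),
            "j_start": int(js[0]),
        }
    else:
        branch_section = [
            {
                "offset_ms": b.smo.offset_ms,
                "h": b.smo.h,
                "w_AE": b.weights.w_AE,
                "learned": b.learned,
                "smo_amplified": b.smo_amplified,
            }
            for b in branches
        ]
    out = {
        "smo": {"h": first.smo.h, "fq": first.smo.fq, "ph": first.smo.ph},
        "branches": branch_section,
        "kernels": {
            "epsp_k": config.epsp_kernel.k,
            "bsp_k": config.bsp_kernel.k,
            "g": config.epsp_kernel.g,
            "tau": config.epsp_kernel.tau,
            "cutoff": config.kernel_cutoff,
        },
        "weights": {
            "w_IE": first.weights.w_IE,
            "w_AE": first.weights.w_AE,
            "w_AE_max": first.weights.w_AE_max,
        },
        "soma": {
            "resting": config.soma.resting,
            "phi_dend": config.soma.phi_dend,
            "threshold": config.soma.threshold,
            "u_pass": config.soma.u_pass,
            "u_B": config.soma.u_B,
            "spike_peak": config.soma.spike_peak,
            "spike_width": config.soma.spike_width,
            "hyper_depth": config.soma.hyper_depth,
            "hyper_tau": config.soma.hyper_tau,
        },
        "grid": {
            "gamma_period": config.gamma_period,
            "duration": config.duration,
            "dt": config.dt,
        },
        "learning": {
            "rule": config.learning_rule,
            "smo_amp_factor": config.smo_amp_factor,
        },
        "refractory": {"dendritic": config.dendritic_refractory},
        "seed": config.seed,
    }
    if config.attention_train is not None:
        out["attention"] = list(config.attention_train)
    if config.input_train is not None:
        out["input"] = list(config.input_train)
    return out


def config_from_dict(data: Optional[Dict]) -> NetworkConfig:
    """Build and validate a :class:`NetworkConfig` from a nested mapping."""
    data = {} if data is None else dict(data)
    _reject_unknown(
        data,
        [
            "smo",
            "branches",
            "kernels",
            "weights",
            "soma",
            "grid",
            "learning",
            "refractory",
            "seed",
            "attention",
            "input",
        ],
        "config",
    )

    smo_sec = data.get("smo", {}) or {}
    _reject_unknown(smo_sec, ["h", "fq", "ph"], "smo")
    h = _num(smo_sec, "h", 6.0, "smo")
    fq = _num(smo_sec, "fq", 8.33, "smo")
    ph = _num(smo_sec, "ph", 10.0, "smo")

    weights_sec = data.get("weights", {}) or {}
    _reject_unknown(weights_sec, ["w_IE", "w_AE", "w_AE_max"], "weights")
    weights = SynapticWeights(
        w_IE=_num(weights_sec, "w_IE", 0.15, "weights"),
        w_AE=_num(weights_sec, "w_AE", 0.40, "weights"),
        w_AE_max=_num(weights_sec, "w_AE_max", 0.55, "weights"),
    )

    branch_sec = data.get("branches", {"count": 12, "j_start": -2})
    if isinstance(branch_sec, dict):
        _reject_unknown(branch_sec, ["count", "j_start", "offsets_ms"], "branches")
        if "offsets_ms" in branch_sec:
            offsets = branch_sec["offsets_ms"]
            branches = tuple(
                BranchState(
                    branch_id=i,
                    smo=SMOParams.with_offset(float(off), h=h, fq=fq),
                    weights=weights,
                )
                for i, off in enumerate(offsets)
            )
        else:
            branches = regular_branches(
                n_branches=int(branch_sec.get("count", 12)),
                j_start=int(branch_sec.get("j_start", -2)),
                h=h,
                fq=fq,
                ph=ph,
                weights=weights,
            )
    elif isinstance(branch_sec, list):
        built = []
        for i, entry in enumerate(branch_sec):
            _reject_unknown(
                entry,
                ["j", "offset_ms", "h", "w_AE", "learned", "smo_amplified"],
                f"branches[{i}]",
            )
            b_h = _num(entry, "h", h, f"branches[{i}]")
            if "j" in entry:
                smo = SMOParams(h=b_h, fq=fq, ph=ph, j=entry["j"])
            elif "offset_ms" in entry:
                smo = SMOParams.with_offset(float(entry["offset_ms"]), h=b_h, fq=fq)
            else:
                raise ValueError(f"branches[{i}] needs either 'j' or 'offset_ms'")
            b_weights = replace(weights, w_AE=_num(entry, "w_AE", weights.w_AE, f"branches[{i}]"))
            built.append(
                BranchState(
                    branch_id=i,
                    smo=smo,
                    weights=b_weights,
                    learned=bool(entry.get("learned", False)),
                    smo_amplified=bool(entry.get("smo_amplified", False)),
                )
            )
        branches = tuple(built)
    else:
        raise ValueError("branches must be a mapping or a list of branch entries")

    kern_sec = data.get("kernels", {}) or {}
    _reject_unknown(kern_sec, ["epsp_k", "bsp_k", "g", "tau", "cutoff"], "kernels")
    g = _num(kern_sec, "g", 2.0, "kernels")
    tau = _num(kern_sec, "tau", 1.0, "kernels")
    epsp_kernel = AlphaKernelParams(k=_num(kern_sec, "epsp_k", 39.0, "kernels"), g=g, tau=tau)
    bsp_kernel = AlphaKernelParams(k=_num(kern_sec, "bsp_k", 40.0, "kernels"), g=g, tau=tau)

    soma_sec = data.get("soma", {}) or {}
    _reject_unknown(
        soma_sec,
        [
            "resting",
            "phi_dend",
            "threshold",
            "u_pass",
            "u_B",
            "spike_peak",
            "spike_width",
            "hyper_depth",
            "hyper_tau",
        ],
        "soma",
    )
    soma = SomaParams(
        resting=_num(soma_sec, "resting", -65.0, "soma"),
        phi_dend=_num(soma_sec, "phi_dend", -48.7, "soma"),
        threshold=_num(soma_sec, "threshold", -50.0, "soma"),
        u_pass=_num(soma_sec, "u_pass", 0.08, "soma"),
        u_B=_num(soma_sec, "u_B", 1.0, "soma"),
        spike_peak=_num(soma_sec, "spike_peak", 30.0, "soma"),
        spike_width=_num(soma_sec, "spike_width", 1.0, "soma"),
        hyper_depth=_num(soma_sec, "hyper_depth", -70.0, "soma"),
        hyper_tau=_num(soma_sec, "hyper_tau", 3.0, "soma"),
    )

    grid_sec = data.get("grid", {}) or {}
    _reject_unknown(grid_sec, ["gamma_period", "duration", "dt"], "grid")
    learning_sec = data.get("learning", {}) or {}
    _reject_unknown(learning_sec, ["rule", "smo_amp_factor"], "learning")
    refr_sec = data.get("refractory", {}) or {}
    _reject_unknown(refr_sec, ["dendritic"], "refractory")

    attention = data.get("attention")
    input_train = data.get("input")
    return NetworkConfig(
        branches=branches,
        soma=soma,
        epsp_kernel=epsp_kernel,
        bsp_kernel=bsp_kernel,
        gamma_period=int(_num(grid_sec, "gamma_period", 10, "grid")),
        duration=int(_num(grid_sec, "duration", 120, "grid")),
        learning_rule=learning_sec.get("rule", "stdp"),
        smo_amp_factor=_num(learning_sec, "smo_amp_factor", 1.5, "learning"),
        dt=int(_num(grid_sec, "dt", 1, "grid")),
        dendritic_refractory=int(_num(refr_sec, "dendritic", 10, "refractory")),
        kernel_cutoff=int(_num(kern_sec, "cutoff", 20, "kernels")),
        seed=int(data.get("seed", 0)),
        attention_train=None if attention is None else as_spike_train(attention),
        input_train=None if input_train is None else as_spike_train(input_train),
    )


def load_config(path: Union[str, Path]) -> NetworkConfig:
    """Load and validate a YAML configuration file.

    An empty file yields the full default configuration.  Schema
    violations and invariant breaches raise ``ValueError`` naming the
    offending key path.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return config_from_dict(data)


def write_config(config: NetworkConfig, path: Union[str, Path]) -> None:
    """Write a configuration as canonical YAML (round-trips with :func:`load_config`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def export_traces(result: SimulationResult, outdir: Union[str, Path]) -> List[Path]:
    """Export the potential decomposition of one run as CSV files.

    Writes ``branch_<id>.csv`` with columns ``time_ms, smo_mV, epsp_A_mV,
    epsp_I_mV, bsp_mV, net_mV`` for every branch, and ``soma.csv`` with
    ``time_ms, potential_mV, spike_flag``.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    time_ms = np.arange(result.duration, dtype=int)
    paths = []
    for branch_id, tr in sorted(result.branch_traces.items()):
        frame = pd.DataFrame(
            {
                "time_ms": time_ms,
                "smo_mV": tr.smo,
                "epsp_A_mV": tr.epsp_A,
                "epsp_I_mV": tr.epsp_I,
                "bsp_mV": tr.bsp,
                "net_mV": tr.net,
            }
        )
        path = outdir / f"branch_{branch_id:02d}.csv"
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
        paths.append(path)
    spike_flag = np.zeros(result.duration, dtype=int)
    for t in result.somatic_spikes:
        spike_flag[t] = 1
    soma_frame = pd.DataFrame(
        {
            "time_ms": time_ms,
            "potential_mV": result.somatic_trace,
            "spike_flag": spike_flag,
        }
    )
    soma_path = outdir / "soma.csv"
    soma_frame.to_csv(soma_path, index=False, float_format=_FLOAT_FMT)
    paths.append(soma_path)
    return paths


@dataclass
class RunManifest:
    """Provenance record of one command-line run."""

    command: str
    seed: Optional[int]
    version: str
    config: Dict
    outputs: List[str]
    wall_time_s: float

    @classmethod
    def collect(
        cls,
        command: str,
        config: NetworkConfig,
        seed: Optional[int],
        outputs: Sequence[Union[str, Path]],
        started: float,
    ) -> "RunManifest":
        return cls(
            command=command,
            seed=seed,
            version=_version,
            config=config_to_dict(config),
            outputs=[str(p) for p in outputs],
            wall_time_s=round(time.monotonic() - started, 3),
        )


def write_manifest(manifest: RunManifest, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
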