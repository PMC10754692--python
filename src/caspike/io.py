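"""Delimited-text I/O for spike times, ISI sequences, result tables and
YAML run configurations.

Formats
-------
Spike-time file: one time (seconds) per line; ``#``-prefixed header lines
carry metadata as ``# key: value``.  ISI file: same layout, one interval
per line, with the onset interval stored in the header (``# t_first``)
because it is not an ISI.  Decimal separator is always the dot.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .params import BufferParams, ClusterParams, ModelParams
from .simulate import SpikeTrain
from .stats import ISISequence

__all__ = [
    "write_spike_times", "read_spike_times",
    "write_isi_sequence", "read_isi_sequence",
    "load_config", "dump_config", "model_from_config",
]

_MODEL_KEYS = {"tau", "p", "ci0", "c_threshold", "n_clusters", "tau_er", "eps",
               "k_act", "cer0"}
_CLUSTER_KEYS = {"n_open", "n_refractory", "k_minus", "k_plus", "lambda0",
                 "hill_exponent", "hill_midpoint", "closing_rate_rule",
                 "recovery_rate_rule"}
_BUFFER_KEYS = {"b_total", "k_star"}
_SIM_KEYS = {"dt", "t_end", "trials", "seed", "scheme", "store_traj"}
_ANALYSIS_KEYS = {"truncate", "k_max", "bin_fraction"}
_FIT_KEYS = {"tolerance", "n_restarts", "max_iter"}


def _write_lines(path, header: dict, values) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        for v in values:
            fh.write(f"{v:.12g}\n")


def _read_lines(path):
    header, values = {}, []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if ":" in body:
                    k, v = body.split(":", 1)
                    header[k.strip()] = v.strip()
                continue
            try:
                values.append(float(line))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed value {line!r}") from err
    return header, np.array(values)


def write_spike_times(path, train: SpikeTrain) -> None:
    _write_lines(path, {
        "format": "spike-times", "t0": train.t0, "t_end": train.t_end,
        "seed": train.seed, "scheme": train.scheme,
    }, train.spike_times)


def read_spike_times(path) -> SpikeTrain:
    header, values = _read_lines(path)
    return SpikeTrain(
        spike_times=values,
        t0=float(header.get("t0", 0.0)),
        t_end=float(header.get("t_end", values[-1] if len(values) else 0.0)),
        seed=int(header.get("seed", 0)),
        scheme=header.get("scheme", ""),
    )


def write_isi_sequence(path, seq: ISISequence) -> None:
    header = {"format": "isi", "t0": seq.t0}
    if seq.first_interval is not None:
        header["t_first"] = f"{seq.first_interval:.12g}"
    if seq.seed is not None:
        header["seed"] = seq.seed
    _write_lines(path, header, seq.intervals)


def read_isi_sequence(path) -> ISISequence:
    header, values = _read_lines(path)
    first = header.get("t_first")
    return ISISequence(
        intervals=values,
        first_interval=float(first) if first is not None else None,
        t0=float(header.get("t0", 0.0)),
        seed=int(header["seed"]) if "seed" in header else None,
    )


def _check_keys(block: dict, allowed: set, name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name} block: {sorted(unknown)}")


def load_config(path) -> dict:
    """Load and schema-check a YAML run configuration."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    _check_keys(cfg, {"model", "cluster", "buffer", "simulation", "analysis", "fit"}, "top-level")
    _check_keys(cfg.get("model", {}) or {}, _MODEL_KEYS, "model")
    _check_keys(cfg.get("cluster", {}) or {}, _CLUSTER_KEYS, "cluster")
    _check_keys(cfg.get("buffer", {}) or {}, _BUFFER_KEYS, "buffer")
    _check_keys(cfg.get("simulation", {}) or {}, _SIM_KEYS, "simulation")
    _check_keys(cfg.get("analysis", {}) or {}, _ANALYSIS_KEYS, "analysis")
    _check_keys(cfg.get("fit", {}) or {}, _FIT_KEYS, "fit")
    return cfg


def model_from_config(cfg: dict) -> ModelParams:
    cluster = ClusterParams(**(cfg.get("cluster") or {}))
    buffer = BufferParams(**(cfg.get("buffer") or {}))
    return ModelParams(cluster=cluster, buffer=buffer, **(cfg.get("model") or {}))


def dump_config(path, params: ModelParams, simulation: dict | None = None) -> None:
    """Write the resolved configuration (for reproducibility records)."""
    cfg = {
        "model": {
            "tau": params.tau, "p": params.p, "ci0": params.ci0,
            "c_threshold": params.c_threshold, "n_clusters": params.n_clusters,
            "tau_er": params.tau_er, "eps": params.eps,
        },
        "cluster": {
            "n_open": params.cluster.n_open,
            "n_refractory": params.cluster.n_refractory,
            "k_minus": params.cluster.k_minus, "k_plus": params.cluster.k_plus,
            "lambda0": params.cluster.lambda0,
            "hill_exponent": params.cluster.hill_exponent,
            "hill_midpoint": params.cluster.hill_midpoint,
            "closing_rate_rule": params.cluster.closing_rate_rule,
            "recovery_rate_rule": params.cluster.recovery_rate_rule,
        },
        "buffer": {"b_total": params.buffer.b_total, "k_star": params.buffer.k_star},
    }
    if simulation:
        cfg["simulation"] = simulation
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
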