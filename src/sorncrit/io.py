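"""Configuration files, result tables, checkpoints and run manifests.

Analysis outputs are plain TSV/JSON so they can be inspected, diffed
and version-controlled; only network checkpoints use a binary
container (a versioned ``.npz`` holding the full state plus RNG stream
states, enough to resume a run bit-exactly).

Config files are flat YAML key/value mappings; unknown keys are
rejected and every omitted key falls back to the standard study
defaults (N_E = 200, Gaussian noise variance 0.05, the usual learning
rates).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .avalanche import AvalancheSet
from .core import NetworkParams, NetworkState, NoiseModel, SimulationRecord
from .experiments import ExperimentConfig

__all__ = [
    "SimulationConfig",
    "load_config",
    "dump_config",
    "write_raster_tsv",
    "read_raster_tsv",
    "write_avalanches_tsv",
    "read_avalanches_tsv",
    "write_fit_json",
    "read_fit_json",
    "save_checkpoint",
    "load_checkpoint",
    "RunManifest",
    "get_logger",
]

_CHECKPOINT_VERSION = 1

_FLOAT_FMT = "%.17g"          # round-trips IEEE doubles exactly


def get_logger(run_id: str) -> logging.Logger:
    """Timestamped, level-tagged logger carrying the run id."""
    logger = logging.getLogger(f"sorncrit.{run_id}")
    if not logger.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter(
            f"%(asctime)s %(levelname)s [{run_id}] %(message)s"
        ))
        logger.addHandler(h)
        logger.setLevel(logging.INFO)
    return logger


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Resolved full configuration: model, noise and protocol."""

    params: NetworkParams = NetworkParams()
    noise: NoiseModel = NoiseModel()
    experiment: ExperimentConfig = ExperimentConfig()

    def as_flat_dict(self) -> dict:
        out: dict = {}
        for prefix, obj in (("", self.params), ("noise_", self.noise),
                            ("", self.experiment)):
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                if isinstance(v, np.ndarray):
                    v = v.tolist()
                if isinstance(v, tuple):
                    v = list(v)
                out[prefix + f.name] = v
        return out


_PARAM_KEYS = {f.name for f in dataclasses.fields(NetworkParams)}
_NOISE_KEYS = {"noise_" + f.name for f in dataclasses.fields(NoiseModel)}
_EXP_KEYS = {f.name for f in dataclasses.fields(ExperimentConfig)}


def load_config(path) -> SimulationConfig:
    """Read a flat YAML config; defaults fill every omitted key.

    Unknown keys and out-of-range values are rejected with the
    offending key named (range checks are delegated to the dataclass
    validators).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat key/value mapping")
    unknown = set(raw) - _PARAM_KEYS - _NOISE_KEYS - _EXP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    p_kw = {k: raw[k] for k in raw if k in _PARAM_KEYS}
    n_kw = {k[len("noise_"):]: raw[k] for k in raw if k in _NOISE_KEYS}
    e_kw = {k: raw[k] for k in raw if k in _EXP_KEYS}
    if "freeze_set" in e_kw:
        e_kw["freeze_set"] = tuple(e_kw["freeze_set"])
    try:
        return SimulationConfig(
            params=NetworkParams(**p_kw),
            noise=NoiseModel(**n_kw),
            experiment=ExperimentConfig(**e_kw),
        )
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: {err}") from err


def dump_config(config: SimulationConfig, path) -> None:
    """Write the resolved configuration back as flat YAML."""
    Path(path).write_text(yaml.safe_dump(config.as_flat_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_raster_tsv(record: SimulationRecord, path) -> None:
    """Spike events as (time_step, unit_index) rows, 0-based.

    The comment header records network size and seeds.
    """
    if record.raster is None:
        raise ValueError("record was made without raster=True")
    with open(path, "w") as fh:
        fh.write(f"# n_e={record.n_e}\tn_i={record.n_i}\t"
                 f"seeds={json.dumps(record.seeds)}\n")
        fh.write("time_step\tunit_index\n")
        for t, fired in enumerate(record.raster):
            for i in fired:
                fh.write(f"{t}\t{i}\n")


def read_raster_tsv(path) -> tuple[list[np.ndarray], dict]:
    """Read a raster event table back to per-step index arrays."""
    meta: dict = {}
    events: dict[int, list[int]] = {}
    n_steps = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for kv in line[1:].strip().split("\t"):
                    k, v = kv.split("=", 1)
                    meta[k] = json.loads(v) if k == "seeds" else int(v)
                continue
            if line.startswith("time_step"):
                continue
            t_s, i_s = line.split()
            t = int(t_s)
            events.setdefault(t, []).append(int(i_s))
            n_steps = max(n_steps, t + 1)
    raster = [np.array(sorted(events.get(t, [])), dtype=np.int64)
              for t in range(n_steps)]
    return raster, meta


def write_avalanches_tsv(avset: AvalancheSet, path) -> None:
    """Avalanche table (t0, T, S, S_alt) with theta in the header."""
    alt = avset.alt_sizes
    with open(path, "w") as fh:
        fh.write(f"# theta={avset.theta}\ttrace_length={avset.trace_length}\n")
        fh.write("t0\tT\tS\tS_alt\n")
        for i in range(len(avset)):
            a = "" if alt is None else str(int(alt[i]))
            fh.write(f"{avset.t0[i]}\t{avset.durations[i]}\t{avset.sizes[i]}\t{a}\n")


def read_avalanches_tsv(path) -> AvalancheSet:
    t0, dur, siz, alt = [], [], [], []
    theta = trace_length = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for kv in line[1:].strip().split("\t"):
                    k, v = kv.split("=")
                    if k == "theta":
                        theta = int(v)
                    elif k == "trace_length":
                        trace_length = int(v)
                continue
            if line.startswith("t0"):
                continue
            parts = line.rstrip("\n").split("\t")
            t0.append(int(parts[0]))
            dur.append(int(parts[1]))
            siz.append(int(parts[2]))
            alt.append(int(parts[3]) if len(parts) > 3 and parts[3] else -1)
    alt_arr = np.array(alt, dtype=np.int64)
    return AvalancheSet(
        t0=np.array(t0, dtype=np.int64),
        durations=np.array(dur, dtype=np.int64),
        sizes=np.array(siz, dtype=np.int64),
        theta=theta,
        trace_length=trace_length,
        alt_sizes=None if (alt_arr < 0).all() else alt_arr,
    )


# ---------------------------------------------------------------------------
# fit reports
# ---------------------------------------------------------------------------

def write_fit_json(fits: dict, path) -> None:
    """Fit report: a mapping of labels to fit dataclasses (or numbers)."""
    def enc(v):
        if dataclasses.is_dataclass(v):
            return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
        if isinstance(v, dict):
            return {k: enc(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [enc(x) for x in v]
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, np.ndarray):
            return v.tolist()
        return v
    Path(path).write_text(json.dumps({k: enc(v) for k, v in fits.items()},
                                     indent=2, sort_keys=True))


def read_fit_json(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(state: NetworkState, streams: dict, path) -> None:
    """Full network state + RNG stream states, versioned binary npz."""
    rng_states = {name: g.bit_generator.state for name, g in streams.items()}
    np.savez_compressed(
        path,
        schema_version=np.int64(_CHECKPOINT_VERSION),
        x=state.x, y=state.y,
        w_ee=state.w_ee, w_ei=state.w_ei,
        mask_ei=state.mask_ei, w_ie=state.w_ie,
        t_e=state.t_e, t_i=state.t_i, h_ip=state.h_ip,
        t=np.int64(state.t),
        rng_json=np.frombuffer(
            json.dumps(rng_states).encode(), dtype=np.uint8
        ),
    )


def load_checkpoint(path) -> tuple[NetworkState, dict]:
    with np.load(path) as z:
        version = int(z["schema_version"])
        if version != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint schema v{version}")
        state = NetworkState(
            x=z["x"], y=z["y"], w_ee=z["w_ee"], w_ei=z["w_ei"],
            mask_ei=z["mask_ei"], w_ie=z["w_ie"],
            t_e=z["t_e"], t_i=z["t_i"], h_ip=z["h_ip"], t=int(z["t"]),
        )
        rng_states = json.loads(bytes(z["rng_json"]).decode())
    streams = {}
    for name, st in rng_states.items():
        g = np.random.default_rng()
        g.bit_generator.state = st
        streams[name] = g
    return state, streams


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Write-once record tying outputs to the exact run conditions."""

    run_id: str
    config: dict
    seeds: dict
    outputs: dict = field(default_factory=dict)   # path -> sha256
    started: float = field(default_factory=time.time)
    finished: Optional[float] = None

    def add_output(self, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def write(self, path) -> None:
        if Path(path).exists():
            raise FileExistsError(f"manifest {path} already exists (write-once)")
        self.finished = time.time()
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
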