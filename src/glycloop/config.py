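"""Run configuration: one YAML document drives the whole pipeline.

Every stochastic stage derives its seed deterministically from the master
seed and the stage name, so stages can be re-run in isolation without
disturbing each other's random streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .bolus import BolusConfig
from .cohort import SimScenario
from .ensemble import SearchConfig


@dataclass
class ProfilingConfig:
    k: int = 3
    som_epochs: int = 500
    include_hour: bool = False


@dataclass
class ProtocolConfig:
    n_iter: int = 20
    test_frac: float = 0.1
    negatives: str = "local"
    search: SearchConfig = field(default_factory=SearchConfig)


@dataclass
class ExplainConfig:
    n_instances: int = 5        # instances attributed per system
    n_background: int = 100     # background sample size for Shapley
    lime_samples: int = 1000


@dataclass
class ClosedLoopConfig:
    n_patients: int = 10
    n_days: int = 14
    bolus: BolusConfig = field(default_factory=BolusConfig)


@dataclass
class RunConfig:
    scenario: SimScenario = field(default_factory=SimScenario)
    profiling: ProfilingConfig = field(default_factory=ProfilingConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    explain: ExplainConfig = field(default_factory=ExplainConfig)
    closed_loop: ClosedLoopConfig = field(default_factory=ClosedLoopConfig)
    master_seed: int = 0
    out_dir: str = "runs/latest"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "scenario": SimScenario,
    "profiling": ProfilingConfig,
    "protocol": ProtocolConfig,
    "explain": ExplainConfig,
    "closed_loop": ClosedLoopConfig,
}


def _build(cls, data: dict, path: str):
    fields = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        if key == "search" and isinstance(val, dict):
            val = _build(SearchConfig, val, f"{path}.search")
        elif key == "bolus" and isinstance(val, dict):
            val = _build(BolusConfig, val, f"{path}.bolus")
        elif isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys raise naming the key."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data.update(raw)
    if overrides:
        data.update(overrides)
    kwargs = {}
    for key, val in data.items():
        if key in _SECTIONS:
            if not isinstance(val, dict):
                raise ConfigError(f"{key}: expected a mapping")
            kwargs[key] = _build(_SECTIONS[key], val, key)
        elif key in ("master_seed", "out_dir", "log_level"):
            kwargs[key] = val
        else:
            raise ConfigError(f"unknown top-level config key {key!r}")
    return RunConfig(**kwargs)


def stage_seed(master_seed: int, stage: str, extra: int = 0) -> int:
    """Deterministic per-stage seed below 2^31."""
    tag = zlib.crc32(stage.encode())
    return int(np.random.SeedSequence([master_seed, tag, extra])
               .generate_state(1)[0] % (2**31))


__all__ = [
    "RunConfig", "ProfilingConfig", "ProtocolConfig", "ExplainConfig",
    "ClosedLoopConfig", "load_config", "stage_seed",
]
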