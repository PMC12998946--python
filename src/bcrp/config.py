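"""Configuration loading with command-line > file > defaults precedence."""

from __future__ import annotations

from typing import Optional

import yaml

from .records import ConfigurationError
from .simulate import SimulationConfig

#: clustering / refinement defaults layered on top of the simulator fields
PIPELINE_DEFAULTS = {
    "cluster_thre": 3,
    "overlap_thre": 0.1,
    "consensus_thre": None,
    "public_quantile": 0.10,
    "min_subcluster_size": 3,
    "shm_cutoff": None,
}


def default_config() -> dict:
    cfg = {f: getattr(SimulationConfig(), f) for f in SimulationConfig.__dataclass_fields__}
    cfg.update(PIPELINE_DEFAULTS)
    return cfg


def load_config(path: Optional[str], overrides: Optional[dict] = None) -> dict:
    """Merge defaults, an optional YAML file, and explicit overrides.

    Unknown keys in the file or overrides are rejected by name; override
    values of None are ignored (unset CLI flags).
    """
    merged = default_config()
    known = set(merged)
    if path:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        unknown = sorted(set(loaded) - known)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {', '.join(unknown)}")
        for key, value in loaded.items():
            if key in (
                "hc_junction_indels", "lc_junction_indels", "mutation_type_weights"
            ) and isinstance(value, list):
                value = tuple(value)
            merged[key] = value
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if key not in known:
            raise ConfigurationError(f"unknown config key(s): {key}")
        merged[key] = value
    return merged


def simulation_config(merged: dict) -> SimulationConfig:
    fields = set(SimulationConfig.__dataclass_fields__)
    return SimulationConfig(**{k: v for k, v in merged.items() if k in fields})


def dump_config(merged: dict, path) -> None:
    serializable = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in merged.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(serializable, fh, sort_keys=True)
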