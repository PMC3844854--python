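"""Structured-text (YAML) configuration covering every module.

An empty file resolves to the default healthy 100-GP network.  Unknown
keys are rejected with field-level messages; all type invariants are
re-checked on load; the resolved config can be dumped back to an
equivalent file (load -> dump -> load is idempotent).
"""

from __future__ import annotations

from dataclasses import asdict, fields, replace
from pathlib import Path

import yaml

from .neuron import CalciumParams, MembraneParams
from .network import NetworkConfig
from .plasticity import DownregulationParams
from .stn import IFGeneratorParams

__all__ = ["load_config", "validate_config", "dump_config"]

_BLOCKS = {
    "downregulation": ("downregulation", DownregulationParams),
    "generator": ("generator", IFGeneratorParams),
    "membrane": ("membrane", MembraneParams),
    "calcium": ("calcium", CalciumParams),
}
_SCALAR_KEYS = {
    "n_gp", "n_stn", "gp_fanout", "stn_fanout", "condition", "beta",
    "beta_high_inhibition", "duration", "analysis_window_start", "dt", "seed",
}


class ConfigError(ValueError):
    """Schema violation in a config file."""


def _build_block(name: str, cls, raw: dict):
    if not isinstance(raw, dict):
        raise ConfigError(f"block {name!r} must be a mapping")
    allowed = {f.name for f in fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in block {name!r}; "
            f"allowed: {sorted(allowed)}"
        )
    try:
        return cls(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid block {name!r}: {exc}") from exc


def validate_config(raw: dict | None) -> NetworkConfig:
    """Resolve a raw mapping into a fully-validated `NetworkConfig`."""
    raw = dict(raw or {})
    kwargs = {}
    for key in list(raw):
        if key in _BLOCKS:
            field_name, cls = _BLOCKS[key]
            kwargs[field_name] = _build_block(key, cls, raw.pop(key))
        elif key in _SCALAR_KEYS:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ConfigError(
            f"unknown top-level key(s) {sorted(raw)}; allowed: "
            f"{sorted(_SCALAR_KEYS | set(_BLOCKS))}"
        )
    try:
        return NetworkConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path | None = None) -> NetworkConfig:
    """Load a YAML config file; an empty or missing body gives defaults."""
    if path is None:
        return NetworkConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)


def dump_config(cfg: NetworkConfig, path: str | Path) -> None:
    """Write a config echo that `load_config` reads back identically."""
    data = {
        key: getattr(cfg, key) for key in sorted(_SCALAR_KEYS)
    }
    for block_key, (field_name, _) in _BLOCKS.items():
        data[block_key] = asdict(getattr(cfg, field_name))
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
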