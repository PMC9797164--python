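"""YAML configuration loading with strict schema validation.

A config file has up to three top-level sections, all optional::

    registration:
      levels: 3
      grid_spacing_mm: 12.0
      max_iterations: 500
      weights:
        fiducial: 1
        region: 1
        intensity: 100
    phantom:
      shape: [96, 96, 48]
      deformation_amplitude_mm: 12.0

Unknown keys are rejected; defaults are materialized so the effective
configuration can be echoed into reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .metrics import MetricWeights
from .phantom import PhantomConfig
from .registration import RegistrationConfig

__all__ = ["AppConfig", "load_config", "config_echo", "config_hash"]


@dataclass(frozen=True)
class AppConfig:
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)


def _coerce_tuple(value):
    return tuple(value) if isinstance(value, (list, tuple)) else value


def _build(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ValueError(f"unknown {context} config keys: {', '.join(unknown)}")
    kwargs = {k: _coerce_tuple(v) for k, v in data.items()}
    return cls(**kwargs)


def load_config(path: str | Path | None) -> AppConfig:
    """Parse and validate a YAML config file; ``None`` gives all defaults."""
    if path is None:
        return AppConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return AppConfig()
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = sorted(set(raw) - {"registration", "phantom"})
    if unknown:
        raise ValueError(f"unknown top-level config keys: {', '.join(unknown)}")
    reg_data = dict(raw.get("registration") or {})
    weights = reg_data.pop("weights", None)
    if weights is not None:
        reg_data["weights"] = _build(MetricWeights, dict(weights), "weights")
    registration = _build(RegistrationConfig, reg_data, "registration")
    phantom = _build(PhantomConfig, dict(raw.get("phantom") or {}), "phantom")
    return AppConfig(registration=registration, phantom=phantom)


def config_echo(cfg: AppConfig) -> dict:
    """The fully materialized configuration as plain JSON-able data."""
    return json.loads(json.dumps(dataclasses.asdict(cfg)))


def config_hash(cfg: AppConfig) -> str:
    return hashlib.sha256(
        json.dumps(config_echo(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]
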