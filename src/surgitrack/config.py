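"""Run configuration: every tunable threshold/parameter in one place.

Configs load from a YAML file with section names matching the pipeline
stages; unknown keys are rejected so typos cannot silently fall back to
defaults.  A fully defaulted config is valid.  The canonical JSON hash of a
config is embedded in every output artifact for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .hemorrhage import HemorrhageParams
from .instruments import InstrumentParams
from .tracking import TrackerParams

__all__ = ["FlowParams", "EvalParams", "RunConfig", "ConfigError",
           "load_config", "config_to_dict", "config_hash"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a config file."""


@dataclass
class FlowParams:
    smooth_window: int = 5
    window_frames: int = 30
    slope_threshold: float = 10.0  # area px per frame
    stride: int = 1


@dataclass
class EvalParams:
    tau_mode: str = "width15"


@dataclass
class RunConfig:
    """Top-level configuration for an end-to-end run."""

    fps: float = 10.0
    seed: int = 0
    kind: str = "both"  # blood | tools | both
    hemorrhage: HemorrhageParams = field(default_factory=HemorrhageParams)
    instruments: InstrumentParams = field(default_factory=InstrumentParams)
    tracker: TrackerParams = field(default_factory=TrackerParams)
    flow: FlowParams = field(default_factory=FlowParams)
    evaluation: EvalParams = field(default_factory=EvalParams)

    def kinds(self) -> tuple[str, ...]:
        return {
            "blood": ("hemorrhage",),
            "tools": ("instrument",),
            "both": ("hemorrhage", "instrument"),
        }[self.kind]

    def __post_init__(self) -> None:
        if self.kind not in ("blood", "tools", "both"):
            raise ConfigError(f"kind must be blood|tools|both, got {self.kind!r}")
        if self.fps <= 0:
            raise ConfigError("fps must be positive")


def _update_dataclass(obj, data: dict, section: str):
    valid = {f.name: f for f in fields(obj)}
    for key, value in data.items():
        if key not in valid:
            raise ConfigError(f"unknown key {key!r} in section {section!r}")
        current = getattr(obj, key)
        if isinstance(current, tuple) and isinstance(value, (list, tuple)):
            value = tuple(value)
        setattr(obj, key, value)
    return obj


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides."""
    cfg = RunConfig()
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data = {**data, **overrides}
    sections = {
        "hemorrhage": cfg.hemorrhage,
        "instruments": cfg.instruments,
        "tracker": cfg.tracker,
        "flow": cfg.flow,
        "evaluation": cfg.evaluation,
    }
    for key, value in data.items():
        if key in ("fps", "seed", "kind"):
            setattr(cfg, key, value)
        elif key in sections:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            _update_dataclass(sections[key], value, key)
        else:
            raise ConfigError(f"unknown top-level key {key!r}")
    cfg.__post_init__()
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the canonical JSON form of the config."""
    payload = json.dumps(config_to_dict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
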