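"""Configuration schema, validation, and run provenance.

Config files are flat YAML key-value documents; unknown keys are
rejected with an itemized error list, defaults are filled in, and every
run writes its resolved config back out next to its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import ModelParams

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "RunManifest"]


class ConfigError(ValueError):
    """Invalid configuration; ``errors`` lists every violation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
_RUN_KEYS = {
    "init": str,
    "n_cells": int,
    "duration": float,
    "burn_in": float,
    "frame_interval": float,
    "output_dir": str,
    "keep_tissues": bool,
}


@dataclass
class RunConfig:
    """A resolved simulation run configuration."""

    params: ModelParams = field(default_factory=ModelParams)
    init: str = "honeycomb"
    n_cells: int = 156
    duration: float = 80.0
    burn_in: float = 20.0
    frame_interval: float = 0.5
    output_dir: str = "run_output"
    keep_tissues: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.params)
        for k in _RUN_KEYS:
            d[k] = getattr(self, k)
        return d


def load_config(path: str | Path | None, overrides: dict | None = None) -> RunConfig:
    """Read and validate a flat YAML config; empty/missing keys fall
    back to the wild-type defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(["config root must be a key-value mapping"])
    if overrides:
        raw.update(overrides)

    errors = [f"unknown key '{k}'" for k in raw if k not in _MODEL_KEYS | set(_RUN_KEYS)]
    model_kwargs = {k: raw[k] for k in raw if k in _MODEL_KEYS}
    run_kwargs = {k: raw[k] for k in raw if k in _RUN_KEYS}
    if errors:
        raise ConfigError(errors)
    try:
        params = ModelParams(**model_kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError([str(exc)]) from exc
    cfg = RunConfig(params=params, **run_kwargs)
    more = []
    if cfg.init not in ("honeycomb", "voronoi"):
        more.append(f"init must be honeycomb|voronoi, got '{cfg.init}'")
    if cfg.n_cells < 4:
        more.append("n_cells must be >= 4")
    if cfg.duration < 0 or cfg.burn_in < 0:
        more.append("duration and burn_in must be nonnegative")
    if cfg.frame_interval <= 0:
        more.append("frame_interval must be positive")
    if more:
        raise ConfigError(more)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


@dataclass
class RunManifest:
    """Provenance for one run directory."""

    config: dict
    seed: int
    code_version: str
    started: str
    finished: str = ""
    file_digests: dict = field(default_factory=dict)

    def add_digest(self, path: str | Path) -> None:
        p = Path(path)
        self.file_digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
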