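"""YAML/JSON experiment configuration loading with strict validation."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .experiment import ExperimentConfig

__all__ = ["load_config", "dump_config"]

_FIELDS = {f.name: f for f in dataclasses.fields(ExperimentConfig)}


def load_config(path: str | Path | None = None, **overrides) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML or JSON file.

    Missing keys fall back to defaults; unknown keys fail fast with the key
    path. An empty (or absent) file yields the full default configuration.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        text = path.read_text()
        if text.strip():
            data = (
                json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
            )
            if not isinstance(data, dict):
                raise ValueError(f"{path}: top level must be a mapping")
    data.update(overrides)
    unknown = sorted(set(data) - set(_FIELDS))
    if unknown:
        raise ValueError(
            f"unknown config keys {unknown}; valid keys: {sorted(_FIELDS)}"
        )
    for key, value in data.items():
        if key == "methods" and isinstance(value, list):
            data[key] = tuple(value)
    return ExperimentConfig(**data)


def dump_config(cfg: ExperimentConfig, path: str | Path) -> None:
    """Write the fully resolved configuration beside experiment outputs."""
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True))
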