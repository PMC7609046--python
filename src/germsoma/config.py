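"""Run configuration and reproducibility metadata.

Evolution runs are configured from YAML files whose keys mirror
:class:`~germsoma.wright_fisher.EvolutionConfig`; unknown keys are
rejected so typos fail loudly.  A missing seed is auto-generated and
recorded, and every command writes a metadata JSON (command, full
parameters, seed, package version, timestamp) sufficient to reproduce
the run bit-exactly.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import secrets
from pathlib import Path

import yaml

from .wright_fisher import EvolutionConfig

__all__ = ["load_config", "save_metadata"]


def load_config(path: str | Path) -> EvolutionConfig:
    """Parse an evolution config file; reject unknown keys; ensure a seed."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping of keys to values")
    known = {f.name for f in dataclasses.fields(EvolutionConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}; valid keys: {sorted(known)}")
    cfg = EvolutionConfig(**raw)
    if cfg.seed is None:
        cfg.seed = secrets.randbelow(2**31)
    return cfg


def save_metadata(params: dict, path: str | Path, command: str | None = None) -> None:
    """Write a reproducibility record next to a command's outputs."""
    from . import __version__

    meta = {
        "command": command,
        "parameters": params,
        "package": "germsoma",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")
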