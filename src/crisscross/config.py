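"""Run configuration: YAML config files, validation, run manifests.

Config values override library defaults; CLI flags override the config.
Unknown keys are rejected (all problems reported at once, not just the
first).  Every CLI run writes a manifest capturing the effective config,
package version and seeds, so any artifact can be regenerated from its
manifest alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, List

import yaml

from . import __version__
from .io import write_json

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "write_manifest"]


class ConfigError(ValueError):
    """Invalid configuration; message lists every problem found."""


@dataclass
class RunConfig:
    """Top-level run configuration with per-stage parameter blocks."""

    rng_seed: int = 0
    out_dir: str = "results"
    verbose: bool = False
    ktam: Dict[str, Any] = field(default_factory=dict)
    growth: Dict[str, Any] = field(default_factory=dict)
    quantify: Dict[str, Any] = field(default_factory=dict)
    design: Dict[str, Any] = field(default_factory=dict)
    synth: Dict[str, Any] = field(default_factory=dict)


_BLOCK_KEYS = {
    "ktam": {"kind", "n", "circumference", "epsilon", "concentration", "g_mc",
             "eps_max", "steps", "max_size"},
    "growth": {"v", "k_stall", "k_resume", "k_term", "times_h", "n_ribbons",
               "n_bootstrap"},
    "quantify": {"nucleation_phase_h", "detection_floor_M", "seed_conversion"},
    "design": {"n", "bp_per_turn", "phase", "symmetry", "brush_length",
               "brush_end", "sticky_end_length", "gc_min", "gc_max",
               "max_homopolymer", "max_self_stem"},
    "synth": {"preset", "noise_sd"},
}


def _validate(raw: Dict[str, Any]) -> List[str]:
    problems = []
    top = {f.name for f in fields(RunConfig)}
    for key in raw:
        if key not in top:
            problems.append(f"unknown top-level key {key!r}")
    for block, allowed in _BLOCK_KEYS.items():
        sub = raw.get(block) or {}
        if not isinstance(sub, dict):
            problems.append(f"block {block!r} must be a mapping")
            continue
        for key in sub:
            if key not in allowed:
                problems.append(f"unknown key {key!r} in block {block!r}")
    design = raw.get("design") or {}
    if isinstance(design, dict) and "bp_per_turn" in design:
        if design["bp_per_turn"] not in (10.0, 10.5, 11.0, 11.5, 12.0):
            problems.append(
                f"design.bp_per_turn {design['bp_per_turn']} is not attainable "
                "with 5/6-nt half-turn domains"
            )
    if "rng_seed" in raw and not isinstance(raw["rng_seed"], int):
        problems.append("rng_seed must be an integer")
    return problems


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; an empty/missing block means defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    problems = _validate(raw)
    if problems:
        raise ConfigError("; ".join(problems))
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    data = {f.name: getattr(config, f.name) for f in fields(RunConfig)}
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


def write_manifest(
    config: RunConfig, stage: str, out_dir: str | Path, extra: Dict | None = None
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "version": __version__,
        "rng_seed": config.rng_seed,
        "config": {f.name: getattr(config, f.name) for f in fields(RunConfig)},
    }
    if extra:
        manifest.update(extra)
    return write_json(manifest, out_dir / f"manifest_{stage}.json")
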