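"""YAML run configuration: validated load, unknown keys rejected, hashed.

All lengths carry unit suffixes in their key names (``*_um``, ``*_nm``,
``*_deg``, ``*_min``) so a config file is unambiguous without a manual.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import MillingGeometry
from .planner import DEFAULT_CURRENT_SCHEDULE_PA, ErrorBudget
from .scene import Blob, Emitter, ReferencePatternSpec, SceneSpec

__all__ = ["RunConfig", "load_config", "config_hash"]

_TOP_KEYS = {"geometry", "budget", "scene", "io", "seed", "log_level", "current_schedule_pA"}


@dataclass
class RunConfig:
    geometry: MillingGeometry = field(default_factory=MillingGeometry)
    budget: ErrorBudget = field(default_factory=ErrorBudget)
    scene: SceneSpec | None = None
    io: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"
    current_schedule_pA: dict = field(default_factory=lambda: dict(DEFAULT_CURRENT_SCHEDULE_PA))


def _build(cls, section: dict, where: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section '{where}'; "
            f"allowed: {sorted(names)}"
        )
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in section.items()}
    return cls(**kwargs)


def _build_scene(section: dict) -> SceneSpec:
    section = dict(section)
    emitters = tuple(
        _build(Emitter, e, "scene.emitters") for e in section.pop("emitters", [])
    )
    blobs = tuple(_build(Blob, b, "scene.blobs") for b in section.pop("blobs", []))
    rp = _build(ReferencePatternSpec, section.pop("rp", {}), "scene.rp")
    spec = _build(SceneSpec, section, "scene")
    return dataclasses.replace(spec, emitters=emitters, blobs=blobs, rp=rp)


def load_config(source: str | Path | dict) -> RunConfig:
    """Load and validate a run configuration from YAML (or a mapping)."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(
            f"unknown top-level config key(s) {sorted(unknown)}; allowed: {sorted(_TOP_KEYS)}"
        )
    cfg = RunConfig()
    if "geometry" in raw:
        cfg.geometry = _build(MillingGeometry, raw["geometry"], "geometry")
    if "budget" in raw:
        cfg.budget = _build(ErrorBudget, raw["budget"], "budget")
    if raw.get("scene") is not None:
        cfg.scene = _build_scene(raw["scene"])
    cfg.io = dict(raw.get("io", {}))
    cfg.seed = int(raw.get("seed", 0))
    cfg.log_level = str(raw.get("log_level", "INFO"))
    if "current_schedule_pA" in raw:
        cfg.current_schedule_pA = dict(raw["current_schedule_pA"])
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of a configuration, for provenance records."""

    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, dict):
            return {k: enc(v) for k, v in sorted(o.items())}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        return o

    blob = json.dumps(enc(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
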