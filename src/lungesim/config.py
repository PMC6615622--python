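"""Run configuration: YAML/JSON loading with validated blocks.

A run config bundles the geometry/apparatus block (rates, latency,
trigger threshold, zone fractions), the behaviour block (the synthetic
fencer's parameters) and the cohort block (how many fencers, their
anthropometric distribution).  Everything has defaults, so an empty file
is a valid configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fencer_sim import ApparatusConfig, FencerBehavior
from .geometry import FencerProfile
from .scenario import Condition


class ConfigError(ValueError):
    """A configuration file that cannot be interpreted."""


@dataclass(frozen=True)
class CohortConfig:
    n_fencers: int = 11
    height_mean: float = 1.78
    height_sd: float = 0.06
    mass_mean: float = 75.0
    mass_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.n_fencers < 1:
            raise ConfigError("cohort.n_fencers must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    apparatus: ApparatusConfig = field(default_factory=ApparatusConfig)
    behavior: FencerBehavior = field(default_factory=FencerBehavior)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    save_recordings: bool = False

    def digest(self) -> str:
        """Stable hash of the full configuration, for replay manifests."""
        payload = json.dumps(to_dict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _condition_dict(raw: dict, block: str) -> dict[Condition, float]:
    out = {}
    for key, val in raw.items():
        try:
            out[Condition(key)] = float(val)
        except ValueError as e:
            raise ConfigError(f"{block}: unknown condition {key!r}") from e
    missing = [c.value for c in Condition if c not in out]
    if missing:
        raise ConfigError(f"{block}: missing conditions {missing}")
    return out


def _build(cls, raw: dict, block: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in raw.items():
        if key not in fields:
            raise ConfigError(f"{block}.{key}: unknown parameter")
        if key in ("rt_median", "aim_sigma"):
            val = _condition_dict(val, f"{block}.{key}")
        elif isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{block}: {e}") from e


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a run configuration from YAML (or JSON); missing blocks and
    keys fall back to defaults, unknown keys are errors naming the key."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    known = {"apparatus", "behavior", "cohort", "seed", "save_recordings"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level blocks: {sorted(unknown)}")
    return RunConfig(
        apparatus=_build(ApparatusConfig, raw.get("apparatus", {}), "apparatus"),
        behavior=_build(FencerBehavior, raw.get("behavior", {}), "behavior"),
        cohort=_build(CohortConfig, raw.get("cohort", {}), "cohort"),
        seed=int(raw.get("seed", 0)),
        save_recordings=bool(raw.get("save_recordings", False)),
    )


def to_dict(obj) -> dict:
    """JSON-friendly dict of any config dataclass (enum keys to strings)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {getattr(k, "value", k): to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_dict(v) for v in obj]
    return obj


def load_profile(path: str | Path) -> FencerProfile:
    """Read one fencer profile from a JSON file."""
    raw = json.loads(Path(path).read_text())
    try:
        return FencerProfile(**raw)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{path}: {e}") from e


def load_behavior(path: str | Path) -> FencerBehavior:
    """Read a behaviour block from YAML."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return _build(FencerBehavior, raw, "behavior")
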