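"""Configuration loading and run manifests.

A single YAML file with ``optics``, ``ga``, ``fitness``, ``phantom`` and
``filter`` blocks drives every command.  Unknown keys are rejected so a
typo cannot silently fall back to a default.  Every command writes exactly
one run manifest recording the configuration snapshot, seeds, tool version
and SHA-256 hashes of its outputs, which is sufficient to reproduce the
run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .ga import FitnessSpec, GAConfig
from .optics import OpticalConfig
from .phantom import PhantomSpec

__all__ = [
    "ConfigError",
    "load_config",
    "default_config_dict",
    "dump_config",
    "RunManifest",
]


class ConfigError(ValueError):
    """Schema violation in a YAML configuration, with the offending key path."""


_BLOCKS = {
    "optics": OpticalConfig,
    "ga": GAConfig,
    "fitness": FitnessSpec,
    "phantom": PhantomSpec,
}

_FILTER_KEYS = {"sigma", "min_diameter_px"}

# keys that arrive from YAML as lists but are tuples in the dataclasses
_TUPLE_KEYS = {"z_target", "depth_range_um"}


def _build_block(name: str, cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls) if f.init}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown key(s) under '{name}': {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _TUPLE_KEYS and isinstance(value, (list, tuple)):
            value = tuple(value)
        if key == "bounds" and isinstance(value, dict):
            value = {k: tuple(v) for k, v in value.items()}
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value under '{name}': {exc}") from exc


def load_config(path: str | Path) -> dict:
    """Parse and validate a YAML config; returns a dict of typed blocks.

    Required block: ``optics``.  Optional blocks get their defaults when
    absent.  The special key ``source_diameter_um`` (top level, default 5)
    and ``scattering_length_um`` (top level, default 100) configure the
    forward model's source and decay.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    known_top = set(_BLOCKS) | {"filter", "source_diameter_um", "scattering_length_um"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    if "optics" not in raw:
        raise ConfigError("missing required block 'optics'")
    for block in _BLOCKS:
        if block in raw and not isinstance(raw[block], dict):
            raise ConfigError(f"block '{block}' must be a mapping")
    if "optics" in raw:
        for required in ("na",):
            if required not in raw["optics"]:
                raise ConfigError(f"missing required key 'optics.{required}'")

    cfg = {
        name: _build_block(name, cls, raw.get(name, {})) for name, cls in _BLOCKS.items()
    }
    filt = raw.get("filter", {})
    if not isinstance(filt, dict):
        raise ConfigError("block 'filter' must be a mapping")
    unknown = set(filt) - _FILTER_KEYS
    if unknown:
        raise ConfigError(f"unknown key(s) under 'filter': {sorted(unknown)}")
    cfg["filter"] = {"sigma": 8.0, "min_diameter_px": 4.0, **filt}
    cfg["source_diameter_um"] = float(raw.get("source_diameter_um", 5.0))
    ls = raw.get("scattering_length_um", 100.0)
    cfg["scattering_length_um"] = float("inf") if ls in ("inf", None) else float(ls)
    return cfg


def default_config_dict() -> dict:
    """The design configuration as a plain dict (YAML-serializable)."""
    return {
        "optics": dataclasses.asdict(OpticalConfig()),
        "ga": dataclasses.asdict(GAConfig()),
        "fitness": {
            "z_target": list(FitnessSpec().z_target),
            "threshold": 0.5,
            "alpha": 4.0,
            "mode": "profile",
        },
        "phantom": dataclasses.asdict(PhantomSpec()),
        "filter": {"sigma": 8.0, "min_diameter_px": 4.0},
        "source_diameter_um": 5.0,
        "scattering_length_um": 100.0,
    }


def dump_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    command: str
    config_snapshot: dict
    seeds: list[int]
    outputs: dict = dataclasses.field(default_factory=dict)

    def add_output(self, path: str | Path) -> None:
        path = Path(path)
        self.outputs[path.name] = _file_sha256(path)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "tool": "edofmask",
            "version": __version__,
            "command": self.command,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "seeds": self.seeds,
            "config": self.config_snapshot,
            "output_sha256": self.outputs,
        }
        path.write_text(json.dumps(payload, indent=2, default=str))
        return path
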