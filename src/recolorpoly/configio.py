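"""Run configuration: TOML in, validated parameter objects out.

A run config has up to four tables — ``[simulation]``, ``[schedule]``,
``[output]`` and ``[imaging]`` — whose keys map one-to-one onto
:class:`~recolorpoly.params.SimulationParams`,
:class:`~recolorpoly.params.ProtocolSchedule` and the output/imaging
options.  Every key has a default equal to the model's stated value, so an
empty file is a valid (full-scale) configuration.  Unknown keys are
rejected by name.
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .params import ProtocolSchedule, SimulationParams


class ConfigError(ValueError):
    """Invalid run configuration (unknown key, bad type, broken invariant)."""


@dataclass
class OutputOptions:
    directory: str = "out"
    trajectory_format: str = "xyz"
    write_events: bool = True

    def __post_init__(self) -> None:
        if self.trajectory_format != "xyz":
            raise ConfigError(f"unsupported trajectory format {self.trajectory_format!r}")


@dataclass
class ImagingOptions:
    mask_mode: str = "colocalization"
    normalize_variance: bool = True
    density_radius: float = 2.0

    def __post_init__(self) -> None:
        if self.mask_mode not in ("colocalization", "coexpression", "variance"):
            raise ConfigError(f"unknown mask_mode {self.mask_mode!r}")
        if self.density_radius <= 0:
            raise ConfigError("density_radius must be positive")


@dataclass
class RunConfig:
    simulation: SimulationParams = field(default_factory=SimulationParams)
    schedule: ProtocolSchedule = field(default_factory=ProtocolSchedule)
    output: OutputOptions = field(default_factory=OutputOptions)
    imaging: ImagingOptions = field(default_factory=ImagingOptions)
    source_path: str | None = None
    source_hash: str | None = None


_SECTIONS = {
    "simulation": SimulationParams,
    "schedule": ProtocolSchedule,
    "output": OutputOptions,
    "imaging": ImagingOptions,
}


def _build(section: str, cls, data: dict):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"[{section}] has unknown keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = known[key]
        if f.type in ("int",) and isinstance(value, bool):
            raise ConfigError(f"[{section}] {key}: expected int, got bool")
        if f.type == "int" and not isinstance(value, int):
            raise ConfigError(f"[{section}] {key}: expected int, got {type(value).__name__}")
        if f.type == "float" and not isinstance(value, (int, float)):
            raise ConfigError(f"[{section}] {key}: expected number")
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"[{section}]: {exc}") from exc


def read_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration; defaults fill gaps."""
    path = Path(path)
    raw = path.read_bytes()
    try:
        data = tomllib.loads(raw.decode())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    built = {
        name: _build(name, cls, data.get(name, {})) for name, cls in _SECTIONS.items()
    }
    return RunConfig(
        **built,
        source_path=str(path),
        source_hash=hashlib.sha256(raw).hexdigest(),
    )


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if v is None:
        raise ConfigError("cannot serialize None; omit the key instead")
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_config(config: RunConfig, path) -> None:
    """Serialize a RunConfig back to TOML (round-trips through read_config)."""
    lines = []
    for name, cls in _SECTIONS.items():
        obj = getattr(config, name)
        lines.append(f"[{name}]")
        for f in fields(cls):
            value = getattr(obj, f.name)
            if value is None:
                continue
            lines.append(f"{f.name} = {_toml_value(value)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def provenance_record(config: RunConfig, seeds, extra: dict | None = None) -> dict:
    """Machine-readable record sufficient to reproduce a run bit-identically."""
    import numpy

    from . import __version__

    rec = {
        "config_path": config.source_path,
        "config_sha256": config.source_hash,
        "seeds": list(map(int, seeds)),
        "package_version": __version__,
        "numpy_version": numpy.__version__,
        "simulation": config.simulation.to_dict(),
        "schedule": config.schedule.to_dict(),
    }
    if extra:
        rec.update(extra)
    return rec
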