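"""Run configuration: YAML schema, validation, overrides and manifests.

The configuration mirrors the library objects section by section; shipped
defaults reproduce the published wrist-model parameters (media table, vessel
mechanics, obesity scenario rows, sensor geometry).  Unknown keys are
rejected so typos fail loudly.  Every command writes a manifest (config
hash + seed) sufficient to reproduce its outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .grid import GridSpec
from .optical_properties import (
    ChromophoreModel,
    MediumTable,
    MelaninSetting,
    ObesityScenario,
    OpticalProperties,
    DEFAULT_SCENARIOS,
)
from .photon_transport import DetectorSpec, SourceSpec
from .ppg_waveform import SimulationSettings
from .pulse_geometry import default_pulse_shape, PulseShape
from .tissue_volume import lumen_axis_depth
from .vessel_mechanics import PressureLoad, VesselSpec

__all__ = ["ConfigError", "RunConfig", "load_config", "config_hash", "write_manifest"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class RunConfig:
    """Validated top-level configuration for the command-line tools."""

    vessel: VesselSpec = field(default_factory=VesselSpec)
    pressure: PressureLoad = field(default_factory=PressureLoad)
    grid: GridSpec = field(default_factory=GridSpec)
    source: SourceSpec = field(default_factory=SourceSpec)
    detector: DetectorSpec = field(default_factory=DetectorSpec)
    chromophores: ChromophoreModel = field(default_factory=ChromophoreModel)
    table: MediumTable = field(default_factory=MediumTable)
    scenario: ObesityScenario = DEFAULT_SCENARIOS[0]
    melanin: MelaninSetting = field(default_factory=MelaninSetting)
    pulse_shape: dict = field(default_factory=dict)  # overrides for default_pulse_shape
    wavelength: int = 660
    n_photons: int = 30_000
    n_trials: int = 3
    n_positions: int = 89
    seed: int = 1
    internal_fresnel: bool = True
    use_weight_windows: bool = True
    output_dir: str = "ppgsim_out"

    def settings(self) -> SimulationSettings:
        return SimulationSettings(
            grid=self.grid, vessel=self.vessel, table=self.table,
            chromophores=self.chromophores, source=self.source,
            detector=self.detector, wavelength=self.wavelength,
            n_photons=self.n_photons, n_trials=self.n_trials,
            n_positions=self.n_positions, seed=self.seed,
            internal_fresnel=self.internal_fresnel,
            use_weight_windows=self.use_weight_windows,
        )

    def shape(self) -> PulseShape:
        return default_pulse_shape(
            self.vessel, self.pressure,
            lumen_axis_depth_cm=lumen_axis_depth(self.scenario, self.vessel),
            **self.pulse_shape,
        )


_SECTION_TYPES = {
    "vessel": VesselSpec,
    "pressure": PressureLoad,
    "grid": GridSpec,
    "source": SourceSpec,
    "detector": DetectorSpec,
    "chromophores": ChromophoreModel,
    "scenario": ObesityScenario,
    "melanin": MelaninSetting,
}

_SCALAR_KEYS = {
    "wavelength": int,
    "n_photons": int,
    "n_trials": int,
    "n_positions": int,
    "seed": int,
    "internal_fresnel": bool,
    "use_weight_windows": bool,
    "output_dir": str,
}

_PULSE_SHAPE_KEYS = {"secondary_fraction", "pwd1", "pwd2", "psep"}


def _build_section(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section {path!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in {path!r}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {path!r}: {exc}") from exc


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (defaults if ``path`` is None) and apply overrides.

    Overrides use dotted paths (``vessel.inner_diameter_cm=0.3``); values are
    parsed as YAML scalars.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("top-level config must be a mapping")
        data = raw
    for dotted, value in (overrides or {}).items():
        parts = dotted.split(".")
        node = data
        for p in parts[:-1]:
            node = node.setdefault(p, {})
            if not isinstance(node, dict):
                raise ConfigError(f"cannot override {dotted!r}: {p!r} is not a mapping")
        node[parts[-1]] = yaml.safe_load(str(value))

    kwargs: dict = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        elif key == "media":
            if not isinstance(value, dict):
                raise ConfigError("'media' must map 'medium@wavelength' to properties")
            entries = {}
            for mkey, props in value.items():
                medium, wl = str(mkey).rsplit("@", 1)
                entries[(medium, int(wl))] = _build_section(
                    OpticalProperties, props, f"media.{mkey}"
                )
            try:
                kwargs["table"] = MediumTable(entries)
            except KeyError as exc:
                raise ConfigError(str(exc)) from exc
        elif key == "pulse_shape":
            if not isinstance(value, dict):
                raise ConfigError("'pulse_shape' must be a mapping")
            unknown = set(value) - _PULSE_SHAPE_KEYS
            if unknown:
                raise ConfigError(f"unknown keys in 'pulse_shape': {sorted(unknown)}")
            kwargs["pulse_shape"] = dict(value)
        elif key in _SCALAR_KEYS:
            kwargs[key] = _SCALAR_KEYS[key](value)
        else:
            raise ConfigError(f"unknown top-level config key {key!r}")
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full configuration."""

    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, MediumTable):
            return obj.to_dict()
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in sorted(obj.items())}
        return obj

    blob = json.dumps(encode(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(config: RunConfig, out_dir: Path, command: str, extra: dict | None = None) -> Path:
    """Write the reproduction manifest (config hash, seed, command) as JSON."""
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_photons": config.n_photons,
        "n_trials": config.n_trials,
        "wavelength": config.wavelength,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / f"{command}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
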