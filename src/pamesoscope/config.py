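"""Run configuration: YAML-serializable description of a full pipeline run.

A RunConfig fully determines a run: a master seed, the scan geometry, the
sensor, the phantom, the SOS model, the reconstruction grid and the analysis
stage.  Persisting the config and re-running reproduces deterministic outputs
bit-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import synthetic
from .constants import (
    DEFAULT_BANDWIDTH_3DB,
    DEFAULT_NEP_PA,
    DEFAULT_PITCH,
    DEFAULT_PULSE_FWHM,
    DEFAULT_REP_RATE,
    DEFAULT_SAMPLING_RATE,
    SOUND_SPEED_WATER,
)
from .types import (
    AbsorberPhantom,
    Ellipsoid,
    ReconGrid,
    ScanGeometry,
    SensorModel,
    SOSModel,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "build_geometry",
    "build_sensor",
    "build_phantom",
    "build_sos_model",
    "build_grid",
]

KNOWN_STAGES = ("simulate", "reconstruct", "analyze")


class ConfigError(ValueError):
    """A run configuration field is missing or invalid."""


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs/out"
    stages: list = field(default_factory=lambda: list(KNOWN_STAGES))
    scan: dict = field(default_factory=dict)
    sensor: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=lambda: {"kind": "wires"})
    sos: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        for stage in self.stages:
            if stage not in KNOWN_STAGES:
                raise ConfigError(
                    f"stages: unknown stage {stage!r}; known: {KNOWN_STAGES}"
                )
        kind = self.phantom.get("kind")
        if kind not in ("wires", "vessels"):
            raise ConfigError(f"phantom.kind: unknown phantom kind {kind!r}")
        return self

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f_.name for f_ in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)


def build_geometry(scan: dict) -> ScanGeometry:
    nx = int(scan.get("nx", 32))
    ny = int(scan.get("ny", 32))
    pitch = float(scan.get("pitch", DEFAULT_PITCH))
    rep = float(scan.get("rep_rate", DEFAULT_REP_RATE))
    if scan.get("centered", True):
        origin = (-(nx - 1) / 2.0 * pitch, -(ny - 1) / 2.0 * pitch, 0.0)
    else:
        origin = tuple(scan.get("origin", (0.0, 0.0, 0.0)))
    return synthetic.make_raster_geometry(nx, ny, pitch, rep, origin=origin)


def build_sensor(sensor: dict, fs: Optional[float] = None) -> SensorModel:
    return synthetic.make_default_sensor(
        fs=float(fs if fs is not None else sensor.get("fs", DEFAULT_SAMPLING_RATE)),
        bw_3db=float(sensor.get("bw_3db", DEFAULT_BANDWIDTH_3DB)),
        nep=float(sensor.get("nep", DEFAULT_NEP_PA)),
        tail_amp=float(sensor.get("tail_amp", 0.1)),
        tail_freq=float(sensor.get("tail_freq", 18e6)),
        tail_tau=float(sensor.get("tail_tau", 50e-9)),
    )


def build_phantom(phantom: dict, seed: int) -> AbsorberPhantom:
    kind = phantom.get("kind", "wires")
    sos = float(phantom.get("sos", SOUND_SPEED_WATER))
    if kind == "wires":
        depths = phantom.get("depths", [2e-3, 4e-3, 6e-3])
        return synthetic.make_wire_phantom(
            n_wires=len(depths),
            wire_diameter=float(phantom.get("wire_diameter", 9e-6)),
            depths=[float(d) for d in depths],
            sos=sos,
            length=float(phantom.get("length", 2e-3)),
            amplitude=float(phantom.get("amplitude", 1e6)),
        )
    if kind == "vessels":
        return synthetic.make_vessel_phantom(
            seed=seed,
            n_branches=int(phantom.get("n_branches", 4)),
            so2_artery=float(phantom.get("so2_artery", 0.95)),
            so2_vein=float(phantom.get("so2_vein", 0.65)),
            sos=sos,
        )
    raise ConfigError(f"phantom.kind: unknown phantom kind {kind!r}")


def build_sos_model(sos: dict) -> SOSModel:
    bg = float(sos.get("background_sos", SOUND_SPEED_WATER))
    ell = sos.get("ellipsoid")
    if ell is None:
        return SOSModel(background_sos=bg)
    return SOSModel(
        background_sos=bg,
        ellipsoid=Ellipsoid(
            center=tuple(ell["center"]),
            semi_axes=tuple(ell["semi_axes"]),
            inner_sos=float(ell["inner_sos"]),
        ),
    )


def build_grid(grid: dict) -> ReconGrid:
    return ReconGrid(
        shape=tuple(int(s) for s in grid.get("shape", (64, 64, 128))),
        voxel=float(grid.get("voxel", 50e-6)),
        origin=tuple(grid.get("origin", (0.0, 0.0, 0.0))),
    )
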