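"""Core domain containers for the planar-scan photoacoustic pipeline.

Coordinate convention: right-handed, SI meters, the detector plane sits at
``z = plane_z`` (0 by default) and ``z`` increases with depth into tissue.
All grids are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ScanGeometry",
    "Absorber",
    "AbsorberPhantom",
    "SensorModel",
    "SignalSet",
    "Ellipsoid",
    "SOSModel",
    "ReconGrid",
    "ReconVolume",
]


def _vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise ValueError(f"{name} must be a 3-vector, got shape {np.shape(x)}")
    return v


@dataclass(frozen=True)
class ScanGeometry:
    """Planar raster scan: ``nx * ny`` detector positions on a regular grid.

    Point ``[i, j]`` sits at ``origin + (i*pitch, j*pitch, 0)``; all points lie
    in the plane ``z = plane_z``.
    """

    nx: int
    ny: int
    pitch: float
    origin: np.ndarray = (0.0, 0.0, 0.0)
    rep_rate: float = 10.0

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("nx and ny must be >= 1")
        if not self.pitch > 0:
            raise ValueError("pitch must be positive")
        if not self.rep_rate > 0:
            raise ValueError("rep_rate must be positive")
        object.__setattr__(self, "origin", _vec3(self.origin, "origin"))

    @property
    def plane_z(self) -> float:
        return float(self.origin[2])

    @property
    def n_points(self) -> int:
        return self.nx * self.ny

    @property
    def positions(self) -> np.ndarray:
        """Detector positions, shape ``(nx, ny, 3)``."""
        ii, jj = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        pos = np.empty((self.nx, self.ny, 3))
        pos[..., 0] = self.origin[0] + ii * self.pitch
        pos[..., 1] = self.origin[1] + jj * self.pitch
        pos[..., 2] = self.origin[2]
        return pos

    @property
    def extent(self) -> tuple[float, float]:
        """Physical span (x, y) of the scan aperture in meters."""
        return ((self.nx - 1) * self.pitch, (self.ny - 1) * self.pitch)


@dataclass(frozen=True)
class Absorber:
    """Spherical absorber with per-wavelength absorbed-energy amplitude.

    ``amplitude_per_wavelength`` maps wavelength in nm to the pressure-generating
    source amplitude (Pa-scale arbitrary units, >= 0).  A ``None`` key marks a
    wavelength-independent absorber (e.g. a metal wire).
    """

    center: np.ndarray
    radius: float
    amplitude_per_wavelength: Mapping[Optional[float], float]
    label: str = ""
    so2: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "center", _vec3(self.center, "center"))
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        for wl, a in self.amplitude_per_wavelength.items():
            if a < 0:
                raise ValueError(f"amplitude at {wl} nm must be >= 0")
        if self.so2 is not None and not 0.0 <= self.so2 <= 1.0:
            raise ValueError("so2 must lie in [0, 1]")

    def amplitude(self, wavelength_nm: float) -> float:
        table = self.amplitude_per_wavelength
        if wavelength_nm in table:
            return float(table[wavelength_nm])
        if None in table:
            return float(table[None])
        raise KeyError(
            f"absorber {self.label!r} has no amplitude at {wavelength_nm} nm"
        )


@dataclass(frozen=True)
class AbsorberPhantom:
    """Ordered collection of spherical absorbers in a homogeneous medium."""

    absorbers: Sequence[Absorber]
    medium_sos: float = 1500.0
    name: str = ""

    def __post_init__(self):
        if not self.medium_sos > 0:
            raise ValueError("medium_sos must be positive")
        object.__setattr__(self, "absorbers", tuple(self.absorbers))

    def __len__(self) -> int:
        return len(self.absorbers)

    def subset(self, labels: Sequence[str]) -> "AbsorberPhantom":
        keep = tuple(a for a in self.absorbers if a.label in labels)
        return AbsorberPhantom(keep, self.medium_sos, self.name)


@dataclass(frozen=True)
class SensorModel:
    """Ultrasound sensor: impulse response, directivity and noise floor.

    ``impulse_response`` is sampled at ``fs`` with its time-zero at sample
    ``center_index`` and is area-normalized (sum * dt == 1, unit DC gain), so
    its values carry units of 1/s.  ``directivity`` maps incidence angle in
    degrees (-90..90, 0 = normal incidence) to a gain in [0, 1].
    """

    impulse_response: np.ndarray
    fs: float
    bw_3db: float
    directivity: Callable[[np.ndarray], np.ndarray]
    nep: float
    center_index: int = 0

    def __post_init__(self):
        h = np.asarray(self.impulse_response, dtype=float)
        object.__setattr__(self, "impulse_response", h)
        if not np.all(np.isfinite(h)) or h.size == 0:
            raise ValueError("impulse_response must be finite and non-empty")
        if not self.fs > 2.0 * self.bw_3db:
            raise ValueError("fs must exceed twice the design bandwidth")
        if self.nep < 0:
            raise ValueError("nep must be >= 0")
        g0 = float(np.asarray(self.directivity(np.array(0.0))))
        if abs(g0 - 1.0) > 1e-6:
            raise ValueError("directivity(0) must equal 1")
        if not 0 <= self.center_index < h.size:
            raise ValueError("center_index out of range")


@dataclass(frozen=True)
class SignalSet:
    """Time-series pressure records on the scan grid.

    ``data`` has axis semantics ``[scan_x, scan_y, time]`` in Pa; ``t0`` is the
    time of the first sample relative to the laser pulse.
    """

    data: np.ndarray
    fs: float
    t0: float
    geometry: ScanGeometry
    wavelength_nm: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if d.ndim != 3 or d.shape[:2] != (self.geometry.nx, self.geometry.ny):
            raise ValueError(
                f"data shape {d.shape} does not match geometry "
                f"({self.geometry.nx}, {self.geometry.ny}, nt)"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(d)):
            raise ValueError("data must be finite")

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid of different speed of sound."""

    center: np.ndarray
    semi_axes: np.ndarray
    inner_sos: float

    def __post_init__(self):
        object.__setattr__(self, "center", _vec3(self.center, "center"))
        ax = _vec3(self.semi_axes, "semi_axes")
        object.__setattr__(self, "semi_axes", ax)
        if not np.all(ax > 0):
            raise ValueError("semi_axes must all be positive")
        if not self.inner_sos > 0:
            raise ValueError("inner_sos must be positive")


@dataclass(frozen=True)
class SOSModel:
    """Background speed of sound plus an optional higher/lower-SOS ellipsoid."""

    background_sos: float
    ellipsoid: Optional[Ellipsoid] = None

    def __post_init__(self):
        if not self.background_sos > 0:
            raise ValueError("background_sos must be positive")


@dataclass(frozen=True, eq=False)
class ReconGrid:
    """Regular isotropic voxel grid: ``shape`` voxels of size ``voxel``.

    Voxel ``[i, j, k]`` center sits at ``origin + voxel * (i, j, k)``.
    """

    shape: tuple[int, int, int]
    voxel: float
    origin: np.ndarray = (0.0, 0.0, 0.0)

    def __eq__(self, other):
        if not isinstance(other, ReconGrid):
            return NotImplemented
        return (
            self.shape == other.shape
            and self.voxel == other.voxel
            and bool(np.all(self.origin == other.origin))
        )

    def __hash__(self):
        return hash((self.shape, self.voxel, tuple(self.origin)))

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError("shape must be three positive voxel counts")
        if not self.voxel > 0:
            raise ValueError("voxel size must be positive")
        object.__setattr__(self, "origin", _vec3(self.origin, "origin"))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.voxel * np.arange(self.shape[axis])

    def point_to_index(self, point) -> tuple[int, int, int]:
        p = _vec3(point, "point")
        idx = np.rint((p - self.origin) / self.voxel).astype(int)
        idx = np.clip(idx, 0, np.array(self.shape) - 1)
        return tuple(int(i) for i in idx)

    def index_to_point(self, idx) -> np.ndarray:
        return self.origin + self.voxel * np.asarray(idx, dtype=float)


@dataclass(frozen=True)
class ReconVolume:
    """Reconstructed PA amplitude on a :class:`ReconGrid`."""

    grid: ReconGrid
    values: np.ndarray
    wavelength_nm: Optional[float] = None
    envelope_applied: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != self.grid.shape:
            raise ValueError(f"values shape {v.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if self.envelope_applied and np.any(v < 0):
            raise ValueError("envelope volumes must be non-negative")
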