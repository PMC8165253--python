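"""Downstream image analysis: resolution, MIP rendering, segmentation,
fluence compensation and dual-wavelength artery/vein contrast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from matplotlib import colormaps
from scipy import ndimage
from scipy.optimize import curve_fit

from .types import AbsorberPhantom, ReconGrid, ReconVolume

__all__ = [
    "WireResolution",
    "ResolutionReport",
    "estimate_resolution",
    "pulse_limited_resolution",
    "DepthCodedMIP",
    "depth_coded_mip",
    "VesselSegmentation",
    "segment_vessels",
    "mean_paa",
    "FluenceMap",
    "compute_fluence",
    "fluence_compensate",
    "DualWavelengthResult",
    "dual_wavelength_difference",
    "phantom_label_mask",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# resolution

@dataclass(frozen=True)
class WireResolution:
    depth: float
    axial_fwhm: float
    lateral_fwhm: float
    fit_r2_axial: float
    fit_r2_lateral: float
    usable: bool


@dataclass(frozen=True)
class ResolutionReport:
    """Per-wire Gaussian-fit FWHMs plus linear depth-trend coefficients.

    ``axial_trend`` / ``lateral_trend`` are (slope, intercept) of FWHM vs
    depth over the usable wires.
    """

    wires: tuple[WireResolution, ...]
    axial_trend: tuple[float, float]
    lateral_trend: tuple[float, float]

    @property
    def usable(self) -> tuple[WireResolution, ...]:
        return tuple(w for w in self.wires if w.usable)

    @property
    def mean_axial_fwhm(self) -> float:
        return float(np.mean([w.axial_fwhm for w in self.usable]))


def _gauss_offset(x, amp, mu, sigma, off):
    return off + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_gaussian_fwhm(coords: np.ndarray, profile: np.ndarray) -> tuple[float, float]:
    """Least-squares Gaussian + constant-offset fit; returns (FWHM, r^2)."""
    prof = np.asarray(profile, dtype=float)
    x = np.asarray(coords, dtype=float)
    off0 = float(prof.min())
    amp0 = float(prof.max() - off0)
    mu0 = float(x[np.argmax(prof)])
    above = prof - off0 > amp0 / 2.0
    sigma0 = max((above.sum() * abs(x[1] - x[0])) / FWHM_PER_SIGMA, abs(x[1] - x[0]))
    try:
        popt, _ = curve_fit(
            _gauss_offset,
            x,
            prof,
            p0=(amp0, mu0, sigma0, off0),
            bounds=(
                (0.0, x.min(), 1e-12, -np.inf),
                (np.inf, x.max(), (x.max() - x.min()), np.inf),
            ),
            maxfev=10000,
        )
    except RuntimeError:
        return math.nan, 0.0
    resid = prof - _gauss_offset(x, *popt)
    ss_tot = float(np.sum((prof - prof.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return FWHM_PER_SIGMA * float(popt[2]), r2


def estimate_resolution(
    volume: ReconVolume,
    approx_positions: Sequence,
    wire_axis: int = 1,
    search_radius: float = 0.4e-3,
    profile_halfwidth: float = 0.6e-3,
    min_r2: float = 0.5,
) -> ResolutionReport:
    """Per-wire line-spread-function FWHMs from an envelope volume.

    For each approximate wire position (meters), the intensity peak is located
    within ``search_radius``, then the axial (z) and lateral (x, for wires
    along y) profiles through the peak are fitted with a Gaussian plus
    constant offset; FWHM = 2*sqrt(2 ln 2)*sigma.  Wires whose fit r^2 falls
    below ``min_r2`` are flagged unusable and excluded from the depth-trend
    fits.
    """
    if not volume.envelope_applied:
        raise ValueError("resolution estimation requires an envelope volume")
    if wire_axis not in (0, 1):
        raise ValueError("wire_axis must be 0 (x) or 1 (y)")
    lateral_axis = 1 - wire_axis
    grid = volume.grid
    v = volume.values
    rad = max(1, int(round(search_radius / grid.voxel)))
    half = max(3, int(round(profile_halfwidth / grid.voxel)))
    wires = []
    for pos in approx_positions:
        i0, j0, k0 = grid.point_to_index(pos)
        sl = tuple(
            slice(max(0, c - rad), min(s, c + rad + 1))
            for c, s in zip((i0, j0, k0), grid.shape)
        )
        local = v[sl]
        pk = np.unravel_index(np.argmax(local), local.shape)
        idx = tuple(s.start + p for s, p in zip(sl, pk))

        def line(axis: int):
            lo = max(0, idx[axis] - half)
            hi = min(grid.shape[axis], idx[axis] + half + 1)
            sel = [idx[0], idx[1], idx[2]]
            sel[axis] = slice(lo, hi)
            prof = v[tuple(sel)]
            coords = grid.axis_coords(axis)[lo:hi]
            return coords, prof

        fz, r2z = fit_gaussian_fwhm(*line(2))
        fl, r2l = fit_gaussian_fwhm(*line(lateral_axis))
        usable = (r2z >= min_r2) and (r2l >= min_r2) and math.isfinite(fz) and math.isfinite(fl)
        wires.append(
            WireResolution(
                depth=float(grid.axis_coords(2)[idx[2]]),
                axial_fwhm=fz,
                lateral_fwhm=fl,
                fit_r2_axial=r2z,
                fit_r2_lateral=r2l,
                usable=usable,
            )
        )
    good = [w for w in wires if w.usable]
    if len(good) >= 2:
        depths = np.array([w.depth for w in good])
        ax_tr = tuple(np.polyfit(depths, [w.axial_fwhm for w in good], 1))
        la_tr = tuple(np.polyfit(depths, [w.lateral_fwhm for w in good], 1))
    else:
        ax_tr = (math.nan, math.nan)
        la_tr = (math.nan, math.nan)
    return ResolutionReport(wires=tuple(wires), axial_trend=ax_tr, lateral_trend=la_tr)


def pulse_limited_resolution(pulse_duration: float, sos: float) -> float:
    """Elastic-relaxation resolution floor: pulse duration times sound speed."""
    if pulse_duration < 0 or sos <= 0:
        raise ValueError("pulse_duration must be >= 0 and sos > 0")
    return pulse_duration * sos


# ---------------------------------------------------------------------------
# rendering

@dataclass(frozen=True)
class DepthCodedMIP:
    """Maximum-intensity projection with arg-max depth coding."""

    rgb: np.ndarray
    intensity: np.ndarray
    depth_index: np.ndarray
    axis: int


def depth_coded_mip(
    volume: ReconVolume, axis: int = 2, cmap: str = "viridis"
) -> DepthCodedMIP:
    """Project max intensity along ``axis``; hue encodes the arg-max index.

    Ties break to the first (shallowest) index, numpy ``argmax`` convention.
    The RGB image is the colormap of the normalized depth scaled by the
    normalized intensity.
    """
    if not volume.envelope_applied:
        raise ValueError("depth-coded MIP requires an envelope volume")
    v = volume.values
    intensity = v.max(axis=axis)
    depth_index = v.argmax(axis=axis)
    n = v.shape[axis]
    depth_norm = depth_index / max(n - 1, 1)
    imax = intensity.max()
    inten_norm = intensity / imax if imax > 0 else intensity
    rgb = colormaps[cmap](depth_norm)[..., :3] * inten_norm[..., None]
    return DepthCodedMIP(rgb=rgb, intensity=intensity, depth_index=depth_index, axis=axis)


# ---------------------------------------------------------------------------
# segmentation and per-vessel amplitude

@dataclass(frozen=True)
class VesselSegmentation:
    """Integer label volume (0 = background) with per-label voxel counts."""

    labels: np.ndarray
    grid: ReconGrid
    voxel_counts: dict[int, int]
    mean_paa_per_wavelength: dict[int, dict[float, float]] = field(default_factory=dict)

    @property
    def n_labels(self) -> int:
        return len(self.voxel_counts)


def segment_vessels(
    volume: ReconVolume,
    high_thresh: float = 0.5,
    low_thresh: float = 0.2,
    min_voxels: int = 10,
) -> VesselSegmentation:
    """Hysteresis segmentation: seed at >= high, grow into >= low (26-conn).

    Thresholds are fractions of the volume maximum.  Components smaller than
    ``min_voxels`` are discarded; surviving components are relabeled 1..n by
    decreasing size.  No voxel above the high threshold yields an empty
    segmentation with a warning.
    """
    if not volume.envelope_applied:
        raise ValueError("segmentation requires an envelope volume")
    if not 0.0 < low_thresh < high_thresh <= 1.0:
        raise ValueError("need 0 < low_thresh < high_thresh <= 1")
    v = volume.values
    vmax = v.max()
    out = np.zeros(v.shape, dtype=np.int32)
    if vmax <= 0 or not np.any(v >= high_thresh * vmax):
        warnings.warn("no voxel above the high threshold; empty segmentation")
        return VesselSegmentation(labels=out, grid=volume.grid, voxel_counts={})
    structure = np.ones((3, 3, 3), dtype=bool)
    low_mask = v >= low_thresh * vmax
    lab, n = ndimage.label(low_mask, structure=structure)
    seeds = v >= high_thresh * vmax
    seeded = np.unique(lab[seeds])
    seeded = seeded[seeded > 0]
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=seeded)
    keep = [(int(s), int(l)) for s, l in zip(sizes, seeded) if s >= min_voxels]
    keep.sort(key=lambda t: (-t[0], t[1]))
    counts = {}
    for new, (size, old) in enumerate(keep, start=1):
        out[lab == old] = new
        counts[new] = size
    return VesselSegmentation(labels=out, grid=volume.grid, voxel_counts=counts)


def mean_paa(
    segmentation: VesselSegmentation,
    volumes: Mapping[float, ReconVolume],
) -> dict[int, dict[float, float]]:
    """Mean photoacoustic amplitude per label per wavelength.

    All volumes must share the segmentation's grid.  Returns
    ``{label: {wavelength: mean amplitude}}``.
    """
    labels = sorted(segmentation.voxel_counts)
    result: dict[int, dict[float, float]] = {l: {} for l in labels}
    for wl, vol in volumes.items():
        if vol.grid != segmentation.grid:
            raise ValueError(f"volume at {wl} nm is not on the segmentation grid")
        if labels:
            means = ndimage.mean(vol.values, segmentation.labels, index=labels)
            for l, m in zip(labels, np.atleast_1d(means)):
                result[l][wl] = float(m)
    return result


# ---------------------------------------------------------------------------
# fluence

@dataclass(frozen=True)
class FluenceMap:
    """Relative optical fluence (max 1) on a recon grid."""

    values: np.ndarray
    grid: ReconGrid
    wavelength_nm: Optional[float]
    mu_a: float
    mu_s_prime: float

    @property
    def mu_eff(self) -> float:
        return math.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_prime))


def compute_fluence(
    surface_height_map: np.ndarray,
    grid: ReconGrid,
    mu_a: float,
    mu_s_prime: float,
    wavelength_nm: Optional[float] = None,
) -> FluenceMap:
    """Diffusion-approximation fluence below an arbitrary surface profile.

    ``fluence = exp(-mu_eff * depth_below_surface)`` with
    ``mu_eff = sqrt(3 mu_a (mu_a + mu_s'))``; 1 at and above the surface.
    ``surface_height_map`` gives the tissue surface z (meters) per (x, y)
    column of the grid.
    """
    if mu_a <= 0 or mu_s_prime <= 0:
        raise ValueError("optical coefficients must be positive")
    surf = np.asarray(surface_height_map, dtype=float)
    if surf.shape != grid.shape[:2]:
        raise ValueError(
            f"surface map shape {surf.shape} does not match grid xy {grid.shape[:2]}"
        )
    z = grid.axis_coords(2)
    depth = np.clip(z[None, None, :] - surf[:, :, None], 0.0, None)
    mu_eff = math.sqrt(3.0 * mu_a * (mu_a + mu_s_prime))
    return FluenceMap(
        values=np.exp(-mu_eff * depth),
        grid=grid,
        wavelength_nm=wavelength_nm,
        mu_a=mu_a,
        mu_s_prime=mu_s_prime,
    )


def fluence_compensate(
    volume: ReconVolume, fluence: FluenceMap, floor: float = 0.01
) -> ReconVolume:
    """Divide the image by the fluence, clamped below at ``floor``.

    The floor caps the maximum gain at ``1/floor`` so noise at depth is not
    blown up.
    """
    if not 0.0 < floor < 1.0:
        raise ValueError("floor must lie in (0, 1)")
    if fluence.grid != volume.grid:
        raise ValueError("fluence map is not on the volume grid")
    comp = volume.values / np.maximum(fluence.values, floor)
    return ReconVolume(
        grid=volume.grid,
        values=comp,
        wavelength_nm=volume.wavelength_nm,
        envelope_applied=volume.envelope_applied,
    )


# ---------------------------------------------------------------------------
# dual-wavelength difference

@dataclass(frozen=True)
class DualWavelengthResult:
    """Energy-normalized long-minus-short wavelength difference volume.

    ``difference`` is positive where the long-wavelength (1,064 nm,
    artery-favoring) image dominates and negative where the short-wavelength
    (800 nm) image does; MIPs use a diverging map, red positive, blue
    negative.
    """

    difference: np.ndarray
    grid: ReconGrid
    mips: dict[str, np.ndarray]


def dual_wavelength_difference(
    vol_long: ReconVolume,
    vol_short: ReconVolume,
    cmap: str = "RdBu_r",
) -> DualWavelengthResult:
    """Normalize both envelope volumes by total energy and subtract.

    Total energy is the L1 sum of envelope amplitudes, so each normalized
    volume sums to exactly 1; the result is invariant to rescaling either
    input by a positive constant.  ``D = norm(vol_long) - norm(vol_short)``.
    """
    if vol_long.grid != vol_short.grid:
        raise ValueError("volumes are not co-registered on the same grid")
    if not (vol_long.envelope_applied and vol_short.envelope_applied):
        raise ValueError("dual-wavelength difference requires envelope volumes")
    mips = {}
    normed = []
    for vol in (vol_long, vol_short):
        total = float(vol.values.sum())
        if total <= 0:
            raise ValueError("zero total energy: normalization undefined")
        normed.append(vol.values / total)
    diff = normed[0] - normed[1]
    span = float(np.abs(diff).max()) or 1.0
    cm = colormaps[cmap]
    for name, axis in (("xy", 2), ("xz", 1), ("yz", 0)):
        # project the extremal (largest-magnitude) difference along the axis
        pos = diff.max(axis=axis)
        neg = diff.min(axis=axis)
        proj = np.where(pos >= -neg, pos, neg)
        mips[name] = cm(0.5 + 0.5 * proj / span)[..., :3]
    return DualWavelengthResult(difference=diff, grid=vol_long.grid, mips=mips)


# ---------------------------------------------------------------------------
# ground-truth rasterization (for validating segmentation on synthetic data)

def phantom_label_mask(
    phantom: AbsorberPhantom, grid: ReconGrid, labels: Sequence[str]
) -> np.ndarray:
    """Boolean voxel mask of all phantom absorbers carrying one of ``labels``."""
    mask = np.zeros(grid.shape, dtype=bool)
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    for a in phantom.absorbers:
        if a.label not in labels:
            continue
        lo = grid.point_to_index(a.center - a.radius)
        hi = grid.point_to_index(a.center + a.radius)
        sx = slice(lo[0], hi[0] + 1)
        sy = slice(lo[1], hi[1] + 1)
        sz = slice(lo[2], hi[2] + 1)
        dx = xs[sx] - a.center[0]
        dy = ys[sy] - a.center[1]
        dz = zs[sz] - a.center[2]
        r2 = (
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        )
        mask[sx, sy, sz] |= r2 <= a.radius**2
    return mask
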