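"""Synthetic phantoms, scan geometries and forward-simulated PA signals.

The forward model is the closed-form N-wave of a uniformly heated sphere: a
sphere of radius ``a`` and source amplitude ``A`` at distance ``d`` from the
detector radiates

    p(t) = A * (d - c*t) / (2*d)   for |d - c*t| < a,  else 0,

a bipolar wave of peak magnitude ``A*a/(2*d)`` supported on
``[(d-a)/c, (d+a)/c]``.  Detected signals are the superposition of these
waves over all absorbers, attenuated by the sensor's angular directivity,
convolved with the excitation pulse and the sensor impulse response, plus
white Gaussian noise at the sensor's noise-equivalent pressure.

The convolution is evaluated in continuous time: the N-wave is piecewise
linear, so its convolution with a sampled kernel reduces to differences of the
kernel's running integrals.  This stays exact for absorbers whose acoustic
transit time (2a/c) is far below one sample period — the 9 um resolution
wires — where a discrete convolution would alias to nearly zero.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numba
import numpy as np
from scipy.optimize import brentq

from . import characterization
from .constants import (
    DEFAULT_BANDWIDTH_3DB,
    DEFAULT_NEP_PA,
    DEFAULT_PULSE_FWHM,
    DEFAULT_SAMPLING_RATE,
    DEFAULT_SO2_ARTERY,
    DEFAULT_SO2_VEIN,
    HB_EXTINCTION,
    SOUND_SPEED_WATER,
)
from .types import Absorber, AbsorberPhantom, ScanGeometry, SensorModel, SignalSet

__all__ = [
    "make_raster_geometry",
    "acquisition_time",
    "acquisition_time_ceil",
    "make_wire_phantom",
    "make_vessel_phantom",
    "sphere_pressure_waveform",
    "simulate_signals",
    "design_fp_kernel",
    "make_default_sensor",
    "super_gaussian_directivity",
    "vessel_amplitude",
]


# ---------------------------------------------------------------------------
# scan geometry and acquisition accounting

def make_raster_geometry(
    nx: int,
    ny: int,
    pitch: float,
    rep_rate: float,
    origin=(0.0, 0.0, 0.0),
) -> ScanGeometry:
    """Regular planar raster scan of ``nx * ny`` detector positions.

    One laser pulse is fired per scan point; ``origin`` is the position of
    point ``[0, 0]`` (pass a negative x/y origin to center the aperture).
    """
    return ScanGeometry(nx=nx, ny=ny, pitch=pitch, origin=origin, rep_rate=rep_rate)


def acquisition_time(geometry: ScanGeometry) -> float:
    """Scan duration in seconds: one pulse per point, no averaging."""
    return geometry.n_points / geometry.rep_rate


def acquisition_time_ceil(geometry: ScanGeometry) -> int:
    """Scan duration rounded up to whole seconds."""
    return math.ceil(acquisition_time(geometry))


# ---------------------------------------------------------------------------
# phantoms

def make_wire_phantom(
    n_wires: int,
    wire_diameter: float,
    depths: Sequence[float],
    sos: float = SOUND_SPEED_WATER,
    length: float = 2e-3,
    amplitude: float = 1e6,
    x_positions: Optional[Sequence[float]] = None,
) -> AbsorberPhantom:
    """Thin wires parallel to the y-axis, one per depth, as sphere chains.

    Each wire is a dense chain of overlapping spheres of radius
    ``wire_diameter/2`` with center spacing equal to the radius (<= radius, as
    required to keep the chain ripple below the noise floor).  ``amplitude``
    is wavelength-independent (metal absorber).
    """
    depths = [float(d) for d in depths]
    if len(depths) == 0:
        raise ValueError("depths must not be empty")
    if len(depths) != n_wires:
        raise ValueError(f"expected {n_wires} depths, got {len(depths)}")
    if any(d <= 0 for d in depths):
        raise ValueError("depths must be strictly positive")
    radius = wire_diameter / 2.0
    spacing = radius
    n_spheres = max(2, int(math.ceil(length / spacing)) + 1)
    y = np.linspace(-length / 2.0, length / 2.0, n_spheres)
    if x_positions is None:
        x_positions = [0.0] * n_wires
    absorbers = []
    for w, (depth, x0) in enumerate(zip(depths, x_positions)):
        for yk in y:
            absorbers.append(
                Absorber(
                    center=(x0, yk, depth),
                    radius=radius,
                    amplitude_per_wavelength={None: amplitude},
                    label=f"wire{w}",
                )
            )
    return AbsorberPhantom(absorbers, medium_sos=sos, name="wire_phantom")


def vessel_amplitude(
    so2: float,
    wavelength_nm: float,
    extinction_table: Mapping[float, Mapping[str, float]] = HB_EXTINCTION,
    total_hb: float = 1.0,
    pressure_scale: float = 2e4,
) -> float:
    """Source amplitude of a blood vessel at one wavelength.

    Proportional to total hemoglobin times the so2-weighted extinction mix,
    normalized to the 800 nm isosbestic value so a fully oxygenated vessel of
    ``total_hb = 1`` generates ``pressure_scale`` Pa at 800 nm.
    """
    if wavelength_nm not in extinction_table:
        raise ValueError(f"extinction table has no entry at {wavelength_nm} nm")
    eps = extinction_table[wavelength_nm]
    # written so equal extinctions give exact so2-invariance (isosbestic)
    mix = eps["Hb"] + so2 * (eps["HbO2"] - eps["Hb"])
    ref = extinction_table[800.0]["HbO2"]
    return pressure_scale * total_hb * mix / ref


def _grow_tree(
    rng: np.random.Generator,
    root: np.ndarray,
    direction: np.ndarray,
    n_branches: int,
    radius: float,
    seg_len: float,
) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Random branching tree of straight segments: (start, end, radius)."""
    segments = []
    frontier = [(root, direction / np.linalg.norm(direction), radius)]
    while segments.__len__() < n_branches and frontier:
        start, d, r = frontier.pop(0)
        # jitter the direction, keep the tree growing roughly forward
        jitter = rng.normal(scale=0.35, size=3)
        d = d + jitter
        d[2] = abs(d[2]) * 0.2  # stay roughly parallel to the surface
        d /= np.linalg.norm(d)
        end = start + d * seg_len * rng.uniform(0.7, 1.3)
        segments.append((start, end, r))
        n_children = 2 if rng.uniform() < 0.6 else 1
        for _ in range(n_children):
            frontier.append((end, d, max(r * 0.75, 40e-6)))
    return segments


def make_vessel_phantom(
    seed: int,
    n_branches: int = 4,
    so2_artery: float = DEFAULT_SO2_ARTERY,
    so2_vein: float = DEFAULT_SO2_VEIN,
    extinction_table: Mapping[float, Mapping[str, float]] = HB_EXTINCTION,
    wavelengths: Sequence[float] = (800.0, 1064.0),
    sos: float = SOUND_SPEED_WATER,
    depth: float = 1.5e-3,
    vessel_radius: float = 150e-6,
    total_hb: float = 1.0,
    pressure_scale: float = 2e4,
) -> AbsorberPhantom:
    """Random branching artery and vein trees as labeled sphere chains.

    The artery tree grows in the ``y < 0`` half-space and the vein tree in
    ``y > 0`` (spatially disjoint so segmentation labels map cleanly onto
    vessel classes).  Per-vessel amplitudes follow
    ``total_hb * (so2 * eps_HbO2 + (1 - so2) * eps_Hb)`` at each requested
    wavelength.  Reproducible for a fixed seed.
    """
    for so2 in (so2_artery, so2_vein):
        if not 0.0 <= so2 <= 1.0:
            raise ValueError("so2 must lie in [0, 1]")
    for wl in wavelengths:
        if wl not in extinction_table:
            raise ValueError(f"extinction table has no entry at {wl} nm")
    rng = np.random.default_rng(seed)
    seg_len = 0.9e-3
    trees = {
        "artery": _grow_tree(
            rng, np.array([-1.1e-3, -0.9e-3, depth]), np.array([1.0, -0.3, 0.0]),
            n_branches, vessel_radius, seg_len,
        ),
        "vein": _grow_tree(
            rng, np.array([1.1e-3, 0.9e-3, depth + 0.3e-3]), np.array([-1.0, 0.3, 0.0]),
            n_branches, vessel_radius, seg_len,
        ),
    }
    so2_of = {"artery": so2_artery, "vein": so2_vein}
    absorbers = []
    for label, segments in trees.items():
        amp = {
            float(wl): vessel_amplitude(
                so2_of[label], wl, extinction_table, total_hb, pressure_scale
            )
            for wl in wavelengths
        }
        for start, end, r in segments:
            seg = end - start
            n = max(2, int(math.ceil(np.linalg.norm(seg) / r)) + 1)
            for t in np.linspace(0.0, 1.0, n):
                absorbers.append(
                    Absorber(
                        center=start + t * seg,
                        radius=r,
                        amplitude_per_wavelength=amp,
                        label=label,
                        so2=so2_of[label],
                    )
                )
    return AbsorberPhantom(absorbers, medium_sos=sos, name=f"vessel_phantom_seed{seed}")


# ---------------------------------------------------------------------------
# sensor model

def super_gaussian_directivity(order: int = 8, halfwidth_deg: float = 88.0):
    """Smooth near-uniform directivity: gain exp(-(theta/halfwidth)^order).

    With the defaults the half-gain points sit near +/-86 degrees, i.e. angular
    coverage close to 180 degrees across the band.
    """

    def gain(theta_deg):
        th = np.asarray(theta_deg, dtype=float)
        return np.exp(-np.abs(th / halfwidth_deg) ** order * math.log(2.0))

    return gain


def _raw_kernel(fs, sigma, tail_amp, tail_freq, tail_tau):
    t_lo = -6.0 * sigma
    t_hi = max(6.0 * sigma, 8.0 * tail_tau if tail_amp > 0 else 0.0)
    n_lo = int(math.ceil(-t_lo * fs))
    n_hi = int(math.ceil(t_hi * fs))
    t = np.arange(-n_lo, n_hi + 1) / fs
    h = np.exp(-0.5 * (t / sigma) ** 2)
    if tail_amp > 0:
        tail = np.where(
            t > 0,
            tail_amp * np.exp(-t / tail_tau) * np.sin(2.0 * math.pi * tail_freq * t),
            0.0,
        )
        h = h + tail
    return h, n_lo


def design_fp_kernel(
    fs: float = DEFAULT_SAMPLING_RATE,
    bw_3db: float = DEFAULT_BANDWIDTH_3DB,
    tail_amp: float = 0.1,
    tail_freq: float = 18e6,
    tail_tau: float = 50e-9,
) -> tuple[np.ndarray, int]:
    """Band-limited sensor kernel: Gaussian core plus a causal ringing tail.

    The core width is solved (Brent root-finding) so the kernel's measured
    -3 dB amplitude bandwidth equals ``bw_3db`` exactly, tail included — the
    packaged kernel round-trips through the FFT bandwidth estimator by
    construction.  The tail mimics the small post-pulse ringing seen on
    Fabry-Perot sensors; set ``tail_amp=0`` for a pure Gaussian response.
    Returns ``(kernel, center_index)`` with the kernel area-normalized to unit
    DC gain (values in 1/s).
    """

    def bw_error(sigma):
        h, _ = _raw_kernel(fs, sigma, tail_amp, tail_freq, tail_tau)
        return characterization.frequency_response(h, fs).bw_3db - bw_3db

    sigma = brentq(bw_error, 0.5e-9, 40e-9, xtol=1e-13)
    h, center = _raw_kernel(fs, sigma, tail_amp, tail_freq, tail_tau)
    h = h / (np.sum(h) / fs)  # unit DC gain
    return h, center


def make_default_sensor(
    fs: float = DEFAULT_SAMPLING_RATE,
    bw_3db: float = DEFAULT_BANDWIDTH_3DB,
    nep: float = DEFAULT_NEP_PA,
    tail_amp: float = 0.1,
    tail_freq: float = 18e6,
    tail_tau: float = 50e-9,
) -> SensorModel:
    """Packaged default Fabry-Perot sensor: 23 MHz, 65.8 Pa NEP, ringing on."""
    h, center = design_fp_kernel(fs, bw_3db, tail_amp, tail_freq, tail_tau)
    return SensorModel(
        impulse_response=h,
        fs=fs,
        bw_3db=bw_3db,
        directivity=super_gaussian_directivity(),
        nep=nep,
        center_index=center,
    )


# ---------------------------------------------------------------------------
# forward model

def sphere_pressure_waveform(
    absorber: Absorber,
    detector,
    sos: float,
    times,
    wavelength_nm: Optional[float] = None,
) -> np.ndarray:
    """Closed-form N-wave of a uniformly heated sphere at the detector.

    ``p(t) = A*(d - c*t)/(2*d)`` inside ``|d - c*t| < a`` and zero outside.
    The detector must lie outside the sphere.
    """
    det = np.asarray(detector, dtype=float).reshape(3)
    t = np.asarray(times, dtype=float)
    d = float(np.linalg.norm(det - absorber.center))
    if d <= absorber.radius:
        raise ValueError("detector lies inside the absorber")
    if wavelength_nm is None:
        amp = absorber.amplitude(next(iter(absorber.amplitude_per_wavelength)))
    else:
        amp = absorber.amplitude(wavelength_nm)
    arg = d - sos * t
    p = np.where(np.abs(arg) < absorber.radius, amp * arg / (2.0 * d), 0.0)
    return p


@numba.njit(cache=True)
def _cum_interp(x, tau0, dt, cum):  # pragma: no cover - numba
    """Linear interpolation of a cumulative-integral table; clamps outside."""
    n = cum.shape[0] - 1
    xe = (x - tau0) / dt
    if xe <= 0.0:
        return 0.0
    if xe >= n:
        return cum[n]
    k = int(xe)
    f = xe - k
    return cum[k] * (1.0 - f) + cum[k + 1] * f


@numba.njit(cache=True)
def _accumulate_nwaves(
    data, t0, fs, dist, amp_eff, radii, sos, Hc, Gc, tau0, dtk
):  # pragma: no cover - numba
    n_det, n_sph = dist.shape
    nt = data.shape[1]
    nk = Hc.shape[0]
    tau_end = tau0 + (nk - 1) * dtk
    for i in range(n_det):
        for j in range(n_sph):
            amp = amp_eff[i, j]
            if amp == 0.0:
                continue
            d = dist[i, j]
            a = radii[j]
            t1 = (d - a) / sos
            t2 = (d + a) / sos
            s0 = d / sos
            nlo = int(math.ceil((t1 + tau0 - t0) * fs))
            nhi = int(math.floor((t2 + tau_end - t0) * fs))
            if nlo < 0:
                nlo = 0
            if nhi > nt - 1:
                nhi = nt - 1
            coef = amp * sos / (2.0 * d)
            for n in range(nlo, nhi + 1):
                t = t0 + n / fs
                h1 = _cum_interp(t - t1, tau0, dtk, Hc)
                h2 = _cum_interp(t - t2, tau0, dtk, Hc)
                g1 = _cum_interp(t - t1, tau0, dtk, Gc)
                g2 = _cum_interp(t - t2, tau0, dtk, Gc)
                data[i, n] += coef * ((s0 - t) * (h1 - h2) + (g1 - g2))


def _effective_kernel(sensor: SensorModel, pulse_fwhm: Optional[float]):
    """Sensor impulse response composed with the excitation pulse shape."""
    h = sensor.impulse_response
    center = sensor.center_index
    if pulse_fwhm is not None and pulse_fwhm > 0:
        sigma = pulse_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        n = max(1, int(math.ceil(4.0 * sigma * sensor.fs)))
        tg = np.arange(-n, n + 1) / sensor.fs
        g = np.exp(-0.5 * (tg / sigma) ** 2)
        g /= np.sum(g) / sensor.fs  # unit DC gain
        h = np.convolve(h, g) / sensor.fs
        center = center + n
    return h, center


def _cumulative_tables(kernel: np.ndarray, center: int, fs: float):
    """Running integrals H(x)=int h du and G(x)=int u*h du on the kernel grid."""
    dt = 1.0 / fs
    tau = (np.arange(kernel.size) - center) * dt
    trap = 0.5 * (kernel[1:] + kernel[:-1]) * dt
    Hc = np.concatenate(([0.0], np.cumsum(trap)))
    uh = tau * kernel
    trap_g = 0.5 * (uh[1:] + uh[:-1]) * dt
    Gc = np.concatenate(([0.0], np.cumsum(trap_g)))
    return Hc, Gc, float(tau[0]), dt


def simulate_signals(
    phantom: AbsorberPhantom,
    geometry: ScanGeometry,
    sensor: SensorModel,
    fs: float,
    n_samples: int,
    wavelength_nm: Optional[float] = None,
    noise_seed: Optional[int] = None,
    t0: float = 0.0,
    pulse_fwhm: Optional[float] = DEFAULT_PULSE_FWHM,
) -> SignalSet:
    """Forward-simulate the raster-scan pressure records for one wavelength.

    Per scan point: superpose the N-waves of all absorbers, attenuated by the
    directivity gain at each source's incidence angle, convolved with the
    excitation pulse (Gaussian of FWHM ``pulse_fwhm``; ``None`` disables it)
    and the sensor impulse response; optionally add white Gaussian noise of
    standard deviation ``sensor.nep`` (skipped when ``noise_seed`` is None).
    Deterministic (bit-identical) for fixed inputs and seed.
    """
    if fs < 2.5 * sensor.bw_3db:
        raise ValueError(
            f"fs={fs:g} undersamples the sensor band (need >= 2.5 x {sensor.bw_3db:g})"
        )
    if abs(sensor.fs - fs) > 1e-9 * fs:
        raise ValueError("sensor impulse response was sampled at a different fs")
    sos = phantom.medium_sos
    data = np.zeros((geometry.n_points, n_samples))
    if len(phantom) > 0:
        centers = np.stack([a.center for a in phantom.absorbers])
        radii = np.array([a.radius for a in phantom.absorbers])
        amps = np.array([a.amplitude(wavelength_nm) for a in phantom.absorbers])
        det = geometry.positions.reshape(-1, 3)
        diff = centers[None, :, :] - det[:, None, :]
        dist = np.sqrt(np.sum(diff**2, axis=2))
        if np.any(dist <= radii[None, :]):
            raise ValueError("a detector lies inside an absorber")
        cos_inc = diff[:, :, 2] / dist
        angles = np.degrees(np.arccos(np.clip(cos_inc, -1.0, 1.0)))
        gain = sensor.directivity(angles)
        amp_eff = amps[None, :] * gain
        kernel, center = _effective_kernel(sensor, pulse_fwhm)
        Hc, Gc, tau0, dtk = _cumulative_tables(kernel, center, fs)
        _accumulate_nwaves(data, t0, fs, dist, amp_eff, radii, sos, Hc, Gc, tau0, dtk)
    data = data.reshape(geometry.nx, geometry.ny, n_samples)
    if noise_seed is not None and sensor.nep > 0:
        rng = np.random.default_rng(noise_seed)
        data = data + rng.normal(0.0, sensor.nep, size=data.shape)
    return SignalSet(
        data=data,
        fs=fs,
        t0=t0,
        geometry=geometry,
        wavelength_nm=wavelength_nm,
        seed=noise_seed,
    )
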