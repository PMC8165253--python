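"""3D universal back projection with single- or dual-SOS time of flight.

Image formation follows the analytic back-projection of the filtered term
``b(t) = 2 p(t) - 2 t dp/dt`` evaluated at each voxel's time of flight and
weighted by the solid angle each detector's grid cell subtends at the voxel
(far-field form ``cos(theta) * pitch^2 / r^2``, normalized over the aperture).
The medium is either homogeneous or a two-speed model with an axis-aligned
ellipsoid of different speed; time of flight is computed analytically along
straight (unrefracted) rays: the segment length inside the ellipsoid travels
at the inner speed, the remainder at the background speed.

The reconstruction output is kept signed; envelope detection (magnitude of
the analytic signal along z, removing the bipolar oscillation) is an explicit
separate stage.
"""

from __future__ import annotations

import logging
import math

import numba
import numpy as np
from scipy.signal import hilbert

from .types import ReconGrid, ReconVolume, SignalSet, SOSModel

__all__ = ["time_of_flight", "ubp_reconstruct", "hilbert_envelope_z"]

logger = logging.getLogger(__name__)


def _ellipsoid_chord(p0: np.ndarray, p1: np.ndarray, center, semi_axes) -> float:
    """Length of the segment p0->p1 inside the axis-aligned ellipsoid."""
    v = p1 - p0
    q = v / semi_axes
    p = (p0 - center) / semi_axes
    a = float(np.dot(q, q))
    if a == 0.0:
        return 0.0
    b = 2.0 * float(np.dot(p, q))
    c = float(np.dot(p, p)) - 1.0
    disc = b * b - 4.0 * a * c
    if disc <= 0.0:  # miss or tangent: zero interior length
        return 0.0
    sq = math.sqrt(disc)
    s1 = (-b - sq) / (2.0 * a)
    s2 = (-b + sq) / (2.0 * a)
    lo = max(s1, 0.0)
    hi = min(s2, 1.0)
    if hi <= lo:
        return 0.0
    return (hi - lo) * float(np.linalg.norm(v))


def time_of_flight(detector, voxel, sos_model: SOSModel) -> float:
    """Analytic straight-ray time of flight from detector to voxel.

    Homogeneous medium: distance / background speed.  With an ellipsoid, the
    interior chord travels at ``inner_sos`` and the rest at ``background_sos``.
    The degenerate cases (no ellipsoid, missed ellipsoid, or equal speeds)
    return exactly ``distance / background_sos``.
    """
    p0 = np.asarray(detector, dtype=float).reshape(3)
    p1 = np.asarray(voxel, dtype=float).reshape(3)
    dist = float(np.linalg.norm(p1 - p0))
    if dist == 0.0:
        raise ValueError("detector and voxel coincide")
    ell = sos_model.ellipsoid
    if ell is None or ell.inner_sos == sos_model.background_sos:
        return dist / sos_model.background_sos
    chord = _ellipsoid_chord(p0, p1, ell.center, ell.semi_axes)
    if chord == 0.0:
        return dist / sos_model.background_sos
    return (dist - chord) / sos_model.background_sos + chord / ell.inner_sos


@numba.njit(cache=True)
def _ubp_kernel(
    b, t0, fs, det, pitch2, origin, voxel, shape, c_bg,
    has_ell, ec, ea, c_in, out
):  # pragma: no cover - numba
    n_det, nt = b.shape
    nx, ny, nz = shape[0], shape[1], shape[2]
    trunc = 0
    for ix in range(nx):
        x = origin[0] + ix * voxel
        for iy in range(ny):
            y = origin[1] + iy * voxel
            for iz in range(nz):
                z = origin[2] + iz * voxel
                acc = 0.0
                wsum = 0.0
                for k in range(n_det):
                    dx = x - det[k, 0]
                    dy = y - det[k, 1]
                    dz = z - det[k, 2]
                    r2 = dx * dx + dy * dy + dz * dz
                    r = math.sqrt(r2)
                    if r < 0.5 * voxel:
                        continue
                    if has_ell:
                        # chord of the det->voxel segment inside the ellipsoid
                        qx = dx / ea[0]
                        qy = dy / ea[1]
                        qz = dz / ea[2]
                        px = (det[k, 0] - ec[0]) / ea[0]
                        py = (det[k, 1] - ec[1]) / ea[1]
                        pz = (det[k, 2] - ec[2]) / ea[2]
                        qa = qx * qx + qy * qy + qz * qz
                        qb = 2.0 * (px * qx + py * qy + pz * qz)
                        qc = px * px + py * py + pz * pz - 1.0
                        disc = qb * qb - 4.0 * qa * qc
                        chord = 0.0
                        if disc > 0.0:
                            sq = math.sqrt(disc)
                            s1 = (-qb - sq) / (2.0 * qa)
                            s2 = (-qb + sq) / (2.0 * qa)
                            lo = s1 if s1 > 0.0 else 0.0
                            hi = s2 if s2 < 1.0 else 1.0
                            if hi > lo:
                                chord = (hi - lo) * r
                        if chord > 0.0:
                            tof = (r - chord) / c_bg + chord / c_in
                        else:
                            tof = r / c_bg
                    else:
                        tof = r / c_bg
                    w = (dz / r) * pitch2 / r2
                    wsum += w
                    ti = (tof - t0) * fs
                    if ti < 0.0 or ti > nt - 1:
                        trunc += 1
                        continue
                    i0 = int(ti)
                    if i0 >= nt - 1:
                        val = b[k, nt - 1]
                    else:
                        f = ti - i0
                        val = b[k, i0] * (1.0 - f) + b[k, i0 + 1] * f
                    acc += w * val
                if wsum > 0.0:
                    out[ix, iy, iz] = acc / wsum
    return trunc


def ubp_reconstruct(
    signals: SignalSet, sos_model: SOSModel, grid: ReconGrid
) -> ReconVolume:
    """Universal back projection of a planar-scan SignalSet onto a voxel grid.

    Linear in the signals.  Voxels whose time of flight falls outside the
    recorded window receive zero from those detectors; the truncation fraction
    is logged.  The output is signed — apply :func:`hilbert_envelope_z` for a
    non-negative image.
    """
    p = signals.data.reshape(-1, signals.n_samples).astype(float)
    t = signals.times
    dpdt = np.gradient(p, 1.0 / signals.fs, axis=1)  # central differences
    b = 2.0 * p - 2.0 * t[None, :] * dpdt
    det = signals.geometry.positions.reshape(-1, 3).astype(float)
    ell = sos_model.ellipsoid
    # equal speeds short-circuit to the homogeneous path so the dual-SOS
    # reconstruction is bit-identical in the degenerate limit
    has_ell = ell is not None and ell.inner_sos != sos_model.background_sos
    ec = ell.center if has_ell else np.zeros(3)
    ea = ell.semi_axes if has_ell else np.ones(3)
    c_in = ell.inner_sos if has_ell else sos_model.background_sos
    out = np.zeros(grid.shape)
    trunc = _ubp_kernel(
        b,
        float(signals.t0),
        float(signals.fs),
        det,
        float(signals.geometry.pitch) ** 2,
        grid.origin.astype(float),
        float(grid.voxel),
        np.asarray(grid.shape, dtype=np.int64),
        float(sos_model.background_sos),
        has_ell,
        np.asarray(ec, dtype=float),
        np.asarray(ea, dtype=float),
        float(c_in),
        out,
    )
    total = det.shape[0] * int(np.prod(grid.shape))
    if trunc:
        logger.info(
            "UBP: %.2f%% of voxel-detector pairs fell outside the recorded window",
            100.0 * trunc / total,
        )
    return ReconVolume(
        grid=grid,
        values=out,
        wavelength_nm=signals.wavelength_nm,
        envelope_applied=False,
    )


def hilbert_envelope_z(volume: ReconVolume) -> ReconVolume:
    """Envelope detection along z: magnitude of the analytic signal per column.

    Removes the bipolar oscillation of the back-projected image; the output is
    non-negative and dominates the input magnitude pointwise.
    """
    if volume.envelope_applied:
        raise ValueError("envelope already applied to this volume")
    if volume.grid.shape[2] < 4:
        raise ValueError("need at least 4 samples along z for envelope detection")
    env = np.abs(hilbert(volume.values, axis=2))
    return ReconVolume(
        grid=volume.grid,
        values=env,
        wavelength_nm=volume.wavelength_nm,
        envelope_applied=True,
    )
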