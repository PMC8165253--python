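"""Phantom generation and forward-signal simulation."""

import numpy as np
import pytest

from pamesoscope import synthetic
from pamesoscope.constants import HB_EXTINCTION
from pamesoscope.types import Absorber, AbsorberPhantom


# ---------------------------------------------------------------------------
# raster geometry and acquisition accounting

def test_raster_geometry_span_and_count():
    geom = synthetic.make_raster_geometry(128, 128, 100e-6, 10.0)
    assert geom.n_points == 16384
    assert geom.extent == pytest.approx((12.7e-3, 12.7e-3))


def test_raster_geometry_indexing():
    geom = synthetic.make_raster_geometry(3, 2, 1e-3, 10.0)
    assert geom.n_points == 6
    np.testing.assert_allclose(geom.positions[2, 1], [2e-3, 1e-3, 0.0])
    single = synthetic.make_raster_geometry(1, 1, 1e-4, 10.0)
    np.testing.assert_allclose(single.positions[0, 0], [0.0, 0.0, 0.0])


@pytest.mark.parametrize("bad", [dict(nx=0), dict(pitch=-1e-4), dict(rep_rate=0.0)])
def test_raster_geometry_invalid_arguments(bad):
    kwargs = dict(nx=4, ny=4, pitch=1e-4, rep_rate=10.0)
    kwargs.update(bad)
    with pytest.raises(ValueError):
        synthetic.make_raster_geometry(**kwargs)


@pytest.mark.parametrize(
    "nx,ny,rep,expected,ceil",
    [
        (128, 128, 10.0, 1638.4, 1639),
        (1, 1, 10.0, 0.1, 1),
        (10, 10, 1000.0, 0.1, 1),
    ],
)
def test_acquisition_time(nx, ny, rep, expected, ceil):
    geom = synthetic.make_raster_geometry(nx, ny, 1e-4, rep)
    assert synthetic.acquisition_time(geom) == pytest.approx(expected)
    assert synthetic.acquisition_time_ceil(geom) == ceil


# ---------------------------------------------------------------------------
# wire phantom

def test_wire_phantom_sphere_chains():
    depths = [1e-3, 2e-3, 3e-3]
    ph = synthetic.make_wire_phantom(3, 9e-6, depths, 1500.0)
    labels = {a.label for a in ph.absorbers}
    assert labels == {"wire0", "wire1", "wire2"}
    for w, depth in enumerate(depths):
        centers = np.stack(
            [a.center for a in ph.absorbers if a.label == f"wire{w}"]
        )
        assert np.all(centers[:, 2] == depth)
        gaps = np.diff(np.sort(centers[:, 1]))
        assert gaps.max() <= 4.5e-6 + 1e-12  # spacing bounded by the radius


def test_wire_phantom_single_wire():
    ph = synthetic.make_wire_phantom(1, 9e-6, [1e-3], 1500.0)
    assert all(a.center[2] == 1e-3 for a in ph.absorbers)
    assert all(a.radius == 4.5e-6 for a in ph.absorbers)


def test_wire_phantom_empty_depths_rejected():
    with pytest.raises(ValueError):
        synthetic.make_wire_phantom(0, 9e-6, [], 1500.0)


# ---------------------------------------------------------------------------
# vessel phantom and hemoglobin amplitudes

def test_vessel_amplitudes_isosbestic_and_1064_ordering():
    a800 = synthetic.vessel_amplitude(0.95, 800.0)
    v800 = synthetic.vessel_amplitude(0.65, 800.0)
    assert a800 == pytest.approx(v800)  # 800 nm is isosbestic
    a1064 = synthetic.vessel_amplitude(0.95, 1064.0)
    v1064 = synthetic.vessel_amplitude(0.65, 1064.0)
    assert a1064 > v1064  # more oxyhemoglobin -> larger amplitude at 1,064 nm


def test_vessel_amplitude_so2_independent_when_extinctions_equal():
    table = {800.0: {"HbO2": 500.0, "Hb": 500.0}}
    vals = [synthetic.vessel_amplitude(s, 800.0, table) for s in (0.0, 0.5, 1.0)]
    assert vals[0] == vals[1] == vals[2]


def test_vessel_amplitude_missing_wavelength_rejected():
    with pytest.raises(ValueError):
        synthetic.vessel_amplitude(0.9, 532.0)
    with pytest.raises(ValueError):
        synthetic.make_vessel_phantom(0, wavelengths=(532.0,))


def test_vessel_phantom_seed_determinism():
    a = synthetic.make_vessel_phantom(7)
    b = synthetic.make_vessel_phantom(7)
    c = synthetic.make_vessel_phantom(8)
    ca = np.stack([x.center for x in a.absorbers])
    cb = np.stack([x.center for x in b.absorbers])
    np.testing.assert_array_equal(ca, cb)
    cc = np.stack([x.center for x in c.absorbers])
    assert ca.shape != cc.shape or not np.array_equal(ca, cc)


def test_vessel_phantom_has_both_classes():
    ph = synthetic.make_vessel_phantom(3)
    labels = {a.label for a in ph.absorbers}
    assert labels == {"artery", "vein"}
    for a in ph.absorbers:
        assert a.so2 is not None and 0 <= a.so2 <= 1


# ---------------------------------------------------------------------------
# sphere N-wave

def _sphere(radius=200e-6, amp=1000.0, depth=5e-3):
    return Absorber(
        center=(0.0, 0.0, depth),
        radius=radius,
        amplitude_per_wavelength={None: amp},
        label="s",
    )


def test_sphere_waveform_zero_amplitude_is_zero():
    s = Absorber((0, 0, 5e-3), 1e-4, {None: 0.0})
    t = np.linspace(0, 8e-6, 1000)
    p = synthetic.sphere_pressure_waveform(s, (0, 0, 0), 1500.0, t)
    assert np.all(p == 0)


def test_sphere_waveform_shape_and_antisymmetry():
    s = _sphere()
    c, d, a = 1500.0, 5e-3, 200e-6
    t = np.linspace((d - 2 * a) / c, (d + 2 * a) / c, 20001)
    p = synthetic.sphere_pressure_waveform(s, (0, 0, 0), c, t)
    # peak magnitude A*a/(2d)
    assert np.abs(p).max() == pytest.approx(1000.0 * a / (2 * d), rel=1e-3)
    # equal positive and negative lobes: integral over support vanishes
    assert abs(np.trapezoid(p, t)) < 1e-6 * np.abs(p).max() * (2 * a / c)


def test_sphere_waveform_detector_inside_rejected():
    s = _sphere(radius=1e-3)
    with pytest.raises(ValueError):
        synthetic.sphere_pressure_waveform(s, (0, 0, 4.5e-3), 1500.0, np.zeros(4))


def _spherical_means_pressure(amp, a, d, c, times):
    """Independent oracle: Poisson (spherical-means) solution of the wave
    equation for a uniform ball of initial pressure.

    p(t) = d/dt [ t * mean of p0 over the sphere of radius c*t around the
    detector ].  The surface mean is the spherical-cap area fraction of the
    detector-centered sphere inside the ball (law of cosines); the time
    derivative is taken numerically by central differences.
    """

    def t_mean(t):
        R = c * t
        mu0 = (d * d + R * R - a * a) / (2.0 * d * R)
        frac = np.clip((1.0 - mu0) / 2.0, 0.0, 1.0)
        return t * amp * frac

    dt = 1e-12
    return np.array([(t_mean(t + dt) - t_mean(t - dt)) / (2 * dt) for t in times])


def test_sphere_waveform_matches_spherical_means_oracle():
    amp, a, d, c = 1000.0, 200e-6, 5e-3, 1500.0
    s = _sphere()
    # stay clear of the support edges where the derivative is discontinuous
    t = np.linspace((d - 0.95 * a) / c, (d + 0.95 * a) / c, 81)
    p = synthetic.sphere_pressure_waveform(s, (0, 0, 0), c, t)
    oracle = _spherical_means_pressure(amp, a, d, c, t)
    err = np.linalg.norm(p - oracle) / np.linalg.norm(oracle)
    assert err < 1e-3


# ---------------------------------------------------------------------------
# simulate_signals

FS = 125e6


def test_simulate_empty_phantom_noise_off_is_zero(default_sensor):
    geom = synthetic.make_raster_geometry(4, 4, 1e-4, 10.0)
    ph = AbsorberPhantom([], 1500.0)
    ss = synthetic.simulate_signals(ph, geom, default_sensor, FS, 128)
    assert np.all(ss.data == 0)


def test_simulate_undersampled_fs_rejected(default_sensor):
    geom = synthetic.make_raster_geometry(2, 2, 1e-4, 10.0)
    ph = AbsorberPhantom([], 1500.0)
    with pytest.raises(ValueError):
        synthetic.simulate_signals(ph, geom, default_sensor, 50e6, 128)


def test_simulate_arrival_time_and_earliest_scan_point(default_sensor):
    from scipy.signal import hilbert

    geom = synthetic.make_raster_geometry(
        9, 9, 2e-4, 10.0, origin=(-8e-4, -8e-4, 0.0)
    )
    depth = 3e-3
    ph = AbsorberPhantom(
        [Absorber((0, 0, depth), 8e-6, {None: 1e7})], 1500.0
    )
    ss = synthetic.simulate_signals(ph, geom, default_sensor, FS, 512)
    env = np.abs(hilbert(ss.data, axis=2))
    peak_times = ss.times[np.argmax(env, axis=2)]
    # the scan point directly above the source (center) hears it first
    assert np.unravel_index(np.argmin(peak_times), (9, 9)) == (4, 4)
    assert abs(peak_times[4, 4] - depth / 1500.0) <= 1.0 / FS


def test_simulate_superposition(default_sensor):
    geom = synthetic.make_raster_geometry(4, 4, 2e-4, 10.0)
    a = Absorber((2e-4, 1e-4, 2e-3), 5e-5, {None: 1e4})
    b = Absorber((-1e-4, 3e-4, 3.5e-3), 8e-5, {None: 2e4})
    kw = dict(fs=FS, n_samples=512)
    both = synthetic.simulate_signals(
        AbsorberPhantom([a, b], 1500.0), geom, default_sensor, **kw
    )
    pa = synthetic.simulate_signals(
        AbsorberPhantom([a], 1500.0), geom, default_sensor, **kw
    )
    pb = synthetic.simulate_signals(
        AbsorberPhantom([b], 1500.0), geom, default_sensor, **kw
    )
    np.testing.assert_allclose(both.data, pa.data + pb.data, rtol=1e-12, atol=1e-18)


def test_simulate_seed_determinism_bitwise(default_sensor):
    geom = synthetic.make_raster_geometry(4, 4, 2e-4, 10.0)
    ph = AbsorberPhantom([Absorber((0, 0, 2e-3), 5e-5, {None: 1e4})], 1500.0)
    kw = dict(fs=FS, n_samples=256, noise_seed=99)
    s1 = synthetic.simulate_signals(ph, geom, default_sensor, **kw)
    s2 = synthetic.simulate_signals(ph, geom, default_sensor, **kw)
    np.testing.assert_array_equal(s1.data, s2.data)


def test_simulate_noise_standard_deviation_matches_nep(default_sensor):
    geom = synthetic.make_raster_geometry(32, 32, 1e-4, 10.0)
    ph = AbsorberPhantom([], 1500.0)
    ss = synthetic.simulate_signals(
        ph, geom, default_sensor, FS, 1024, noise_seed=4
    )
    assert ss.data.size >= 1e6
    assert np.std(ss.data) == pytest.approx(default_sensor.nep, rel=0.02)


def test_simulate_directivity_attenuates_off_axis(default_sensor):
    # a source far off-axis is attenuated relative to an on-axis one
    geom = synthetic.make_raster_geometry(1, 1, 1e-4, 10.0)
    on = AbsorberPhantom([Absorber((0, 0, 2e-3), 5e-5, {None: 1e4})], 1500.0)
    off = AbsorberPhantom(
        [Absorber((39.9e-3, 0, 1e-3), 5e-5, {None: 1e4})], 1500.0
    )
    kw = dict(fs=FS, n_samples=4096)
    s_on = synthetic.simulate_signals(on, geom, default_sensor, **kw)
    s_off = synthetic.simulate_signals(off, geom, default_sensor, **kw)
    # compensate the 1/d spherical spreading before comparing gains
    d_on, d_off = 2e-3, np.hypot(39.9e-3, 1e-3)
    assert np.abs(s_off.data).max() * d_off < 0.9 * np.abs(s_on.data).max() * d_on
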