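"""Resolution fitting, MIP rendering, segmentation, fluence and dual-wavelength."""

import math
import warnings

import numpy as np
import pytest

from pamesoscope import analysis
from pamesoscope.analysis import FWHM_PER_SIGMA
from pamesoscope.types import ReconGrid, ReconVolume


def _envelope_volume(values, voxel=10e-6, origin=(0, 0, 0)):
    grid = ReconGrid(shape=values.shape, voxel=voxel, origin=origin)
    return ReconVolume(grid=grid, values=values, envelope_applied=True)


def _gaussian_blob(shape, voxel, center_idx, sigmas, amp=1.0, offset=0.0):
    ax = [voxel * (np.arange(n) - c) for n, c in zip(shape, center_idx)]
    xx = np.exp(-0.5 * (ax[0] / sigmas[0]) ** 2)
    yy = np.exp(-0.5 * (ax[1] / sigmas[1]) ** 2)
    zz = np.exp(-0.5 * (ax[2] / sigmas[2]) ** 2)
    return offset + amp * xx[:, None, None] * yy[None, :, None] * zz[None, None, :]


def fwhm_by_crossing(coords, profile):
    """Independent FWHM oracle: linear interpolation of the half-max crossings."""
    p = np.asarray(profile, dtype=float)
    half = (p.max() + p.min()) / 2.0  # offset-aware half maximum
    above = p >= half
    idx = np.nonzero(above)[0]
    lo, hi = idx[0], idx[-1]

    def cross(i, j):
        return coords[i] + (half - p[i]) * (coords[j] - coords[i]) / (p[j] - p[i])

    left = cross(lo - 1, lo) if lo > 0 else coords[0]
    right = cross(hi + 1, hi) if hi < len(p) - 1 else coords[-1]
    return right - left


# ---------------------------------------------------------------------------
# resolution estimation

def test_gaussian_blob_axial_fwhm_matches_90_um():
    voxel = 10e-6
    sigma_z = 38.2e-6  # 2 sqrt(2 ln 2) * 38.2 um = 90 um
    vals = _gaussian_blob((41, 41, 81), voxel, (20, 20, 40), (60e-6, 60e-6, sigma_z))
    vol = _envelope_volume(vals, voxel)
    rep = analysis.estimate_resolution(vol, [(20 * voxel, 20 * voxel, 40 * voxel)])
    (w,) = rep.wires
    assert w.usable
    assert w.axial_fwhm == pytest.approx(90e-6, abs=voxel)


def test_symmetric_blob_is_isotropic():
    voxel = 10e-6
    vals = _gaussian_blob((61, 61, 61), voxel, (30, 30, 30), (50e-6,) * 3)
    rep = analysis.estimate_resolution(
        _envelope_volume(vals, voxel), [(30 * voxel,) * 3]
    )
    (w,) = rep.wires
    assert w.axial_fwhm == pytest.approx(w.lateral_fwhm, rel=1e-6)


def test_gaussian_fit_agrees_with_crossing_oracle_over_sigmas():
    rng = np.random.default_rng(11)
    voxel = 10e-6
    x = voxel * np.arange(201)
    for sigma in rng.uniform(25e-6, 120e-6, 20):
        prof = 0.05 + np.exp(-0.5 * ((x - x[100]) / sigma) ** 2)
        fit, r2 = analysis.fit_gaussian_fwhm(x, prof)
        oracle = fwhm_by_crossing(x, prof)
        assert abs(fit - oracle) <= voxel
        assert r2 > 0.99


def test_low_r2_wire_flagged_unusable(rng):
    voxel = 10e-6
    vals = rng.uniform(0.0, 1.0, size=(41, 41, 41))  # pure noise, no blob
    rep = analysis.estimate_resolution(
        _envelope_volume(vals, voxel), [(20 * voxel,) * 3]
    )
    assert not rep.wires[0].usable


@pytest.mark.parametrize(
    "pulse,sos,expected",
    [(25e-9, 1500.0, 37.5e-6), (0.0, 1500.0, 0.0), (50e-9, 1500.0, 75e-6)],
)
def test_pulse_limited_resolution(pulse, sos, expected):
    assert analysis.pulse_limited_resolution(pulse, sos) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# depth-coded MIP

def test_mip_single_bright_voxel():
    vals = np.zeros((8, 9, 10))
    vals[3, 4, 7] = 2.0
    mip = analysis.depth_coded_mip(_envelope_volume(vals))
    assert mip.intensity[3, 4] == 2.0
    assert mip.depth_index[3, 4] == 7
    assert np.count_nonzero(mip.intensity) == 1


def test_mip_argmax_picks_brighter_voxel_on_ray():
    vals = np.zeros((4, 4, 60))
    vals[1, 1, 10] = 5.0
    vals[1, 1, 50] = 3.0
    mip = analysis.depth_coded_mip(_envelope_volume(vals))
    assert mip.intensity[1, 1] == 5.0
    assert mip.depth_index[1, 1] == 10


def test_mip_tie_breaks_to_shallowest_index():
    vals = np.ones((3, 3, 7))
    mip = analysis.depth_coded_mip(_envelope_volume(vals))
    assert np.all(mip.depth_index == 0)
    assert np.all(mip.intensity == 1.0)


def test_mip_matches_brute_force_per_ray(rng):
    vals = rng.uniform(size=(7, 6, 20))
    mip = analysis.depth_coded_mip(_envelope_volume(vals))
    for i in range(7):
        for j in range(6):
            ray = vals[i, j]
            assert mip.intensity[i, j] == ray.max()
            assert mip.depth_index[i, j] == int(np.argmax(ray))


# ---------------------------------------------------------------------------
# segmentation

def _two_tube_volume(noise=0.02):
    rng = np.random.default_rng(5)
    vals = rng.uniform(0.0, noise, size=(40, 40, 30))
    vals[8:12, 5:35, 10:14] = 1.0
    vals[28:32, 5:35, 18:22] = 0.8
    return _envelope_volume(vals, voxel=50e-6)


def test_two_disjoint_tubes_give_two_labels():
    seg = analysis.segment_vessels(_two_tube_volume(), 0.5, 0.2, min_voxels=10)
    assert seg.n_labels == 2
    # labels ordered by decreasing size
    assert seg.voxel_counts[1] >= seg.voxel_counts[2]


def test_min_voxels_filter_can_remove_everything():
    seg = analysis.segment_vessels(_two_tube_volume(), 0.5, 0.2, min_voxels=10**6)
    assert seg.n_labels == 0


def test_no_seed_above_high_threshold_warns_and_returns_empty():
    vals = np.full((10, 10, 10), 0.1)
    vals[0, 0, 0] = 1.0  # defines the max; threshold 1.0 catches only it
    vol = _envelope_volume(vals)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        seg = analysis.segment_vessels(
            ReconVolume(grid=vol.grid, values=np.zeros((10, 10, 10)),
                        envelope_applied=True),
            0.5, 0.2, 1,
        )
    assert seg.n_labels == 0
    assert caught


def test_raising_high_threshold_never_adds_components():
    vol = _two_tube_volume()
    counts = [
        analysis.segment_vessels(vol, h, 0.1, min_voxels=1).n_labels
        for h in (0.3, 0.5, 0.7, 0.85, 0.95)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_mean_paa_uniform_labels_and_grid_mismatch():
    vol = _two_tube_volume()
    seg = analysis.segment_vessels(vol, 0.5, 0.2, min_voxels=10)
    means = analysis.mean_paa(seg, {800.0: vol})
    assert set(means) == {1, 2}
    # label 2 is the dimmer tube
    assert means[1][800.0] > means[2][800.0]
    other = _envelope_volume(np.zeros((4, 4, 8)))
    with pytest.raises(ValueError):
        analysis.mean_paa(seg, {800.0: other})


# ---------------------------------------------------------------------------
# fluence

def _grid(shape=(11, 11, 41), voxel=100e-6):
    return ReconGrid(shape=shape, voxel=voxel)


def test_fluence_closed_form_value():
    # mu_a = 0.1/mm, mu_s' = 1.0/mm -> mu_eff = 0.5745/mm; at 2 mm: 0.3170
    grid = _grid()
    fl = analysis.compute_fluence(np.zeros((11, 11)), grid, 100.0, 1000.0)
    k = int(round(2e-3 / grid.voxel))
    assert fl.values[5, 5, k] == pytest.approx(0.3170, abs=5e-4)
    assert fl.mu_eff == pytest.approx(574.5, rel=1e-3)


def test_fluence_approaches_one_for_vanishing_absorption():
    grid = _grid()
    fl = analysis.compute_fluence(np.zeros((11, 11)), grid, 1e-9, 1e-9)
    assert np.all(fl.values > 0.999999)


def test_fluence_flat_surface_constant_per_slice_and_monotone():
    grid = _grid()
    fl = analysis.compute_fluence(np.zeros((11, 11)), grid, 100.0, 1000.0)
    for k in range(grid.shape[2]):
        sl = fl.values[:, :, k]
        assert np.all(sl == sl[0, 0])
    assert np.all(np.diff(fl.values[5, 5, :]) <= 0)
    assert np.all((fl.values > 0) & (fl.values <= 1))


def test_fluence_one_above_tilted_surface():
    grid = _grid()
    surf = np.full((11, 11), 1.5e-3)
    fl = analysis.compute_fluence(surf, grid, 100.0, 1000.0)
    above = grid.axis_coords(2) <= 1.5e-3
    assert np.all(fl.values[:, :, above] == 1.0)


def test_fluence_compensation_restores_constant_absorber():
    grid = _grid()
    fl = analysis.compute_fluence(np.zeros((11, 11)), grid, 100.0, 1000.0)
    truth = 7.0
    observed = _envelope_volume(truth * fl.values, voxel=grid.voxel)
    comp = analysis.fluence_compensate(observed, fl, floor=0.01)
    region = fl.values > 0.01
    assert np.all(np.abs(comp.values[region] - truth) < 0.01 * truth)


def test_fluence_compensation_identity_and_floor_clamp():
    grid = _grid((4, 4, 8))
    ones = analysis.FluenceMap(np.ones((4, 4, 8)), grid, None, 100.0, 1000.0)
    vol = _envelope_volume(np.full((4, 4, 8), 3.0), voxel=grid.voxel)
    np.testing.assert_array_equal(
        analysis.fluence_compensate(vol, ones, 0.5).values, vol.values
    )
    tiny = analysis.FluenceMap(np.full((4, 4, 8), 1e-9), grid, None, 100.0, 1000.0)
    comp = analysis.fluence_compensate(vol, tiny, floor=0.01)
    assert np.all(comp.values == 3.0 / 0.01)  # gain capped at 100x


def test_fluence_compensation_grid_mismatch_rejected():
    fl = analysis.compute_fluence(np.zeros((11, 11)), _grid(), 100.0, 1000.0)
    vol = _envelope_volume(np.zeros((4, 4, 8)))
    with pytest.raises(ValueError):
        analysis.fluence_compensate(vol, fl, 0.1)


# ---------------------------------------------------------------------------
# dual-wavelength difference

def _pair(rng):
    grid = ReconGrid(shape=(9, 9, 16), voxel=50e-6)
    a = ReconVolume(grid=grid, values=rng.uniform(0, 1, grid.shape),
                    wavelength_nm=1064.0, envelope_applied=True)
    b = ReconVolume(grid=grid, values=rng.uniform(0, 1, grid.shape),
                    wavelength_nm=800.0, envelope_applied=True)
    return a, b


def test_identical_volumes_give_zero_difference(rng):
    a, _ = _pair(rng)
    res = analysis.dual_wavelength_difference(a, a)
    np.testing.assert_allclose(res.difference, 0.0, atol=1e-15)


def test_normalized_volumes_sum_to_one(rng):
    a, b = _pair(rng)
    res = analysis.dual_wavelength_difference(a, b)
    # D = n1 - n0 with each n summing to 1, so D sums to ~0
    assert abs(res.difference.sum()) < 1e-12


def test_difference_invariant_to_positive_rescaling(rng):
    a, b = _pair(rng)
    base = analysis.dual_wavelength_difference(a, b)
    scaled = analysis.dual_wavelength_difference(
        ReconVolume(grid=a.grid, values=37.0 * a.values, envelope_applied=True),
        ReconVolume(grid=b.grid, values=0.004 * b.values, envelope_applied=True),
    )
    np.testing.assert_allclose(base.difference, scaled.difference, atol=1e-15)


def test_zero_energy_volume_rejected():
    grid = ReconGrid(shape=(4, 4, 8), voxel=50e-6)
    z = ReconVolume(grid=grid, values=np.zeros(grid.shape), envelope_applied=True)
    with pytest.raises(ValueError):
        analysis.dual_wavelength_difference(z, z)
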