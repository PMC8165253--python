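# pamesoscope

Simulation, reconstruction and analysis pipeline for a planar-scan
photoacoustic (PA) mesoscope that detects ultrasound with a broadband
fiber-tip Fabry-Pérot interferometric (FPI) sensor.

PA mesoscopy images optical absorption — chiefly hemoglobin — at ultrasonic
resolution several millimeters deep: a nanosecond laser pulse deposits energy
in absorbers, thermoelastic expansion launches ultrasound, and a sensor
raster-scanned in a plane above the tissue records one time trace per scan
point. This package provides the full computational chain for such an
instrument, with a synthetic-data generator standing in for the physical
scanner so every stage is testable end to end:

- **Forward simulation** (`pamesoscope.synthetic`): closed-form N-waves of
  spherical absorbers, `p(t) = A (d − ct) / 2d` on `|d − ct| < a`, superposed
  over wire or branching artery/vein phantoms, attenuated by the sensor's
  angular directivity, convolved with the 25 ns excitation pulse and a 23 MHz
  band-limited sensor impulse response (with ringing tail), plus white noise
  at the 65.8 Pa noise-equivalent pressure.
- **Sensor characterization** (`pamesoscope.characterization`): FFT frequency
  response with interpolated −3 dB bandwidth, 181-angle directivity maps with
  half-gain angular coverage, full-band NEP estimation.
- **Reconstruction** (`pamesoscope.recon`): 3D universal back projection
  (UBP), summing `b(t) = 2p − 2t ∂p/∂t` at each voxel's time of flight with
  solid-angle weighting; analytic straight-ray time of flight through an
  optional higher-speed-of-sound ellipsoid (dual-SOS imaging of a head-like
  region); Hilbert-transform envelope detection along z.
- **Image analysis** (`pamesoscope.analysis`): Gaussian line-spread-function
  fits (FWHM = 2√(2 ln 2) σ), depth-coded maximum-intensity projections,
  hysteresis vessel segmentation, diffusion-approximation fluence
  (`exp(−μ_eff z)`, `μ_eff = √(3 μ_a (μ_a + μ_s'))`) with compensation, and
  total-energy-normalized dual-wavelength (1,064 − 800 nm) difference imaging
  that separates arteries from veins via the isosbestic point of hemoglobin
  at 800 nm.
- **I/O and orchestration** (`io`, `config`, `pipeline`, `cli`): HDF5 signal
  sets, NIfTI/TIFF volumes, YAML run configs, a manifest-writing pipeline
  driver and a `pamesoscope` command-line front end.

## Worked example

The numbered drivers under `analysis/` run the three studies and write their
tables under `results/`:

```sh
python analysis/01_sensor_bench.py
python analysis/02_wire_resolution.py --seed 1
python analysis/03_dual_wavelength.py --seed 1
```

`02_wire_resolution.py` images three 9 μm wires at 2, 4 and 6 mm depth with a
32 × 32-point, 100 μm-pitch scan and prints:

```
1024-point scan, wires at 2 mm, 4 mm, 6 mm
  depth  2.0 mm: axial   87.9 um  lateral  100.6 um  (r2 0.996/0.997)
  depth  4.0 mm: axial   83.9 um  lateral  170.9 um  (r2 0.995/0.998)
  depth  6.0 mm: axial   81.0 um  lateral  243.9 um  (r2 0.991/0.998)
mean axial FWHM: 84.2 um; pulse-duration floor: 37.5 um
lateral FWHM slope vs depth: 35.8 um/mm (axial slope -1.7 um/mm)
```

Axial resolution is set by the sensor bandwidth and excitation pulse and is
nearly depth-independent (~84 μm here), while lateral resolution degrades
with depth as the effective detection aperture shrinks — the classic
planar-scan behavior. `03_dual_wavelength.py` reports, per segmented vessel,
the mean photoacoustic amplitude at both wavelengths after total-energy
normalization; arteries (sO₂ ≈ 0.95) come out brighter at 1,064 nm and veins
(sO₂ ≈ 0.65) brighter at 800 nm, so the sign of the difference image alone
classifies them:

```
segmented 2 vessels (8442 voxels total)
  vessel 1 (artery): PAA 800 nm 2.858e-05, 1064 nm 3.201e-05, difference sign + (ok)
  vessel 2 (vein  ): PAA 800 nm 2.874e-05, 1064 nm 2.407e-05, difference sign - (ok)
sign separation: 2/2 vessels classified by the difference sign alone
```

The same chain is scriptable from a single YAML config:

```sh
pamesoscope run --config run.yaml
```

## Documentation

`docs/methods.md` describes the forward model, the reconstruction algorithm,
the sensor and phantom defaults and their rationale, numerical choices, and
what the synthetic studies can and cannot say about a physical instrument.
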