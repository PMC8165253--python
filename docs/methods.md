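# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic studies do and do not demonstrate.

## Coordinate and unit conventions

Right-handed coordinates in SI meters; the detector plane sits at `z = 0`
and `z` increases with depth into tissue. All grids are 0-based; scan point
`[i, j]` sits at `origin + (i·pitch, j·pitch, 0)`. All physical quantities
are stored in SI units (m, s, Hz, Pa); μm/MHz conversions are confined to
reporting code.

## Forward model

**Source primitive.** Every absorber is a uniformly heated sphere. Its
radiated pressure at distance `d` is the classic N-wave

    p(t) = A (d − c t) / (2 d),   |d − c t| < a,

with radius `a`, source amplitude `A` (Pa-scale arbitrary units) and sound
speed `c`. Wires are dense sphere chains (center spacing equal to the
radius), not analytic cylinders: one forward primitive serves every phantom,
and at spacing ≤ radius the chain ripple is far below the noise floor.
Summing the chain reproduces the cylinder's effective `a²`-per-length
amplitude scaling.

**Detection chain.** Each detector trace is the superposition over absorbers
of the N-wave, scaled by the sensor's directivity gain at the incidence
angle, convolved with (i) a Gaussian excitation pulse of 25 ns FWHM — the
instrument's optical pulse, which bounds resolution at
`c·τ ≈ 38 μm` — and (ii) the sensor impulse response. White Gaussian noise
with σ equal to the sensor's full-band noise-equivalent pressure (NEP,
65.8 Pa) is added when a noise seed is given; the NEP is specified full-band
only, so no colored-noise model is attempted.

**Exact sub-sample convolution.** The 9 μm wire spheres have an acoustic
transit time `2a/c ≈ 6 ns`, below one sample period at the default 125 MHz
sampling rate; a discrete convolution of the sampled N-wave would alias to
nearly zero. The N-wave is piecewise linear, so its continuous-time
convolution with a linearly interpolated kernel is evaluated exactly through
the kernel's running integrals `H(x) = ∫ h du` and `G(x) = ∫ u·h du`:

    (p ∗ h)(t) = (A c / 2d) [ (d/c − t)(H(t−t₁) − H(t−t₂)) + G(t−t₁) − G(t−t₂) ]

with `t₁,₂ = (d ∓ a)/c`. This is validated against an independent
spherical-means (Poisson) solution of the wave equation in the tests.

**Sensor model.** The default impulse response is a Gaussian core plus a
small causal ringing tail (decaying sinusoid, amplitude 0.1 of the peak at
18 MHz with a 50 ns decay), mimicking the post-pulse ringing seen on
Fabry-Pérot sensors. The core width is solved by Brent root-finding at
construction so that the kernel's *measured* −3 dB amplitude bandwidth —
computed by the package's own FFT estimator, tail included — equals the
23 MHz design value; the bandwidth estimator therefore round-trips by
construction. The −3 dB point uses the amplitude (not power) convention;
the kernel is area-normalized to unit DC gain. Directivity is a
frequency-independent scalar gain per incidence angle (the physical sensor's
coverage is nearly uniform across its band); the default is a super-Gaussian
with half-gain points near ±86°, i.e. angular coverage close to 180°.

**Sampling defaults.** The instrument's digitizer rate and record length are
not part of the model; 125 MHz (≥ 2.5× the 23 MHz band, enforced) and
per-experiment record lengths covering the deepest target from the aperture
corner are package choices.

## Phantoms

**Wire phantom.** Thin wires (default 9 μm diameter, wavelength-independent
amplitude 10⁶ Pa — a strongly absorbing metal target) parallel to y at
stated depths, for line-spread-function studies.

**Vessel phantom.** Two random branching trees of sphere-chain vessels
(default radius 150 μm, tapering), one labeled `artery` (sO₂ = 0.95), one
`vein` (sO₂ = 0.65), grown in disjoint half-spaces so segmentation labels
map unambiguously onto classes. Per-wavelength amplitude follows

    A(λ) ∝ THb · [ ε_Hb(λ) + sO₂ (ε_HbO₂(λ) − ε_Hb(λ)) ],

written so that equal extinctions give *exact* sO₂-invariance. The packaged
extinction constants treat 800 nm as exactly isosbestic
(ε_HbO₂ = ε_Hb = 816 cm⁻¹ M⁻¹; the physical isosbestic point is a few nm
lower) and use ε_HbO₂ = 1062, ε_Hb = 204 cm⁻¹ M⁻¹ at 1,064 nm — standard
tabulated magnitudes; only their ordering matters for the contrast studies.
The amplitude scale (2 × 10⁴ Pa at 800 nm for a fully oxygenated vessel of
unit THb) is of the order of Γ μ_a F for blood under ~20 mJ/cm² surface
fluence.

## Reconstruction

**Universal back projection.** Each voxel accumulates
`b(t) = 2 p(t) − 2 t ∂p/∂t` evaluated at its time of flight per detector,
weighted by the far-field solid angle of the detector's grid cell,
`cos θ · pitch² / r²`, and normalized by the summed weights over the
aperture. Exact spherical-cap weighting was rejected as negligible at
pitch ≪ distance. The time derivative uses central differences; delayed
samples are linearly interpolated; both are unremarkable and unstated in
the underlying algorithm, so the simplest consistent choice is used.
Voxel-detector pairs whose delay falls outside the record contribute zero
and the truncation fraction is logged. The output stays signed.

**Dual speed of sound.** A head-like higher-SOS region is modeled as an
axis-aligned ellipsoid; time of flight along the straight detector-voxel ray
is `L_in/c_in + (L − L_in)/c_bg`, with the interior chord `L_in` from the
ray-ellipsoid quadratic. Rays are not refracted at the boundary — an
analytic two-speed TOF is only consistent with straight rays. Tangent and
missing rays have zero interior chord. When the ellipsoid is absent, missed,
or has `c_in = c_bg`, the code short-circuits to `L/c_bg`, making the
degenerate dual-SOS reconstruction *bit-identical* to the homogeneous one.
Arbitrary ellipsoid orientation is deferred: a rotation would complicate the
quadratic with no specified use.

**Envelope detection.** The magnitude of the analytic signal (Hilbert
transform) along each z column removes the bipolar oscillation; output is
non-negative and pointwise ≥ the input magnitude.

## Image analysis

- **Resolution**: per wire, the axial (z) and lateral (x) intensity profiles
  through the local peak are fitted by least squares with a Gaussian plus
  constant offset; FWHM = 2√(2 ln 2) σ. Fits with r² < 0.5 are flagged
  unusable and excluded from the linear FWHM-vs-depth trend.
- **Depth-coded MIP**: per projected ray, intensity = max, hue = arg-max
  index through a stated colormap; ties break to the shallowest index.
- **Segmentation**: hysteresis thresholding (seeds ≥ high fraction of max,
  grown into ≥ low by 26-connectivity) with a minimum-size filter, labels
  ordered by decreasing size. The simplest reproducible choice; thresholds
  are parameters.
- **Fluence**: diffusion approximation `Φ = exp(−μ_eff · depth_below_surface)`
  with `μ_eff = √(3 μ_a (μ_a + μ_s'))`, clamped to 1 at and above the
  surface — a desk-verifiable, swappable stand-in for a voxel Monte-Carlo
  transport solve. Compensation divides by `max(Φ, floor)`; the floor caps
  the gain (default 100×) so deep noise is not amplified without bound.
- **Dual-wavelength difference**: both envelope volumes are normalized by
  total energy, taken as the **L1** sum of envelope amplitudes ("total
  energy" is ambiguous between L1 and L2; L1 preserves mean-amplitude
  comparison semantics and makes each normalized volume sum to exactly 1).
  `D = norm(V₁₀₆₄) − norm(V₈₀₀)` is rendered on a diverging map, positive
  (artery-like) red, negative (vein-like) blue. No inter-wavelength image
  registration is attempted. Quantitative sO₂ estimation is out of scope.

## Determinism and seeding

A master seed is expanded through `numpy.random.SeedSequence` into per-stage
substreams (all < 2³¹), so stages re-run independently yet reproducibly.
Noise generation is the only stochastic element of the forward model;
simulation, reconstruction and analysis are bit-deterministic, and the
pipeline manifest records SHA-256 hashes to verify it.

## Study sizes

The packaged studies are scaled down to single-CPU scale while keeping the
instrument's physical parameters (100 μm pitch, 23 MHz sensor, 65.8 Pa NEP,
25 ns pulse): the wire study uses a 32 × 32-point scan over three wires at
2–6 mm depth reconstructed at 10 μm voxels, and the dual-wavelength study a
28 × 28-point scan over a two-tree vessel phantom at 40 μm voxels. A full
128 × 128 scan and 360 × 240 × 360 grid run the same code paths, only
longer.

## Known limitations

- No full-wave acoustics: no attenuation, dispersion, refraction or skull
  modeling; superposition of free-space N-waves only.
- The ringing tail and directivity are stylized single-parameter stands-ins
  for a measured sensor response; passing the synthetic studies shows the
  *chain* is correct, not that a physical sensor matches these curves.
- The fluence model ignores lateral transport and boundary effects, so
  compensation is exact only in the model's own geometry.
- Breathing motion, coupling-gel bubbles and other in vivo artifacts are not
  emulated; real-data resolution at depth will degrade faster than the
  synthetic trend suggests.
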