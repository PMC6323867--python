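# Methods

## Imaging model

The forward model is orthographic parallel-ray tomography of an object in
normalized coordinates: every axis of the voxel grid spans `[-1, 1]`, voxel
centers sit at `-1 + (2i + 1)/N`, and physical units attach only through
`voxel_size_um`. The sample rotates counterclockwise about the vertical
`z` axis (viewed from above); the detector is fixed, angle 0 views along
`+x`, and rays are spaced by `r` along the detector (default: the detector
spans the object cube, `r = 2/detector_px`). A point at detector offset `s`
and path parameter `t` sits at `(x, y) = (t cos θ + s sin θ, −t sin θ + s
cos θ)` in the sample frame; back projection reads the adjoint offset
`s = x sin θ + y cos θ`. These conventions are pinned so sinograms are
reproducible across sessions and implementations.

Three projection modes share this geometry:

* **Transmission** integrates the attenuation grid along each ray (the
  Radon transform), sampled at half-pixel steps with linear interpolation.
  It is linear in the grid and conserves mass (`Σ bins · r = Σ grid ·
  pixel area`) to discretization accuracy.
* **Reflective** marches each ray in half-voxel steps with nearest-voxel
  lookup; a ray that meets no opaque voxel records the background level
  `B`, otherwise the first-hit voxel's per-channel diffuse reflectance.
  With `shading_mode="lambertian"` the value is additionally scaled by
  `max(0, cos)` between the outward surface normal and the reversed ray —
  the diffuse-reflection cosine law. Normals come from central differences
  of the opacity field smoothed with a Gaussian of σ = 1 voxel, because
  gradients of a raw binary mask are degenerate. Flat shading is the
  default: it matches the idealized perfectly diffuse, angle-independent
  illumination the imaging chamber aims for, and makes projections of a
  uniform convex object exactly angle-invariant. Illumination
  inhomogeneity, shadows, specular highlights, refraction and
  interreflection are deliberately not modeled.
* **Semitransparent** composites front to back over the voxels a ray
  enters: each contributes its reflectance attenuated by the product of
  the transmittances in front of it, and the background enters with the
  residual product. Opaque voxels carry transmittance 0, so they
  contribute and terminate the ray; an `n`-voxel slab of transmittance `t`
  passes exactly `B·tⁿ`. The voxel list comes from the same half-voxel
  marching as reflective mode, so silhouettes agree exactly between the
  two modes (a fully transparent shell is invisible).

The default acquisition is the standard protocol: 360° in 0.9° steps (400
projections) with `B = 1` in simulation units (255 for 8-bit export). The
step must divide the total angle exactly or the configuration is rejected.
Reflective imaging genuinely needs the full turn — opposite faces differ —
while transmission obeys `P_{θ+180}(s) = P_θ(−s)` and needs only 180°.

## Reconstruction

Reflected-light sinograms have inverted polarity (background bright), so
the normative preprocessing is the elementwise min/max swap
`s' = min + max − s`, an exact involution applied before filtering. Each
projection is then zero-padded to the next power of two (≥ 2× detector
length), multiplied by `|f|` in the frequency domain (optionally tapered
by a Shepp–Logan sinc or Hann window), and back projected with weight
`π / n_angles` and linear (or nearest, for oracle comparisons)
interpolation; angles beyond 180° are used as acquired. The center of
rotation is assumed at the detector midpoint. Values outside the inscribed
circle are unconstrained by parallel-beam data and are masked by default.

Two post-inversion options exist because the value the background maps to
after the min/max swap is not zero:

* `air_calibration` subtracts that constant so empty rays carry exactly 0
  and object rays carry the surface absorbance `B − ρ` — the
  reflected-light analogue of the air calibration every absorption scanner
  performs. Without it the background pedestal back projects into a bias
  field plus a detector-edge ring, and no single global threshold
  separates the object cleanly (sphere surface Dice 0.67 vs 0.93 with
  calibration). It is off by default (the min/max swap alone is the
  normative chain) and recommended for quantitative surface extraction.
* `reinvert_output` flips the reconstructed values so reflective surfaces
  display bright on dark.

Numerical notes: the ramp filter's DC response is exactly zero, but
zero-padding leaves a step response at the two outermost detector samples
(amplitude `c/8` for a constant projection `c`) decaying quadratically
inward — harmless in practice because projections of an in-field object
are flat (background) at the detector edges, and removed entirely by air
calibration. Volume reconstruction applies the min/max inversion with the
global extrema of the whole stack so slices stay mutually consistent, and
runs FBP independently per detector row.

## Multichannel processing

White balance follows the constant-background convention: each channel is
multiplied by `reference / background`, with the background estimated as
the median over a border frame (default 5% fractional width) and the
reference defaulting to the brightest channel's background. The operation
is exactly idempotent. Composition clips (never rescales) so balanced
radiometry survives. The six standard bandpass filters are encoded as
`SPECTRAL_BANDS_6` (377/50, 420/40, 460/50, 525/50, 600/50, 690/70 nm);
spectral profiles report per-band ROI mean ± sd ordered by center
wavelength.

Channel/modality alignment is landmark-driven (matched `x y z` point
files, ≥ 3 non-collinear pairs; five is typical). The fit is the Kabsch /
orthogonal-Procrustes solution with the smallest singular direction
sign-corrected, so the returned rotation always has determinant +1 —
reflections are never returned, even for degenerate-ish configurations,
and collinear landmark sets are rejected because the rotation about the
line is unconstrained. Volumes resample under the fitted transform with
linear interpolation and a declared fill value; points map exactly.

## Surface metrics and morphometrics

Surface masks are thresholded volumes (orientation set by a bright-sample
flag, so raising the threshold never adds voxels), with optional removal
of connected components below a voxel count, optional largest-component
selection, and optional hole filling for solid objects traced as shells.
Boundary voxels are foreground voxels with a background face-neighbor
(6-connectivity). Dice is `2|A∩B|/(|A|+|B|)` (defined as 1 for two empty
masks); the mean surface distance is the symmetric mean of
nearest-boundary Euclidean distances in micrometers.

Straight extents are the foreground span projected on an axis plus one
voxel width, so a bar of 100 voxels at 10 µm/voxel measures 1000 µm;
polyline extents are arc lengths of vertices given in voxel coordinates.
Percent shape change between two states is
`round_half_up(100·|state − reference| / reference)` with the relaxed
(reference) state as denominator — the only rounding/denominator rule
consistent with all four printed worked-example percentages (29, 13, 12,
23); for the 848 vs 758 µm pair the 758 µm denominator is an
interpretation, chosen for consistency with the other three.

## Synthetic fixtures

The fixture generator emulates the published study conditions with no
external data: full-turn 0.9° series, white background normalized to 1,
scaled-down 128-px detectors by default (the 512-px protocol is one flag
away), and optional seeded additive Gaussian detector noise (off by
default; the physical system's noise is otherwise not modeled). The named
objects mirror the kinds of specimens imaged: an opaque sphere, a 2D
opaque ellipse, a banded cylinder with colored rings in three (R, G, B)
channels, a two-tone compound solid with landmark files, and a six-sector
shell tagged with the six bandpass filters. What the fixtures do *not*
reproduce: surface texture and roughness, uneven illumination, specular
highlights, perspective (non-telecentric) distortion, mechanical
center-of-rotation drift, and camera noise beyond the optional additive
Gaussian term — so passing tests demonstrate the correctness of the
computational chain, not the image quality attainable on real hardware.

## Verification workflows and problem sizes

`optsurf.workflows` (used by both `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs the chain end to end at desk scale, chosen
so each workflow completes in seconds to ~1 minute on one CPU:

* rim recovery: 2D opaque ellipse, 128² grid, 128-px detector, 400 angles;
  the reconstructed rim (mid-range threshold) must cover ≥ 95% of the true
  boundary within 2 px (measured: 100%);
* transmission oracle: 128² uniform disk, RMSE vs ground truth at 400
  angles under the frozen 0.05 bound, strictly decreasing over
  25→50→100→400 angles spanning 180° (a centered disk is
  rotation-symmetric, so a 360° span makes the 25- and 50-angle runs
  coincide exactly — transmission needs only the half turn);
* occlusion: perturbing interior voxels changes no projection, exactly;
* registration: a known rigid motion of 5 landmarks recovered to < 1e−9,
  determinant +1;
* white balance: backgrounds equal to the reference within 1e−6 relative,
  idempotent to 1e−12;
* color recovery: 64³ three-channel banded cylinder, 400 angles; the
  reconstructed reflectance estimate (`B −` calibrated absorbance) must be
  dominated by the true channel along an axial surface line profile in all
  four rings and the body;
* surface recovery: 64³ opaque sphere, surface mask thresholded at the
  mid-range of the calibrated absorbance scale, Dice ≥ 0.90 at 400 angles
  and strictly above the 100-angle run (measured: 0.933 vs 0.929 — the
  margin is small because a sphere's silhouette is angle-invariant, so
  extra angles only reduce angular-smearing artifacts);
* morphometrics: the four printed larva length pairs reproduce 29, 13, 12
  and 23 percent exactly.

## Known limitations

Perspective/cone-beam geometry, iterative or PSF-aware reconstruction,
ring-artifact and center-of-rotation correction, intensity-based
(non-landmark) registration, spectral unmixing and ICC color management
are out of scope. The semitransparent mode is implemented for 2D phantoms;
multiple-reflection physics at interfaces is not modeled, so its interior
intensities are schematic. Reconstruction values in reflective mode are
not quantitative reflectances — the first-hit image is not a line
integral, so FBP concentrates signal at the surface and channel
*orderings*, not absolute values, are the reliable readout.
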