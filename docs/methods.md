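# Methods

This note records the models, default parameters, numerical choices and
known limitations of `mribulk`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The question being modelled

Bulk density assignment replaces per-voxel electron densities with one
representative value per tissue class, so that an MRI — which carries no
density information — can support dose calculation. The package compares
three assignment schemes of increasing fidelity (W: all water; W+B: bone
and teeth at RED 1.45; W+B+A: air additionally at RED 0) by optimizing a
plan on each scheme's density, freezing the beamlet weights, and
recomputing the dose on a heterogeneity-corrected CT density. Coverage
differences (predicted − actual V100 %/V93 %) quantify how much each
scheme's missing heterogeneity misleads the optimizer. Two side studies
quantify MRI geometric distortion with a grid phantom and the dosimetric
cost of a distorted body contour at the shoulder.

## Synthetic phantoms

Patient images are institutional and unavailable, so all inputs are
procedural phantoms. The head phantom is an elliptical face/cranium
column (semi-axes 70 × 85 mm) with a dome, on a 46 mm-radius neck; a
cranial bone shell (6 mm skin, 8 mm thick, metric erosions of the body),
sinonasal air boxes anterior of the target, mandible and tooth arcs
around a mouth center, and optionally two dental implants embedded in the
tooth arc with a 6 mm streak-artifact shell. Structures: a spherical
PTV70 (r = 24 mm) at the isocenter region with 10 mm/6 mm expansions to
PTV63/PTV59 (targets exclude air cavities — no dose is deposited in air),
brainstem/cord/cord+5 mm posterior, chiasm and optic nerves superior.
A per-patient seed jitters face size and target position/radius (±2 mm,
±1 mm) and drives the artifact HU pattern and MRI noise; everything is
bitwise reproducible for a fixed (config, seed).

CT numbers per class — soft 40, bone 700, air −1000, tooth 1400, implant
3000 HU, artifact shell uniform in [−500, 500] — sit strictly inside the
segmentation threshold regions, so thresholding (HU > 250 / < −300)
recovers the generating bone∪teeth and air labels exactly; the randomized
artifact shell reproduces the corrupted Hounsfield numbers around dental
hardware. The MRI gives teeth, implants and air the same signal-void
intensity and the artifact shell the soft-tissue intensity, encoding the
physical fact that none of them can be told apart on the MRI alone.

The phantoms emulate only the topology that drives the studied effects
(bone shells, air pockets, dental hardware near targets); they are not
anatomically realistic, so absolute coverage differences characterize
this geometry, not any patient population — only signs, orderings and
rough magnitudes transfer.

The grid phantom is a 256 × 256, 25 cm-FOV axial image of a 20 cm disk
with an additive anti-aliased line grid at 15 mm pitch (one top-hat
profile per direction, so intersections carry twice the line amplitude).
A 13 × 13 candidate lattice clipped at 88 mm radius leaves exactly 109
interior intersections (any clip radius in [15·√34 ≈ 87.46, 90) mm does;
the grid lines extend to 89 mm so no further intersections are rendered);
the layout is locked by a regression test. Distortion fields are uniform
shifts, radial polynomials |d|(r) = A·(r/R)^k about the scanner axis, or
per-axis polynomials; images are warped by pull-back resampling (linear
interpolation, zero fill) and truth coordinates by the exact fixed point
of the same map, so image and truth stay consistent at any amplitude.

## Density schemes and calibration

The engine works exclusively in relative electron density; the bulk bone
value is the published pair 1.53 g/cm³ ↔ RED 1.45, of which RED is
operative. The default HU→RED curve is piecewise linear through
(−1000, 0), (0, 1), (700, 1.45), (1400, 1.84), (3071, 3.0), clamped at
the ends: anchoring phantom bone at its exact bulk value makes the CT arm
and the bulk schemes agree on bone by construction, so scheme comparisons
isolate scheme effects rather than calibration error. Implants are
overridden to RED 3.0 via mask on the CT arm (the clinical workflow) and
deliberately treated as teeth (RED 1.45) on the MRI arms — the failure
mode under study. Contour cropping uses the Euclidean distance transform
in millimetres (voxel anisotropy makes structuring-element erosion
wrong); the inferior cut is a world z-plane (vertebral-level detection is
anatomical and out of scope); cropping is idempotent for margin ≤ the
internal retention distance (5 mm ≤ 10 mm defaults).

## Dose engine

A declared, primary-only divergent pencil model stands in for a clinical
dose algorithm. Per beamlet, at a point p inside its top-hat pencil:

    D(p) = w · B(d) · exp(−μ_eff · max(d − d_ref, 0)) · (SAD / r(p))²

with d the water-equivalent depth along the source ray, B a linear
build-up ramp over d_max = 15 mm, d_ref = d_max (unit weight ⇒ unit dose
at reference depth on the axis at SAD = 1000 mm), μ_eff = 0.049 cm⁻¹ (a
6 MV effective primary attenuation: 4 mm of water changes dose at depth
by ≈ 2 %). Scatter kernels, electron transport, penumbra and off-axis
softening are deliberately absent: the compared quantities are driven by
missing *primary-path* attenuation (bone, teeth, implants, contour
errors), and a primary-only model preserves their sign and ordering.

Radiological depth is computed two ways. `radiological_depth` is an exact
Siddon-style voxel traversal (constant-density boxes), used as the
oracle. The vectorized engine integrates RED by midpoint sampling at a
1 mm step with nearest-voxel lookup; the sample count derives from the
volume diagonal, so any subset of rays integrates with the identical
pattern — `beamlet_dose` and `compute_dose` are therefore mutually
consistent to machine precision, and both agree with the exact traversal
to well under 1 % per ray (exactly, in uniform media). Because every
point receives each beam through exactly one top-hat beamlet, a beam's
influence on a voxel is one kernel value plus a beamlet index, which is
what makes full coverage evaluations cheap.

The fluence optimizer minimizes quadratic penalties — two-sided on
targets with separate under/over weights (60 : 1; a symmetric penalty
centres the dose on the prescription and can never reach 95 % coverage),
one-sided above each OAR cap (weight 30) — by projected gradient with a
fixed 200-iteration budget, step 1/L from a seeded 25-step power
iteration, uniform initialization scaled to the mean prescription, and
non-negativity projection. Nested targets are disambiguated by assigning
each voxel its highest prescription. The final plan is rescaled so that
D95 of the highest-prescription target equals its prescription (the
"95 % receives the prescribed dose" normalization; the quantile uses
`method="lower"`, guaranteeing V100 ≥ 95 on the optimization density).
Everything is deterministic given the seed. Default seven-field
nonopposing angles: 0, 51, 103, 154, 206, 257, 309°; beamlets 5 mm at
isocenter; dose grid 2 mm isotropic (the head-phantom default grid, so no
resampling is needed; a CT-like 1 × 1 × 2 mm grid is available in the
phantom config).

## Coverage statistics

V100/V93 use the inclusive convention (dose ≥ level) and V93 the printed
planning levels 65 / 58.6 / 55 Gy rather than recomputed 0.93·Rx
products. DVHs are exact voxel-count cumulative histograms at 0.1 Gy
bins; differences are predicted − actual in percentage points (negative =
smaller volume on the MRI side); cohort aggregates report mean ± standard
error of the mean. Coverage denominators use the cropped structures.
Dose-difference maps label voxels by the highest exceeded |Δ| threshold
(1/2/3 Gy) within a 2 cm expansion of the implant-slab target.

## Distortion QA pipeline

Grid and background images are subtracted, up-sampled 2× (linear,
alignment-preserving), and smoothed with a Gaussian of σ = 1.5 output
pixels. Intersections are local maxima above 0.55× the image maximum
(between the one-line and two-line levels), non-maximum-suppressed at
half the grid pitch (7.5 mm), and refined per axis by a three-point
parabolic fit through the peak; a plain 3×3 intensity centroid was tried
first and left a ~0.17 mm bias from the ridge background, whereas the
parabolic vertex reaches the ~0.03 mm discretization floor. Matching is
mutual nearest neighbour with a half-pitch rejection radius; statistics
are per-pair Euclidean distances (mean, sample SD, max). Scanner offsets
are emulated by shifting the distortion-field center, not by a scanner
model.

## Contour-error experiments

The neck phantom is a water-equivalent 46 mm neck on an elliptical
shoulder slab (170 × 80 mm half-axes, slices z ≤ −10 mm) with an
ellipsoidal PTV63 surrogate extending into the shoulder slices. The body
contour error adds `shift_mm` (default 4 mm) of water outside the lateral
surface where x ≥ 70 mm on the shoulder slices — with the default seven
angles, exactly the 51° and 103° beams partially traverse the modified
region (verified by a ray diagnostic in the result). Single-field mode
reports the percent dose change at a point 6 cm deep on a lateral field's
axis (≈ 1 − exp(−0.049·0.4) ≈ 2 %); seven-field mode freezes a plan
optimized on the correct contour and reports the percent change of the
mean dose over the PTV63 slab slices (≈ 0.4–0.5 %, the multi-field
dilution of the single-field rule of thumb).

## Problem sizes and determinism

Default experiment scale: 110 × 110 × 84 voxels at 2 mm, 7 beams × 20 ×
20 beamlets, ≤ 4000 sampled voxels per structure for optimization, full
structure voxel sets for coverage; one patient runs in well under a
minute on one core. All randomness (phantom jitter, artifact HU, MRI
noise, power-iteration start) flows from explicit integer seeds;
identical configurations reproduce reports bitwise.

## Known limitations

* Primary-only dose: no scatter, build-down, penumbra or electron
  transport; absolute dose and OAR values are indicative only.
* Procedural anatomy: coverage-difference magnitudes depend on the
  phantom's bone/air/implant geometry; only directions and orderings are
  meaningful beyond it.
* Soft tissue is a single class at 40 HU, so the bulk schemes carry a
  small systematic soft-tissue density bias (RED 1.026 vs 1.0) that real
  mixed fat/muscle tissue averages away; this inflates all coverage
  differences by a common component.
* The MRI is never segmented directly (the study design transfers
  CT-derived contours); MRI pulse-sequence physics, susceptibility
  distortion, and scanner distortion-correction are out of scope.
* The distortion analysis is strictly in-plane (axial), as is the grid
  phantom's landmark definition.
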