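# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `corneasym`.

## Data model

An `ElevationGrid` is an n×n matrix (default n = 140) of surface elevation in
micrometers relative to a reference (best-fit) sphere, with NaN marking
unmeasured points. The grid step defaults to 0.1 mm (140 points ≈ 14 mm
chord, covering the ~12 mm corneal footprint with margin); the physical
x/y origin is the integer index nearest the geometric center, (70, 70) for
n = 140. Device exports with a circular footprint therefore carry ≈ 11 300
measured points of the 19 600 lattice points. All zone geometry is computed
in millimeters, so a different grid step is a configuration change only.

Readers accept comma- and semicolon-delimited grids (semicolon implies
decimal commas, the convention of the device's locale), blank/`NaN`/`-1000`
missing-value encodings, and µm or mm source units; anything else is a loud
error naming the offending cell. The writer emits shortest round-trip
decimal representations so write∘read is the identity.

## Registration

Fellow eyes are compared under mirror symmetry: the left map is reflected
about the y axis (x → −x). Reflection is about the integer center column, so
the single column with no mirror image inside the matrix becomes missing;
for circular footprints no measured point is affected.

Four adjustments absorb acquisition misalignment: in-plane shift (dx, dy),
frontal-plane rotation θ about the map center, a uniform elevation offset dz,
and a planar tilt t_x·x + t_y·y. Tilt is modeled as a plane rather than a
3-D rigid rotation of the surface: for the few degrees of head pitch/yaw
seen in practice acting on a ~tens-of-µm elevation range, the planar
small-angle term dominates, and it makes the (dz, t_x, t_y) subproblem
linear. Resampling is bilinear and mask-aware — a target point is valid only
if all four supporting lattice points are valid — so transforms never
extrapolate across the missing-data boundary.

The auto-registration objective is the zone-mean absolute difference (VBS).
For fixed (flip, dx, dy, θ) the minimizing (dz, t_x, t_y) are an L1 plane
fit to the signed difference, solved by iteratively reweighted least squares
(weights 1/max(|r|, ε), ε = 1e−6 µm, ≤ 50 iterations, started from the
least-squares plane). The outer search over (dx, dy, θ) is a Nelder–Mead
simplex (initial steps 0.2 mm / 2°, stopping when the VBS improvement falls
below 1e−3 µm or after 200 iterations), started from zero — the maps are
pre-aligned by their centers — with a deterministic 3×3×3 coarse-lattice
probe that triggers a restart only when it beats the zero start by more than
0.05 µm. In symmetry mode `auto` both the mirror and direct branches are
optimized and the lower-VBS branch returned, ties going to mirror (the
anatomical default). The whole procedure is deterministic: fixed inputs
reproduce a bit-identical trace of accepted (improving) steps, whose VBS
sequence is non-increasing by construction.

### Objective zone

VBS is reported for the 4.0 and 6.0 mm zones, but the *optimizer* minimizes
VBS on the 6.0 mm zone by default. Two measured reasons:

1. **Rotation leverage.** The rotational signal of a toric surface grows as
   r², and the displacement a rotation produces grows as r. Restricted to
   the central 4 mm, cyclotorsion is weakly determined (median recovery
   error ≈ 1° at 1 µm noise on realistic surfaces); on 6 mm it is ≈ 0.3–0.5°.
2. **Noise overfitting.** Minimizing an empirical mean over ~1 250 points
   selects the low tail of the noise landscape and biases post-registration
   VBS below the theoretical noise floor; with ~2 800 points the bias stays
   within a few percent.

A genuinely degenerate fact worth knowing: a shifted *quadratic* surface
differs from the original by exactly a plane, which the tilt correction
absorbs. Decentration is therefore identifiable only through third- and
higher-order surface structure; this is true of the real instrument as much
as of this implementation, and it drives the simulator design below.

## VBS metric

VBS is the arithmetic mean of |registered left − right| over the valid
lattice points of the zone, in µm; the computation errors out when zone
coverage falls below 90%. Ring summaries use 0.5 mm annuli. Averaging is
per lattice point (not area-weighted); on a 0.1 mm grid inside a ≥ 4 mm zone
the two differ negligibly. The "volume" reading of the index
(mean × zone area, mm³) is exposed as a derived field but plays no role in
thresholds. Useful closed forms used in the tests: a constant difference c
gives VBS = c; independent per-eye Gaussian noise of SD σ gives
VBS = 2σ/√π (folded-normal mean of an N(0, 2σ²) difference).

## Pattern classification

The original pattern labeling of interocular difference maps was machine
learned; training data being unavailable, this package substitutes a
transparent rule set on the low-order Zernike spectrum (orthonormal basis
through radial order 4, least-squares fit on valid in-zone points with
coordinates normalized to the zone radius). With orthonormal scaling,
squared coefficients are energies; piston is excluded throughout:

* non-piston RMS < 3 µm → `flat`;
* otherwise the energy fractions of three term groups are compared — tilt
  (Z1^±1), defocus+spherical (Z2^0, Z4^0), astigmatism (Z2^±2) — and a group
  holding ≥ 0.5 of the non-piston energy wins (`tilt`, `cone`, `four_leaf`);
* `cone` additionally requires a real central dome: the non-piston
  reconstruction at the origin must be at least as large as the RMS;
* no dominant group → `irregular`.

The 3 µm flat threshold sits above the classifier's noise response (a 2 µm
correlated-noise map projects to ≈ 0.8 µm of spurious low-order RMS) and
below any clinically meaningful pattern amplitude. Scores are normalized
energy fractions (plus an irregularity score 1 − max fraction), so the
argmax of the scores is always the label, and classification is invariant to
adding a constant and to rotating a four-leaf field between its sine/cosine
astigmatism terms.

## Screening statistics

The unit of analysis is the eye pair: one VBS value per pair. Group means
are compared with a Welch (unequal-variance) t test and a 95% CI from the
Welch–Satterthwaite degrees of freedom — chosen over Student's t because it
reduces to it under equal variances and is safer otherwise. Threshold
screening calls a pair positive iff VBS > t (strict), so a cohort in which
no control exceeds t is exactly all-negative at t. PPV and NPV are reported
as null when their denominators are zero, never coerced to 0 or 1.
Degenerate inputs (single-class labels, both groups constant) are errors.

## The simulator

Each surface is a conicoid (apical radius R, asphericity Q) expressed
relative to a fixed reference sphere (default: the base apical radius —
interocular radius differences therefore appear as defocus-like elevation
differences, as they do on device maps sharing a reference), plus a toric
term cyl·cos²(θ − axis)·(r/r_max)² and an optional Gaussian cone. Useful
conversion: 1 D of corneal astigmatism ≈ r²·1.5 µm/mm² of elevation
toricity, i.e. cyl ≈ 54 µm at the 12 mm footprint edge; the default normal
anterior surface uses cyl = 70 µm (≈ 1.3 D, with-the-rule).

A pair is built as: right eye = base surface + per-field biological deltas
(radius, asphericity, cyl, axis, cone); left eye = mirror of the base
surface, *acquired* under an injected flip/shift/rotate/tilt misalignment.
The misaligned left grid is produced by evaluating the analytic surface on
warped coordinates, so the injected parameters are exactly what a perfect
registration should recover — the ground truth carries no resampling error.

Two random surface components complete the anatomy:

* a **mirror-shared** smooth higher-order field (sum of 40 random cosines,
  wavelengths ~2–5 mm, SD 2.5 µm), identical (mirrored) in both eyes. It
  cancels in a registered difference map but supplies the spatial landmarks
  that make decentration and cyclotorsion identifiable (see the quadratic
  degeneracy above). Fellow-eye higher-order shape is mirror-correlated in
  real corneas; a landmark-free simulator would make registration an
  ill-posed problem the real instrument does not face.
* an optional **per-eye independent** smooth field (correlation ≈ 1.5 mm)
  representing normal corneal micro-irregularity; it contributes residual
  interocular asymmetry.

Measurement noise is zero-mean Gaussian with the requested marginal SD and a
short spatial correlation (default 0.1 mm, one grid step), reflecting the
smoothing inherent in Scheimpflug surface reconstruction; each realization
is rescaled to the exact target SD. White noise (correlation 0) is
available but unrealistic in two ways at once: real elevation maps are
reconstruction-smoothed, and under white noise the bilinear resampling at a
generically off-lattice registered position averages independent samples and
deflates post-registration VBS ~15–20% below the 2σ/√π floor — an estimator
artifact, not a property of the surfaces. Under the correlated default the
floor law holds within 10% for σ between 0.5 and 4 µm.

### Cohort scenarios

`separated` draws, for every pair: interocular deltas (ΔR ~ N(0, 0.2 mm),
ΔQ ~ N(0, 0.08), Δcyl ~ U(0, 12) µm, Δaxis ~ U(±30°)), acquisition
misalignment (shift U(±0.3) mm, rotation U(±3)°, dz U(±10) µm, tilt
U(±5) µm/mm), independent irregularity 7 µm, noise 2.5 µm — and, for cases
only, a decentered Gaussian cone (amplitude U(40, 85) µm, σ U(0.6, 1.2) mm,
center within 1.5 mm of the apex, i.e. confined to the central cornea).
Posterior surfaces share the biology and head pose with 1.3× cone amplitude
and 1.5× noise. `null` is identical with cones disabled.

These priors were calibrated once so that post-registration group VBS lands
on a clinically plausible scale (normals ≈ 4 µm, cone group ≈ 10–11 µm at
4 mm, group differences ≈ 5.6 µm at 4 mm and ≈ 3.5 µm at 6 mm). A point
worth noting: auto-registration legitimately absorbs roughly 40% of a
unilateral cone's raw contribution — it minimizes VBS, and partial
cancellation of the cone by mis-rotation is often optimal — so raw cone
amplitudes exceed the VBS they produce. Cone-group separation is therefore a
property of the *pipeline*, not of the generator alone.

### What the simulator does not model

Biconic cross-terms, epithelial remodeling, real Scheimpflug ray geometry
and its spatially varying error, bilateral (two-eye) keratoconus, and any
empirical population distribution of the deltas. Passing tests demonstrate
the pipeline's correctness and sensitivity under these controlled
conditions; they do not certify clinical screening performance, which in the
source setting was established on patient data this package does not have.

## Problem sizes and numerics

The test suite and acceptance script use 140×140 grids throughout;
registration evaluates ~2 800 in-zone points per objective call and
converges in 100–250 calls (&lt; 1 s per pair on one CPU). The acceptance
script runs 20 recovery pairs, an 11×11×11 brute-force comparison on 8
pairs, 200 pattern maps, and a 30 + 30 screening cohort in about two
minutes. Tolerances: interpolation identity 1e−9 µm on lattice-aligned
queries; IRLS convergence 1e−9 on parameters; simplex ftol 1e−3 µm.
Degenerate inputs (all-missing grids, zones outside the grid, single-class
cohorts, zero-variance groups) raise typed errors rather than returning
numbers.
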