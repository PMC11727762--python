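# Methods

`canalfill` re-creates, on fully synthetic data, the computational chain
used to study how the volumetric canal fill ratio (VFR) of stemmed
reverse-shoulder humeral components relates to primary stability and
proximal bone loading: CT densitometry, canal morphometry, virtual implant
planning, postoperative 2D–3D verification, cyclic-loading kinematics,
and the statistical layer that ties them together. Every quantitative
claim below is either asserted by the test suite or computed by
`scripts/acceptance.py`; nothing else is reported as a result.

## Coordinate conventions

All volumes are indexed `[ix, iy, iz]` with +x medial, +y anterior and
+z proximal along the diaphyseal axis; the x–z plane is the coronal
plane. Loads act in the coronal plane, subsidence is distal (−z)
migration reported positive, and varus/valgus tilt is rotation about +y.
Poses are proper rigid transforms `x → R x + t` in mm.

## Synthetic humerus phantom

The phantom is a stacked solid of revolution: a tubular diaphysis (lumen
radius 4.5 mm, cortical wall 4 mm, default length 70 mm), a metaphysis
whose outer radius flares as √(fractional height) from 8.5 mm to 11.5 mm
while the cortex thins from 4 mm to 1.5 mm, and a spherical head
(radius 16 mm, shell 1.5 mm) offset 5 mm medially. The √-flare makes the
metaphysis widen quickly above the diaphysis, like the real bone, so a
metaphyseal cup can seat below the neck cut. Tissue classes (cortical,
trabecular, canal marrow, background air) are voxelized at 0.5 mm
isotropic by default, with exact boolean ground-truth masks returned
alongside the grayscale volume.

Grayscale means are HU-like scanner units (air −1000, fat −100, muscle
40, marrow −50, trabecular 305, cortical 1500) plus iid Gaussian noise
(default sd 20). Air/fat/muscle calibration patches are embedded in a
corner of the grid so densitometric calibration is self-contained. The
trabecular mean is set so that, after calibration and thresholding at
250 mgHA/cm³, the metaphyseal bone volume fraction lands near 0.22 —
the magnitude reported for cadaveric metaphyseal BV/TV — making the
density metrics realistic rather than saturated at 0 or 1.

What the phantom does *not* emulate: trabecular microarchitecture,
cortical porosity, anisotropic voxels, beam hardening, scatter, or a
statistical shape population. Tests passing on the phantom demonstrate
correctness of the measurement chain on known geometry, not segmentation
performance on clinical CT.

## Densitometry

Calibration is the three-anchor piecewise-linear map taking the measured
air/fat/muscle grayscales to −840 / −80 / 30 mgHA/cm³, extrapolated
linearly beyond the outer segments; beyond the muscle anchor the
fat→muscle slope continues so cortical bone maps to realistically high
BMD (the anchor sources give no prescription there). The map is exact at
the anchors by construction and monotone because the anchors are ordered
in both coordinates.

VOI metrics are plain pixel counting: mean BMD over the VOI, and BV/TV
as the fraction of VOI voxels at or above a bone threshold
(default 250 mgHA/cm³, configurable — the threshold is a parameter, not
a claim of fidelity). Default VOIs are axis-aligned cylinders placed
from the bone's z-extent (epiphyseal, metaphyseal, and a medial
"inferior support" cylinder); their exact placement is configurable.

## Resection, canal segmentation, fill ratios

The anatomic-neck resection plane follows the 135° neck-shaft
convention: its normal lies at 45° to the shaft axis in the coronal
plane. Resection removes bone voxels on the proximal side; a plane above
the bone is a no-op, a plane that would remove everything is rejected.

Threshold segmentation reproduces the standard chain: threshold the BMD
volume for the cortical shell (default 800 mgHA/cm³), close it
morphologically, fill each transverse slice of the (still uncut) shell
to obtain the interior, clip by the resection plane, and keep the
largest connected component. Filling is slice-wise because the shaft is
an open tube in 3D. On the default phantom this reaches Dice ≈ 0.99
against the ground-truth interior and is insensitive to grayscale noise
up to sd 30.

The three fill ratios:

* **3D VFR** — implant volume (stem + cup) distal to the resection plane
  divided by the canal volume between the plane and the transverse level
  of the implant tip, both counted on the same voxel lattice. The distal
  bound at the tip level keeps short and standard stems on a common
  scale. Boolean midpoint counting carries a lattice-resonance error of
  a few percent when a radius is commensurate with the spacing (e.g.
  R = 4 mm at 0.5 mm); partial-volume (supersampled) counting is
  available on both sides of the ratio and reduces the error to well
  under 1%, which is what the analytic-oracle tests use.
* **2D metaphysis / diaphysis FR** — implant-to-canal width ratios on
  the AP silhouette at two transverse lines: the metaphysis line halfway
  between the resection plane and the top of the cylindrical diaphysis,
  the diaphysis line one stem-diameter above the tip (both
  config-exposed; the literature places them by clinical convention).
  For concentric cylinders VFR = (2D FR)² exactly, which the tests
  verify within discretization tolerance.

Any implant voxel center inside the cortical mask is a perforation: the
ratio is withheld and the placement rejected.

## Implant model and planning

Implants are parametric solids of revolution: a tapered stem (distal to
proximal diameter over the stem length) carrying a cylindrical
metaphyseal cup, at the fixed 135° neck inclination. Meshes (for STL
export) are watertight revolution surfaces; voxelization uses the exact
radius profile rather than the mesh. The default catalog grades proximal
diameters 6–9 mm (taper 1 mm) with cups of 10/12/14 mm over short
(35 mm) and standard (60 mm) stems — sizes chosen so phantom cohorts
realize fill ratios from roughly 0.4 to 0.8, bracketing the 0.72
low/high threshold.

Planning inserts each candidate along the shaft axis, centered on the
distal canal, cup seated at the plane (small proximal shifts resolve
borderline perforation). `best_fit` keeps the largest-volume
non-perforating entry; `target_ratio` keeps the entry whose achieved
VFR is closest to the requested value. Ties break toward the shorter
stem (less invasive). Group labels follow the threshold rule: VFR < 0.72
is low, ≥ 0.72 is high, crossed with stem type.

The oblique neck cut leaves sub-plane lateral metaphyseal interior that
no axisymmetric implant can reach, capping attainable VFR near ~0.85 on
the default geometry; cohort targets are therefore set at the group
means (low ≈ 0.62, high ≈ 0.80) rather than the extreme upper end of
the clinically reported range.

## Radiographs and 2D–3D registration

Radiographs are parallel-beam line integrals (AP along +y, ML along +x);
parallel projection keeps 2D widths scale-true, and no source geometry
is modeled. Postoperative scenes render implant metal at a grayscale far
above any bone line integral so metal pixels are separable.

Bone registration minimizes `2 − NCC(AP) − NCC(ML)` over the 6-DOF pose,
where the images are Gaussian-smoothed gradient magnitudes — invariant
to projection intensity scaling. The search is coarse-to-fine (half
resolution with heavier smoothing, then full resolution) using Powell
line searches with seeded multi-starts. Powell was chosen after the
originally planned Nelder–Mead simplex proved unable to traverse the
nearly flat axial-rotation direction of the quasi-axisymmetric bone
(stalling ~2 mm / 2° from truth); Powell recovers 2 mm / 5°
perturbations to ≲0.01 mm / 0.02° on noise-free renders. Convergence is
flagged when the final residual is below 0.1; on postoperative images
the metal region (thresholded, dilated) is excluded from the metric.

Implant pose correction matches soft silhouettes: the implant's
projected occupancy uses a ~one-voxel linear ramp at the boundary so
the loss varies continuously with pose, and the update is parametrized
as rotation about the implant's mid-axis point plus translation — about
the world origin, tilt and shift form a near-degenerate diagonal valley.
Rotation about the implant's own axis is not searched: stem and cup are
solids of revolution, so it is invisible in any silhouette. The target
silhouette comes from subtracting the registered bone's own projection
from the postoperative image. Pose deviation is decomposed in the fixed
order varus/valgus (about +y), then axial (about +z), then residual
(about +x), then translation; the order is stated because Euler-order
changes the numbers, and composing the components reproduces the
transform to 1e-9.

## Cyclic-loading tracking and kinematics

The load protocol is three force-controlled blocks of 1000 cycles at
1.5 Hz with peaks 220/520/820 N, applied at 30° in the coronal plane; a
20 N valley force (a typical seating preload; the protocol sources do
not print one) keeps the construct loaded between peaks. Optical
tracking runs at 30 Hz with iid Gaussian marker noise of 4.9 µm per
coordinate — the accuracy class of dual-camera photogrammetry rigs.

Marker model: the embedding (fixture) cloud spans the whole rig
(8 markers over ~80 mm) because the rigid-body correction amplifies
marker noise by the lever arm from the reference cloud to the measured
bodies; a fixture-scale reference keeps that amplification near the raw
marker accuracy. The bone cloud is a 6-marker patch on the medial calcar
cortex, implant and actuator carry tetrads. Bone deformation is modeled
as a pure translation of the bone cloud: an elastic component
phase-locked to the load (the reversible, hysteresis-width part) plus a
plastic drift that ramps within each block and saturates before the
final cycle, so block-end landmarks see the full per-block increment.
The implant rides on the bone and its prescribed subsidence/tilt are
exactly its motion relative to the bone body, giving the
generator/estimator closure the tests assert (< 0.1 µm / 0.001°
noise-free). The actuator follows the applied force and is used to
locate the analysis landmarks a–g (time-zero reference; valley and peak
of each block's final cycle) when no sidecar is available.

Pose estimation is the least-squares rigid fit (SVD of the
cross-covariance, reflection-corrected). Rigid-body correction fits the
embedding pose per frame and re-expresses all bodies in the embedding
frame; it is idempotent and makes all metrics invariant to any rigid
motion applied to the whole scene. Outcome metrics use the marker-cloud
centroid (the natural low-noise point-cloud statistic): implant
subsidence/tilt relative to the bone at block ends; bone micromotion as
the valley-to-peak hysteresis width of the final cycle; total bone
deformation from the time-zero reference. Displacements default to 3D
magnitudes with an along-axis option (the along-axis convention is not
universal in the literature, so both are provided).

## Statistics

* **ICC(C,1)** — two-way random effects, single measures, consistency
  (McGraw–Wong), from the two-way ANOVA mean squares, with the exact
  F-based confidence interval and a p-value testing ICC = 0 (the
  conventional null; testing against a threshold is a documented
  alternative not implemented). The absolute-agreement variant is
  deliberately *not* the default: consistency ignores fixed pre/post
  offsets, matching the planned-versus-implanted design.
* **One-way ANOVA** with pairwise pooled t tests under step-down Šidák
  adjustment `p(i) → 1 − (1 − p(i))^(m−i+1)` (monotonicity enforced,
  capped at 1), and observed power from the noncentral F at the sample
  effect size.
* **Distribution gate** — Shapiro–Wilk per group plus Brown–Forsythe
  (Levene on deviations from group medians); any rejection at 0.05
  routes to Kruskal–Wallis with Dunn's pairwise z tests under Bonferroni.
* **Pearson r** with the t-distributed p-value.

Type-I calibration is verified at 10 000 simulations with groups of
n = 20. Twenty (even) is used because the median-centered
Brown–Forsythe statistic is conservative for small odd samples — one
absolute deviation is identically zero — and only approaches its
nominal level from n ≈ 20 upward; the other three tests are already
calibrated at n = 10.

## Synthetic cohort (end-to-end)

The cohort driver cycles specimens through the four groups
(standard/short × low/high target), randomizing canal caliber
(4.2–4.8 mm), metaphyseal width and head size between specimens. The
loading generator couples biomechanics to the achieved fill ratio:
elastic bone amplitude falls with VFR (load sharing shifts to the
implant), looseness (0.9 − VFR) scales subsidence, tilt and drift, and
the native-bone run uses 1.3× amplitudes. These couplings encode the
qualitative orderings of interest (native micromotion > implanted;
high fill < low fill) and are what the cohort statistics then recover —
the cohort demonstrates pipeline integrity, not new biology.

Problem sizes are scaled for a single-CPU run: 1 mm voxels for the
cohort imaging chain (0.5 mm elsewhere), 10 cycles per load block in the
tracking sequences (the per-cycle motion model is exact, so block-end
metrics are unaffected), and single-start registration. An 8-specimen
cohort completes in a few minutes and emits the reliability table
(ICC per fill-ratio measure), the four-group comparison table, and the
fill-ratio-versus-micromotion correlations as CSV and markdown.

## Numerical choices and degenerate inputs

Tolerances: rigid-transform orthogonality 1e-9; registration Powell
`xtol` 1e-3 (mm/deg); deviation round-trip 1e-9; ICC oracle agreement
1e-10. Degenerate inputs are rejected with specific messages: coplanar
marker layouts (pose unidentifiable), collinear point sets, constant
ICC ratings, empty VOIs, solid bone without a canal, planes removing
all bone, perforating placements, unordered calibration anchors.
Boundary convention: VFR exactly 0.72 is assigned to the high group.

## Known limitations

Parallel-beam (not cone-beam) projection; axisymmetric implants (axial
rotation unobservable by design); the phantom's geometric idealization;
bone deformation modeled as cloud translation (no strain field); the
registration's capture range (~±10 mm / ±15°) assumes a coarse initial
alignment; 2D width ratios quantize at coarse pixel sizes and can
slightly exceed 1 when the segmented canal underestimates the true
interior near the cup.
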