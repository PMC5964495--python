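# Methods

This note documents the models, numerical choices and limitations of
the bundledissect pipeline and of the synthetic phantom that the tests
and the acceptance script run on.

## Coordinate conventions

All geometry is computed in world millimetres in an MNI-like RAS+ frame
(+x right, +y anterior, +z superior). Voxel indices are 0-based and a
voxel's world position is the centre of its cell; voxel space appears
only at interpolation and label-lookup boundaries. TCK is the canonical
tractogram format (world-native); TRK is converted on read using its
header affine, never silently assumed. The default analysis grid is
3 mm isotropic covering x ∈ [−75, 75], y ∈ [−110, 75], z ∈ [−50, 80]
mm (51 × 62 × 44 voxels).

## Streamline selection

Three predicates, all strict where they are inequalities:

- **VTA sphere.** Any point of the polyline — including points on
  segments between stored vertices — within 3 mm (inclusive) of
  (±6, −12, −8). The segment-aware point-to-segment distance makes the
  test invariant to resampling.
- **Frontal–basal connection.** Implemented on *terminals*: one
  endpoint with y > 18, the other with z < −8. A visitation variant
  (any point in each half-space) is available via
  `connects_frontal_basal(..., endpoint_rule=False)` for sensitivity
  analysis; the terminal interpretation is the default because the
  selection constrains fiber terminals.
- **Hemisphere exclusivity.** All x > 0 (right) or all x < 0 (left);
  any x = 0 contact conservatively voids exclusivity.

Predicates are evaluated in the order sphere → frontal/basal →
hemisphere and the first failure is recorded per streamline, giving an
auditable rejection log.

## Sub-bundle decomposition

The distal segment is the sub-polyline of arc length exactly
min(20 mm, total) ending at the frontal terminal, with an interpolated
cut point. It is subdivided at ≤ 0.5 mm and looked up in the label grid
with nearest-voxel sampling (labels are categorical; no interpolation).
A streamline belongs to every prefrontal parcel its distal segment
touches — multi-membership is kept, so per-parcel percentages can sum
to more than 100. "Frontal projection" means a non-empty parcel set;
that count is the denominator of all per-parcel percentages, while
"percent of full" relates it to the whole selected bundle. A streamline
whose trunk passes under a parcel without its distal segment touching
it is *not* counted — terminal anatomy, not passage, defines the
sub-bundles.

Tract-averaged scalars are unweighted means over the sub-bundle's
density-defined region (density ≥ 1 mm of streamline per voxel). A
density-weighted mean is available (`tract_scalar_stats(...,
weights=...)`) since the averaging scheme is a genuine free choice;
sampling along streamlines would be a third option and is not
implemented. FA and compartment fractions can be emitted ×1000
(per-mille) for direct comparison with normative tables.

## Density, group and relative maps

Density is streamline-**length** splatting: each streamline is
subdivided into ≤ 0.5 mm steps *preserving its vertices* (so geometry
and arc length are exactly unchanged), and each step's length is
distributed over the 8 voxel centres around its midpoint with trilinear
weights. The grid therefore sums to the total in-grid streamline length
to machine precision — the central correctness oracle — and the unit of
the 1 mm/voxel indicator threshold is physical. Thresholding is
inclusive (≥). Group maps average subject indicators to percent
occurrence, so values live on {0, 100/n, …, 100}. Relative maps count
*streamlines* (not length) passing each voxel, because they answer
"what share of the bundle runs through here"; a length-mass variant
would weight slow, meandering trajectories differently.

## Tensor model

Fitting is linear least squares on log-signal with the design matrix of
the usual 7-parameter DTI model, restricted to volumes with
b ≤ max_b (default 1000 s/mm²) — the high shell is removed from the
data before any arithmetic, which makes its exclusion provable by
corruption tests. OLS is the default; signal-weighted LS is a flag. The
estimator choice is a recorded default, not an inferred one.
Non-positive signals are clamped to machine epsilon with a logged
count. Diffusivities are in μm²/s (b·D carries a 10⁻⁶ factor against
b in s/mm²). Metrics use eigenvalues sorted non-increasingly; negative
eigenvalues are clamped to zero for FA only (flagged), ADCs keep raw
values.

## FACT tracker

Classic nearest-voxel FACT: bidirectional from each seed, stepping
1 mm along the current voxel's principal eigenvector, sign-aligned with
the previous direction; stopping on FA < 0.15, turning > 45°, leaving
the white-matter mask or the grid, or 300 mm length. These defaults are
stated choices (the comparison they serve is qualitative); an
interpolated direction field is available behind
`TrackingParams(interpolate=True)`. No retained point lies outside the
mask, output is deterministic and independent of seed order, and
sub-2-point streamlines are discarded. Seeds are drawn uniformly in a
ball (inverse-CDF radius sampling), deterministically per seed value.

## The phantom cohort

The generator emulates the *statistical structure* of a VTA-
connectivity cohort, not brain anatomy:

- **Geometry.** Each streamline is a cubic spline through a basal start
  (~(±7, −16, −22)), a point inside the VTA sphere (uniform in a 1 mm
  ball around the centre), a trunk waypoint (~(±14, 8, 14)), and a
  parcel-specific approach/terminal pair; sampled at ~1 mm with control
  points kept as exact vertices. All prefrontal classes share the
  basal–sphere–waypoint trunk and fan out distally — creating the
  bottleneck through which every sub-bundle passes.
- **Parcels.** Eight thin slabs per hemisphere (1 voxel thick): six
  tiles on the coronal y = 58 plane, two orbitofrontal tiles on the
  axial z = 1 plane; all label voxels have y > 18 and strictly
  one-signed x. The thinness forces the distal-20 mm terminal test to
  matter. A temporal block (y < 0, z < −8) hosts the distractors.
- **Composition.** Default 2000 streamlines/subject, split evenly
  between hemispheres; 80% prefrontal with within-class proportions
  38/35/24% for the three dominant parcels and 0.6% for each of the
  five minor ones; 20% distractors, of which 85% project temporally
  (they visit the sphere but never reach frontal territory) and 15%
  are anterior-commissure-like arcs built to fail *only* hemisphere
  exclusivity. Class counts are multinomial draws; per-subject seeds
  derive from one cohort seed, so identical seeds give bit-identical
  cohorts.
- **Jitter.** Gaussian with per-point marginal SD 0.3 mm but
  *correlated* along the streamline (smoothed white noise, correlation
  length 3 points). Pure i.i.d. vertex noise at 1 mm spacing would make
  segment directions jagged by tens of degrees, destroying the
  orientation coherence that any tensor model or tracker needs;
  correlation preserves the marginal displacement statistics (the
  chi-3 oracle in the tests) while keeping tangents physical.
- **Tensor fields.** Per voxel, segment directions accumulate into a
  length-weighted orientation tensor S (unit trace); D = radial·I +
  (axial − radial)·w·S with axial = 935, radial = 520 μm²/s (FA 0.349
  when coherent and saturated) and w = min(1, mass/saturation).
  Two saturations serve two purposes: **scalar maps** saturate at
  20 mm/voxel — a voxel a few streamlines deep already represents
  fully myelinated tissue, so tract-averaged FA/ADC land on the scale
  of normative tables — whereas the **tracking field** saturates at
  350 mm/voxel (~115 passages of a 3 mm voxel at the default cohort
  scale), keeping the distal fan partial-volumed. The phantom contains
  no crossing bundles, so this partial-volume decay is its stand-in
  for the crossing/kissing regime in which local deterministic
  tracking fails distally while the trunk remains trackable. The
  ground-truth trunk used in that comparison is every sphere-visiting
  streamline cut at its divergence vertex (the waypoint; the temporal
  branch's mid control), rendered and thresholded like any density
  map.
- **DWI.** Single-tensor signal S = S₀·exp(−b·gᵀDg) on a deterministic
  Fibonacci-hemisphere scheme (default 2 × b0 + 30 directions at
  b = 1000 and 2000 s/mm²), with Rician noise (magnitude MR
  convention) at a configurable SNR.

### What passing on the phantom does and does not show

The phantom validates the *pipeline*: predicate logic, exact
arc-length bookkeeping, mass conservation, label lookup, estimator
algebra, proportion recovery, and the qualitative trunk-vs-fan
behaviour of local tracking. It does not contain cortical folding,
crossing fibre systems, susceptibility distortions, or inter-subject
anatomical variability, so passing says nothing about registration
quality or about tractography biases on real data — those enter the
real pipeline through the input tractogram, which this package treats
as given.

## Problem sizes

Tests and the acceptance script use desk-scale conditions chosen to
keep sampling error well inside the asserted tolerances: 5 subjects ×
2000 streamlines for proportion recovery (multinomial SE of the mean
≈ 0.5 pp against a ±2 pp band), 1000 streamlines for the selection
oracle, 20 random tractograms for conservation, 4³ voxel grids for
tensor round trips, 300 seeds for the tracker comparison.

## Known limitations

- The phantom's parcels are axis-aligned slabs; real parcellations
  curve, so real multi-membership rates will be higher.
- The relative-map "share at the trunk" equals sub-bundle proportions
  by construction only where all streamlines overlap; in real data the
  trunk is defined anatomically, not by passage counts.
- The FACT comparison is qualitative by design; its Dice level depends
  on the phantom's partial-volume model, and only the *contrast*
  (trunk recovered, distal territories missed) is the validated claim.
- Compartment-fraction maps are smoothed indicator fields, not outputs
  of a biophysical model; they exercise the reporting path only.
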