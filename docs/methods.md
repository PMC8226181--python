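# Methods

## Scope and model

The package measures the static deformation of implanted DBS leads visible
on an immediate post-implantation CT. A lead is treated as a space curve
from its proximal point (entry through the inner table of the skull) to its
distal tip. The measurement chain is: threshold segmentation → component
selection → slab-centroid centerline → third-order polynomial model →
100-point deformation profile → tissue-layer regional means → scalar
indices → mixed-model cohort statistics. Coregistration of pre/post
imaging is out of scope: frontier distances, planned points and hemisphere
volumes are accepted as inputs (identity transform in all synthetic cases),
and contact points are metadata, not extrapolated from the CT artifact.

## Coordinate conventions

Scanner coordinates are continuous millimetres, assumed LPS (+x left, +y
posterior, +z superior); voxel indices are 0-based with voxel centers at
integer indices, and the NIfTI affine is taken at face value as the
voxel→mm map. The electrode frame puts the proximal point at the origin
with +x toward the midline, +y posterior, +z inferior. Because "toward the
midline" mirrors between hemispheres, the frame is right-handed for the
left hemisphere and left-handed for the right; per-axis deviations and
curvature are unaffected, while torsion flips sign under the mirror — the
relevant sign convention is recorded on every regional summary by
`orient_signs`.

## Segmentation and centerline

Segmentation is a plain intensity threshold (default 2000 on the synthetic
scale, where the lead is 3000 against tissue 40 and bone 1200; real-HU data
would use a metal-artifact threshold, untested here). Manual artifact
editing is replaced by an explicit rule: a connected component qualifies as
a lead when it has ≥ 30 voxels and principal-axis extent ≥ 5 × its mean
transverse extent. Skull shells extend in all directions and fail the
ratio; artifact blobs fail the size floor.

The centerline is computed slab-wise: component voxels (plus a one-voxel
dilation ring, so partial-volume edge voxels contribute with small
weights) are projected on the component's weighted principal axis and
binned into slabs one max-voxel-dimension wide; each slab's
intensity-weighted centroid is one centerline point. This guarantees an
ordered, branch-free polyline with sub-voxel transverse accuracy for
near-linear objects — the regime of DBS leads — and is deliberately *not*
topological thinning, which can branch and is voxel-quantized. Components
spanning fewer than 10 slabs are rejected as degenerate. Proximal-first
ordering is resolved by proximity (≤ 3 mm) to the stated proximal point,
not by any axis, so oblique trajectories are handled.

## Trajectory model and deformation parameters

Each axis is regressed on t = normalized cumulative chord-length of the
centerline points with a cubic, by least squares. The parametrization
choice matters: a cubic in its *own* parameter is a cubic in chord-length
only when speed is constant, so "exact recovery" of generating coefficients
holds exactly for skeletons whose arc column is proportional to the
generating parameter (which uniform slab spacing approximates) and to
within micrometres for realistic near-straight leads. Diagnostics:
R² = 1 − SSR/SST pooled over the three axes (one value per lead), and
rms_residual = √(SSR/3n), the pooled per-coordinate RMS in mm — with
isotropic noise of sd σ this estimates σ, which is the convention used
throughout.

The fitted curve is resampled at 100 points uniform in arc length
(cumulative trapezoid of |r′| on a dense grid, inverted by interpolation).
The deviation at arc fraction f is curve(t(f)) minus the point at fraction
f along the chord joining curve(0) and curve(1); the first and last samples
are zero by construction. Note that deviations *along* the chord direction
are largely absorbed by this correspondence (a tangential reparametrization
is not an observable bending), so z-amplitude perturbations of the
generator appear only at second order in the profile — transverse (x, y)
deviations are the informative ones, matching how bending is read off
images.

Curvature κ = |r′×r″|/|r′|³ and torsion τ = (r′×r″)·r‴/|r′×r″|² are
evaluated analytically from the cubic (r‴ constant). Where κ < 10⁻⁶ mm⁻¹
the binormal is numerically meaningless: the sample is flagged
`torsion_defined = False` and τ reported as 0; regional torsion means use
only flagged-defined samples. This makes explicit a rule that plotted
torsion spikes in near-straight segments otherwise hide.

## Tissue layers and indices

Three brain layers (superficial gyration, white-matter stem, deep brain)
plus the subdural gap are delimited by frontier distances measured from the
proximal point. Samples are labelled by Euclidean distance from the
proximal point (the frontiers were measured that way); an arc-length
alternative is available by flag and differs by < 0.1 mm at observed
curvatures. Intervals are half-open, lower-inclusive, so each sample has
exactly one label; the subdural segment is labelled but excluded from
regional statistics. Whole-lead means equal the count-weighted means over
all segments (a conservation property asserted in the tests).

Scalar indices: lead length is the proximal-distal Euclidean chord (not
arc). Rigid percentage = 100 × rigid length / chord with rigid length 7.5
mm (non-directional) or 21.5 mm (directional). Extracerebral percentage =
100 × cortex-entry distance / chord. The brain shift index is the frontal
air bubble's height × width × thickness over the hemisphere volume, scaled
to units of 10⁻⁴ %; the full box product is kept (a deliberate
overestimate), with an ellipsoid π/6 variant by flag. Note that a cohort
mean of this index cannot be reconstructed from mean bubble dimensions
(mean of products ≠ product of means), so only the formula, not cohort
index means, is checked. Surgical inaccuracy is the planned-vs-achieved
Euclidean distance rounded half-up to 0.1 mm, the planning-software grid.

## Cohort statistics

Each regional parameter is modelled as fixed effects type × hemisphere ×
layer with a patient random intercept, fitted by REML (statsmodels
MixedLM; fallback optimizers guard against fragile likelihood surfaces).
If model residuals fail Shapiro–Wilk at 0.05 the response is
log-transformed with an offset making it positive and refitted; estimates
are then on the log scale and flagged. Contrasts are differences of cell
means averaged over electrode type: the three layer pairs within each
hemisphere form one Sidak family each, and the right-vs-left differences
across the three layers form a third family (family sizes are declared in
the output metadata, since plausible alternatives exist). ICC =
σ²_between/(σ²_between + σ²_residual), classed low < 0.6, moderate
0.6–0.8, high > 0.8. The two-sample gate: Shapiro–Wilk per sample at 0.05
decides parametric vs Mann–Whitney; the F variance-ratio test decides
pooled vs Welch within the parametric path. All tests two-sided at α =
0.05.

## Synthetic data: what it emulates, what it does not

Ground-truth trajectories are exact per-axis cubics over t ∈ [0, 1] from
the origin to (0, 0, chord): each axis carries a bump t(1−t)(1+γ(t−½)) with
seed-drawn asymmetry γ, scaled by its closed-form maximum so the requested
per-axis amplitude is exact; an optional quartic term makes the truth
deliberately non-cubic for diagnostics testing. Exact cubics make the
curve model identifiable, separating fitting error from modelling error.

Rasterization emulates the scanner geometry (0.488 × 0.488 mm pixels,
0.625 mm slices) and lead caliber (radius 0.635 mm) on an arbitrary
CT-like intensity scale: air −1000, tissue 40, bone 1200 (a shell at the
grid boundary), lead 3000, with a linear partial-volume skirt of half-width
0.25 × max voxel dimension at the lead edge. This produces a thresholdable
metal-bright lead without CT physics: no beam hardening, no metal-artifact
streaks, no noise texture, no MRI. Passing the recovery suite therefore
shows the geometric chain is correct at scanner resolution, not that
segmentation thresholds transfer to clinical Hounsfield data.

Cohorts follow the study conditions: 30 patients bilateral (left always
first), electrode types allocated half/half (non-directional block first),
subthalamic target probability 0.7, chord 67.7 ± 3.6 mm (clipped 58–77),
per-(type, hemisphere) deformation means/sds from the reported cohort
table used as layer-invariant baselines (per-layer offsets are injectable),
patient random-intercept sd defaulting to half the residual sd (so ICC
defaults land near 0.2 and the sd ratio is the dial that reaches all three
ICC classes), frontier distances ~4.1 / 25.3 / 40.6 mm, hemisphere volumes
~480/474 cm³, bubble dimensions half-normal with left-hemisphere excess
matching the reported means, and surgical inaccuracy ~1.0/1.3 ± 0.5 mm by
hemisphere. Truth curvature draws are clipped at 10⁻⁵ mm⁻¹ since one
reported sd exceeds its mean and curvature is nonnegative. A single global
seed expands into per-patient and per-case streams via
`numpy.random.SeedSequence` spawning; identical seeds give bit-identical
tables and volumes.

## Numerical choices and problem sizes

Arc-length inversion uses a 4001-point dense grid (error far below the
0.001 mm scale of interest). Profile size is fixed at 100 samples.
Acceptance-style validation uses 20 seeded volumes for geometry recovery,
100 seeds for fit-noise calibration, and 200 null cohorts of 30 patients
for type-I-error calibration — sizes at which every Monte-Carlo band in
the tests is stable across seeds while the whole suite runs in about a
minute on one core.

## Known limitations

- No real-CT validation: thresholds and the elongation rule replace the
  original manual editing and are untested on clinical data.
- Contact-level localization within the metal artifact is out of scope;
  surgical inaccuracy takes both points as inputs.
- The mixed-model p-values use the large-sample normal reference
  (statsmodels MixedLM); at 30 patients the measured null type-I error is
  ~0.05, but very small cohorts would need degree-of-freedom corrections.
- Torsion of near-straight leads is intrinsically ill-posed; the κ
  threshold rule reports it as undefined rather than amplifying noise.
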