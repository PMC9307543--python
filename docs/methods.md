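# Methods

This note documents the models, conventions and numerical choices behind
cranionav, in the order the simulated protocol uses them.

## Coordinate frames and rigid transforms

All geometry lives in right-handed frames with millimetre units.  A rigid
transform is a rotation–translation pair `x -> R x + t` with
`det(R) = +1`, serialized as a 4×4 homogeneous row-major matrix.  The CT
frame is defined by the mesh coordinates; FCSV point files declaring RAS
are converted to the internal LPS convention on read (x, y negated).
Rotations are re-orthonormalized through an SVD on construction so that
long composition chains stay orthonormal at machine precision.

The `FrameGraph` stores calibrated transforms between named tracker
frames (EMTS, QR sensor, QR marker, HMD, patient sensor, CT, OTS) as
directed edges and resolves any connected pair by breadth-first search,
inverting edges traversed backwards.  When more than one simple path
connects the endpoints, all paths (up to a cap of 64) are evaluated on a
unit probe — the origin plus the three basis points — and a disagreement
above 1e-6 mm raises an error instead of silently picking a path: two
calibrations that contradict each other are a fault worth surfacing, not
averaging.

## Paired-point registration

Every alignment is paired-point: correspondences are fixed by label
(anatomical landmark names, fiducial ids, divot indices), never by
closest-point matching.  The least-squares rigid fit is the closed-form
orthogonal Procrustes solution: SVD of the cross-covariance of the
demeaned point sets with the determinant-sign correction, so a proper
rotation is always returned even when a reflection would fit noisy
near-planar data better.  Configurations are rejected as degenerate when
fewer than 3 pairs exist or the second singular value of the scatter is
below 1e-9 of the first (collinear points leave a rotation about the line
unconstrained).

FRE is the RMS of the post-alignment residuals at the registration
points; TRE is the RMS distance at held-out targets.  The Monte-Carlo
propagator perturbs the measured side with isotropic per-axis Gaussian
noise of sd σ — the simplest defensible model of tracked-pointer
digitization error — and registers repeatedly.  Its mean FRE² can be
checked against the first-order approximation `E[FRE²] ≈ (1 − 2/N)·3σ²`,
which the test suite and acceptance script do at N = 24 and σ = 0.1 mm
with 10⁴ repetitions.

## Closest points, projection, resampling

Closest-point queries on a triangulated surface are exact: the distance
to the nearest mesh vertex (scipy cKDTree) is an achievable upper bound,
so only triangles whose centroid lies within that bound plus the largest
triangle circumradius can contain a closer point; the exact
point–triangle distance (region classification, via trimesh's pure-numpy
kernel) is evaluated on those candidates.  Equidistant triangles (a query
point over a shared edge or vertex) are resolved to the lowest triangle
index within a 1e-12 mm tie tolerance, making the query deterministic.

Curve projection snaps each polyline vertex to its closest surface point
independently — the model of digitizing a drawn curve with a pointer.  No
continuity is enforced: a curve passing over a deep concavity can project
discontinuously.  This is irrelevant on the convex vault but is a known
limitation for pathological geometry.

Arc-length resampling interpolates linearly between polyline vertices
(no spline), always retains both endpoints, and allows the final spacing
to be shorter than the step.  The planning default step is 0.25 mm.
Resampling is length-non-increasing (chords never exceed arcs); on smooth
curves the loss is below one step, but across sharp corners of a jagged
polyline losses can accumulate beyond one step — the tests assert the
bounds that actually hold (monotone convergence as the step halves,
endpoint-chord lower bound).

## The delineation distance d = S_A / D_L

Scoring a drawn suture against the planned one proceeds as:

1. **Project** both curves onto the skull surface, **resample** at the
   step (0.25 mm default), and **re-project** the samples.  The final
   snap exists because resampling interpolates on chords that sit a
   sagitta below the faceted surface; without it the two curves would be
   compared at systematically different heights and the metric's floor
   would be the chord sagitta (~2·10⁻³ mm at the default tessellation)
   instead of ~10⁻⁷ mm.  On planar patches the snap is a no-op, so the
   analytic test cases are unaffected.
2. **Clip to overlap**: the reference is clipped to [t₀, t₁], the ordered
   arc-length parameters of the closest reference points to the drawn
   curve's endpoints; the drawn curve is clipped symmetrically against
   the reference's endpoints.  `D_L = t₁ − t₀` is measured along the
   clipped *reference* — the planning ground truth.  An overlap shorter
   than one resample step raises a no-overlap error (e.g. a curve drawn
   entirely beyond the reference's end).
3. **Spanned area**: both clipped curves are resampled to the same count
   `N = ⌈max(L₁, L₂)/step⌉ + 1` at uniform normalized arc length;
   points correspond by index; each quad between consecutive pairs is
   split into two triangles along its shorter diagonal and the 3-D
   triangle areas are summed.  `S_A` is therefore the area of a ruled
   strip in space, not a geodesic area on the mesh — well defined,
   convergent, and exact in the planar case; at millimetre separations on
   a decimetre-scale vault the difference from a geodesic strip is second
   order.  Correspondence by normalized arc length (rather than
   closest-point re-matching) avoids degenerate many-to-one pairings on
   curved strips.

For parallel fully-overlapping segments at separation h the metric
returns d = h exactly (to floating-point precision).  The half-overlap
configuration (reference spanning [0, 100] mm, drawn parallel at 3 mm
spanning [50, 150] mm) yields D_L = 50 mm, S_A = 150 mm², d = 3 mm under
the clipping rule above.  d is reported per suture pair; study summaries
average d across records (not point distances across curves).

## The synthetic phantom

No anatomical mesh ships with the package.  The skull vault is the upper
half (z ≥ 0) of a triangulated ellipsoid, default semi-axes 70 × 55 ×
50 mm — a child-skull scale — built from a subdivided icosahedron
(subdivision level 4 ≈ 2.6k triangles after halving).  This captures what
the accuracy chain actually exercises: a convex surface and a distinct
anterior–posterior axis.  It does not capture suture wiggle, fontanelles,
surface texture, or skin/foam thickness, so absolute delineation numbers
from the simulator characterize the *protocol geometry and noise model*,
not any specific anatomy; real skull meshes can be supplied via STL/PLY
instead.

Carried features, all snapped to the faceted surface (hence on it to
~10⁻¹⁵ mm):

* **Sutures** — plane sections of the ellipsoid: sagittal on the midline,
  coronal and lambdoid at fractions +0.35 and −0.55 of the AP semi-axis,
  and three virtual sutures at evenly spaced fractions in between;
  sampled at the 0.25 mm planning spacing.
* **Six anatomical landmarks** — a fixed nose/eye-region cluster on the
  anterior face (nasion, glabella, orbital and canthal points).  The
  anterior-only cluster is deliberate: it reproduces the registration
  geometry whose TRE grows toward the posterior vault.
* **Fiducials** — configurable count (10 for the SK1-like layout, 8 for
  SK2-like), spread over the vault by seeded stratified sampling in
  azimuth with jittered elevation, kept off the cut rim.

Every generator output is a pure function of (spec, seed).

## Noise models

* **Digitization** (tracker + pointer): isotropic zero-mean Gaussian per
  axis.  Defaults: σ_EMTS = 0.35 mm for the experiment registration —
  chosen so the 6-landmark FRE ≈ σ√(3·(1−2/6)) ≈ 0.5 mm, the scale a
  clinical EM tracker achieves — and σ_OTS = 0.4 mm for the evaluation
  side (8–10 markers, FRE ≈ 0.6–0.7 mm; the optical tracker itself is
  more precise, but marker-center localization in CT contributes).
* **Delineation** (human tracing): a displacement field in the local
  tangent plane — independent along-curve and cross-curve components —
  built by convolving white noise along arc length with a Gaussian kernel
  of scale equal to the correlation length, rescaled per sample (by the
  root of the squared kernel weights) so the marginal sd equals
  `delineation_sigma` exactly despite edge truncation.  Pen strokes are
  smooth, so the correlation is essential: independent per-point jitter
  at 0.25 mm spacing would make the ruled strip pathological.  Defaults:
  sd 1.5 mm, correlation length 20 mm — the residual magnitude a ~2.4 mm
  aggregate error implies once a ~1.9 mm registration TRE is accounted
  for.  An optional constant cross-curve `systematic_offset` models a
  biased overlay.  Displaced points are re-projected onto the surface.

These magnitudes are free inputs, not fitted constants: no ground-truth
measurement of human tracing error is available, so passing tests
demonstrate correct propagation of the assumed noise, not the noise
itself.

## The simulated protocol

Per phantom, a ground-truth pose places the phantom in tracker space
(seeded random rotation, translation within ±200 mm).  Per participant:

1. Experiment registration: the six landmarks are digitized (EMTS noise)
   and the CT model registered to them; FRE recorded, TRE evaluated at
   the held-out fiducials.
2. The planned sutures are displayed *through the imperfect alignment* —
   the participant traces what the misaligned overlay shows.  This is the
   causal chain that turns registration error into delineation error.
3. Tracing is simulated on the physical surface with the delineation
   noise model.
4. Evaluation registration: fiducials digitized with OTS noise,
   registered back to CT; FRE recorded.
5. The drawn curves are digitized point-wise (OTS noise) and mapped into
   CT space through the evaluation alignment.
6. Each curve is scored with d = S_A/D_L against its planned suture.
   A no-overlap failure is recorded as a missing record with a warning,
   never a crash, and excluded from summaries.

Sub-seeds derive from `SeedSequence([master, phantom, participant,
stage])`, so any record is reproducible independently of execution order,
and a fixed config + seed reproduces the records CSV byte for byte.  The
experiment registration is performed once per participant (configurable
by re-running with one participant), since a per-participant spread is
what a registration table with sd columns implies.

Summaries report mean and sample sd (n − 1) of d per phantom × suture
class, pooling the three virtual sutures, plus an "all" row; a
single-record group reports sd = 0 with `sd_defined = False`.

## Problem sizes and runtimes

The default study (12 participants × 2 phantoms × 5 sutures = 120
records, ~2.6k-triangle meshes, 0.25 mm step) runs in ~10 s on one CPU.
The error-gradient property (posterior lambdoid worse than anterior
coronal) is asserted over 200 simulated participants on one phantom, and
the noise-monotonicity sweep over σ_EMTS ∈ {0, 0.5, 1.0} mm uses 60
participants per level with a common master seed — sizes at which the
~1 mm effect dwarfs the standard error of the group means.  Monte-Carlo
calibration checks use 10⁴ repetitions (registration noise propagation,
perturbation chi-square) and 200 repetitions (delineation-field
calibration).

## Known limitations

* The vault is an ellipsoid: no suture interdigitation, no fontanelles,
  no posterior flattening; absolute d values are not predictions for any
  real skull.
* S_A is a ruled-strip area, not geodesic; the difference is unquantified
  but second-order at millimetre separations on a convex vault.
* Curve projection is pointwise and can be discontinuous across deep
  concavities (not present on the synthetic vault).
* The delineation noise field is stationary along the curve; real tracing
  error likely grows near curve ends and in low-visibility regions.
* No tracker-field distortion, latency, or occlusion modeling: the two
  tracking modalities differ only in their digitization sd.
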