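# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `hpvmleaf`, in the order the pipeline runs.

## Skeleton representation and fitting

A leaf skeleton is a set of level-coded curves: `MARGIN` (0), `RIDGE` (1,
wrinkle crest lines), `PRIMARY` (2), `SECONDARY` (3), `TERTIARY` (4). The
hierarchy is ordered by importance during resampling: lower levels fix
their sampling points first and higher levels yield to them. Attachment
rules are a fixed table — primaries attach to the margin, secondaries to a
primary (or another secondary), tertiaries to a secondary; margin parts and
ridge crests are free curves. The margin is supplied split at sharp points
into parts that chain head-to-tail into one closed loop; the number of
parts is data-dependent and not enforced.

All curves are clamped cubic B-splines (degree 3 by default; the degree is
a free choice, cubic being the field's standard for feature curves).
Fitting is least-squares with chord-length parameterization — appropriate
for unevenly spaced, interactively picked feature points — with the first
and last input points interpolated exactly by pinning the end control
points, and an optional second-difference penalty on interior control
points (`smooth`, default 0). The control-point count defaults to half the
input point count (clamped to [degree+1, 60]). Coincident consecutive input
points are collapsed with a warning.

Arc length uses composite Gauss–Legendre quadrature (8-point rule on 512
uniform parameter segments, relative error far below 1e-6 for the smooth
curves that occur here); inversion (parameter at a given arc length)
interpolates the cumulative table and polishes with Newton steps.
Equal-arc-length division uses spacing `L / round(L / l)` so both curve
ends are always included.

Parent resolution projects each non-free curve's start point onto every
admissible lower-level curve (dense seeding plus bounded scalar
minimization) and takes the nearest within `tol`; `tol` defaults to 1 % of
the skeleton's bounding-box diagonal. Validation reports margin-closure
gaps, attachment residuals and level-rule violations rather than raising.

## Auxiliary membrane

The membrane is a tensor-product NURBS surface (bicubic, 15x15 control net,
all weights 1 unless configured; with equal weights it reduces to the
polynomial B-spline surface, which the tests exploit as an oracle).

Constraint points are sampled from every skeleton curve at roughly 2 mm
spacing (16–200 per curve). Their surface parameters come from an affine
bounding-box normalisation of their coordinates in the skeleton's principal
(PCA) plane, with a 2 % pad; the surface's own parameter rectangle is the
uv domain used downstream, and the margin maps near the rectangle boundary
because the planform fills its bounding box. No separate flattening
algorithm is used; for the gently curved blades this package targets, the
principal-plane projection is injective. This choice replaces pinning the
boundary control rows to the margin: it is simpler, better conditioned for
lobed (non-convex) planforms, and nothing downstream requires the margin to
lie exactly on the rectangle edge, because meshing is restricted to the
margin polygon anyway.

The control net solves a weighted least-squares system: margin constraint
points carry weight 10 (the margin is the surface boundary in all but
name), vein and ridge points carry `vein_weight` (default 2; raising it
tightens vein interpolation monotonically in the aggregate). A
second-difference (thin-plate-like) penalty on the control net with
coefficient `smoothing x trace(A'WA)/(mn)` regularises the rectangle
corners outside the leaf and the constraint-free pockets between veins.
`smoothing` defaults to 1e-2: weaker values let the net oscillate by
several millimetres in the constraint-free pockets between veins (the
constraints only cover curves, not the interior), which would put parts of
the membrane beyond the calibration snap radius at fine element sizes;
1e-2 keeps the interior deviation of the synthetic leaf below ~1.7 mm at
constraint residuals of ~0.35 % of the midvein length — comfortably inside
the 1 % recovery target. The surface is auxiliary: metric accuracy is
recovered later by snapping interior points to the scanned cloud, so
smoothness is worth more than interpolation tightness.

Point inversion (xyz -> uv) is damped Gauss–Newton with finite-difference
Jacobians, seeded from a cached 41x41 surface grid (or warm-started along a
curve), clamped to the domain; non-convergence is flagged, never raised. A
batched variant iterates whole arrays at once.

Distances in the parameter plane are made metrically meaningful by scaling
u and w with the mean magnitudes of dS/du and dS/dw over the domain
("metric-scaled uv"); the element size l then has consistent millimetre
meaning both along curves (3D arc length) and in the plane (relaxation,
advancing front, triangulation).

## Resampling

The rules and their parameters:

- **Ignore factor** `alpha` (default 1): curves shorter than `alpha*l` are
  skipped at scale l. This is what makes the series multi-scale: tertiary
  veins and ridges drop out at coarse sizes.
- **Relaxing factors** `beta1 < beta2` (defaults 0.5, 0.8): processing
  curves in (level, id) order, each test point is compared with all
  already-fixed points in metric uv. Below `beta1*l` it is deleted; between
  `beta1*l` and `beta2*l` it is re-inserted on its own curve at arc
  distance `(beta1+beta2)/2*l` from the projection of the blocking fixed
  point, toward the test point (and re-checked against the `beta1*l`
  clearance); above `beta2*l` it is kept. The numeric defaults are this
  package's choice; the thresholds themselves are the method's rules.
- **Junction anchors**: curve start/end points are never deleted, and the
  arc position where a sampled child attaches is folded into its parent's
  sample set (moving the nearest equal-arc sample onto the junction when it
  is within 0.35 of the spacing, otherwise inserting it). This keeps the
  discrete skeleton connected at branchings and avoids sliver triangles at
  junction vertices; the corresponding vertices are welded in the PSLG
  (tolerance 0.05*l).
- **Advancing front**: fronts start at the margin loop (marching inward)
  and on both sides of every vein/ridge polyline. Shortest front first
  (ties by insertion order); the candidate sits on the perpendicular
  bisector at height `h_factor*l` with `h_factor = sqrt(3)/2`, the
  equilateral height (a height of 3l/2, sometimes quoted for this
  construction, contradicts the equilateral triangle it is meant to
  produce; `h_factor` is configurable for anyone who wants it). A node within `r_factor*l`
  (default 0.7, standard AFM practice below the target spacing) replaces
  the candidate. Candidates outside the margin polygon retire their front.
  Fronts cancel against opposite-direction fronts; an edge is never
  re-created once retired, which bounds the iteration count (safety cap
  1e6). Only points are produced — triangulation is a separate step.
- **Calibration**: interior points are lifted through the surface and
  snapped to the nearest cloud point when it is within `snap_max*l`
  (default 0.5). The cap prevents pulling points across lobes of noisy
  clouds; with no cloud the lift alone is used. Nearest neighbours are
  exact (KD-tree).

## Meshing

Consecutive surviving samples of each curve become constrained edges; the
margin loop closes; interior points are free vertices. Pairs of constrained
edges are checked for proper crossings (an error naming the pair — it
indicates the input feature lines run closer than the relaxation clearance
`beta1*l` somewhere). Near-collinear contact at junction vertices is not a
crossing.

Duplicate u-coordinates are resolved by deterministic seeded perturbations
below `eps` (resampled from the original value each pass, so the total
displacement stays below `eps`).

The Delaunay core is the classical quad-edge divide-and-conquer on u-sorted
vertices — single-vertex strips pasted pairwise, O(n log n) — with
floating-point orientation/in-circle predicates that fall back to exact
rational arithmetic near zero; exact cocircular ties do not flip, which
fixes the diagonal deterministically. Constrained edges are then enforced
by removing the edges each constraint crosses and retriangulating the two
cavities with the circumcircle rule; this is the standard robust CDT route
and leaves every unconstrained edge locally Delaunay with respect to
visible vertices. (Handling constraints as walls inside the strip merges
would give the same result; post-insertion is simpler to make robust.)

Triangles whose centroid falls outside the margin polygon are culled after
triangulation (the bounding-rectangle framing of the strip algorithm
otherwise leaves corner triangles). Vertices lift to their known xyz
(curve samples, calibrated interior points) or through the surface; then
`iters` (default 10) Gauss–Seidel rounds of uv Laplacian smoothing move
only unconstrained interior vertices, rejecting any move that would invert
an incident uv triangle, re-lifting after each round and re-snapping moved
vertices to the cloud at the end.

## Quality metrics

Element number; percentage of pass = share of triangles with minimum
interior 3D angle >= 30 deg (the criterion is this package's choice — the
standard Delaunay-refinement quality bound — and configurable); area error
= |mesh area − reference| / reference; maximum distance error = max over
cloud points of the exact point-to-nearest-triangle distance, measured
cloud→mesh because the mesh is judged against the scan. The distance is
computed exhaustively (vectorised exact point-triangle distance in chunks),
not via spatial acceleration, so it is exact by construction.

## Synthetic leaves

The generator emulates a scanned cucumber-like palmate leaf at realistic
scale: midvein 140 mm, five lobes (lobe depth 0.35 of the local radius,
width 0.85 of length), three secondary veins per side with two tertiaries
each, wrinkle amplitude 1.5 mm, vein grooves 0.8 mm deep (Gaussian
cross-sections, so the analytic surface stays smooth and the membrane fit
well-posed), blade fold curvature 0.002/mm, cloud density 1 point/mm² and
noise 0.12 mm — the order of a handheld structured-light scanner. The
margin is an ellipse-based radius function modulated by a triangular wave,
whose kinks provide the sharp points where margin parts split; the base and
apex fall on kinks by construction, so the primary vein starts and ends at
margin part joints.

Vein starts coincide exactly with vertices of their parent polyline.
Feature lines are kept geometrically separated: tertiaries stop at the
first crossing with, or 7 mm approach to, any other vein, and ridge crests
keep 12 mm clearance from the whole vein system (shorter remnants are
dropped). Real leaves have crest lines that terminate at veins too; here
the clearance is sized so that the relaxation deletion radius `beta1*l`
cannot hollow out a curve next to a neighbour and leave a chord crossing it
at the element sizes where both curves are still sampled. Each wrinkle
bump of the height field is tied to one surviving crest line (same ray,
same radial band): wrinkles exist exactly where the skeleton can express
them, which is what the crest-line representation assumes of real leaves. Cloud noise is
3-sigma-truncated Gaussian, so every cloud point is provably within
3*noise_sd of the analytic surface. The true area comes from dense
triangulated quadrature over the planform polygon (exact for planar
leaves). Everything is deterministic given the seed; the seed also jitters
the vein layout so different seeds give genuinely different leaves.

What the generator does not emulate: scanning holes and occlusions,
registration ghosting, serrated (toothed) margins, anisotropic noise, or
petiole geometry. Passing tests therefore demonstrate the pipeline's
correctness on clean, well-separated feature inputs, not robustness to
defective scans — feature extraction is an input to this package, exactly
as an interactive picking tool would provide it.

## Problem sizes and tolerances in the tests

The test and acceptance runs use the defaults above: one leaf per seed,
four element sizes (5, 10, 20, 40 mm — the multi-scale series the method
is built around), ~13k cloud points, meshes up to ~1.4k triangles; the
Delaunay oracle uses 100 sets of 30 points (the O(n^4) oracle is the
binding cost), retention 50 PSLGs of 50 points with 10 constraints, and the
scaling check times n = 1000/2000/4000 (best of three, ratio < 2.6 per
doubling). Numerical tolerances in tests mirror the guarantees stated
here: 1e-9 for algebraic identities, 1e-6 mm for inversion round trips,
0.1 % spacing uniformity, 1 % of midvein length for skeleton recovery, 2 %
for area recovery.

## Known limitations

- The principal-plane parameterization assumes the blade is a height field
  over its PCA plane; strongly curled or folded leaves violate this.
- Margin parts shorter than `alpha*l` would break the loop at that scale;
  the generator keeps parts longer than the coarsest tested size, real
  inputs must do the same (or lower `alpha`).
- The advancing front's never-recreate-an-edge rule can retire a region
  early, leaving packing density below the ideal (the CDT closes such
  regions with larger triangles); density stays within the documented
  packing band.
- Constrained-edge crossings caused by feature lines closer than `beta1*l`
  are reported as errors, not repaired.
- Percentage of pass degrades at coarse sizes by design: feature
  preservation takes precedence over element quality.
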