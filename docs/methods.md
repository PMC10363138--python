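# Methods

This note documents the models, parameters, numerical choices and known
limitations of `toothprep`, in the spirit of a package vignette.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting and assumptions

The input is a *registered* pair of triangle meshes in millimetres: the
anatomical (pre-preparation) tooth and the prepared abutment, as exported
by an intraoral scanner.  Key assumptions:

* Below the preparation margin the two scans show the same physical
  surface, so they agree to within scan noise; above it they diverge by the
  removed tooth structure.  Margin detection exploits exactly this.
* The path of insertion **p** and the mesial direction are supplied by the
  user (or a config file), not estimated.  Buccal is 90° counter-clockwise
  from mesial about p (right-handed); chirality can be flipped by supplying
  a different mesial direction.
* Meshes are edge-manifold after cleaning (duplicate vertices within
  1e-6 mm merged, zero-area faces dropped).  STL carries no units; mm is
  assumed throughout.

## Margin detection

**Vertex sharpness** is the magnitude of the cotangent Laplacian of the
vertex coordinates — the discrete mean-curvature normal, ≈ 2H at smooth
vertices, large on creases.  The vertex cell area Ω_i is barycentric (one
third of incident triangle areas) by default because it is robust on the
obtuse slivers common in scan meshes; mixed Voronoi areas are available via
`cotangent_laplacian(..., cell="mixed")`.  Cotangents are clamped to
±100 to survive near-degenerate triangles.  The sharpness scalar is the
unsigned magnitude: a finish line is detected equally whether the crease is
convex or concave.

**Edge sharpness** rescales each interior edge by
(n₁·n₂ + 1)/2 ∈ [0, 1]: coplanar faces keep their length, a right-angle
crease halves it, a fold-back zeroes it.  Boundary edges are unchanged.
Dijkstra paths under these adjusted lengths prefer running *along* feature
lines, which is what closes the margin loop between anchors.  Zero-length
edges are floored at 1e-12 mm so the graph stays connected.

**Search procedure.**  Seeds: `seed_count` (default 12) vertices at equal
azimuth increments at 25% of the bounding-box height — "in the root area",
safely below any clinically plausible margin.  Each seed walks crown-ward
(to the 1-ring neighbour with the greatest projection on p) while the
closest-point distance to the prepared mesh stays below the error bound ε;
the walk hands over the last vertex still inside the ε-tube.  That
candidate is snapped to the nearest prepared-mesh vertex; the sharpest
vertex within a metric ball of radius 1.5 ε replaces it, followed by a
1-ring hill-climb (≤ 20 hops, ties to the lowest index).  The metric ball —
rather than a fixed number of topological rings — makes crease capture
independent of tessellation density and rigidly invariant.

**Choosing ε.**  ε separates "same surface" from "diverged": it must
exceed a few standard deviations of scan noise (≈ 25 µm scanners → the
0.15 mm default) yet stay below the geometric deviation that builds up
*inside* the finish-line band, or the walk overshoots the margin and the
refinement ball can reach the wrong crease.  For a chamfer of width c this
means ε ≲ c/√2; the phantom-matched configuration uses
ε = min(0.15, 0.4 c).  With very narrow finish lines, a correspondingly
fine mesh is required (the phantoms use row spacing ≤ c/3).

**Margin width** projects the margin loop and the lower axial boundary
onto the plane ⟂ p and reports (outer area − inner area) / mean perimeter
(shoelace via polygon area).  For concentric circles this is exactly
r₂ − r₁.  Self-intersecting projections are rejected; numerically tiny
self-touches are repaired by a zero-width buffer.

## Regions

* **Lower axial boundary**: the margin polyline translated by
  `band_offset` along p, mapped back to the surface by closest point,
  snapped to vertices and joined by geodesic Dijkstra.  The literal
  "translating surface" (the margin swept along p) only touches the
  prepared model at the margin itself, so closest-point projection of the
  translated curve is the mesh-realizable reading; it reproduces the
  obvious special cases (offset 0 → the margin; a cylinder → a ring at
  margin height + offset).  `band_offset` should span the finish-line
  band; the default 0.8 mm is twice the default 0.4 mm chamfer.
* **Upper axial boundary**: each lower vertex moves fraction t (default
  0.5 — "internally divided" with no stated ratio, so the midpoint) of the
  way to the occlusal plane (⟂ p at the highest prepared vertex) and is
  mapped back to the surface.  Sides with higher occlusal anatomy get
  taller axial bands.
* **Quadrants**: faces are assigned whole (no splitting) by centroid
  azimuth in 90° sectors centred on mesial/buccal/distal/lingual; the
  azimuth origin is the margin-loop centroid, which sits on the insertion
  axis even when asymmetric tapers shift the band's area centroid.
* **Occlusal area**: the feet of the seven standard landmarks, joined in
  cyclic azimuthal order by geodesic (not sharpness-adjusted) paths — the
  occlusal boundary is not a sharp feature.  Face sets are extracted by
  flood fill over face adjacency with all boundary loops acting as cuts,
  and components are classified by which boundaries they touch.

## Measurements and grading

Taper uses exact per-face arithmetic: T = 90° − (Σ a_f·θ_f)/(Σ a_f) with
θ_f the angle between p and the face normal; TOC sums opposing walls.  Cusp
reduction is a single closest-point query per landmark through the BVH
(median-split on the longest axis, leaf size 4, priority-queue traversal
with box lower-bound pruning — verified exact against a brute-force
all-triangle scan).  Marginal-ridge and fifth-cusp reductions are measured
identically but appear only in the provenance log: the rubric has no ridge
criterion.  An experimental minimum-reduction search over the whole
occlusal area (`EvalConfig.experimental_min_reduction`) reports the
smallest anatomical-to-prepared distance over the occlusal region; it is
logged, never graded.

Grading bins are closed intervals checked best-grade-first, so a value
exactly on an acceptable/marginal boundary takes the better grade and a
value exactly on a marginal/unacceptable boundary stays marginal.  This
convention is forced by the packaged measurement table: grading its printed
values must reproduce the packaged per-criterion score means, which only
this boundary rule does.  Grading operates on full-precision measurements;
table-style reporting rounds half-up to 2 decimals.  The BL-plane score
mean computed from the packaged table is 48/35 ≈ 1.37; the originally
reported value for that one criterion (1.29) cannot be reconciled with the
printed per-specimen values under any single boundary convention, so it is
documented here rather than asserted anywhere.  Colors: A green (0,170,0),
B yellow (255,200,0), C red (220,30,30); ungraded regions grey.  The six
criterion points sum to an unweighted 0–12 total; clinical weighting of
criteria into a single grade is out of scope.

## Registration

`register_icp` is deterministic point-to-surface ICP: all source vertices,
closest-point feet through the BVH, least-squares rigid fit by SVD
(proper rotation enforced), stopping when the RMS improves by < 1e-6 mm or
at 100 iterations.  A final RMS above 0.5 mm emits a warning rather than
failing silently.  The pipeline assumes pre-registered pairs by default
(scanner software exports them aligned); with `register=True` it runs a
robust variant that trims the worst 50% of correspondences each iteration,
so the unchanged cervical/root region drives the fit while the prepared-
away crown region is ignored.  Note that registration can only be as good
as the shared geometry is pose-identifying: on a perfectly rotationally
symmetric root (as in the synthetic phantoms) the azimuthal degree of
freedom is unconstrained, which is a phantom artifact, not a property of
real dentitions.

## Synthetic phantoms

The generator builds structured ring meshes (azimuth × graded height rows,
refined to `fine_res` near the creases) so that every target quantity is
analytic:

* margin: a sharp crease at radius R (default 4.6 mm) and height 3 mm,
  where the root cylinder meets a 45° chamfer of width c (default 0.4 mm);
* axial walls: per-quadrant taper (default 6° per wall → TOC 12°), blended
  over ±3° of azimuth at sector boundaries;
* occlusal: the prepared table is flat; the anatomical crown carries
  cone-shaped cusp and ridge bumps whose apexes sit exactly the nominal
  reduction above the table (defaults: 1.5 mm cusps, 1.0 mm ridges,
  matching a standard 1.5 mm occlusal-reduction protocol); the CLI phantom
  defaults to 1.7/1.2 mm so every criterion grades acceptable;
* noise: Gaussian displacement along vertex normals, σ = 10 µm by default
  (mimicking a scanner with ≈ 25 µm precision), seeded and reproducible.

The truth record stores nominal tapers and reductions, the margin circle,
and the expected band width for a given offset, computed by closest-point
projection onto the ideal 2D profile — independent of both the mesh and the
pipeline code.

What the phantoms do *not* emulate: real occlusal anatomy (fossae, ridges,
functional cusp bevels), scan artifacts (holes, topological noise), blood/
saliva reflectance errors, or asymmetric root shapes.  Passing the phantom
recovery tests therefore demonstrates the geometric correctness of the
algorithms at realistic noise levels, not robustness to every pathology of
clinical scans.

Known accuracy limits, measured by the test suite: per-wall taper recovery
on uniform frustums is accurate to well under 0.1°; when neighbouring walls
differ strongly (e.g. 4° next to 18°), the blended transition strips pull
the area-weighted quadrant means by up to ≈ 0.3° and TOC by ≈ 0.2° — an
effect of the constructed transition geometry, which is why per-wall
accuracy is asserted on uniform phantoms and mixed phantoms are checked at
the TOC level.  Margin-loop recovery is ≈ 0.03 mm RMS against the
constructed circle across chamfer widths 0.2–0.8 mm and radii 3–6 mm, with
occasional single-edge chord-cutting dips where a shortest path shortcuts
between anchors; the loop's vertex identity across rigidly transformed
re-runs holds only up to floating-point tie-breaking, so invariance is
asserted geometrically.

## Problem sizes and determinism

Default phantoms use 96 azimuth samples and graded rows (≈ 8k faces per
mesh), which resolves all tolerances while keeping a full pipeline run
under half a second; the family tests in the suite and the acceptance
script run a handful of such phantoms.  There is no unseeded randomness
anywhere: identical inputs and configuration give byte-identical reports,
which is also what makes the repeated-run agreement statistic α = 1 exact
rather than approximate.
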