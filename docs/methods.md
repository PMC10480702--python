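# Methods

This note documents the models, numerical choices and limitations behind
`spheroidkit`'s measurements, in the order the pipeline applies them.

## Mesh model and units

All metrics consume a cleaned triangle mesh: duplicate vertices merged,
zero-area faces dropped, normals consistently outward (for watertight
meshes), coordinates in millimetres.  Loading rescales from `cm`, `m` or
`um` tags.  Non-watertight meshes are accepted with degraded
functionality — volume-based quantities are absent and the object length
scale r_eq falls back from the equal-volume-sphere radius (3V/4π)^(1/3) to
the equal-area radius sqrt(A/4π), with a warning — because real scans can
carry small defects that should not abort a batch.  Quad faces in OBJ input
are fan-triangulated in deterministic vertex order by the reader.

## Principal orientation

Orientation comes from the *surface tensor* T = Σ_f a_f n_f n_fᵀ / Σ_f a_f,
the area-weighted second moment of the outward unit face normals.  Its
eigenvectors (descending eigenvalues) define a right-handed frame in which
the bounding box and the spherical parametrization are expressed, making
every downstream metric rotation-invariant through canonicalisation.  A
vertex-covariance tensor is a possible alternative; the normal-based form
is used because it weights orientation by surface area rather than by
tessellation density.  Determinism details: each axis is flipped so its
largest-magnitude component is positive; if that leaves a left-handed set
the last (smallest-eigenvalue) axis is flipped back.  Near-degenerate
eigenvalue pairs (relative gap < 1e-6) are re-spanned by the directions in
the degenerate subspace closest to the world axes, and a fully isotropic
tensor (a sphere) returns the world frame outright — so symmetric objects
get a reproducible frame instead of an eigensolver-dependent one.

## CoM / CoBB dispersion

The centre of mass is by default the *area-weighted surface centroid*
Σ a_f c_f / Σ a_f (the quantity the original measurement software reports
for homogeneous material); the true volumetric centroid via the divergence
theorem is available as an option and differs measurably on asymmetric
solids (for a closed hemisphere: z̄ = 1/3 vs 3/8 of the radius).  The
bounding box is axis-aligned in the principal frame; its midpoint is the
CoBB.  The CoM–CoBB distance is normalised by r_eq, which makes the
dispersion dimensionless and similarity-invariant.  Normalising "by
volume" directly would carry units of mm⁻²; the r_eq convention preserves
the intent (volume-derived scale) while keeping the number comparable
across object sizes.  Both raw (mm) and normalised values are reported.

## Surface roughness

At each face, the k nearest face centroids (Euclidean, including the face
itself) are fitted with an area-weighted total-least-squares plane (the
smallest principal component of the weighted covariance); the face's local
curvature is the orthogonal distance of its own centroid to that plane,
and mean roughness is the area-weighted average over all faces.
k = max(4, round(f · A_total / mean face area)) with f = 0.05% by default,
so the neighbourhood covers a fixed *fraction of surface area* regardless
of object size or scan resolution.  This is a plane-deviation statistic at
a normalised scale, not a differential-geometric curvature: scar margins
and facet edges score high, scar interiors low.  On a sphere of radius R
the estimator has a closed-form anchor: the neighbourhood is a cap of area
fraction k/n, whose area-uniform mean plane sits half the cap height below
the apex, so the expected deviation is R·k/n (half the cap sagitta); the
implementation reproduces this within a fraction of a percent at 20k
faces.  The measure depends on tessellation through k, which is why the
synthetic generator (below) keeps face sizes uniform, as structured-light
scans do.  Raw (mm) and r_eq-normalised roughness are both reported;
normalised is the cross-assemblage default.

## Spherical parametrization and sphericalness

Objects are parametrized radially from the area-weighted CoM: for each
direction on a midpoint-equiangular (θ, φ) grid (default 256×256), r is
the distance to the unique surface intersection of the ray, found by
candidate-pruned Möller–Trumbore casting with an exact full-mesh fallback.
Exactly-one-intersection is a precondition (star-shapedness); a second
distinct crossing raises an error naming the offending direction rather
than silently approximating, because near-spherical knapped objects are
expected to be star-shaped and violations signal an input problem.
Grazing edge/vertex hits are retried with a 1e-9-radian perturbation.

The three coordinate functions x, y, z of the parametrized surface (in the
principal frame) are analysed in real orthonormal spherical harmonics up
to lmax = 20 by default.  The transform is separable — real FFT over
longitude, stable normalised associated-Legendre recurrence over
colatitude — with Fejér-1 quadrature weights in cos θ, which make the
analysis *exact* for band-limited inputs on this grid (the midpoint
colatitudes are Fejér-1 nodes); the round-trip
analysis∘synthesis error on random band-limited functions is at machine
precision.

Sphericalness: with E_l^(i) the degree-l band energy of coordinate
function i, the three normalised first coefficients are
c_i = E_1^(i) / (3 Σ_l E_l^(i)) and the deviation is Σ_i |c_i − 1/3|.
Each coordinate function of a perfect sphere is a pure degree-1 harmonic,
so the sphere anchors the scale at exactly 1/3 per coefficient.  Two
normalisations satisfy that anchor — dividing by the per-function total
energy (scaled by 3) or by the summed total over all three functions.
The per-function form is used: it scores the *harmonic purity* of each
coordinate function, so a smooth ellipsoid (nearly pure degree-1 in every
coordinate, just anisotropic) sits close to the sphere while a faceted
cube sits farther away — matching the intuition that sphericalness should
respond to faceting and topography, the things knapping changes, more than
to overall elongation.  Under the summed-total normalisation the ordering
inverts (the ellipsoid scores ~7× worse than the cube), which contradicts
the intended cube > ellipsoid > sphere behaviour.  Energies above lmax are
not represented; sphericalness is therefore "sphericity at the resolved
orders", and the default lmax = 20 resolves structure down to ~1/6 of the
object radius.  Deviation is invariant to translation (CoM centering),
scale (energy ratios) and rotation (principal-frame canonicalisation; for
the per-axis energies themselves a rotation mixes the three coordinate
functions, which is exactly why the frame is fixed first).

Reconstruction at increasing truncation degree l is provided for
inspection (synthesised UV-sphere meshes); its RMS radial error is
non-increasing in l by orthogonality, which the tests assert.

## Gauss maps

The Gauss map bins |r − r̄| / r̄ (r̄ = solid-angle-weighted mean radius =
best-fit sphere radius) from the parametrization grid onto a 100 × 100
(θ, φ) grid by cell mean.  Empty cells — impossible when the sampling grid
is at least as fine as the map — would be filled nearest-neighbour and
flagged in `fill_policy`.  Patch deviation looks up each face's cell and
averages with face-area weights, so the whole surface as a patch recovers
the map's solid-angle-weighted global mean.

## Edge angles and patch metrics

Angle between surfaces: each picked point set is fitted by a TLS plane,
the worst 20% of points by absolute residual are dropped (one pass —
deterministic, unlike RANSAC) and the plane is refitted; the trimming
floor keeps at least 60% of points.  Plane normals are oriented away from
the material — away from the midpoint of the two set centroids, which for
any wedge between 0 and 180° points both normals out of the solid — and
the reported angle is 180° minus the angle between the oriented normals.
Convention: coplanar continuation = 180°, perpendicular = 90°, fold-back
→ 0°; more spherical objects therefore carry higher surface angles.  At
2% Gaussian jitter the estimator recovers wedge angles within a degree
when a few hundred points per surface are supplied.

Patch (primary-surface) metrics, computed against user-supplied face-index
annotations (identification is an expert task; a heuristic scorer is
provided but never applied automatically):

- *area proportion* — patch area / total area; this is the reduction
  proxy, ordered descending along the reduction sequence;
- *planarity* — RMS orthogonal distance of patch vertices to the patch TLS
  plane;
- *signed concavity* — mean depth of patch vertices below the TLS plane of
  the patch *boundary ring*, inward (toward the CoM) positive, normalised
  by the ring diameter.  The rim plane is the reference because the mean
  signed distance to a patch's own TLS plane is identically zero;
- *platform angle* — edge-length-weighted mean of the per-boundary-edge
  dihedral angles between adjacent patch and exterior face planes, same
  through-the-material convention.  A single plane fit to the full
  boundary ring cannot measure this: the TLS plane of a closed ring around
  a cap has its normal along the cap axis and the angle would read ~180°
  regardless of the true rim dihedral.  The per-edge mean reproduces the
  90° cube-side case and the closed-form rim dihedral of a spherical cap
  (180° − arccos(1 − h/R)).

## Trend analysis and the hypothesis report

Each metric is regressed on the primary-surface proportion with
closed-form simple OLS on raw (untransformed) variables plus Spearman rank
correlation; no iterative fitting, and near-zero variances are detected
with relative tolerances.  The hypothesis report is deliberately
rule-based and descriptive: a metric "improves with reduction" when its
Spearman rho against the proxy is at least +0.5 (it falls as the proxy
falls).  Both roughness and sphericalness improving reads as
percussor-consistent; sphericalness alone as intentional shaping;
roughness alone as core-consistent; neither as no patterning.  No p-values
are attached — with assemblage sizes in the dozens to low hundreds the
fitted directions, not significance stars, carry the argument.

## The synthetic generator

`simulate_reduction` emulates the geometric model of spheroid reduction:
every stage is a sphere-based solid with one reserved planar *primary
facet* whose area proportion follows a strictly decreasing schedule
(default: 10 stages, geometric from 0.30 to 0.03), ringed by planar flake
facets cut around the facet perimeter at scheduled platform angles
(default 100° → 150°).  Stages are independent geometric states, not
cumulative carvings: the facet fraction is imposed by root-finding the cut
height on the actual (flaked, textured) mesh, so the ground truth is exact
rather than emergent, and every stage is convex, watertight and
star-shaped by construction.  Defaults model a fist-sized limestone
spheroid: base radius 40 mm, 8 flakes per stage, flake depth 1.5% of the
radius scaled by sqrt(F_s/F_0) so scars shrink with the facet, 3% radius
shrink per stage (knapping removes material).

Surface texture: flake scars and the primary facet are kept as exact
planes (conchoidal fracture surfaces are smooth); the uncut "cortex"
region receives radial vertex noise whose amplitude is drawn per stage,
uniformly in 0.2–1.2% of the stage radius, *independently of the stage
index*.  The noise is high-passed on the vertex graph (neighbour mean
subtracted twice, then re-normalised) so it drives small-scale
plane-deviation roughness without injecting low-degree shape energy that
would contaminate the sphericalness trend.  Cap triangulations use
concentric rings at the base mesh's edge length, keeping face sizes — and
hence the roughness neighbourhood k — uniform across stages, as uniform
scan resolution does for real scans.

What the simulator emulates: the monotone primary-surface shrinkage,
the rising platform angle, convergence toward the sphere, and
stage-decoupled surface texture.  What it does not: fracture mechanics,
Hertzian cones, scar superposition and battering, cortex percentage, or
measurement noise from scanning.  Passing the trend-recovery tests
therefore shows that the *measurement chain* recovers known geometric
signal in the presence of stage-independent texture — not that real
assemblages behave this way.

## Problem sizes and numerical defaults

Analytic fixtures use icospheres at subdivision 4–5 (5 120–20 480 faces);
the sphere anchor is evaluated at 20 480 faces on a 256×256 ray grid;
sequence analyses use a 128×128 grid, which changes sphericalness values
by < 0.1% relative to 256×256 on these shapes.  Ray casting prunes
candidates with a k-d tree over face-centroid directions (24, then 96
candidates, then an exact all-faces fallback), so a full parametrization
of a 20k-face mesh takes a few seconds.  Tolerances asserted in the test
suite: 1e-3 on the sphere's first coefficients, 1e-3 relative on
similarity invariance (20 random transforms), 1% against the independent
dense-quadrature sphericalness oracle, 1° on jittered edge-angle recovery,
10% on the curvature cap oracle, and 1e-12 on the OLS closed form.

## Known limitations

- Radial parametrization requires star-shapedness from the CoM; deeply
  notched or shelved artifacts are rejected, and an area-preserving
  parametrization for such genus-0 surfaces is out of scope.
- Sphericalness is truncation-dependent (see above); comparisons are only
  meaningful at a common lmax and grid.
- The primary surface must be supplied as an annotation against the
  *cleaned* mesh's face indexing; no automatic scar segmentation is
  included.
- The minimum-volume bounding box over all orientations is not computed;
  the box is axis-aligned in the principal frame by design.
- Roughness depends on tessellation through the neighbourhood rule;
  meshes with strongly non-uniform face sizes should be remeshed before
  cross-object comparison.
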