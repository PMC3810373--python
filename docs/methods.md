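# Methods

## Scope and coordinate conventions

`anchor3d` reconstructs a deformable 3D model of a monogenean haptoral
anchor from a single 2D outline. The template plane is x–y with x
rightward and y upward; one grid unit is one graph square (physical units
are recorded only as `grid_spacing` metadata). The model is extruded
symmetrically in z with a default thickness of 1 grid unit — anchors are
drawn in lateral view and carry no depth information, so thickness is a
free display parameter.

## Template representation and synthesis

A template is a simple, counter-clockwise closed outline plus an open
medial path from the inner-root end to the point tip, annotated with up to
seven non-overlapping intervals (sites I–VII) of normalized medial arc
length where across-species shape variation concentrates. The packaged
annotation places the inner root and its base in sites I–II, the base
curvature in III, the outer root in IV (interval [0.30, 0.44] — wide
enough that a protruding, possibly bifid outer root spans several
stations), the upper shaft in V, the 'ear' region in VI and the recurved
point in VII.

The synthetic generator integrates a medial curve from piecewise-constant
curvature segments (inner root, shaft with total turn `shaft_curvature`,
point with total turn `point_curl`) and offsets it on each side by a
smooth half-width profile. The outer root is a one-sided Gaussian bump in
site IV (optionally several lobes for bifid roots), the optional 'ear' a
one-sided lobe in site VI, and small seeded ornament bumps emulate surface
irregularity. Output is deterministic for a fixed seed. The medial path
must be supplied (the generator emits it analytically); medial-axis
estimation from raster drawings is out of scope.

What the generator does *not* emulate: digitisation noise of scanned
plates, open or branching outlines (true two-pronged roots are modelled as
side lobes of a single band), and out-of-plane bending. Passing tests
therefore demonstrate correctness of the geometry pipeline on clean,
simply-connected anchor-like bands, not robustness to raster artefacts.

## Station layout and block assembly

A site with count c = n_along × n_across receives n_along stations of
n_across points spanning its interval; packaged factorizations are
4 → 2×2, 6 → 3×2, 8 → 4×2, 16 → 4×4 (other even counts use 4 across when
divisible by 4 and ≥ 16, else 2 across). Counts are interpreted as
in-plane primitives: the extrusion doubles them into the 8 vertices per
block. Normal spans receive 2-point stations allocated proportionally to
span length (≥ 1 per span, default 12 in total). Station points sit at
equal fractions of the chord between the two outline crossings of the
local medial normal, taking the nearest crossing on each side so the
recurved point's far limb is never spanned.

Where the across-resolution changes (2 ↔ 4 points), a duplicated or
coincident transition station would create zero-area quads or T-junction
edges and break the closed-manifold invariants, so the gap is tiled with
the standard conforming 1→3 quad transition template: four quads and two
interior points (tagged with the coarser side's site so site counts stay
exact). Blocks are welded by shared vertex ids; interior faces shared by
two blocks cancel, a face shared by three is rejected as non-manifold, and
quads below 1e-9 grid² are rejected as slivers. The result is verified
closed, consistently oriented and Euler-characteristic 2.

## Catmull-Clark subdivision

Smoothing uses the classic rules (face centroids; edge points as the mean
of the two endpoints and two adjacent face points; vertex update
(Q + 2R + (n−3)S)/n). Only closed meshes are supported — the assembly
always produces closed surfaces — so no boundary/crease rules exist.
Because every rule is a fixed convex combination, each level is a sparse
linear operator cached per topology (`SubdivisionOperator`); repeated
smoothing during deformation is a single sparse mat-vec. The default
display level is 2, which is visually smooth at the block resolutions
used here and keeps silhouette extraction cheap (~3.3k faces).

## Silhouette and fit metrics

The silhouette is the boundary of the union of the smoothed mesh's
projected faces in the template plane. For a closed mesh this equals the
union of upward-facing projections, but filtering by |n_z| > 1e-12 instead
of n_z > 0 stays robust when the model is viewed edge-on (90° rotation
views). GEOS failures on near-degenerate overlaps are retried with
snap-rounded union at grid 1e-9. Fit quality between silhouette and
target outline is quantified by the mean symmetric nearest-boundary
distance over 256 uniform samples per ring (absolute and relative to the
target bounding-box diagonal), the sampled Hausdorff distance, and the
area IoU.

## Direct-manipulation fitting

Every control vertex is a pilot point. Fitting starts by aligning the
model to the target's bounding box (uniform scale + translation), then
iterates:

1. boundary pilots (the rim of the front-layer faces) are put in cyclic
   arc-length correspondence with the target outline; the cyclic offset
   and orientation are chosen by brute force over 64 coarse offsets × 2
   orientations with a local refinement pass;
2. candidate displacement fields are formed from several residual
   families — the arc-length correspondence residual, an order-preserving
   nearest-point residual (nearest target arc positions made cyclically
   monotone by pool-adjacent-violators, which keeps pilots from swapping
   targets around narrow protrusions), their blend, and a residual focused
   on the worst-matched half of the boundary. Each residual is measured
   from the pilot's nearest point on the *current smoothed silhouette*,
   not from the pilot itself: subdivision shrinks the displayed surface
   inside its control cage, so pilots must settle slightly outside the
   outline for the silhouette to match;
3. displacements are scaled by λ (default 0.8, halved on rejection,
   recovered ×1.5 on success) and propagated to interior/back-layer
   vertices by inverse-distance weighting (power 2) over each vertex's 6
   nearest boundary pilots — local support prevents a large move at one
   pilot from dragging distant regions; a vertex coincident in x–y with a
   pilot (its back-layer twin) copies the displacement exactly;
4. the best candidate that does not increase the mean symmetric distance
   is accepted, so the reported trace is monotone non-increasing; if all
   candidates fail, the persistent step drops below the range just tried
   (λ/32) and the fit stops when steps become negligible.

z coordinates are never modified during fitting (targets are 2D; an
optional thickness scaling was considered and left out — nothing in 2D
targets constrains it). Convergence requires mean relative distance
≤ 0.015 *and* IoU ≥ 0.95; the stopping rule in the original workflow is
visual, and these values are strict enough that converged fits look like
correct overlays while remaining attainable on coarse control meshes.
Non-convergence returns a result flagged `converged=False`, never an
exception.

## Per-site count optimization

`optimize_site` rebuilds the model at counts 4, 6, 8, … (step 2, cap 32)
and accepts the first count whose fit converges. Sites are optimized
independently. The packaged outer-root demonstration pairs the plain
template with a target whose outer root is bifid: two Gaussian lobes of
amplitude 4.5 and σ = 0.02 centred at the interior station positions of
the 4×2 layout (medial positions 0.3467 and 0.3933). With 2×2 or 3×2
patches the smoothed silhouette bridges the notch between the lobes and
the fit stalls below tolerance; the 4×2 patch places stations on both
lobes and converges — reproducing the canonical 4 → 6 → 8 progression.
The lobe geometry was chosen by construction against the fit procedure
and verified by brute-force fits at every count. Because the fitter is a
heuristic, the mean distance of *rejected* counts is not guaranteed to be
strictly monotone in the count; the chosen count always fits at least as
well as every rejected one, and on the packaged demo the full trace is
monotone.

## Numerical choices

- degenerate-quad tolerance 1e-9 grid²; convex-hull containment tolerance
  1e-7; affine-equivariance and route-equivalence tolerances 1e-9;
- coordinate tables are written with `repr` floats, so write → read →
  write is byte identical and coordinate replay reproduces a fitted mesh
  exactly (the two deformation routes agree to machine identity);
- OBJ/PLY keep quads (1-based indices in OBJ); STL splits each quad along
  its shorter diagonal;
- ring resampling uses 256 points for metrics and 1024 for correspondence;
  costs from rolled/re-parameterized outlines agree only to a few percent,
  which bounds how precisely two correspondences can be compared.

## Problem sizes

The packaged model has 208 control vertices (206 faces); test suites use
50 seeded templates for mesh-validity and subdivision properties, 8 shape
variants for deformation recovery, and the three-step site IV sweep for
the optimization demonstration. These sizes exercise every code path at
the same resolution as the packaged model.

## Known limitations

- Single-band topology: anchors are modelled as one curved strip; genus-0
  only, no holes or true bifurcations.
- The fitter is greedy and deterministic; it can stall short of tolerance
  on targets with deep re-entrant notches, which is reported honestly via
  `converged=False`.
- Site annotation is manual (packaged defaults); automatic site detection
  and raster vectorization are out of scope.
- Exact limit-surface evaluation and adaptive subdivision are not
  implemented; the displayed surface is the level-2 refinement.
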