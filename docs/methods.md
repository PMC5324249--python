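# Methods

This note documents the models and numerical choices behind `vesselgauge`:
what each stage computes, the parameters that matter, what the phantom
generator does and does not emulate, and the known limitations.

## Surface handling (`mesh_core`)

Lumen surfaces are triangle meshes in millimetres.  STL input is welded at
1e-6 mm (STL stores a triangle soup; topology checks require shared
vertices), degenerate and duplicate faces are dropped, unreferenced vertices
removed, and edge-manifoldness enforced (every edge on at most two faces).
Open rims are recorded as ordered boundary vertex cycles; a closed surface
has none.  ASCII STL output writes 17 significant digits so a write/read
cycle reproduces coordinates exactly; binary STL follows the standard
(float32), which limits round-trips to single precision.

Smoothing is the Taubin lambda/mu scheme on the uniform umbrella Laplacian:
each iteration applies a forward neighbor-average step of weight
`factor` (default 0.5) and a backward step of weight `mu < 0` derived from
the pass-band relation `1/lambda + 1/mu = k_pb` with `k_pb = 0.05`.  The
backward step cancels the first-order shrinkage of plain Laplacian
smoothing.  Defaults (30 iterations, factor 0.5) attenuate white vertex
noise about threefold on tube phantoms while changing the volume of a
closed icosphere (10 mm radius, 2562 vertices) by under 1% and moving its
vertices by under 0.1 mm.  The pass-band default was chosen on those two
criteria jointly; larger values (e.g. 0.1) preserve slightly less volume on
coarse meshes.

Clipping removes faces strictly on the discard side of a half-space and
re-cuts intersected triangles at the plane, adding one boundary loop per
cut.  A plane that misses the mesh warns and is skipped.  Note that on a
candy-cane geometry a transverse inlet plane also intersects the parallel
descending limb — clip planes act globally, as in any plane-clip tool.

## Voxel segmentation (`voxel_segmentation`)

Segmentation is a grey-value window (defaults 310–640 GV, the documented
range for bright-lumen angiographic contrast; scanner-specific) followed by
removal of connected components below `min_component_voxels`
(26-connectivity, so thin oblique vessels stay connected).

Surface extraction runs marching cubes at the 0.5 iso-level.  The binary
mask is first Gaussian-filtered (sigma 1 voxel): contouring the raw 0/1
field produces a staircase whose area overestimates smooth anatomy by ~8%
on a 20 mm sphere at 1 mm spacing, while the filtered field restores
sub-voxel surface placement (area error ~0.5%).  If filtering pushes the
whole field to one side of the iso-level (tiny or single-voxel foregrounds)
the raw field is contoured instead.  A foreground touching the grid
boundary yields an open surface with a warning; otherwise the mask is
zero-padded and the surface closes.  The isosurface of an isolated voxel
is the cell-dual octahedron (volume 1/6 voxel) — an intrinsic property of
marching cubes, not an implementation artifact.

NIfTI volumes must be axis-aligned; spacing comes from the affine diagonal
and the origin from its translation column.

## Phantoms (`phantom`)

The phantom family emulates thoracic-aorta phenotypes with closed forms:

- **Centerline**: straight ascending limb (length 70 mm by default),
  semicircular arch (radius 40 mm), straight descending limb (120 mm);
  `arch_radius=None` degenerates to a straight tube.  Defaults approximate
  an adult thoracic aorta with a 25 mm lumen.
- **Cross-sections**: ellipses with minor semi-axis `tube_radius`
  (12.5 mm default) and major/minor ratio `section_eccentricity`;
  a **coarctation** multiplies the radius by
  `1 - depth * exp(-(s-c)^2 / 2w^2)`; a **dilation patch** adds an outward
  Gaussian bump, optionally confined to an angular wedge; **branch stubs**
  are short cylinders on the arch outer wall with a matching ostium hole cut
  in the main wall.
- **Frames**: rings sit on rotation-minimizing (parallel transport) frames,
  so the ellipse orientation does not twist around the arch.

Ground truth is evaluated from the same polar radius formula on a dense
grid (0.25 mm arc length, 720 angles): maximum diameter as
`max_phi rho(phi) + rho(phi+pi)`, area by angular quadrature — exact to
quadrature precision for pure ellipses (`2a`, `pi*a*b`).  For one-sided
bumps the through-center chord slightly underestimates the true diameter;
profile tests therefore use full-circumference deformations.  Tortuosity
and apex curvature (`1/arch_radius`) are closed-form.

`make_open_phantom` removes the flat end-cap fans (a half-space clip cannot
open a candy cane, since the limbs are parallel).  Branch-stub composites
are edge-manifold but not watertight at the junction; stubs exist to
exercise open-contour branch exclusion, not to model supra-aortic anatomy.

Voxelization assigns `lumen_gv` (475) inside and `background_gv` (100)
outside — values placed inside and outside the default threshold window —
plus seeded Gaussian noise.  `PhantomSpec` inputs are tested analytically
against the radius formula; mesh inputs by slice rasterization (below).

What the phantoms do **not** emulate: partial-volume intensity gradients,
scanner noise texture and bias fields, motion/ECG artifacts, anatomical
taper and non-planar arch shapes, wall thickness.  Passing on phantoms
demonstrates geometric correctness of the measurement chain, not robustness
to clinical image quality.

## Centerline (`centerline`)

The centerline is the weighted shortest path between two extremal points:

1. **Interior rasterization.**  The interior is voxelized (default pitch
   1 mm, reduced for small lumens) by even-odd slice rasterization: plane
   sections are chained from raw face/plane segments into polylines;
   nearly-closed chains (a section grazing a rim or an ostium hole) are
   closed with a chord.  Rasterization runs in a rim-aligned rotated frame
   (mean open-rim normal mapped to +z) so slice planes never cross the
   inlet/outlet rims regardless of mesh orientation.
2. **Wall-distance graph.**  A Euclidean distance transform gives the wall
   distance `d` per interior voxel; a 26-neighbor graph carries edge costs
   `step_length / ((d_u + d_v)/2)^p` with `p = 2`, and Dijkstra (with
   deterministic node ordering) finds the minimum-cost path.  Penalizing
   wall proximity makes the path ride the locus of maximal inscribed
   spheres.
3. **Sub-voxel refinement.**  Voxel centers quantize the path to half a
   pitch, which is too coarse for ±0.2 mm distance-field accuracy.  Two
   refinement passes replace each point by the area centroid of its normal
   cross-section (the loop enclosing, or nearest to, the current point);
   proposed shifts larger than 3 pitches are rejected — the input is
   already near-medial, so a large move means the plane grazed a rim or
   caught the other limb.  On a cylinder this lands on the axis to
   numerical precision; note that for strongly one-sided bulges the section
   centroid (like the inscribed-sphere center) legitimately leans toward
   the bulge.

The path is resampled at 0.5 mm; inscribed radius is the exact
point-to-surface distance at each point.  `smooth_centerline` is an
arc-length moving average with the window shrinking to zero at the ends
(pinning them); points that leave the lumen are pulled back just inside the
nearest wall.

Tortuosity is total arc length over the endpoint chord.  Curvature uses
the circumscribed circle of three points 2 mm apart — the stencil matches
the plane spacing and controls noise amplification; the arch apex is the
station extremal along a user-supplied elevation axis (patient orientation
in scanner coordinates is not guessed).

## Profiles (`profiles`)

Planes are sampled every 2 mm (the working resolution of the continuous
method) normal to the centerline.  Each mesh/plane intersection may contain
several loops; the one enclosing (or nearest to) the centerline point is
kept.  Maximum diameter is the largest point-pair distance of the contour
(convex hull + exhaustive pairs — not an ellipse fit and not twice the
centroid distance, because real sections are not elliptical); area is the
shoelace magnitude.

Stations are flagged excluded, never dropped, when (a) the contour is open
(rim or branch ostium), (b) the station lies in a user-declared branch
window, or (c) the area jumps >30% against both neighbors.  The 30% jump
rule is this package's explicit stand-in for the manual shading of branch
spans in continuous plots.

Landmark stations (eight named positions from the sinotubular junction to
the descending aorta at the left atrium) are supplied as arc lengths;
anatomical landmark detection is out of scope.  Visit alignment is a single
rigid arc-length shift at one shared landmark — piecewise warping would
invent correspondences the data does not define.  Growth/shrinkage
classification uses a 1.5 mm diameter-change threshold, the scale of
inter-observer variability (about one pixel); changes below it are
"stable".

## Distance maps (`distance_map`)

The field assigns every vertex its distance to the nearest centerline
point, with centerlines resampled at 0.5 mm so chord discretization
contributes well under 0.05 mm.  Multiple centerlines (main vessel plus
branch paths) are queried as a union; the main path parameterizes regional
summaries.  Regions (ascending / arch / descending) are split at two
explicit arc-length cut points — no anatomy inference.  The per-station
asymmetry index `(max - min)/mean` over vertices binned by nearest station
is 0 for circular sections and `(a-b)/mean radius` for ellipses; bins with
fewer than 8 vertices are skipped.  Export is ASCII PLY with a per-vertex
scalar, renderable as a color map by standard viewers.

## Registration and change maps (`registration`)

Alignment is rigid only — by design.  Scaling or affine terms would absorb
the growth that the change map is supposed to expose.  The coarse stage is
an orthogonal-Procrustes (Kabsch) fit of at least three non-collinear
picked point pairs, with reflections rejected.  ICP then alternates exact
point-to-surface correspondences with a Kabsch re-fit from the original
points, dropping correspondences beyond 10x the median distance
(robustness near clipped rims), until the RMS changes by less than
1e-4 mm; an RMS rising five consecutive iterations raises a diagnostic
error.  Subsampling is seeded and deterministic.

Closest-point queries are exact point-to-triangle distances: a KD-tree over
triangle centroids prunes candidates using the nearest-vertex distance as
an upper bound, and the candidate set is resolved with the exact
point/triangle kernel, so results equal brute force over all triangles.

The change map evaluates, for each registered target vertex, the signed
minimum distance to the reference surface; the sign comes from the outward
reference normal at the closest point (positive = outside = growth).

A caution the examples make explicit: on a featureless straight tube, ICP
is degenerate — roll about and slide along the axis leave the residual
unchanged — so registration experiments use the full candy-cane geometry.

## Agreement statistics (`agreement_stats`)

- **Least squares**: OLS of method B on A, Pearson r, p from the
  t-distribution with n-2 df.
- **Bland-Altman**: differences A-B; bias is their mean, the
  reproducibility coefficient is 1.96 x sample SD (n-1 denominator, the
  convention of the method's literature), limits are bias +/- coefficient.
- **Passing-Bablok**: the original rank procedure — all pairwise slopes
  S_ij (i<j), slopes equal to -1 discarded, the median index offset by the
  count K of slopes below -1; intercept = median(b - slope*a); confidence
  bounds from the rank-based normal approximation.  Exact ties in a
  carry no slope information and are dropped; infinite slopes rank at the
  extremes.
- **F test**: larger sample variance over smaller, compared with an
  upper-tail critical value.  Because the larger variance is always in the
  numerator, the critical value is taken at the `1 - alpha/2` quantile so
  the procedure's overall false-alarm rate is `alpha` (a `1 - alpha`
  quantile would double it to ~10%); the measured null rejection rate over
  500 replicates is ~5%.

## Problem sizes and determinism

Default phantom meshes use 200 axial x 64 circumferential rings
(~13k vertices); centerline extraction on them takes a few seconds each,
and the full validation (`scripts/acceptance.py`) runs in well under a
minute on one CPU.  These sizes were chosen because halving them changes
the measured quantities by less than the test tolerances.  All randomness
(phantom noise, ICP subsampling, statistical replicates) flows from
explicit seeds; repeated runs are bit-identical.

## Known limitations

- The centerline is a graph-based approximation of the Voronoi medial
  axis; its accuracy rests on the voxel pitch and the centroid refinement,
  both validated on phantoms only.
- Branch-stub phantoms are not watertight at the junction and the branched
  centerline handling covers an aorta plus a few stubs, not arbitrary
  trees.
- Station mapping needs user-supplied arc lengths; there is no anatomical
  landmark detection.
- Binary STL round-trips at float32 precision.
- The voxelizer assumes axis-aligned grids and near-tubular interiors;
  highly non-convex slice sections with many rim crossings would degrade
  the chord-closure repair.
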