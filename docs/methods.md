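# Methods

This note documents the models, numerical choices, and limitations of
`kneemap`. It states nothing the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate conventions

All geometry is in millimetres in a right-handed patient frame. Left
knees are mirrored across the sagittal (x) plane on load, with triangle
winding flipped to preserve outward normals, so registration always
runs in a right-knee convention; the paper trail of the original side
is kept in the mesh metadata. Cell and voxel indices are 0-based; cells
are half-open boxes [lo, hi), so no voxel center can belong to two
cells.

## Calibration

A solid multi-rod hydroxyapatite phantom provides samples
(mean HUᵢ, ρᵢ). The correspondence is modelled as a two-parameter line
ρ = a·HU + b fitted by ordinary least squares (closed-form normal
equations; r² reported). A line is the standard QCT model for solid
phantoms; rod ROI extraction is accepted as precomputed input —
automatic rod detection is out of scope. Degenerate inputs (fewer than
two distinct HU values) are rejected.

## Surface registration

### Cylinder fit (femur)

The subchondral patch is fitted with a cylinder by orthogonal-distance
least squares: residual = (distance to axis) − radius, 5 parameters
(two axis angles, two in-plane offsets, radius), Levenberg–Marquardt
started from each principal axis of the patch with the best local
optimum kept. The axis sign is fixed to point medial → lateral using
the epicondyle anchors. Coplanar point sets are rejected (smallest
singular value below 1e-9 of the patch scale). On synthetic patches the
fit recovers the generating radius to ≈0.05 % under 0.1 mm vertex noise
(see the acceptance report).

### Global femur steps

- **1a** maps the moving notch projection onto the reference notch
  projection and applies the minimal rotation taking the moving
  cylinder axis onto the reference axis (scale fixed at 1). Both
  post-conditions — colinear axes, coincident notch projections — are
  what the tests verify, not the matrix itself.
- **1b** is a region scaling in the (now common) cylinder frame:
  radial scale = reference radius / moving radius; each condyle is
  scaled axially by the ratio of notch-to-epicondyle extents. The map
  is anchored at the notch projection, so it is continuous at the
  boundary between the two condylar regions by construction
  (piecewise-linear in the axial coordinate; no blending).
- **1c** searches the rotation about the common axis minimising the
  mean squared nearest-neighbour distance between the subchondral
  areas: a coarse grid at `rotation_search_resolution` (default 1°)
  over ±180°, then bounded scalar minimisation inside the best grid
  cell, ties broken toward the smallest |angle|. The distance is
  point-to-nearest-subchondral-*vertex* rather than point-to-facet: a
  subchondral area that lies on (or near) a cylinder slides over
  itself under axial rotation, so a point-to-surface objective is flat
  in the patch interior up to facet-sag ripples, whereas the vertex
  objective is sharply quadratic at alignment. With identical
  tessellations this recovers a known rotation essentially exactly;
  the brute-force 0.01° sweep in the tests confirms the optimiser
  lands on the global optimum.

### Global tibia steps

- **Step 1** is a correspondence-free similarity alignment driven by
  the two plateau patches. Each bone contributes a deterministic
  descriptor set: patch centroids (the subchondral mask is split into
  connected components; the larger component is taken as the medial
  plateau, which holds both anatomically and in the generator), the
  combined centroid, the RMS spread (scale), and an orthonormal frame
  (medial→lateral direction projected into the plateau plane, patch
  normal oriented away from the bone body, their cross product). The
  transform maps moving descriptors onto reference descriptors and is
  exact for similarity-related inputs; the closed-form Umeyama
  solution on corresponding vertices serves as the independent oracle
  in the tests.
- **Step 2** scales along the reference longitudinal axis by the ratio
  of proximal-segment extents, anchored at the subchondral centroid so
  the plateau does not move. It is represented as a region scaling
  with equal axial factors and radial factor 1, which keeps the warp
  chain homogeneous.

### Nonrigid step

Nonrigid ICP with a TPS deformation model: per iteration, (i) each
moving vertex finds its closest point on the reference surface by
exact point-to-triangle projection (KD-tree over face centroids plus
faces incident to the nearest vertex as candidates), and (ii) a TPS is
fitted from a fixed farthest-point control subset (default 500) of the
current vertex positions to their correspondence points, with the TPS
smoothing parameter taken from a decreasing stiffness schedule
(default 100, 10, 1, 0.1 — the kernel is in mm, so these span strong
to nearly-interpolating smoothing). An update that would increase the
mean surface distance is rejected and the schedule advances; the
accepted distance sequence is therefore non-increasing by
construction. Termination: mean vertex displacement < 1e-3 mm (a fixed
point) or the iteration budget (5 per level). The published
formulation of stiffness-regularized nonrigid ICP is not reproduced
term-for-term; conformance is through the behavioural contracts (fixed
point on identical meshes, sub-0.1 mm mean residual on smooth 1.5 mm
warps, monotone descent).

### TPS

The 3D thin-plate spline uses the biharmonic kernel U(r) = r plus an
affine term; the (n+4)×(n+4) symmetric system is solved densely. With
regularization 0 it interpolates every control pair exactly (checked to
1e-9 mm); as regularization → ∞ the solution tends to the least-squares
affine map (this falls out of the system algebraically and is verified
against a direct affine fit). Duplicate or coplanar control points make
the system singular and are rejected up front. Bending energy is
reported as the quadratic form wᵀKw summed over output dimensions.
The full chain is distilled for phase 2 by fitting one TPS on 1000
farthest-point control pairs (pre-nonrigid position → final deformed
position), appended after the global transforms.

## Voxel mapping

Interior voxels are found by +z ray parity against the watertight
surface, with points grouped by (x, y) column so CT grids cost one
ray per column; column coordinates carry a fixed sub-nanometre nudge so
rays do not pass exactly through shared triangle edges. Values are
carried unchanged through the warp — no trilinear resampling and no
Jacobian/density correction, matching the method's definition of
averaging registered voxel values. The cell grid is anchored at the
reference bounding-box minimum, making cell counts deterministic; the
published cell counts (≈7000 tibial, ≈12000 femoral at 2 mm) are
properties of the specific reference bones, not constraints — the
synthetic femur yields ≈9300 interior cells. Aggregation is
center-point binning into half-open cells; empty cells are flagged
missing (serialized as an explicit `NA`), and voxels landing outside
interior cells are counted and logged so that
Σ cell counts + outside count = total registered voxels, always.

## Reliability statistics

ICC is ICC(2,1) — two-way random effects, absolute agreement, single
measurement — computed from the ANOVA mean squares. The two-way
random-effects family leaves single-vs-average and
consistency-vs-agreement open; single-measurement absolute agreement
is chosen because individual standardized maps are compared and
scanner/operator differences are absolute errors. Cells with zero
total variance have an undefined coefficient and are flagged and
excluded from summaries. The class boundaries are poor < 0.5 ≤
moderate < 0.75 ≤ good < 0.9 < excellent; the boundary value 0.9
itself, left unassigned by the quoted classes, is assigned to
excellent. RMSSD uses the per-knee sample SD (denominator k−1), then
the RMS across knees, making RMSSD² unbiased for the error variance.
Setting comparisons are two-sided Wilcoxon signed-rank tests with
zeros dropped, average ranks for ties, no continuity correction, and a
normal-approximation z (an exact-null mode is available and is checked
against exhaustive 2ⁿ enumeration for n ≤ 12); Bonferroni adjustment
is min(1, 3p) for the three pairwise comparisons, effect size
r = |z|/√N over the N non-zero pairs. Per-cell statistics are
complete-case: within a setting and cell, knees with any missing
repeat are dropped; cells with fewer than two complete knees are
excluded.

## Synthetic data

The generators emulate the *assumptions* of the method, not anatomy:

- **Femur**: a closed surface of revolution-like tube along the
  medial–lateral axis whose subchondral sector lies *exactly* on a
  cylinder of known radius (default 20 mm). An intercondylar groove
  with compact support separates two condylar patches without
  perturbing them (the groove is identically zero where the mask is
  true), and the angular extent of the subchondral mask varies along
  the axis so the axial-rotation objective has a unique minimum.
  Medial and lateral half-lengths differ (33/37 mm) so the per-condyle
  scales are distinguishable. Anchors (notch, epicondyles) are exact.
- **Tibia**: a tapered elliptical shaft (default 60 mm) with a gently
  domed plateau carrying two disjoint elliptical subchondral patches,
  the medial one larger; the longitudinal axis is exact.
- **CT**: voxels inside the bone carry HU = (field − b)/a for a known
  ground-truth line (default a = 0.8 mg/cc per HU, b = −5 mg/cc,
  typical of solid-phantom QCT), five rods at 0–400 mg/cc, soft-tissue
  background (−80 HU), optional i.i.d. Gaussian HU noise (default test
  level 5 HU). No beam hardening, scatter, or partial-volume blur is
  simulated.
- **Deformations**: a known similarity plus a sum of Gaussian bumps
  (default amplitude 1.5 mm, width 25 mm — amplitude/width is bounded
  so the warp stays diffeomorphic); the inverse is computed by
  fixed-point iteration and round-trips to <1e-3 mm.
- **Repeated measures**: value = cell mean + knee effect N(0, σb²) +
  error N(0, σe²), knee effects shared across settings. Defaults
  σb = 30, σe = 10 mg/cc with 10 knees × 2 repeats mirror the
  evaluation design scale; the implied true ICC is σb²/(σb²+σe²) = 0.9
  and the implied RMSSD is σe. These defaults sit inside the published
  reliability/reproducibility range for this kind of data.

Consequently, passing tests demonstrate that the algorithms recover
known geometry, calibration, and variance components under the
method's own assumptions; they do not demonstrate robustness to real
segmentation error, osteophytes, cortical thinning, scanner physics,
or anatomical variation beyond smooth deformation.

## Problem sizes and numerical defaults

Synthetic meshes use ~1900–2300 vertices, CT rasterization 1 mm
isotropic (~0.5M voxels), and the end-to-end fidelity experiment one
deformed femur — sizes chosen so the whole suite and the acceptance
script run in a couple of minutes on a single CPU while every check
stays far from its tolerance. Key defaults, all exposed in
`RunConfig`: cell_size 2 mm; ICP stiffness schedule (100, 10, 1, 0.1)
with 5 iterations per level and 500 control points; distilled-TPS
control points 1000 with regularization 0; rotation search resolution
1°; displacement tolerance 1e-3 mm.

## Known limitations

- Anchors are inputs; no automatic landmark detection.
- The tibial medial/lateral patch identification uses the
  larger-component rule; pathological segmentations where the lateral
  patch is larger would swap the frame (a 180° ambiguity) — real
  pipelines should pass side-verified labels.
- TPS evaluation is O(n_control · n_points); fine for CT-scale clouds
  with 1000 controls, but not optimized for much larger control sets.
- The nonrigid step assumes global alignment has already been applied;
  it makes no attempt at large-rotation recovery.
- DICOM series assembly, segmentation, and in-vivo validation are out
  of scope.
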