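# Methods

This note records the models implemented in `tesseg`, the parameters that
matter, the synthetic world the phantom generator emulates, and the
numerical choices made where the underlying procedure was open.

## Problem setting

The target data are 3D gray-scale volumes of a thin, possibly curved,
mineralized layer tiled into convex cells (tesserae). The regime that
drives every design choice: the tiles are wider than the layer is thick;
the dark pores separating tiles survive at scan resolution only near the
junctions of ≥ 3 tiles; the rest of each border is a bright connection that
is itself wider than the layer thickness. Correct tile boundaries run
through the thinnest part of each connection.

## Stage 1 — edge-stopping diffusion

The PDE ∂I/∂t = ∇·(D(‖∇I‖)∇I) is discretized with explicit Euler on the
6-connected grid. The diffusion coefficient lives on voxel faces and is
binary: 1 when |ΔI| ≤ T_s, else 0. In flux form the scheme conserves total
intensity exactly (verified to rel. error < 1e−10) and obeys the extremum
principle for dt ≤ 1/6 (each update is a convex combination of ≤ 6
neighbors).

Parameters:

- `stop_threshold` (T_s, intensity units): choose between the intra-tile
  hole contrast and the tile/pore contrast. For the default phantom
  (hole contrast 60, pore contrast 160) the pipeline uses 100.
- `steps` (default 25) and `dt` (default 1/6, the stability bound): the
  source procedure specifies neither; both are exposed. 25 steps at dt=1/6
  reduce a radius-1.5, contrast-60 cavity to a residual dip below the
  phantom's noise sigma (checked in the tests) while faces across pores
  stay blocked, so pores are preserved bit-exactly.
- `update_coefficients`: whether face coefficients track the evolving field
  (default, the nonlinear PDE) or stay frozen from the input. The source is
  silent; both are available and conserve mass.

## Stage 2 — strip-restricted local thresholding

`F = {x ∈ S : I_s(x) > T_n · mean(I_s over B(x, l) ∩ S)}`, computed with
cumulative-sum box tables (O(N), exactly equal to the naive O(l³) loop —
a tested invariant). Choices where the procedure was open:

- Box clipped at the volume border (mean over existing voxels); avoids
  padding bias.
- Strip growth = Euclidean dilation of the tolerant global mask by `r_g`
  (via the exact EDT). Guidance: `l` ≈ 2–3 × layer thickness,
  `r_g` ≈ `l`/2, `T_n` = 1.
- Strict `>`: with T_n = 1 a perfectly flat region is background, which is
  the desired behavior (the criterion only fires above the local mean).
- Enclosed-cavity fill uses 6-connected background components against the
  (implicitly 26-connected) foreground — the standard duality pairing.

## Stage 3 — distance maps

**Planar map D̃₂D.** Per foreground voxel: cast `n` 3D rays (deterministic
Fibonacci-sphere directions) to the first background voxel (3D integer
Bresenham, voxel-by-voxel); fit the plane minimizing squared distances to
the hit cloud (normal = eigenvector of the smallest covariance eigenvalue);
translate it through the voxel; cast `m` equiangular rays inside the plane
and return the shortest center-to-center distance to a background hit.
Defaults n = 1214, m = 361.

Numerical choices:

- **Out-of-grid rule**: a ray leaving the volume is a background hit at the
  first out-of-grid voxel center. The 3D map pads with background
  correspondingly, so both transforms and the in-plane EDT oracle share one
  convention.
- **Ray cap**: rays stop after a configurable length (default: the largest
  grid dimension; the pipeline uses 4 × mean tile diameter). Fewer than 3
  hits at a voxel means the foreground is unbounded at that cap — an error,
  not a silent value.
- **In-plane basis**: axis of the normal's smallest component, crossed with
  the normal, then completed to an orthonormal pair — deterministic, no
  randomness anywhere in the maps.
- **Degenerate fits** (isotropic hit clouds): the eigensolver's fixed
  ordering plus a sign convention (largest-magnitude component positive)
  makes the returned normal reproducible even when any normal is admissible.
- Accuracy on axis-aligned slabs: |D̃₂D − exact in-plane EDT| ≤ 1 voxel for
  distances ≤ 20 at the default ray counts (acceptance-tested). The planar
  value can only overestimate the true in-plane distance through ray
  discretization, and never falls below the 3D distance on flat slabs.

**3D map D₃D** is the exact Euclidean distance transform
(`scipy.ndimage.distance_transform_edt`), kept as the baseline the planar
map is compared against.

## Stage 4 — hierarchical watershed

Flooding runs on −D̃₂D over the mask with 26-connectivity. Local-minimum
plateaus are collapsed to single basins *before* flooding (connected
components of equal value with no lower neighbor), so a flat maximum of the
distance map yields one basin, not many. Flooding is priority-queue
immersion with FIFO tie-breaking on plateaus and deterministic seeding by
sorted voxel index. The first value at which two basins' regions touch is
recorded once per adjacent pair as their saddle.

Extraction replays events in ascending saddle order with union-find:
merge when `saddle − max(min_A, min_B) < T_p` (the shallower side's
persistence — the reading that makes label count monotone in T_p; the
non-strict variant is available via `inclusive=True`) or when either
current region is smaller than T_v; the merged region keeps the deeper
minimum. T_p = T_v = 0 reproduces the classical oversegmentation (one
label per minimum plateau — verified against an independent plateau
enumeration). Watershed lines are not produced; every foreground voxel is
labelled.

`suggest_persistence` returns the knee of the label-count-vs-persistence
curve: the first local maximum of the second finite difference of the
window-3 moving-average-smoothed curve. "First", not "largest": such curves
have a second corner where everything collapses into one label, and the
global maximum often sits there rather than at the plateau near the true
tile count. The suggestion is advisory.

## Stage 5 — region graph and proofreading

Edges require face contact (6-adjacency): corner-touching labels are not
neighbors, which keeps the graph free of spurious contacts. Per-label
statistics: volume; degree; nearest-vertex distance (NaN for an isolated
vertex); width/height as extents along the principal axes of the label's
voxel cloud (height = least-scatter axis); and a curvature proxy — the RMS
deviation of the vertex's graph neighborhood from its best-fit plane,
normalized by the mean neighbor distance. The proxy is a stand-in for a
mesh-based curvature (the original mesh construction is unspecified); it
separates flat from curved shells in the tests but is not a differential-
geometric curvature.

Outlier flagging uses median/MAD z-scores (0.6745·(x−med)/MAD) per
statistic; it is advisory only — no correction is applied automatically.
Edits (merge, watershed split restricted to one label's voxels, spectral
split via the first k eigenvectors of the symmetric normalized Laplacian of
the unit-weight 6-adjacency voxel graph + seeded k-means, and
merge-then-split) never change which voxels are foreground, and a journal
replays any session deterministically. The spectral split caps the region
size (default 20 000 voxels; dense eigensolver under 1500, shift-invert
Lanczos above) and reattaches stray 26-components to the neighboring part
with the largest face contact so parts come out connected.

## Evaluation

Landmark rules: a segment hit by ≥ 1 landmark is a true positive; n hits
contribute n−1 false negatives; zero hits is a false positive; precision =
t_p/(t_p+f_p), recall = t_p/(t_p+f_n). Hits use nearest-voxel rounding;
landmarks landing on background are excluded from the counts and reported
separately (on real data landmarks are placed on the rendered surface and
always hit foreground). Rand index and VI are computed from the voxel
contingency table over a caller-supplied foreground ROI and are tested
against brute-force pair enumeration / direct entropy computation; VI is
reported in nats by default (base-2 available) with per-label-pair
contributions so the worst-disagreeing pair can be listed.

## The phantom: what it emulates, what it does not

The generator states a world rather than tuning one: K Poisson-disk seeds
(minimum spacing 0.7 × mean tile diameter, so the tessellation is regular
but not degenerate) on the mid-surface of a flat slab or spherical cap;
nearest-seed partition of the shell; pores of radius 2 voxels carved at
every junction of ≥ 3 tiles and along the outer 1 − `connection_fraction`
(default 0.5) of each pairwise border, so connections sit centrally between
pores and are wider than the default shell thickness; intra-tile cavities
(Poisson count, mean 2/tile, radius 1.5) stamped strictly inside tiles — a
cavity opening into background would drain rather than fill during
diffusion, which is not what cell lacunae do; foreground/background means
180/20, hole contrast 60; additive quadratic polynomial drift with
peak-to-peak amplitude 15 % of the foreground mean (the simplest field that
defeats global thresholding); Gaussian noise sigma 8. Truth labels,
landmarks (in-surface centroids, snapped into their tile if a centroid
falls on a pore) and neighbor pairs are frozen before intensity synthesis.
Fixed seed ⇒ bit-identical output.

Not emulated: scanner artifacts (beam hardening, rings), realistic mineral
density microstructure, partial-volume blur at tile surfaces, and irregular
tile shapes beyond what Voronoi cells give. A green pipeline test on the
phantom therefore establishes correctness of the geometry-driven stages in
the stated regime, not robustness to scanner physics.

The spherical-cap mode exists so an analytic surface normal is available at
every shell voxel; plane-fit accuracy is tested against it (≤ 10° away from
pores).

## Known limitations

- Isotropic voxels are assumed throughout (anisotropic headers are
  rejected); distances are in voxel units, physical units by scaling.
- The planar map's assumptions fail where the layer curves sharply within a
  tile diameter; such regions oversegment (the flagged-outlier + merge
  workflow is the intended remedy, as on real edge regions).
- The watershed flooding is a Python priority queue: fine up to a few
  hundred thousand foreground voxels, not tuned for whole-organ scans.
- The curvature statistic is a graph-based proxy, not a surface curvature.
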