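# Methods

## Model and assumptions

A spheroid is reduced to the positions of its cell centers at one instant;
no cell shapes, types, or dynamics enter. Every quantity is computed
relative to the centroid of all cells, which serves as the spheroid center
O. This makes all features exactly translation invariant, and all but the
voxel-grid surface features exactly rotation invariant. Using the centroid
of *all* cells (rather than of the bulk only) is a deliberate choice: the
gaslike classification needs a center before the bulk is known. For heavily
invaded clouds with a strongly asymmetric halo the centroid can drift off
the visual bulk center; this is a known approximation.

## Features and their parameters

| parameter | default | unit | role |
|---|---|---|---|
| `D_crit` | 125 | μm | centroid-distance threshold for gaslike cells |
| `d_crit` | 19 | μm | nearest-neighbor threshold for gaslike cells |
| `shell_thickness` | 10 | μm | density-profile bin width |
| `grid_spacing` | 5 | μm | voxel edge length for the bulk occupancy grid |
| `reach` | 15 | μm | occupancy radius around each bulk cell (≈ one cell radius) |
| `min_core_volume` | 3·10⁴ | μm³ | smallest largest-component still a "solid core" |

The thresholds (125, 19) μm are the published operating point for
MDA-MB-231 spheroids of this size class. Both inequalities are strict;
cells exactly on a threshold are bulk. The shell thickness, voxel spacing
and reach are not fixed by any published value; the defaults resolve the
~10 μm cell spacing without aliasing the 100–150 μm bulk. The 95th
percentile in the gaslike normalization uses the linear-interpolation
convention, which matters in small samples (documented because the hand
examples in the tests depend on it).

**Voronoi volumes.** Regions are clipped to a finite axis-aligned box —
the cloud's system box if known, else the tight bounding box padded by
twice the mean nearest-neighbor distance — rather than dropping unbounded
hull regions, so there is exactly one volume per cell and detached cells
show up as conspicuously large regions. Clipping uses the mirror
construction (the point set reflected across all six box faces before
tessellation); the bisector between a point and its mirror is exactly the
box face, so the volumes sum to the box volume by construction, and volume
conservation is a free correctness oracle. An optional orthonormal `frame`
rotates the clipping box with the cloud, which makes the volume sample
exactly rotation covariant; the transformation-study harness uses this for
its rotation grid. Clouds that are collinear or coplanar within tolerance
are rejected explicitly.

**Surface extraction.** Only the non-gaslike bulk is voxelized (occupied
iff a voxel center lies within `reach` of a bulk cell; the grid is padded
by whole voxels so occupancy never touches the boundary and a lone cell
sits on a voxel center). The 0.5 isosurface is extracted with marching
cubes after smoothing the binary occupancy with a one-voxel Gaussian:
marching cubes on raw binary data produces a staircase surface whose area
overestimates a smooth sphere by ~8%, while the smoothed field places the
isosurface with sub-voxel accuracy (a 100 μm voxel ball comes out within
1% of 4πr²). Vertex normals are area-weighted means of incident face
normals, oriented outward. Disconnected bulk clusters each contribute a
closed component; areas add.

**Missing-surface policy.** Surface area and deformation are reported
MISSING (never NaN-poisoned) when the bulk is empty, the grid has no
isosurface, or the largest connected occupancy component is smaller than
`min_core_volume` — i.e. when the cloud has collapsed into isolated one-
or two-cell blobs and a "bulk surface" is not a meaningful notion. The
default threshold is deliberately permissive: a disordered spheroid whose
bulk forms many small clusters still gets a (per-cluster, highly deformed)
surface, which is informative and keeps the calibration tensor complete;
only genuinely destroyed clouds (e.g. uniform noise of amplitude ~1000 μm)
are cut. Downstream, the deviation score drops MISSING features from the
weighted sum for the affected pairs without renormalizing the remaining
weights (a strict mode errors instead); dropped entries are recorded.

## Metrics

Distribution-valued features are compared with the 1-Wasserstein distance
in its binning-free quantile/CDF formulation (for scalar supports this
equals the optimal-transport cost exactly, which the test suite verifies
against an independent linear-program oracle). The density profile is
treated as a discrete distribution on shell midpoints; Voronoi volumes and
deformation scalar products as empirical samples, so unequal sample sizes
(different mesh sizes, different cell counts) need no truncation. The
gaslike point uses the Euclidean distance; the surface area the squared
difference, whose non-metric scale is absorbed by the standardization.

## Standardization and weights

Standardization statistics are computed over all M² ordered pairs of the
calibration set *including* the zero diagonal (20 spheroids → 400 entries
per feature), with the population (ddof = 0) standard deviation: the
calibration distances are the full population being standardized, not a
sample from a larger one. Because the diagonal zeros are the per-feature
minima, the post-shift standardized self-distance is exactly zero. A
feature whose calibration distances have zero spread is rejected
explicitly. Frozen parameters are applied unchanged to new data; new
distances below the calibration minimum then map to negative standardized
values, which is intended (they are "closer than anything seen in
calibration").

The weight optimization maximizes Σ_f λ_f c_f under Σλ² = 1 and λ ≥ 0,
where c_f is the summed inter- minus intra-phenotype standardized
distance. The objective is linear, so the optimum is analytic:
λ = max(c,0)/‖max(c,0)‖₂. The shipped optimizer is nevertheless numeric
(SLSQP, uniform initialization 1/√F, ftol 1e-9) and is required by the
tests to reproduce the closed form to 1e-6 — the numeric route is what
generalizes if the objective ever becomes nonlinear. Negative contrasts
clamp to zero weight; if *no* feature has positive contrast the labeling
is declared non-separable and calibration fails loudly. The published
default weights (0.41, 0.50, 0.43, 0.34, 0.52) have Σλ² = 0.989 due to
rounding at two decimals; weight vectors therefore accept 2% slack on the
unit norm at construction, while freshly calibrated outputs satisfy it to
1e-6.

## Synthetic phenotypes

The generator emulates the four canonical morphologies as point processes,
not as a mechanistic simulation: there is no Potts model, ECM, division or
motility here. All sampling is dart-throwing with a minimum-separation
constraint (10⁵ attempts per point before an explicit packing error) and a
mandatory seed; identical parameters and seed reproduce clouds bit for
bit.

- *spherical*: 2000 cells uniform in a 120 μm ball at ≥10 μm separation.
  The bulk radius sits below D_crit = 125 μm so the phenotype carries no
  gaslike cells by construction (a 150 μm bulk of 2000 cells at this
  separation has sparse surface pockets whose cells exceed both
  thresholds, which would contaminate the "no gaslikes" reference
  behavior).
- *spherical_far_gaslikes*: the bulk minus 50 cells, plus a 50-cell halo
  at radii 175–350 μm (uniform in shell volume), each halo cell kept
  farther than ~25 μm from every other cell so it is genuinely detached.
- *deformed*: the bulk plus four contiguous radial chains (12 μm spacing,
  5 μm perpendicular jitter, ~100 μm long), emulating invasion strands;
  chain spacing is below d_crit so strands count as attached bulk.
- *disordered*: 2000 cells through a 350 μm ball at ≥25 μm separation;
  ~95% of cells end up beyond both thresholds and the bulk dissolves into
  small clusters.

What the generator does **not** emulate: cell-density gradients, true
surface roughness statistics, anisotropic invasion along fibers,
imaging artifacts (missed nuclei, z-compression), or cell division.
Passing tests on these fixtures therefore demonstrate the correctness and
the invariance/monotonicity/separation behavior of the *pipeline*, not
biological fidelity of any particular spheroid model.

## Transformation study

Five controlled families probe the score: rotation (Rodrigues, about the
centroid), translation, uncentered uniform noise α·U[0,1]³ per cell (the
mean drift is harmless under translation invariance), a radial ripple
α·ê_r·(cos ωφ + sin ωθ) with θ the polar angle from +z and φ ∈ [0, 2π)
(the angle convention is a fixed choice; it changes the ripple pattern but
not the monotonicity being tested; default ω = 6), and a radial scaling
α·(r/r_ref)·r̂ with r_ref defaulting to the 95th-percentile radius. The
literal form α·‖P‖·P has units μm² and no neutral point; the r_ref
normalization is what makes α a dimensionless scale factor ≈ 1 at
identity. Because the map is quadratic in r, the identity holds only at
r = r_ref, so the deviation minimum sits slightly below α = 1 on a
symmetric grid. Rotation and translation leave the density, gaslike and
Voronoi distances at machine zero (asserted ≤ 1e-9) and the surface
distances within voxelization tolerance (2% relative area, 0.02
Wasserstein on deformation); noise and ripple grids are monotone in
deviation up to core breakdown. At this geometry the ripple never
destroys the core (cells remain in a connected thick shell even at
amplitudes ≫ the bulk radius), so the cut regime is exercised with heavy
noise instead.

## Problem sizes and numerics

Tests and the acceptance script run the study conditions directly: 4
phenotypes × 5 replicates of ~2000-cell clouds for calibration and an
independent 20-cloud panel for separation, chosen because a full panel
extracts in well under a minute. Tolerances: Voronoi conservation 1e-6
relative (exact by construction up to float summation); optimizer vs
closed form 1e-6; perfect-sphere deformation 1e-6; Wasserstein vs LP
oracle 1e-7 absolute. Degenerate inputs are errors, not NaNs: empty
clouds, coplanar tessellations, empty/full grids, zero-spread features,
non-separable labelings and infeasible packings all raise typed
exceptions naming the offending quantity.

## Known limitations

- Single time point only; no velocity or growth features.
- One cell type; no per-type decomposition of any feature.
- The centroid-based center is biased by strongly asymmetric halos.
- The voxel surface is resolution-limited; areas of sub-voxel structure
  (isolated cells) are systematically low by ~20%.
- The disordered phenotype's surface features describe per-cluster
  surfaces, not a bulk; they are kept for completeness but are less
  interpretable there.
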