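# Methods

`ccmorph` implements a surface-based morphometry pipeline for elongated,
tube-like neuroanatomical structures, with the corpus callosum (CC) as the
motivating case: per-subject surfaces are brought into correspondence on a
cylindrical conformal grid, local deformation and thickness features are
extracted at every grid vertex, and groups are compared with a vertex-wise
multivariate statistic under permutation inference.  Because real CC
meshes derive from clinical MRI and are not redistributable, the package
ships a synthetic-cohort generator with known ground truth; every claim
the test suite makes is a claim about recovery of that ground truth.

## Synthetic cohorts

A subject is a triangulated tube swept along a C-shaped medial curve in
the sagittal (x–z) plane.  Defaults are callosum-scale: chord length
70 mm, arch height 25 mm, radius 2–4 mm with thicker genu (arclength
fraction t ≈ 0.12) and splenium (t ≈ 0.88) and a thin isthmus
(t ≈ 0.55).  Cross-sections are mildly elliptic (radius factor
1 + 0.15 cos 2θ), wider than tall, as the callosal cross-section is.
Sweep frames are parallel-transported (rotation-minimizing), not Frenet,
so the circumferential coordinate does not flip on straight segments.
The sweep refuses radii exceeding 95% of the local radius of curvature
(self-intersection).

Between-subject variability has three components, each seeded:

* **Radial noise** (default sd 0.2 mm): white noise on a coarse 8×4
  (t, θ) grid, bilinearly upsampled and renormalized by the interpolation
  weight norm so every sample keeps the nominal marginal sd while the
  field stays spatially smooth.  This emulates smooth anatomical shape
  variation rather than meshing noise.
* **Global scale jitter**: isotropic factor exp(N(0, 0.05²)).
* **Rigid jitter**: rotation up to 5°, translation up to 2 mm per axis.

Group effects, applied to group B only inside a window [t_lo, t_hi]:

* **Radius effect**: radius × (1 + δ) with cosine-tapered edges (taper
  width 0.03, below the default grid-row spacing, so the transition stays
  within the window-dilation used by the localization analyses).
* **Tangential shear**: the elliptic cross-section is twisted by
  α(t) = shear·sin²(π(t−t_lo)/(t_hi−t_lo)), rotating the section shape
  along the tube.  A twist of a *circular* tube would be geometrically
  invisible (the swept point set is unchanged — for the same reason a
  pure reparameterization of t cannot serve as a shear effect), so the
  non-circular section is what makes this a genuine tangent-plane shear
  with near-unit area change, the kind of change the deformation tensor
  is sensitive to and det J is not.

Generated vertices are snapped to single precision before use, matching
the PLY files on disk, so a cohort is bitwise reproducible from
(config, seed); per-subject seeds derive from the global seed by SHA-256.

What the generator does **not** emulate: segmentation and meshing
artifacts, partial-volume boundary noise, non-rigid residuals of
template registration, topological defects, or age-structured covariance
between subjects.  Passing tests therefore demonstrate correctness and
calibration of the machinery under smooth, well-posed shape variation,
not robustness to real segmentation pipelines.

## Parameterization

Each mesh must be a connected orientable surface with exactly two open
boundary loops (cylinder topology).  Landmarks are the extreme vertices
of each boundary loop along the first principal axis of the vertex cloud
(axis sign fixed from loop centroids, ties to the lowest vertex index),
and the tube is cut open along the shortest interior edge path between
them, duplicating the path vertices to yield a topological disk.

Harmonic coordinates use cotangent-weight discrete Laplacians solved as
sparse linear systems: u on the *uncut* mesh with u = 0/1 on the two
boundary loops (so both seam copies carry identical u), v on the cut mesh
with v = 0/1 on the seam copies and natural conditions on the end arcs.
Accepted solves must have an interior Laplace residual below 1e-8
relative to the mean diagonal weight, and no flipped parameter triangles;
if flips occur (possible with negative cotangent weights on poor
triangles), the solver falls back to a uniform-weight Tutte embedding
with the whole boundary pinned to the unit square, which is injective by
construction.  On all synthetic fixtures the cotangent map is used and
has zero flips.

**Grid placement.**  The harmonic map supplies the bijection to the
square, but grid nodes are *not* taken at the uniform harmonic lattice.
Two empirical artifacts motivated this design:

1. A localized thickness change alters the conformal modulus, which
   redistributes the harmonic coordinate *globally*; sampled at uniform
   harmonic u, every vertex of an affected subject moves relative to the
   template and the deformation features flag the entire surface instead
   of the effect region.
2. The shortest-path seam route wanders by ~±10° of circumference under
   shape noise; with v anchored at the seam, this rotates the whole v
   labeling per subject and (via the elliptic section) contaminates
   every row.

Grid rows are therefore placed at uniform arclength fractions of the
recovered medial axis, grid columns at uniform circumferential arclength
within each iso-u ring, and v = 0 is anchored at an intrinsic direction:
the in-plane component of the vector from the axis-endpoint chord toward
the mid-axis point (the "arch up" direction), which is rigid-motion
equivariant and independent of the seam route.  Nearly straight tubes
(no apex direction) keep the seam anchor.  Grid positions are obtained
by locating each (u, v) node in the parameter triangulation and
barycentric interpolation; nodes falling in numerical gaps use a logged
nearest-triangle fallback, with more than 1% of fallbacks treated as an
error.  Default grid: 64 rows × 16 columns, which resolves the five
Hofer–Frahm subregions along the tube while keeping permutation testing
fast.

The per-cohort template is the vertex-wise mean of the reference group's
grids after generalized rigid (Kabsch, no scaling) alignment, iterated
three times; no scaling, so genuine size differences survive in the
template-relative Jacobians.

## Features

On each grid cell (two triangles per quad, v periodic) the 2×2 Jacobian
of the template→subject correspondence is J = [target edges][source
edges]⁻¹ with both triangles expressed in their own orthonormal tangent
frames (first axis along the v2−v1 edge).  det J > 1 means local area
expansion relative to the template; det J ≤ 0 anywhere is treated as a
folded correspondence and is an error.  The deformation (Cauchy–Green)
tensor S = (JᵀJ)^{1/2} and log S are computed by symmetric
eigendecomposition with an eigenvalue floor of 1e-12; the mTBM feature is
the 3-vector (log S₁₁, log S₁₂, log S₂₂), invariant to rigid motions of
either surface.  Per-triangle values are area-weighted averaged onto grid
vertices (template areas as weights) so that all features live per
vertex.

The medial axis is the arclength-weighted centroid of each closed iso-u
ring — arclength weighting because the conformal grid samples curved
rings angularly unevenly and the plain vertex mean is biased off-centre
(up to 5% MAD error at the rims).  MAD(u, v) is the Euclidean distance
from grid vertex to its row's medial point, in mm.  The combined
MADMTBM feature is the 4-vector [log S (3), MAD]; a log-MAD variant is
available behind the `log_mad` switch (default off: raw millimetres,
which keeps the ratio-map reading direct).

Noise-free recovery: row-mean MAD matches the generator's radius profile
to better than 2% everywhere and interior vertices individually to 2%;
the two rows at each rim reach ~5% (conformal corner bunching at the
seam endpoints plus chord interpolation), a known discretization limit.

## Group statistics

At each vertex the statistic is the Mahalanobis form of the two-sample
Hotelling T²,

    M = (N_S·N_T/(N_S+N_T)) · (S̄−T̄)ᵀ Σ⁻¹ (S̄−T̄),

with Σ the pooled unbiased covariance.  The plain solve is used whenever
Σ is regular — this makes M agree with the textbook statistic to
machine precision — and a ridge of 1e-8·tr(Σ)/d·I is added only if the
solve fails.  Statistics below 1e-12 are snapped to zero so identical
group means tie exactly under permutation.

Inference is purely by permutation (no F-distribution): B random label
reassignments (default 1000 in tests; 10,000 mirrors common practice for
final maps), the same reassignment applied at every vertex to preserve
the spatial dependence of the maps, p = (1 + #{M_b ≥ M_obs})/(1 + B).
Multiple comparisons are handled by a second, map-level permutation: the
suprathreshold count C = #{vertices with p < α_vertex} of the observed
labeling is ranked within the counts of the permuted labelings, each
scored against the same shared pool of B+1 labelings (rank-based, so the
whole double loop costs one M-matrix of shape (B+1) × V).  Corrected
p = (1 + #{C_b ≥ C_obs})/(1 + B).  A max-statistic FWER variant is
available via `correction="max"`.  Direction of change is reported as
ratio maps of group means (older/B over younger/A) for the scalar
features det J and MAD, values > 1 meaning expansion or thickening.

Measured calibration on null cohorts (no effect): pooled per-vertex
rejection ≈ 4.5% at α = 0.05 over 10 replicate cohorts, omnibus
rejection ≈ 4% over 100 replicate cohorts at B = 199.  On radius-effect
cohorts (δ = 0.2 on t ∈ [0.3, 0.5], noise 0.2 mm, n = 30/group) the
window-mean MAD ratio recovers 1.19–1.21 and ≈ 90% of MAD-significant
vertices fall inside the dilated effect window on average; single
cohorts fluctuate considerably because the smooth anatomical noise
produces spatially correlated chance differences, which is why the
acceptance analyses average over replicate cohorts.  On combined
thickness+shear effects the 4-vector MADMTBM flags more suprathreshold
vertices than det J alone in every tested replicate — the combined
feature's higher detection power is reproduced as a simulation property
at these settings, not claimed as a theorem.

## Problem sizes and numerical choices

Simulation-based analyses use deliberately modest sizes chosen for a
desktop workflow: effect cohorts n = 30/group on the 64×16 grid with
B = 999; calibration cohorts n = 15/group (vertex level, B = 999) and
n = 8/group (omnibus level, B = 199, 100 replicates); power comparisons
n = 15/group on a 32×8 grid with B = 499.  Degenerate inputs are
rejected loudly rather than repaired: non-cylinder topology,
self-intersecting sweeps, degenerate triangles (area ≤ 1e-12 mm²),
folded correspondences, singular pooled covariances with fewer than
d + 2 subjects.  Tie-breaks are always deterministic (lowest vertex
index; add-one p-values; SHA-256 seed splitting), and every pipeline
artifact is hashed into a bundle manifest so re-runs can be verified
byte for byte.

## Known limitations

* The parameterization is harmonic, not genuinely conformal in the
  holomorphic one-form sense; for cylinder topology the two coincide up
  to the modulus, and the topological outputs (bijective square
  parameterization with matched seam) are the same.
* Arclength-based grid placement trades the conformal grid's
  angle-preservation for cross-subject stability; features computed on
  the pure harmonic lattice are available via `row_spacing="harmonic"`.
* MAD at the two rows adjacent to each rim is biased low by a few
  percent (discretization); analyses that care should discard end rows.
* The medial axis is the ring-centroid curve, valid for star-shaped
  cross-sections; strongly bent or branching structures would need a
  true medial-surface method.
* No covariate adjustment (e.g. brain size, continuous age): groups are
  compared as labeled bins.
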