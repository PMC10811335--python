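# Methods

`vessel4d` reconstructs a cardiac cycle's worth of 3D vessel surface meshes
— all sharing one connectivity matrix — from a multi-phase, mixed-resolution
stack of CT-like volumes.  This note records the models, the parameters that
matter, the numerical choices, and the limits of what the synthetic tests
demonstrate.

## Problem setting

ECG-gated coronary CT angiography yields one high-resolution, low-noise
volume at the diastolic rest phase plus a sequence of low-resolution volumes
covering the cycle (10–100% of the R–R interval in 10% steps), with X-ray
dose — and therefore noise — modulated over the cycle.  CFD simulation of
blood flow in the moving vessel needs a surface mesh per time point, and
mesh-morphing solvers additionally require that every mesh share the same
connectivity so only node positions change over time.  The package's core
contract is exactly that invariant: one connectivity matrix, carried
bit-identically through every phase and every interpolated time.

## Coordinate conventions

All physical coordinates are ITK-style LPS millimetres; NIfTI I/O converts
RAS↔LPS at the boundary (negate x and y).  Indices are 0-based, ordered
(x, y, z), voxel centers.  Mixing LPS and RAS silently is the classic
failure mode when several imaging toolkits share a workflow, so the
conversion exists in exactly one module (`geometry`) and every other module
works in LPS only.

## Segmentation: threshold-seeded geodesic active contour

The contour is the zero level set of φ (negative inside), evolved by
`φ_t = −(α·S)·|∇φ| + β·κ·|∇φ|` with Godunov upwinding for the advection
term, central differences for the mean curvature κ = div(∇φ/|∇φ|), and all
spatial derivatives taken in physical mm (slice thickness ≠ pixel spacing in
both acquisitions, so voxel-unit stencils would bias the front).

* `threshold` mode (default): S = clamp((I − 166 HU)/20 HU, −1, 1) — region
  competition against a contrast threshold; 166 HU separates contrast-filled
  lumen (≈350 HU) from tissue (≈50 HU).
* `gradient` mode: the edge-stopping function g = 1/(1 + (NGM/v)^λ) of the
  Gaussian-smoothed (σ = 1 voxel), max-normalized gradient magnitude;
  defaults v = 0.1, λ = 2.

Force weights default to α = 0.95, β = 0.2.  The time step is auto-CFL
(`dt = 0.9·h_min/(6·max|F|)`, with κ clamped to ±1/h_min); a user-forced
larger step raises an error rather than silently destabilising.  φ is
redistanced (Euclidean distance transform) every 20 iterations.  The update
runs on the bounding box of {S > 0} plus the seed spheres (8-voxel pad): the
front cannot advance where S ≤ 0, so this is an exact restriction, not an
approximation.  Seeds are spheres of ≥ ~1.5 voxels radius; sub-voxel seeds
die under the curvature force because an upwind scheme cannot deepen a local
minimum.

## Surface extraction and smoothing

Marching cubes (topology-resolving case table) on the optionally
pre-smoothed occupancy at iso 0.5, vertices mapped to physical mm, largest
connected component kept.  Smoothing is Taubin's shrink-resistant
λ/µ = 0.5/−0.53 pair with a uniform-weight graph Laplacian; the faces array
of the output is the *same array object* as the input's — the topology
invariant is enforced structurally, not by convention.

STL round-trips weld coincident vertices (1e-6 mm) and renumber them by
first occurrence in the triangle soup, so meshes exported with identical
connectivity read back with bit-identical face arrays regardless of vertex
positions.

## Registration: rigid → affine → diffeomorphic demons

All stages register *segmented masks*, not raw volumes: a thin bright
vessel contributes almost nothing to a whole-volume intensity metric, and
the package's own comparison (noisy 90% phase) shows mask-based chains beat
raw-intensity ones by ~0.3 Dice.  Stages:

1. **Rigid (6-DOF)** and **affine (12-DOF)**: mean-squared error on
   Gaussian-smoothed (σ = 1 voxel) mask renditions, cropped to the
   foreground bounding box; 3-level pyramid; gradient-descent line search;
   centroid initialization.  Each stage is guarded never to return a
   transform worse (under an explicitly resampled MSE) than its
   initialization.
2. **Deformable**: diffeomorphic demons (exponential/scaling-and-squaring
   field updates, symmetric gradient forces) over a 4-level pyramid.  The
   force images are clamped (±5 mm) signed-distance maps of the masks:
   distance gradients extend the capture range far beyond the one-voxel
   boundary shell of a tube 1–2 voxels across, which smoothed binary masks
   cannot provide.  The working grid is the moving grid upsampled 2×,
   because a radial-expansion field across a 2–4 voxel tube is sub-grid at
   native resolution.  Field smoothing 1.5 and update smoothing 1.0
   working-grid voxels; iterations (50, 40, 30, 60) coarse→fine.

The product per phase is one affine plus one dense displacement field whose
point map sends reference-space points to phase space, `p ↦ A(p) + u(A(p))`
— the two artifacts mesh propagation needs.  A field whose Jacobian
determinant is not positive at every interior voxel is rejected.

Before registration the pipeline clips all masks to a common
proximal→distal sub-segment (defaults: 2 mm from the proximal end, 16 mm
from the distal end).  The distal millimetre-scale portion of the vessel
segments unreliably in the noisy phases, and inconsistent vessel ends are
the dominant corruption mode of the deformable stage.

## Propagation and temporal interpolation

Reference-mesh vertices are pushed through each chain; faces are shared by
reference and all outputs (same array).  Arbitrary cycle times come from
vertex-wise linear interpolation between the bracketing phases, cyclic at
100% → first phase.  Degenerate triangles after warping raise warnings, not
errors.  Linear interpolation is a deliberate simplification; higher-order
schemes are out of scope.

## Validation machinery

Cross-sections are extracted by plane–triangle intersection (per-triangle
segment, endpoints computed from the sorted vertex pair so shared edges
produce bit-identical points; exact on-plane vertices nudged by 1e-9 to the
positive side) and chained into loops.  Contour overlap is computed on
rasterized polygons (0.05 mm pixels, even-odd fill); refinement by 2×
changes measured areas by <0.5%, which bounds the rasterization error.
Jaccard and Dice obey `JAC = DICE/(2−DICE)` to 1e-9 by construction.
"Centered" variants translate each polygon's *area* centroid to the origin
before rasterizing, separating cross-section shape error from position
error.  When a cut yields several loops, the loop whose centroid is nearest
the reference's is compared.  The oscillatory shear index is
`0.5·(1 − |∫WSS dt| / ∫|WSS| dt)` with trapezoid quadrature at the series'
native sampling.

Mesh-interior voxelization (for mesh-vs-mask Dice) cuts the mesh slice by
slice through voxel centers and fills the loops as polygons — no
ray-casting dependency.

## The synthetic phantom

The phantom emulates the study conditions: ten phases at 10–100%, a
high-resolution reference grid (0.4/0.4/0.6 mm, 192×192×120) at a 67%
diastolic phase with low noise (SD 10 HU), low-resolution phase grids
(0.8125/0.8125/1.5 mm, 96×96×60), and additive Gaussian noise whose SD is
U-shaped over the cycle (13–16 HU at 30–70%, 40–52 HU near full diastole).
Grid extents are desk-scale (reduced field of view at the true spacings) so
an end-to-end run takes minutes.

The vessel is a curved tube extruded along z: centerline
`c_t(z) = (x_c + B_x sin πζ, y_c + B_y(t) sin πζ, z)` with
`B_y(t) = 4 + 2.5 sin(2πt/100)` mm, radius tapering 2.0 → 0.8 mm
proximal→distal times a lumen scale `1 + 0.08 cos(2πt/100)`.  These
amplitudes give phase-to-phase wall excursions of up to ~4 mm and lumen
area changes of ~±16%, representative of a coronary segment over the cycle;
the distal end is deliberately at the resolution limit of the low-res grid
(diameter ≈ 2 in-plane pixels, matching the "thin arteries of ≈1.6 mm"
regime where single-pixel errors are ~25% of the diameter).  Voxel values
are 3×-supersampled partial-volume blends of lumen (350 HU), a tissue
sleeve (50 HU), and background (−50 HU).

Because the family is closed-form, exact ground truth is available
everywhere: masks, surfaces, per-phase displacement maps
(`p ↦ c_t(z) + ρ(p_xy − c_ref(z))`, an exact diffeomorphism with in-plane
Jacobian ρ² > 0), and plane sections (boundary points solved to 1e-12 mm by
root-finding on the tube-boundary function — note the extruded tube's
section perpendicular to a tilted centerline stretch is *not* a circle of
the nominal radius, and the oracle accounts for that exactly).

What the phantom does **not** emulate: beam hardening/blooming, motion
artifacts within a gate, bifurcations (a flag exists but defaults off),
non-Gaussian or spatially correlated noise, and surrounding anatomy
(chambers, bones) that makes raw-intensity registration harder on real
data.  Passing phantom tests therefore demonstrates the machinery's
correctness and its behaviour under the stated noise/resolution conditions,
not clinical-grade robustness.

## Known limitations

* **Tangential correspondence is unobservable.**  Mask-driven registration
  constrains motion normal to the vessel wall; sliding along the wall is
  recovered only through field smoothness.  Bulk-motion-scale warps
  (~100 mm wavelength, 2 mm amplitude) are recovered to ~0.75 mm mean
  surface error (< 1 low-res voxel); warps with wavelength comparable to
  the vessel length degrade to ~1.0–1.3 mm, and point maps to far-away
  phases can carry millimetre-scale tangential drift even when the surfaces
  coincide (overlap metrics stay high).  This is inherent to registering
  shapes rather than textured volumes.
* **Radial bias of propagated surfaces.**  Registered chains under-recover
  ~half of the large (~10%) lumen-scale changes at phases far from the
  reference, leaving propagated cross-sections systematically ~5–8% thin in
  radius at those phases.  End-to-end mesh-vs-truth Dice stays at
  0.88–0.90; per-phase cross-section areas from *registered* chains are
  accurate to ~10–20%, while the propagation/cutting machinery itself is
  area-accurate to ~1.5% (verified with exact fields).
* **Vessel ends.**  Segmentation truncates the distal sub-resolution
  portion inconsistently across noisy phases; the pipeline clips to a
  common segment, so the reconstructed dynamic model covers the reliable
  segment only.
* The summarizer's 2-decimal means use exact decimal arithmetic with
  half-up rounding, matching how printed tables round; float banker's
  rounding differs at ties.
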