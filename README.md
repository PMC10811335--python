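# vessel4d

Constant-topology 4D surface reconstruction of blood vessels from
multi-phase, mixed-resolution 3D image volumes.

Blood-flow (CFD) simulation in coronary arteries usually assumes a static
vessel because building a moving geometry is hard: ECG-gated CT delivers one
high-resolution volume at the diastolic rest phase and ten noisier,
low-resolution volumes across the cardiac cycle, and a mesh-morphing CFD
solver additionally needs every time step's surface mesh to share a single
connectivity matrix.  `vessel4d` implements that reconstruction chain for
researchers working on patient-specific hemodynamics:

1. **Segmentation** — threshold-seeded 3D active contour (level set),
   `φ_t = −α S |∇φ| + β κ |∇φ|`, with the region-competition speed
   `S = clamp((I − 166 HU)/20, −1, 1)` and defaults α = 0.95, β = 0.2;
2. **Surface** — marching cubes + shrink-resistant Taubin smoothing of the
   high-resolution reference phase;
3. **Registration** — per phase, rigid → affine → diffeomorphic demons on
   the segmented masks, producing an affine `A` and a dense displacement
   field `u` with positive Jacobian determinant;
4. **Propagation** — reference-mesh vertices pushed through
   `p ↦ A(p) + u(A(p))` for every phase; the connectivity matrix is stored
   once and shared bit-identically by every output mesh, and meshes at
   arbitrary cycle times come from cyclic linear interpolation;
5. **Validation** — plane–mesh cross-sections compared to reference contours
   by rasterized Jaccard/Dice (`JAC = DICE/(2−DICE)`), plain and after
   aligning centers of gravity; ROI noise statistics; the oscillatory shear
   index `OSI = ½(1 − |∫WSS dt| / ∫|WSS| dt)`.

A fully synthetic dynamic-vessel phantom (curved tube, ten phases,
paper-true voxel spacings, U-shaped noise schedule, closed-form ground
truth for masks/surfaces/displacements/cross-sections) drives all
quantitative tests.

## Worked example

```python
from vessel4d.pipeline import PipelineConfig, run_pipeline

manifest = run_pipeline(PipelineConfig(out_dir="demo_run", seed=1))
print(manifest["stages"]["propagate"]["topology_hash"][:12])
print(manifest["summary"])
```

This generates the phantom acquisition (1 high-res + 10 low-res NIfTI
volumes with ground truth), segments all eleven volumes, extracts and
smooths the reference surface, registers reference → each phase, propagates
the mesh (10 STL files with one shared topology hash), and validates
cross-sections against the phantom's exact contours.  With `seed=1` it
prints a metric summary like

```
jac                0.86 +/- 0.07  (n=100)
dice               0.92 +/- 0.04  (n=100)
jac_centered       0.88 +/- 0.07  (n=100)
dice_centered      0.93 +/- 0.04  (n=100)
centroid_offset    0.08 +/- 0.05  (n=100)
```

i.e. the propagated and per-phase-segmented cross-sections overlap the true
vessel sections at Jaccard ≈ 0.86 / Dice ≈ 0.92 across 5 planes × 10 phases
× 2 model sources, improving slightly when the contours are centered —
vessel cross-section *shape* is reproduced a bit better than its exact
*position*, and the mean in-plane centroid error is ≈ 0.1 mm.  Voxelizing
each propagated mesh against the phantom truth mask gives Dice 0.88–0.91
per phase, and every deformation field is a diffeomorphism (minimum
Jacobian determinant ≈ 0.47 > 0).

The same stages are scriptable from the shell:

```sh
vessel4d run --seed 1 --out demo_run
vessel4d interp --sequence demo_run/sequence --at 65 --out phase65.stl
vessel4d summarize --metrics demo_run/metrics.csv
```

Packaged example data (`vessel4d.datasets`) provides published expert-
validation overlap tables for a left-coronary surface model: 18 cutting
planes for the high-resolution reference model (means JAC 0.76 / DICE 0.86)
and a 12-row per-phase table comparing segmentation against
registration-propagated contours, plain and centered.

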