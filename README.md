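# rbr — recursive boundary registration

Topology-preserving non-linear registration of a cortical grey–white
boundary mesh to a geometrically distorted functional volume.

## The problem

Laminar (layer-resolved) fMRI needs the cortical surface reconstruction —
made on an undistorted anatomical scan — to sit on the grey–white boundary
of the *functional* EPI volume with sub-millimetre accuracy.  B0
inhomogeneity warps EPI geometry by several millimetres along the
phase-encoding axis, and the warp is non-linear, so a single affine
registration cannot fix it.  Cross-contrast non-linear volume registration
is notoriously fragile; this package instead deforms the *mesh*, using only
the intensity gradient across the boundary, and guarantees that the
deformed surface remains a topological sphere — a hard requirement for
downstream level-set cortical layering.

## The method

**Boundary-based registration (BBR).**  For vertex *i* with outward unit
normal **n**ᵢ, the volume is sampled at ±*p* mm along the normal, giving
inner (white) and outer (grey) intensities *w*ᵢ, *g*ᵢ and the percent
contrast Qᵢ = 100 (gᵢ − wᵢ) / (½(gᵢ + wᵢ)).  The cost

  J = (1/N) Σᵢ wᵢ (1 + tanh(M (Qᵢ − Q₀)/2))

is minimal when every vertex straddles a correctly-signed intensity step;
a constrained affine (any subset of translation / rotation / scale, about
the region centroid) is fitted by Nelder–Mead simplex.

**Recursion on an octree lattice.**  The registration bounding box is
recursively split into 2ᵈ×2ᵈ×2ᵈ cuboids.  Each cuboid's vertex set — plus
six half-splits of it, for robustness — is registered independently; every
accepted transform deposits a displacement vector at the cuboid's eight
corner control points (shared with its neighbours).  Per control point the
componentwise **median** of all candidates is taken, then relaxed toward the
6-connected neighbour mean, **d** ← α **d** + (1 − α) M(**x**), with α = 0.9
favouring local specificity.  Regions with too few vertices, or whose best
fit does not materially lower the cost, default to "no change".

**Continuous, topology-preserving warp.**  Each cuboid is split into six
tetrahedra along a globally consistent main diagonal (Kuhn subdivision), so
adjacent cuboids triangulate their shared face identically.  With four
corners per tetrahedron the affine satisfying **D** = **T V** is exactly
determined, and the resulting piecewise-affine warp is globally continuous:
vertices move, faces never change, and the Euler characteristic is
preserved wherever the per-cell Jacobians stay positive (logged).

The package also ships a synthetic gold-standard generator (gyrified-sphere
phantom, rendered tissue volume, smooth cubic-root-tapered displacement
fields) and the matching quality metrics (signed residual histograms with
KDE-based FWHM, average absolute distance, noise-robustness curves).

## Worked example

Register a distorted phantom surface back to its rendered volume:

```python
import numpy as np
import rbr

phantom = rbr.PhantomSpec(subdivisions=5, seed=0)          # 10242-vertex gyrified sphere
distortion = rbr.DistortionSpec(target_mean_abs=2.56, seed=1)
gs = rbr.make_gold_standard(phantom, distortion)

# quarter the vertex count of the full experiment -> quarter the per-region threshold
cfg = rbr.RbrConfig.for_noiseless_contrast(phantom.voxel_size, min_vertices=25)
model = rbr.RecursiveBoundaryRegistration(gs.volume, gs.distorted, cfg)
res = model.fit()

print(res.summary())
before = rbr.displacement_report(gs.truth, gs.distorted, axis="y")
after = res.displacement_report(reference=gs.truth, axis="y")
print(f"distorted : mean |dy| = {np.abs(before.signed).mean():.2f} mm, FWHM = {before.fwhm:.2f} mm")
print(f"registered: mean dy = {after.mean:+.3f} mm, FWHM = {after.fwhm:.2f} mm")
```

which prints:

```
             Recursive Boundary Registration Results
==================================================================
No. vertices:                    10242
No. faces:                       20480
Volume shape / voxel mm:      (79, 79, 79)  (0.90, 0.90, 0.90)
DoF:                             ty+sy
alpha:                            0.90
Linear init cost:               0.4244 -> 0.1933
------------------------------------------------------------------
depth  cells fitted  ident  nconv  negJ  mean|d| mm
    2     64     51      5     96     0      0.6977
    2     64     48      8    186     0      0.0418
    3    512    158    114    593     0      0.0819
    3    512    158    114    210     0      0.1879
    3    512    158    107    101     0      0.1112
------------------------------------------------------------------
Topology (out):           euler=2, closed=True
Total movement (AAD mm):        2.4143
==================================================================
distorted : mean |dy| = 2.56 mm, FWHM = 1.48 mm
registered: mean dy = -0.026 mm, FWHM = 0.30 mm
```

The surface started 2.56 mm from the truth on average; after registration
the signed residual histogram is a sharp zero-centred peak (no bias, FWHM
0.30 mm), the face array is untouched and the mesh is still a closed
topological sphere.

The same pipeline is available from the shell:

```bash
rbr simulate --out-dir work/                 # phantom volume + true/distorted surfaces
rbr register --volume work/volume.nii.gz --surface work/surface_distorted.white \
             --out-surface work/registered.white --log work/run.json
rbr evaluate --surface-a work/surface_true.white --surface-b work/registered.white
rbr noise-curve --volume work/volume.nii.gz --surface work/surface_distorted.white \
             --levels 0,5,10,20,40,80 --out work/noise.csv
```

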