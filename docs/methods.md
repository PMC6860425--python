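# Methods

This note documents the model, the numerical choices, and what the
synthetic validation does and does not show.  It states no number that the
test suite or `scripts/acceptance.py` does not itself compute.

## Registration model

The registration estimates a displacement field for a triangulated
grey–white boundary surface so that it matches the tissue step in a target
intensity volume, without resampling the volume and without changing the
mesh connectivity.

**Cost.** Per vertex, the volume is sampled (trilinear interpolation) at
±p mm along the outward vertex normal; the percent contrast
Q = 100 (g − w)/(½(g + w)) is passed through 1 + tanh(M (Q − Q₀)/2) and
averaged.  `contrast_sign` selects which side is expected brighter
(+1 for T2\*-like targets where grey > white; −1 for T1-like).  The cost
uses only the gradient across the boundary, so absolute intensity scaling
of the volume is irrelevant.  It is bounded in [0, 2] with unit weights.

**Local fits.** Each region's constrained affine (default: translation and
scale along the phase-encoding axis y, scaling about the region centroid)
is found with a Nelder–Mead simplex.  The initial simplex is deterministic
(0.5 mm translation steps, 0.02 scale and radian steps); parameter
tolerance is 1e-4.  The *function* tolerance is 1e-8, far below the 1e-4 a
generic optimizer would use: near the optimum the cost varies by only
~1e-4 per 0.1 mm (the signal carried by partial-volume vertices), and a
coarse function tolerance would terminate the search on arrival.

**Acceptance threshold for a fit.** A region's transform is applied only if
it lowers the cost by at least `min_cost_improvement` (default 1e-4).  On
an already-registered noiseless phantom the best achievable "gains" are
≲2e-6 — pure discretisation bias and flat-valley optimizer drift — while
genuine misregistration yields gains of 1e-3 to 1e-1, three decades above
the threshold.  Regions below the threshold, with too few vertices
(`min_vertices`, default 100), or with non-finite costs default to the
identity: low-information territory does not move.

**Lattice and warp.** At depth d the registration box is split into 8^d
cuboids; each cuboid's full vertex set plus its six half-splits are fitted
independently and deposit displacement vectors at the cuboid's eight corner
control points.  Control points shared between cuboids are stored once;
per point the componentwise median of its candidates is taken
(candidate-order invariant; one gross outlier among several consistent
fits is ignored), then a single synchronous relaxation
d ← α d + (1 − α)·(mean of 6-connected neighbours) with α = 0.9.  Cuboids
*containing* vertices but producing no accepted fit vote zero ("no
change"); cuboids containing *no* vertices cast no vote at all — their
zeros would otherwise dilute the median at the outward corner points of
every surface-crossing cuboid by up to a factor of two and shear the
correction across the cell.  Control points that receive no candidates
resolve to zero displacement.

Each cuboid is subdivided into six tetrahedra sharing the main diagonal
(Kuhn subdivision, identical orientation in all cells), so adjacent cells
triangulate their shared faces identically and the per-tetrahedron affines
— exactly determined by the four corner displacements — agree on shared
faces.  The warp is therefore globally continuous; vertices are mapped by
their containing tetrahedron's affine.  Tetrahedron membership uses the
descending coordinate order of the point within its unit cell; ties lie on
shared faces where both candidate affines coincide.  Negative Jacobian
determinants (possible only under extreme displacement gradients) are
counted and reported as topology risks; none occur in the shipped
experiments, and the deformed meshes keep Euler characteristic 2.

**Recursion order.** The default driver runs one pass per depth from d = 0
until a cuboid edge would span fewer than `min_voxel_size` voxels (default
4).  `RbrConfig.pass_plan` allows explicit (depth, projection) sequences;
`projection_schedule` sets per-depth projection distances.

## Projection distances: capture vs precision

With noiseless data the partial-volume band around the boundary (halfwidth
≈ 0.45–0.8 voxel depending on how obliquely the normal crosses the voxel
grid) is the only source of sub-voxel information.  A vertex contributes
gradient only while a sample sits inside that band, i.e. for residuals
roughly within (p − t, p + t) of zero.  Long projections therefore give
capture range for multi-millimetre residuals but are blind (and, near
curved fold crests or a thin grey shell, biased) at sub-voxel scale; short
projections are precise but near-sighted.  `RbrConfig.for_noiseless_contrast`
encodes the resulting coarse-to-fine ladder: a global axis-matched linear
fit at 1.55 voxels, two passes at quarter-box cuboids (depth 2), then
three passes at depth 3 with projections descending 1.55 → 1.25 → 1.05
voxels.  Two constraints cap the rungs: projection + band must stay inside
the grey shell (≈3 mm), or the opposite-signed grey/CSF gradient drags the
fit inward; and projections should not be shorter than about one voxel, or
the inner sample never reaches pure white for normal-aligned vertices.

Depths 0–1 are deliberately not fitted non-linearly in this configuration:
their cuboids are much larger than the displacement field's structure, so
per-cell affine fits extrapolate steep local slopes to corners up to 15 mm
from the vertex centroid, and the median then blends incompatible
extrapolations.  Even *oracle* transforms (least-squares fits to the known
true residuals) widen the residual distribution when pushed through a
depth-1 lattice.  The global linear fit supplies the same capture without
corner extrapolation.

## Saturation slope

The tanh slope M plays the role of a robust-statistics clipping constant:
it should place typical contrasts inside the sensitive zone
(M·Q ~ O(1)).  The library default M = 0.5 matches the original boundary
cost, tuned for in-vivo contrasts of tens of percent *with noise*.  The
rendered phantom has Q ≈ 100 and no noise; at M = 0.5 the cost is then
saturated to machine precision (tanh(25)) and exactly flat within about a
voxel of the optimum — sub-voxel registration is impossible, and the
"perfect contrast is easy" intuition fails.  The synthetic-experiment
configuration uses M = 0.03 (M·Q ≈ 3), recovering a smooth mean-contrast
regime.  On noisy data the larger default is preferable; parameter
selection per dataset is expected with this family of methods.

## Linear initialisation

`init_dof` is "rigid" (6 DoF) by default, with "affine9" and "dof"
(axis-matched to the local fits) available.  For a distortion known to lie
along one axis, axis-matched initialisation matters: a free rotation can
lower the boundary cost by sliding a smooth surface tangentially along
itself — invisible to any boundary-based cost — while adding out-of-axis
vertex error that axis-restricted local fits can never remove.  This is
one instance of the general aperture limitation discussed below.

## Synthetic gold standard

`make_phantom` builds a gyrified sphere
r(u) = R + A sin(f uₓ) sin(f u_y) sin(f u_z) (star-shaped, hence free of
self-intersections, Euler characteristic 2) and renders white (50), a grey
shell (150, 3 mm) and CSF (80) on a 0.9 mm grid, with the white/grey step
passing exactly through the surface; optional seeded Gaussian noise.
Defaults: R = 28 mm, A = 1.2 mm, f = 14.  The fold wavelength (~12.6 mm)
puts folds inside every depth-2 cuboid so that every local fit sees normals
at many orientations — on a fold-free sphere, patches with normals
perpendicular to y carry no information about y displacement.  The fold
amplitude keeps crest curvature radii near 3 mm, comparable to gyral
crowns; much sharper crests put the boundary's own curvature inside the
sampling projection and bias the contrast optimum.

`make_distortion` interpolates seeded Gaussian control values (default
spacing 60 mm — a couple of lobes across the phantom, mirroring the
smoothness of a B0 field over a head) over the volume, applies a signed
cubic root (pushing displacement mass away from zero into the
characteristic bimodal distribution of a tapered voxel displacement map),
and rescales so the mean |displacement| over the mesh vertices hits the
target (default 2.56 mm).  The cube root has unbounded slope at zero
crossings of the underlying field; the thin slabs around those crossings
contain displacement structure that *no* smooth lattice can invert, and
they dominate the tails of the recovered residual distribution.

What the phantom does not emulate: measurement noise (the validation is
noiseless by design; a separate noise-robustness curve salts the volume),
realistic sulcal geometry (the perturbed sphere cannot produce deep narrow
sulci or buried opposing banks, where the grey/CSF and grey/white
gradients can be confused), receive-field bias, and dropout.  Passing the
recovery test therefore demonstrates the correctness and resolution of the
machinery under ideal contrast, not in-vivo robustness.

## Known limitations

- Vertex-wise recovery is only identifiable up to displacements that slide
  the surface along itself (the aperture problem); fold texture pins this
  down, smooth patches do not.  Part of any reported residual is this
  invisible tangential component.
- Accuracy is bounded by the finest depth at which cuboids still hold
  `min_vertices` vertices; for the 40962-vertex phantom that is depth 3
  (≈7.5 mm cuboids), so displacement structure below ~4 mm wavelength is
  out of reach.
- The tetrahedral subdivision is orientation-asymmetric; a small residual
  directional bias is inherent to the scheme.
- The identity fallback means severely low-contrast regions are left
  untouched rather than extrapolated; this is intentional.

## Experiment sizes

The shipped validation uses a 40962-vertex phantom (subdivision-6
icosphere) on a ~80³ voxel grid for the headline recovery experiment, and
2562-vertex phantoms for the identity-stability and noise-robustness
suites.  These sizes keep the full test suite and the acceptance script in
the minutes range on a single CPU while leaving every mechanism of the
method exercised at full fidelity.
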