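# Methods

This note documents the models, numerical choices, and limitations behind
`grouptemplate`, in the order data flows through the package.

## Coordinate conventions

Everything spatial is expressed in world micrometres with (x, y, z) axis
order. A grid with `origin` and `spacing` places voxel index k at
`origin + k·spacing` (0-based, voxel centres). Scalar arrays are stored
`values[ix, iy, iz]`; displacement fields as `vectors[c, ix, iy, iz]` with
c indexing the world components of u in μm.

Transforms follow the **pull-back** convention throughout: a registration
result maps fixed-image world coordinates into moving-image world
coordinates, and images are resampled by evaluating the moving image at
φ(x) = x + u(x). Points and skeletons travel the opposite way — through the
inverse of each component — so a skeleton follows its image into template
space. This is the single most error-prone convention in registration
tooling, so it is fixed once here and every interface states it. A
`CompositeTransform` applies its components left-to-right; composition
`compose(outer, inner)` therefore concatenates `inner + outer`.

Out-of-bounds behaviour: image resampling fills with a constant (default 0,
the dark background of cleared-tissue confocal data); displacement fields
are edge-clamped when sampled outside their grid, and transported points
that leave a field's grid are flagged per point rather than dropped.

## On-disk formats

NRRD I/O goes through SimpleITK, NIfTI through nibabel (which also serves
as an independent header check in the tests). SWC is the standard 7-column
text format with coordinates interpreted as world μm. A NRRD header that
declares no spacing yields 1.0 μm/voxel with an explicit warning, never
silently.

Displacement fields are stored in an HDF5 layout that is normative for this
package: group `/dfield/{level}` holds a dataset `data` ordered
(component, z, y, x) with attributes `spacing`, `origin` and — when
quantized — `quantization_multiplier` m, with int16 payload q = round(u/m),
m = max|u|/32766. The reconstruction error is bounded by m/2, e.g. ≤ 0.15 nm
for a 10 μm field; the bound is asserted property-style in the tests. Level
L+1 is level L block-averaged 2× per axis with spacing doubled and origin
shifted half an (old) voxel so block centres stay geometrically honest.
Datasets are written with `track_times` off so identical inputs produce
byte-identical files. No attempt is made to be bit-compatible with other
multiscale field containers.

## Pairwise registration backend

The internal backend exists so the groupwise loop and evaluation pipeline
run without external binaries; externally computed fields can be substituted
via the manifest's `transform_path` column.

**Preprocessing.** Both images are Gaussian-smoothed (`presmooth_sigma`,
default 1× mean voxel spacing) and *then* linearly rescaled to [0, 1]. The
order matters: normalising first lets noise extremes set the range, which
leaves the two images with mismatched background levels that a deformable
stage then tries to "fix" geometrically. With 5% intensity noise the
smoothing is what keeps the demons force locked on anatomy instead of noise.

**Affine stage.** Rigid (6), similarity (7: + log-scale) or full affine
(12) parameters about the fixed grid's world centre, optimised with
Powell's derivative-free method on a scale-normalised parameter vector,
coarse-to-fine over a Gaussian-smoothed subsampling pyramid. SSD and
negative NCC metrics are available; the groupwise and evaluation defaults
use NCC on the coarse levels only, because with a dominant dark background
SSD admits a degenerate minimum that shrinks the content out of the frame
(observed in development as determinants near 3). The solution is compared
against identity at full resolution and the worse of the two is discarded,
so the stage can never actively hurt.

**Elastic stage.** A demons-type iteration on the fixed grid. With
M_w = M(init(x + u(x))) and spacing s (level mean):

    f = −(M_w − F) ∇M_w / (‖∇M_w‖² + (M_w − F)²/s²)
    u ← G_total ∗ (u + step · (G_update ∗ f))

The s² normalisation gives the force length units and bounds each step by
s/2; update-field smoothing (default σ = 2× spacing) acts like viscosity,
total-field smoothing (default σ = 1× spacing) like elasticity. Defaults:
pyramid (4, 2, 1), iterations (100, 100, 50), step 1.0. Because the
regularised iteration is not SSD-monotone step-to-step, each pyramid level
keeps the best-SSD field it saw; a level that fails to improve warns, and a
final full-resolution guard returns the zero field rather than a result
worse than its initialisation. Division is guarded by ε = 10⁻¹².

On the default phantom (3 μm RMS deformations, 8 μm smoothness, 5% noise)
the recovered field is within ~1 μm of the truth inside the anatomy, versus
~2–3 μm for no registration; recovery degrades gracefully with noise and
with deformation magnitude approaching the smoothness scale.

## Groupwise template construction

Each iteration: register all images (affine, then elastic) to the current
template; average the warped intensities; average the per-subject *total*
displacement fields with the affine folded in (the literature is silent on
affine handling during transform averaging — folding makes the
inverse-mean step exact); push the averaged intensities through the inverse
of `step_scale` × the mean field. The inverse is computed by fixed-point
iteration v ← −u(x + v) (tolerance 0.01 μm, ≤ 100 sweeps), which converges
for fields that are small relative to their smoothness and reports its
composition residual.

Symmetrization appends an exact voxel mirror of every image (nearest
-neighbour flip about the grid's world mid-plane), doubling the cohort. Two
details matter in practice:

- Working-resolution copies must be resampled on a **centre-preserving**
  grid; a corner-anchored grid shifts the mid-plane half a voxel and
  silently destroys flip-pair symmetry (measured: 0.21 relative L1
  asymmetry instead of 0.003 at 2 μm working spacing).
- The mean displacement field of a flip-paired cohort is mirror-
  antisymmetric in its normal component, so the symmetrized update cannot
  drift the template off the mid-plane.

Convergence is a fixed iteration count (default 4) in keeping with
script-driven template builds; per-iteration diagnostics (mean SSD, mean
|u|, max |mean field|, mirror residual) let users judge. The averaged
intensities are a plain mean — no sharpening. When a working resolution is
set, the loop runs on downsampled copies and the final template is rendered
by warping the native-resolution inputs with the final transforms and
averaging — the same downsample-then-render-at-native strategy used for
real cohort builds, where it has been found not to affect template quality
appreciably. Scaled-down runs here use 2 μm working spacing on 1 μm
phantoms for the same reason.

A cohort of identical images is a fixed point up to registration noise
(verified to ~10⁻³ relative); a cohort of two oppositely translated copies
leaves the template in place (mean field < 0.01 μm after averaging).

## Neuron skeletonization

The neuron channel is masked by direction-selective local thresholding:
the maximum, over cylinder radii (default 2, 6, 10 voxels) and orientations
(default the 13 axis/face-diagonal/body-diagonal directions of the voxel
cube; other counts use a Fibonacci half-sphere), of the image convolved
with a unit-sum cylindrical mean kernel of radius r and length 4r. The
kernel length and orientation set are a faithful-in-spirit reconstruction —
the original filter's exact parameters are not published — and kernels are
built in voxel space because the filter is applied to raw tiles. The
default threshold is Otsu on the response image; note that for very sparse
tubular content Otsu under-thresholds (the halo of the largest kernels
pulls the split point down), in which case the geometrically meaningful
threshold is half the tube-interior response — the response value exactly
at a tube boundary. On a radius-3-voxel tube at SNR 5 that threshold gives
recall 0.98 / precision 0.90.

The mask is thinned to one-voxel centerlines (Lee's 3D thinning via
scikit-image), and the 26-connected voxel graph is converted to SWC trees:
one tree per connected component, rooted at a minimum-degree voxel
(endpoint), breadth-first spanning tree, cycle edges broken and counted in
the log. Node radii default to half the mean voxel spacing — thinning
destroys calibre information, and no radius estimation is attempted.

## Skeleton distance

The directed measure d(A→B): rasterize both skeletons onto a common
isotropic bounding grid (default 0.5 μm/px, padded 1 voxel; degenerate
boxes padded 10 voxels per side), take the Euclidean distance transform of
B's raster, and read it at every raster voxel of A. SWC *edges* are
rasterized at half-voxel steps, not just nodes, so sparse node spacing
cannot fake low distances. Statistics are pooled over every sample of every
ordered pair — a permutation enumeration within each line group, so groups
of sizes (11, 3, 3, 3) give 128 directed comparisons — rather than
averaging per-pair means; population (not sample) SD is used, an
indistinguishable choice at the tens of millions of samples this pooling
produces. The measure only sees displacement perpendicular to the skeleton
and assumes nearest-point correspondence, so it underestimates true
registration error; it is used as a *comparative* score, for which the
self-distance identity d(A, A) = 0, translation invariance, and its strict
decrease after deformable registration on phantoms are the relevant
guarantees. A normalizing bridge transform (to put all templates at one
scale/shape) is accepted but user-supplied; without one, distances are in
raw template space and a caveat is logged.

## Deformation metrics

Jacobian determinant det(I + ∇u) and the full second-derivative tensor of
φ are computed with spacing-aware central differences (one-sided at
borders); default masks exclude the one-voxel border to keep one-sided
stencils out of the statistics. JSD is the population SD of the
determinant; the companion mean is reported because it should sit near 1.0
for honest registrations (global scale lives in the affine, which is
deliberately excluded — the evaluation pipeline hands these functions the
deformable component only). HFM is the mean Frobenius norm over all 27
second partials, reported in μm⁻¹. For a 3D similarity with linear scale s
the determinant is s³ — the *cube* of the scale, the mathematically correct
statement even where informal descriptions say "equal to its scale" — and
both JSD and HFM vanish for any affine field; both facts are asserted to
tight tolerances. Smoothing a field lowers both metrics monotonically,
matching the observation that strongly regularized algorithms score lower
JSD.

## Synthetic phantoms

The generator provides every pipeline a test surface with known truth. The
mean "brain" is a sum of smooth ellipsoidal compartments, made exactly
mirror-symmetric by construction; "neurons" are persistent random walks
confined to the foreground, rendered as tubes (default radius 2 μm) into a
second channel and returned as SWC. Subjects are drawn as
smoothed-white-noise displacement fields (Gaussian smoothness default 8 μm,
vector RMS default 3 μm — small enough that default registration parameters
succeed, large enough that registration is necessary) composed with a small
random similarity whose magnitude scales with the deformation amplitude
(identity at amplitude 0), plus 5% Gaussian intensity noise. Fields are
drawn independently per subject, so the population mean deformation shrinks
as 1/√N — the zero-mean property that makes "the template should recover
the true mean" a testable statement. Skeletons are transported with the
*exact* truth transform rather than re-derived, so skeleton-distance tests
isolate registration error from skeletonization error; end-to-end tests
that re-skeletonize can be built from the DSLT + thinning operations
directly.

Default cohort: 96×96×48 voxels at 1 μm/px, six subjects — a full build in
minutes on one CPU. Reduced problem sizes elsewhere in the tests (48³- and
64³-scale grids, four-subject evaluation cohorts) are chosen the same way:
the smallest cohorts on which the property under test is meaningfully
exercised.

What the phantoms do **not** model: point-spread anisotropy, tiling and
stitching artifacts, lens distortion, chromatic aberration, intensity
inhomogeneity, anatomical outliers, or sexual dimorphism. Passing phantom
tests therefore demonstrates correctness of the algorithms under controlled
deformation and noise, not performance on real acquisitions.

## Known limitations

- The internal registration backend is deliberately plain (Powell + demons
  with Gaussian regularisation). It is the test vehicle, not a competitor
  to production registration suites; real studies should import externally
  computed transforms where quality matters.
- Field inversion by fixed-point iteration assumes displacements small
  relative to their smoothness; strongly folded fields will report large
  composition residuals (warned, never silent).
- Otsu's threshold on DSLT responses is unreliable for very sparse tubular
  content (see above).
- The evaluation pipeline computes distances in raw template space unless a
  normalizing bridge is supplied; cross-template comparisons without one
  conflate template scale with registration error.
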