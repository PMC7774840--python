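# grouptemplate

Unbiased, left-right-symmetric anatomical templates from cohorts of 3D
microscopy volumes, and quantitative evaluation of how well individuals
register to them. The package targets the workflow used for modern
*Drosophila* brain and ventral-nerve-cord atlases — dozens of
confocal-imaged individuals averaged by groupwise registration — but the
machinery is generic for any 3D scalar imagery with physical voxel spacing.

## What it computes

**Template construction (groupwise registration).** Starting from the plain
voxelwise average of the unregistered cohort, each iteration registers every
image *I_i* to the current template *T*, producing pull-back transforms
φ_i = x + u_i(x) (template space → subject space), then updates

&nbsp;&nbsp;&nbsp;&nbsp;Ī = (1/N) Σ I_i ∘ φ_i,&nbsp;&nbsp;&nbsp;
ū = (1/N) Σ u_i,&nbsp;&nbsp;&nbsp;
T ← Ī ∘ (x + ū)⁻¹.

Because the averaged intensities are pushed back through the inverse mean
transform, the template converges to the cohort's mean *shape* as well as
mean intensity — no single subject biases it. Mirroring every image about
the mid-sagittal plane and including both copies makes the limit
left-right symmetric.

**Registration accuracy (skeleton distance).** Neurons from an independent
image channel are skeletonized (direction-selective local thresholding +
3D thinning → SWC). For two individuals carrying the same neurons,
both skeletons are transported into template space, rasterized at 0.5 μm/px,
and one skeleton's Euclidean distance transform is read at every raster
point of the other. Pooling the per-point distances over all ordered
within-line pairs gives a mean (SD) in μm — small distances mean the
registration overlays the same anatomy accurately.

**Deformation measures.** From the deformable component u of a transform
(never the affine part):

- **JSD** — standard deviation over space of the Jacobian determinant
  det(I + ∇u). Spread, not mean: it captures simultaneous local shrinking
  and stretching; the mean only reflects global scale and stays ≈ 1.
- **HFM** — mean Frobenius norm of the full second-derivative tensor of the
  map (μm⁻¹); zero for any affine map, it measures how *quickly* the
  transform varies over space.
- **Jacobian difference maps** between two transforms localize where one
  deforms space more than the other (e.g. male vs. female template
  comparisons).

**Supporting machinery.** NRRD/NIfTI volume I/O with world-coordinate
conventions, SWC skeletons, a multiscale int16-quantized HDF5 format for
displacement fields, transform composition/inversion/application to
images, points and skeletons, an internal affine + elastic (demons-style)
registration backend, and a synthetic phantom generator that produces
cohorts with known ground-truth transforms and tubular "neurons".

## Worked example

Build a symmetric template from four phantom subjects (each a smooth random
3 μm deformation of a known mean shape) and check it recovers the truth:

```python
import warnings; warnings.simplefilter("ignore")
from grouptemplate import (
    PhantomSpec, make_mean_brain, make_subject,
    TemplateConfig, build_template, initial_template, symmetrize_cohort,
)
from grouptemplate.groupwise import mirror_residual

spec = PhantomSpec(grid_shape=(64, 64, 32), n_subjects=4, seed=0)
mean = make_mean_brain(spec)
cohort = [make_subject(mean, spec, seed=100 + i).reference
          for i in range(spec.n_subjects)]

config = TemplateConfig(iterations=2, symmetrize=True, working_spacing=2.0)
result = build_template(cohort, config)

def ssd(v):
    return float(((v.values - mean.reference.values) ** 2).mean())

unregistered = initial_template(symmetrize_cohort(cohort, "x"), cohort[0])
print(f"SSD to true mean shape:")
print(f"  built template      {ssd(result.template):.5f}")
print(f"  unregistered average {ssd(unregistered):.5f}")
print(f"  best single subject  {min(ssd(c) for c in cohort):.5f}")
print(f"mirror-symmetry residual: {mirror_residual(result.template, 'x'):.4f}")
```

Output (about two minutes on one CPU):

```
SSD to true mean shape:
  built template      0.00222
  unregistered average 0.00355
  best single subject  0.01774
mirror-symmetry residual: 0.0487
```

The built template is closer to the true mean than the blurry unregistered
average and far closer than any individual — the unbiasedness the
register–average–invert iteration is designed to deliver — and the
flip-symmetrized cohort leaves under 5% relative L1 asymmetry.

The same pipeline is scriptable from the shell:

```sh
grouptemplate synth population --out pop/ --subjects 4 --seed 0
grouptemplate template build --cohort "pop/sub-00_reference.nrrd" \
    --cohort "pop/sub-01_reference.nrrd" --iterations 2 --symmetrize \
    --work-res 2.0 --out template.nrrd
grouptemplate evaluate --manifest pop/manifest.csv \
    --template pop/mean_reference.nrrd --out report/
grouptemplate metrics summary --dfield pop/sub-00_truth.h5
```

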