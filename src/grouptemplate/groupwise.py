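"""Unbiased symmetric template construction by groupwise registration.

The estimate starts from the plain voxelwise average of the unregistered
cohort. Each iteration then (1) registers every cohort image to the current
template (affine stage then elastic stage), (2) warps the images into
template space and averages them, (3) averages the per-subject total
displacement fields (affine components folded into the field), and
(4) pushes the averaged intensities through the inverse of the mean
transformation. Iterating transports the template toward the cohort's mean
intensity *and* mean shape, so no single subject biases the result.

Left-right symmetry is obtained the same way as in mouse common-coordinate
atlases: every input is mirrored about the mid-sagittal plane and both the
original and the flipped copy join the cohort, doubling the effective image
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Literal, Sequence

import numpy as np

from .core_io import (
    AffineTransform,
    CompositeTransform,
    DisplacementField,
    Volume,
)
from .registration import RegistrationParams, register_affine, register_deformable
from .transforms import (
    affine_to_dfield,
    apply_to_image,
    invert_dfield,
    mirror_transform,
    total_displacement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateResult",
    "TemplateConfig",
    "symmetrize_cohort",
    "initial_template",
    "groupwise_iteration",
    "build_template",
    "mirror_residual",
]


@dataclass
class TemplateResult:
    """Converged template plus per-subject pull-back transforms and diagnostics.

    ``subject_transforms[i]`` maps template world space into subject i's world
    space (one entry per cohort image, including flipped copies).
    ``diagnostics`` has one dict per iteration: mean_metric (mean SSD of the
    warped images against the template), mean_abs_u (mean |total displacement|
    in um), max_mean_field (max |voxelwise mean displacement| in um).
    """

    template: Volume
    subject_transforms: list
    diagnostics: list


def default_affine_params() -> RegistrationParams:
    """Affine-stage defaults: NCC metric (robust to the dominant dark
    background, which admits degenerate SSD minima) on the coarse pyramid
    levels only — the elastic stage owns the fine level."""
    return RegistrationParams(
        pyramid_factors=(4, 2), iterations_per_level=(60, 30), metric="ncc"
    )


@dataclass
class TemplateConfig:
    iterations: int = 4
    params: RegistrationParams = dc_field(default_factory=RegistrationParams)
    affine_params: RegistrationParams = dc_field(default_factory=default_affine_params)
    affine_model: Literal["rigid", "similarity", "affine"] = "similarity"
    symmetrize: bool = True
    axis: Literal["x", "y", "z"] = "x"
    working_spacing: float | None = None  # um/px isotropic; None = native
    step_scale: float = 1.0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0 < self.step_scale <= 1.0):
            raise ValueError("step_scale must be in (0, 1]")


def symmetrize_cohort(
    cohort: Sequence[Volume], axis: str = "x", return_pairing: bool = False
):
    """Append a mirrored copy of every volume: N images in, 2N out.

    Output ordering is all originals followed by all flipped copies, so image
    ``N + i`` is the mirror of image ``i`` (the pairing). Flips are exact voxel
    reflections (mirror transform + nearest-neighbour resampling).
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    flipped = []
    for vol in cohort:
        m = mirror_transform(vol, axis)
        flipped.append(apply_to_image(vol, m, vol, interpolation="nearest"))
    out = list(cohort) + flipped
    if return_pairing:
        n = len(cohort)
        pairing = [(i, n + i) for i in range(n)]
        return out, pairing
    return out


def initial_template(cohort: Sequence[Volume], grid: Volume) -> Volume:
    """Voxelwise arithmetic mean of the cohort resampled onto ``grid``."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    acc = np.zeros(grid.shape, dtype=float)
    ident = AffineTransform.identity()
    for vol in cohort:
        acc += apply_to_image(vol, ident, grid).values
    return Volume(acc / len(cohort), grid.spacing.copy(), grid.origin.copy())


def groupwise_iteration(
    template: Volume,
    cohort: Sequence[Volume],
    params: RegistrationParams | None = None,
    step_scale: float = 1.0,
    affine_model: str = "similarity",
    affine_params: RegistrationParams | None = None,
):
    """One register-average-invert step; returns (new template, transforms).

    Every subject is registered to the template (affine then elastic, both
    pull-back template->subject), warped into template space, and averaged.
    The per-subject total displacement fields (affine folded in) are averaged
    voxelwise, and the averaged intensities are pushed through the inverse of
    ``step_scale`` times that mean field.
    """
    params = params or RegistrationParams()
    affine_params = affine_params or default_affine_params()
    transforms = []
    warped_sum = np.zeros(template.shape, dtype=float)
    mean_field = np.zeros((3, *template.shape))
    mean_metric = 0.0
    mean_abs_u = 0.0

    for i, subject in enumerate(cohort):
        try:
            aff = register_affine(template, subject, affine_params, model=affine_model)
            dfield = register_deformable(template, subject, init=aff, params=params)
        except Exception as e:
            raise RuntimeError(f"registration failed for cohort image {i}: {e}") from e
        t = CompositeTransform.of(dfield, aff)
        transforms.append(t)
        warped = apply_to_image(subject, t, template)
        warped_sum += warped.values
        mean_metric += float(np.mean((warped.values - template.values) ** 2))
        total = total_displacement(t, template)
        mean_field += total.vectors
        mean_abs_u += float(np.mean(np.linalg.norm(total.vectors, axis=0)))

    n = len(cohort)
    mean_intensity = template.like(warped_sum / n)
    mean_field /= n
    scaled = DisplacementField(
        step_scale * mean_field, template.spacing.copy(), template.origin.copy()
    )
    inv_mean = invert_dfield(scaled)
    new_template = apply_to_image(mean_intensity, inv_mean, template)
    diagnostics = {
        "mean_metric": mean_metric / n,
        "mean_abs_u": mean_abs_u / n,
        "max_mean_field": float(np.abs(mean_field).max()),
    }
    return new_template, transforms, diagnostics


def mirror_residual(template: Volume, axis: str = "x") -> float:
    """Relative L1 asymmetry ||T - flip(T)||_1 / ||T||_1."""
    m = mirror_transform(template, axis)
    flipped = apply_to_image(template, m, template, interpolation="nearest")
    denom = float(np.abs(template.values).sum())
    if denom == 0:
        return 0.0
    return float(np.abs(template.values - flipped.values).sum()) / denom


def _resample_iso(volume: Volume, spacing: float) -> Volume:
    """Resample to isotropic ``spacing`` um/px, preserving the world centre.

    Centre preservation matters for symmetrization: the mid-plane of the
    working grid must coincide with the mid-plane of the native grid, or
    mirrored image pairs stop being mirrors of each other after resampling.
    """
    lo, hi = volume.world_extent()
    shape = tuple(int(np.floor((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    center = (lo + hi) / 2.0
    origin = center - (np.array(shape) - 1) * spacing / 2.0
    grid = Volume(np.zeros(shape), np.full(3, spacing), origin)
    return apply_to_image(volume, AffineTransform.identity(), grid)


def build_template(cohort: Sequence[Volume], config: TemplateConfig | None = None) -> TemplateResult:
    """Full template build: symmetrize, iterate, render at native resolution.

    The groupwise loop optionally runs on working copies downsampled to
    ``config.working_spacing`` um/px isotropic; the final transforms are then
    applied to the full-resolution inputs and averaged to render the output
    template at native resolution.
    """
    config = config or TemplateConfig()
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    full_cohort = list(cohort)
    if config.symmetrize:
        full_cohort = symmetrize_cohort(full_cohort, config.axis)

    if config.working_spacing is not None:
        work_cohort = [_resample_iso(v, config.working_spacing) for v in full_cohort]
    else:
        work_cohort = full_cohort

    grid = work_cohort[0]
    template = initial_template(work_cohort, grid)
    diagnostics = []
    transforms = [CompositeTransform.identity() for _ in work_cohort]
    for it in range(config.iterations):
        template, transforms, diag = groupwise_iteration(
            template,
            work_cohort,
            params=config.params,
            step_scale=config.step_scale,
            affine_model=config.affine_model,
            affine_params=config.affine_params,
        )
        diag["iteration"] = it
        if config.symmetrize:
            diag["mirror_residual"] = mirror_residual(template, config.axis)
        diagnostics.append(diag)
        logger.info("groupwise iteration %d: %s", it, diag)

    if config.working_spacing is not None:
        # render at native resolution: warp full-res inputs with the final
        # transforms onto the first input's grid and average
        out_grid = full_cohort[0]
        acc = np.zeros(out_grid.shape, dtype=float)
        for vol, t in zip(full_cohort, transforms):
            acc += apply_to_image(vol, t, out_grid).values
        template = Volume(acc / len(full_cohort), out_grid.spacing.copy(), out_grid.origin.copy())

    return TemplateResult(template=template, subject_transforms=transforms, diagnostics=diagnostics)
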