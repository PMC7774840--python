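"""Jacobian- and Hessian-based deformation statistics of displacement fields.

Two complementary scalar summaries of how much a non-rigid transform
deforms space:

* **JSD** — the population standard deviation of the Jacobian determinant
  det(I + grad u) over the grid. A determinant of 1 preserves volume
  locally; the *spread* of the determinant captures simultaneous local
  stretching and shrinking, while its *mean* only reflects global scaling
  (and stays very near 1 for well-behaved registrations).
* **HFM** — the mean Frobenius norm of the full second-derivative tensor of
  the map phi = x + u (27 entries: 3 components x 3 x 3 second partials),
  in 1/um. It measures how quickly the transform changes over space: zero
  for any affine map, large where the deformation is locally non-linear.

Both are computed from displacement fields only — the deformable component
of a registration, never the affine part — so that global scale changes are
not mistaken for deformation.

Derivatives use central differences scaled by the physical spacing
(one-sided at grid borders); default masks exclude the one-voxel border to
avoid one-sided-stencil artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core_io import DisplacementField, Volume

__all__ = [
    "MetricsSummary",
    "JacobianStats",
    "jacobian_determinant_map",
    "jsd",
    "jacobian_stats",
    "hessian_frobenius_map",
    "hfm",
    "jacobian_difference_map",
    "interior_mask",
    "foreground_mask",
    "summarize_field",
]


@dataclass
class MetricsSummary:
    jsd: float
    jdet_mean: float
    hfm: float
    voxel_count: int
    mask_description: str

    def __post_init__(self):
        if self.jsd < 0 or self.hfm < 0:
            raise ValueError("jsd and hfm must be >= 0")
        if self.voxel_count <= 0:
            raise ValueError("voxel_count must be > 0")


class JacobianStats(NamedTuple):
    sd: float
    mean: float
    n: int


def _axis_coords(field: DisplacementField) -> list:
    return [
        field.origin[i] + field.spacing[i] * np.arange(field.grid_shape[i])
        for i in range(3)
    ]


def jacobian_determinant_map(field: DisplacementField) -> Volume:
    """det(I + grad u) per voxel; 1.0 means volume locally preserved."""
    if min(field.grid_shape) < 3:
        raise ValueError("grid must have at least 3 voxels per axis")
    coords = _axis_coords(field)
    # grad[c][a] = d u_c / d x_a
    J = np.empty((3, 3, *field.grid_shape))
    for c in range(3):
        g = np.gradient(field.vectors[c], *coords)
        for a in range(3):
            J[c, a] = g[a]
    for d in range(3):
        J[d, d] += 1.0
    det = (
        J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
        - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
        + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0])
    )
    return Volume(det, field.spacing.copy(), field.origin.copy())


def interior_mask(shape, border: int = 1) -> np.ndarray:
    """Boolean mask excluding ``border`` voxels on every face."""
    m = np.zeros(shape, dtype=bool)
    sl = tuple(slice(border, s - border) for s in shape)
    m[sl] = True
    return m


def foreground_mask(volume: Volume, border: int = 1) -> np.ndarray:
    """Otsu foreground of an intensity image intersected with the interior."""
    from skimage.filters import threshold_otsu

    thr = threshold_otsu(volume.values)
    return (volume.values > thr) & interior_mask(volume.shape, border)


def jacobian_stats(jdet: Volume, mask: np.ndarray | None = None) -> JacobianStats:
    """Population SD and mean of the Jacobian determinant inside the mask."""
    if mask is None:
        mask = np.ones(jdet.shape, dtype=bool)
    if mask.shape != jdet.shape:
        raise ValueError(f"mask shape {mask.shape} != map shape {jdet.shape}")
    vals = jdet.values[mask]
    if vals.size == 0:
        raise ValueError("mask is empty")
    return JacobianStats(sd=float(vals.std()), mean=float(vals.mean()), n=int(vals.size))


def jsd(jdet: Volume, mask: np.ndarray | None = None) -> float:
    """Standard deviation of the Jacobian determinant (the deformation score)."""
    return jacobian_stats(jdet, mask).sd


def hessian_frobenius_map(field: DisplacementField) -> Volume:
    """Frobenius norm (per voxel) of all 27 second partials of phi = x + u.

    The linear part of phi contributes nothing to second derivatives, so the
    second derivatives of u are those of phi. Units: 1/um.
    """
    if min(field.grid_shape) < 3:
        raise ValueError("grid must have at least 3 voxels per axis")
    coords = _axis_coords(field)
    acc = np.zeros(field.grid_shape)
    for c in range(3):
        first = np.gradient(field.vectors[c], *coords)
        for a in range(3):
            second = np.gradient(first[a], *coords)
            for b in range(3):
                acc += second[b] ** 2
    return Volume(np.sqrt(acc), field.spacing.copy(), field.origin.copy())


def hfm(hmap: Volume, mask: np.ndarray | None = None) -> float:
    """Mean of the Hessian Frobenius-norm map inside the mask (1/um)."""
    if mask is None:
        mask = np.ones(hmap.shape, dtype=bool)
    if mask.shape != hmap.shape:
        raise ValueError(f"mask shape {mask.shape} != map shape {hmap.shape}")
    vals = hmap.values[mask]
    if vals.size == 0:
        raise ValueError("mask is empty")
    return float(vals.mean())


def jacobian_difference_map(
    transform_a: DisplacementField, transform_b: DisplacementField
) -> Volume:
    """Voxelwise difference of two Jacobian determinant maps (a - b).

    Positive values mark regions where transform a locally enlarges space
    relative to transform b — e.g. comparing male-to-unisex against
    female-to-unisex template transforms highlights sexually dimorphic
    anatomy.
    """
    if transform_a.grid_shape != transform_b.grid_shape:
        raise ValueError(
            f"grid mismatch: {transform_a.grid_shape} vs {transform_b.grid_shape}"
        )
    ja = jacobian_determinant_map(transform_a)
    jb = jacobian_determinant_map(transform_b)
    return Volume(ja.values - jb.values, ja.spacing, ja.origin)


def summarize_field(
    field: DisplacementField,
    mask: np.ndarray | None = None,
    mask_description: str | None = None,
) -> MetricsSummary:
    """JSD, mean Jacobian determinant, and HFM of one displacement field."""
    if mask is None:
        mask = interior_mask(field.grid_shape)
        mask_description = mask_description or "interior (1-voxel border excluded)"
    stats = jacobian_stats(jacobian_determinant_map(field), mask)
    h = hfm(hessian_frobenius_map(field), mask)
    return MetricsSummary(
        jsd=stats.sd,
        jdet_mean=stats.mean,
        hfm=h,
        voxel_count=stats.n,
        mask_description=mask_description or "custom mask",
    )
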