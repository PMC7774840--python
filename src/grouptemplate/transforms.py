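"""Applying, composing, inverting, and constructing spatial transforms.

Convention (fixed everywhere in this package): a registration transform is a
**pull-back** map from fixed-image world space into moving-image world space.
Images are resampled by evaluating the moving image at phi(x) for every fixed
voxel x; points and skeletons travel the other way, through the inverse of
each component, so that a skeleton follows its image into template space.

A :class:`~grouptemplate.core_io.CompositeTransform` applies its components
left-to-right: for components ``[c1, c2]`` the total map is x -> c2(c1(x)).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Literal

import numpy as np
from scipy import ndimage

from .core_io import (
    AffineTransform,
    CompositeTransform,
    DisplacementField,
    LabelVolume,
    Skeleton,
    Volume,
)

logger = logging.getLogger(__name__)

__all__ = [
    "sample_field",
    "transform_points_forward",
    "apply_to_image",
    "apply_to_labels",
    "apply_to_points",
    "apply_to_skeleton",
    "compose",
    "invert_dfield",
    "mirror_transform",
    "affine_to_dfield",
    "total_displacement",
]

_TransformLike = CompositeTransform | AffineTransform | DisplacementField


def _as_composite(t: _TransformLike) -> CompositeTransform:
    if isinstance(t, CompositeTransform):
        return t
    return CompositeTransform([t])


def sample_field(field: DisplacementField, points: np.ndarray) -> np.ndarray:
    """Linearly sample displacement vectors (um) at (n, 3) world points.

    Outside the field's grid the displacement is clamped to the edge value,
    giving a continuous extension.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    idx = (p - field.origin) / field.spacing  # (n, 3) fractional voxel indices
    coords = idx.T
    out = np.empty_like(p)
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(
            field.vectors[c], coords, order=1, mode="nearest"
        )
    return out


def _points_in_field_bounds(field: DisplacementField, points: np.ndarray) -> np.ndarray:
    lo = field.origin
    hi = field.origin + (np.array(field.grid_shape) - 1) * field.spacing
    p = np.atleast_2d(points)
    return np.all((p >= lo - 1e-9) & (p <= hi + 1e-9), axis=1)


def _apply_component(points: np.ndarray, comp) -> np.ndarray:
    if isinstance(comp, AffineTransform):
        return comp.apply(points)
    return points + sample_field(comp, points)


def transform_points_forward(
    points: np.ndarray, transform: _TransformLike
) -> np.ndarray:
    """Evaluate the transform (pull-back direction) at (n, 3) world points."""
    transform = _as_composite(transform)
    p = np.atleast_2d(np.asarray(points, dtype=float))
    for comp in transform.components:
        p = _apply_component(p, comp)
    return p


def apply_to_image(
    moving: Volume,
    transform: _TransformLike,
    out_grid: Volume | DisplacementField,
    interpolation: Literal["linear", "nearest"] = "linear",
    fill: float = 0.0,
) -> Volume:
    """Resample ``moving`` onto ``out_grid`` through a pull-back transform.

    Each output voxel at fixed-space world position x receives the moving
    image sampled at phi(x). Samples falling outside the moving image get
    ``fill`` (default 0, the dark background of cleared-tissue confocal data).
    """
    shape = out_grid.shape if isinstance(out_grid, Volume) else out_grid.grid_shape
    if np.prod(shape) == 0:
        raise ValueError("output grid has zero extent")
    coords = out_grid.coordinate_grid().reshape(3, -1).T  # (N, 3) world
    phi = transform_points_forward(coords, transform)
    idx = (phi - moving.origin) / moving.spacing
    order = 1 if interpolation == "linear" else 0
    values = ndimage.map_coordinates(
        moving.values, idx.T, order=order, mode="constant", cval=fill
    ).reshape(shape)
    spacing = out_grid.spacing
    origin = out_grid.origin
    return Volume(values, spacing.copy(), origin.copy())


def apply_to_labels(
    moving: LabelVolume,
    transform: _TransformLike,
    out_grid: Volume | DisplacementField,
) -> LabelVolume:
    """Resample a label volume; always nearest-neighbour so labels never blend."""
    vol = Volume(moving.labels.astype(np.int32), moving.spacing, moving.origin)
    out = apply_to_image(vol, transform, out_grid, interpolation="nearest", fill=0)
    return LabelVolume(np.rint(out.values).astype(np.int32), out.spacing, out.origin)


def apply_to_points(
    points: np.ndarray,
    transform: _TransformLike,
    direction: Literal["forward", "inverse"] = "forward",
    inversion_tol: float = 0.01,
    inversion_max_iter: int = 100,
    return_flags: bool = False,
):
    """Transport world points through a pull-back transform.

    direction="forward" moves points from moving space into fixed space, the
    way a skeleton follows its image into template space: every component is
    inverted (affines exactly, displacement fields via :func:`invert_dfield`)
    and applied in reverse order. direction="inverse" applies the pull-back
    map as-is (fixed -> moving).

    Points that leave a displacement-field grid are still transformed (the
    field is edge-clamped) but flagged out-of-bounds; with
    ``return_flags=True`` the per-point in-bounds mask is returned as well.
    """
    transform = _as_composite(transform)
    p = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    in_bounds = np.ones(p.shape[0], dtype=bool)

    if direction == "inverse":
        seq: Iterable = transform.components
        for comp in seq:
            if isinstance(comp, DisplacementField):
                in_bounds &= _points_in_field_bounds(comp, p)
            p = _apply_component(p, comp)
    elif direction == "forward":
        for comp in reversed(transform.components):
            if isinstance(comp, AffineTransform):
                p = comp.inverse().apply(p)
            else:
                inv, residual = invert_dfield(
                    comp,
                    max_iter=inversion_max_iter,
                    tol=inversion_tol,
                    full_output=True,
                )
                if residual > inversion_tol:
                    warnings.warn(
                        f"displacement-field inversion residual {residual:.4g} um "
                        f"exceeds tolerance {inversion_tol:g} um"
                    )
                in_bounds &= _points_in_field_bounds(comp, p)
                p = p + sample_field(inv, p)
    else:
        raise ValueError(f"unknown direction {direction!r}")

    if return_flags:
        return p, in_bounds
    return p


def apply_to_skeleton(
    skeleton: Skeleton,
    transform: _TransformLike,
    direction: Literal["forward", "inverse"] = "forward",
) -> Skeleton:
    """Transport all skeleton node positions; topology is untouched."""
    new_pos = apply_to_points(skeleton.positions, transform, direction=direction)
    return skeleton.with_positions(new_pos)


def compose(outer: _TransformLike, inner: _TransformLike) -> CompositeTransform:
    """Composite equal to applying ``inner`` first, then ``outer``."""
    outer = _as_composite(outer)
    inner = _as_composite(inner)
    return CompositeTransform(list(inner.components) + list(outer.components))


def invert_dfield(
    field: DisplacementField,
    max_iter: int = 100,
    tol: float = 0.01,
    full_output: bool = False,
):
    """Invert phi(x) = x + u(x) by fixed-point iteration.

    Iterates v_{k+1}(x) = -u(x + v_k(x)) from v_0 = -u, stopping when the
    largest update falls below ``tol`` (um) or after ``max_iter`` sweeps.
    Converges for fields of moderate magnitude relative to their smoothness
    (a contraction when the Jacobian of u has norm < 1).

    Returns the inverse displacement field; with ``full_output=True`` also
    the composition residual max_x |phi(phi^{-1}(x)) - x| in um.
    """
    coords = field.coordinate_grid().reshape(3, -1).T  # (N, 3)
    v = -field.vectors.reshape(3, -1).T  # (N, 3)
    for _ in range(max_iter):
        u_at = sample_field(field, coords + v)
        v_new = -u_at
        update = np.abs(v_new - v).max() if v.size else 0.0
        v = v_new
        if update < tol:
            break
    inv = DisplacementField(
        v.T.reshape(field.vectors.shape), field.spacing.copy(), field.origin.copy()
    )
    # residual of phi o phi^{-1} on the grid
    inv_pts = coords + v
    residual = float(np.abs(inv_pts + sample_field(field, inv_pts) - coords).max()) if v.size else 0.0
    if tol > 0 and residual > 10 * tol:
        warnings.warn(
            f"displacement-field inversion residual {residual:.4g} um exceeds "
            f"10 x tolerance ({tol:g} um); field may be non-invertible"
        )
    logger.debug("invert_dfield residual %.4g um", residual)
    if full_output:
        return inv, residual
    return inv


def mirror_transform(grid: Volume | DisplacementField, axis: str = "x") -> AffineTransform:
    """Reflection about the grid's world-space mid-plane on one axis.

    An involution: mirror o mirror = identity.
    """
    axis_idx = {"x": 0, "y": 1, "z": 2}[axis]
    shape = grid.shape if isinstance(grid, Volume) else grid.grid_shape
    center = grid.origin[axis_idx] + (shape[axis_idx] - 1) * grid.spacing[axis_idx] / 2.0
    matrix = np.eye(3)
    matrix[axis_idx, axis_idx] = -1.0
    translation = np.zeros(3)
    translation[axis_idx] = 2.0 * center
    return AffineTransform(matrix, translation)


def affine_to_dfield(
    affine: AffineTransform, grid: Volume | DisplacementField
) -> DisplacementField:
    """Sample u(x) = (A x + b) - x on the grid geometry."""
    coords = grid.coordinate_grid()  # (3, nx, ny, nz)
    flat = coords.reshape(3, -1).T
    u = affine.apply(flat) - flat
    shape = grid.shape if isinstance(grid, Volume) else grid.grid_shape
    return DisplacementField(
        u.T.reshape(3, *shape), grid.spacing.copy(), grid.origin.copy()
    )


def total_displacement(
    transform: _TransformLike, grid: Volume | DisplacementField
) -> DisplacementField:
    """Fold a whole composite into one displacement field on ``grid``:
    u(x) = phi(x) - x with phi the full left-to-right composition."""
    coords = grid.coordinate_grid()
    flat = coords.reshape(3, -1).T
    phi = transform_points_forward(flat, transform)
    shape = grid.shape if isinstance(grid, Volume) else grid.grid_shape
    return DisplacementField(
        (phi - flat).T.reshape(3, *shape), grid.spacing.copy(), grid.origin.copy()
    )
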