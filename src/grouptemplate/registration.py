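"""Internal pairwise registration backend: multiresolution affine + elastic.

This backend exists so the groupwise loop and the evaluation pipeline run
end-to-end with no external binaries. It is intentionally plain: an affine
stage (rigid / similarity / affine) minimising SSD or negative NCC with a
derivative-free optimiser, followed by a demons-style elastic stage with
Gaussian regularisation of both the update and the accumulated field.
Externally computed transforms can always be substituted through core_io.

All transforms returned are pull-back maps (fixed world -> moving world).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .core_io import AffineTransform, DisplacementField, Volume
from .transforms import apply_to_image, sample_field

logger = logging.getLogger(__name__)

__all__ = ["RegistrationParams", "register_affine", "register_deformable"]

_EPS = 1e-12  # guard for the demons force denominator


@dataclass
class RegistrationParams:
    """Knobs shared by the affine and deformable stages.

    pyramid_factors are voxel downsampling factors, coarse to fine, ending
    at 1 (full resolution). Smoothing sigmas are in um; ``None`` resolves to
    a multiple of the fixed image's mean spacing (2x for the update field,
    1x for the total field) at run time.
    """

    pyramid_factors: Sequence[int] = (4, 2, 1)
    iterations_per_level: Sequence[int] = (100, 100, 50)
    smooth_update_sigma: float | None = None
    smooth_total_sigma: float | None = None
    step: float = 1.0
    metric: Literal["ssd", "ncc"] = "ssd"
    presmooth_sigma: float | None = None  # um; None -> 1 x mean spacing

    def __post_init__(self):
        if len(self.pyramid_factors) != len(self.iterations_per_level):
            raise ValueError("pyramid_factors and iterations_per_level lengths differ")
        if any(f < 1 for f in self.pyramid_factors):
            raise ValueError("pyramid factors must be >= 1")
        if list(self.pyramid_factors) != sorted(self.pyramid_factors, reverse=True):
            raise ValueError("pyramid factors must be in descending order")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        for s in (self.smooth_update_sigma, self.smooth_total_sigma):
            if s is not None and s < 0:
                raise ValueError("smoothing sigmas must be >= 0")

    def resolved_sigmas(self, spacing: np.ndarray) -> tuple[float, float]:
        mean_sp = float(np.mean(spacing))
        update = self.smooth_update_sigma if self.smooth_update_sigma is not None else 2.0 * mean_sp
        total = self.smooth_total_sigma if self.smooth_total_sigma is not None else 1.0 * mean_sp
        return update, total

    def resolved_presmooth(self, spacing: np.ndarray) -> float:
        if self.presmooth_sigma is not None:
            return self.presmooth_sigma
        return float(np.mean(spacing))


def _rescale01(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < _EPS:
        return np.zeros_like(values, dtype=float)
    return (values.astype(float) - lo) / (hi - lo)


def _prepare(volume: Volume, params: "RegistrationParams") -> Volume:
    """Denoise with a small Gaussian, then normalise intensities to [0, 1].

    Smoothing must come first: noise extremes would otherwise set the
    normalisation range and leave the two images with mismatched background
    levels, which a deformable stage would try to fix geometrically.
    """
    values = volume.values.astype(float)
    sigma_um = params.resolved_presmooth(volume.spacing)
    if sigma_um > 0:
        values = ndimage.gaussian_filter(values, sigma=sigma_um / volume.spacing)
    return volume.like(_rescale01(values))


def _downsample(volume: Volume, factor: int) -> Volume:
    if factor == 1:
        return volume
    smoothed = ndimage.gaussian_filter(volume.values.astype(float), sigma=factor / 2.0)
    values = smoothed[::factor, ::factor, ::factor]
    return Volume(values, volume.spacing * factor, volume.origin.copy())


def _metric_value(kind: str, a: np.ndarray, b: np.ndarray) -> float:
    if kind == "ssd":
        return float(np.mean((a - b) ** 2))
    if kind == "ncc":
        a0 = a - a.mean()
        b0 = b - b.mean()
        denom = np.sqrt((a0**2).sum() * (b0**2).sum())
        if denom < _EPS:
            return 0.0
        return -float((a0 * b0).sum() / denom)
    raise ValueError(f"unknown metric {kind!r}")


# ---------------------------------------------------------------------------
# Affine stage
# ---------------------------------------------------------------------------
#
# Parameterisation (about the fixed grid's world centre c):
#   rigid       r (3 rotation, rad) + t (3 translation, um)
#   similarity  rigid + log-scale s
#   affine      12 raw entries: matrix deviation from identity + translation
# Transform: x -> exp(s) * R (x - c) + c + t  (pull-back).


def _params_to_affine(theta: np.ndarray, model: str, center: np.ndarray) -> AffineTransform:
    if model in ("rigid", "similarity"):
        R = Rotation.from_rotvec(theta[:3]).as_matrix()
        t = theta[3:6]
        scale = np.exp(theta[6]) if model == "similarity" else 1.0
        M = scale * R
        b = center + t - M @ center
        return AffineTransform(M, b)
    if model == "affine":
        M = np.eye(3) + theta[:9].reshape(3, 3)
        t = theta[9:12]
        b = center + t - M @ center
        return AffineTransform(M, b)
    raise ValueError(f"unknown model {model!r}")


def _n_params(model: str) -> int:
    return {"rigid": 6, "similarity": 7, "affine": 12}[model]


def _param_scales(model: str, extent: float) -> np.ndarray:
    # characteristic magnitudes: rotations ~0.1 rad, translations ~2% extent,
    # log-scale ~0.05, matrix entries ~0.05
    if model == "rigid":
        return np.array([0.1] * 3 + [0.02 * extent] * 3)
    if model == "similarity":
        return np.array([0.1] * 3 + [0.02 * extent] * 3 + [0.05])
    return np.array([0.05] * 9 + [0.02 * extent] * 3)


def register_affine(
    fixed: Volume,
    moving: Volume,
    params: RegistrationParams | None = None,
    model: Literal["rigid", "similarity", "affine"] = "affine",
) -> AffineTransform:
    """Multiresolution affine registration; returns a pull-back affine.

    The chosen metric is minimised coarse-to-fine with Powell's method on a
    normalised parameter vector. Guaranteed not to be worse than identity at
    full resolution (falls back to identity otherwise).
    """
    params = params or RegistrationParams()
    fixed_n = _prepare(fixed, params)
    moving_n = _prepare(moving, params)
    extent = float(np.max(fixed.world_extent()[1] - fixed.world_extent()[0]))
    center = fixed.world_extent().mean(axis=0)
    scales = _param_scales(model, extent)
    theta = np.zeros(_n_params(model))

    for factor, iters in zip(params.pyramid_factors, params.iterations_per_level):
        f_lvl = _downsample(fixed_n, factor)
        m_lvl = _downsample(moving_n, factor)

        def objective(z):
            aff = _params_to_affine(z * scales, model, center)
            warped = apply_to_image(m_lvl, aff, f_lvl)
            val = _metric_value(params.metric, f_lvl.values, warped.values)
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"non-finite metric at pyramid factor {factor}"
                )
            return val

        res = optimize.minimize(
            objective,
            theta / scales,
            method="Powell",
            options={"maxiter": iters, "xtol": 1e-4, "ftol": 1e-7},
        )
        theta = res.x * scales

    solution = _params_to_affine(theta, model, center)
    warped = apply_to_image(moving_n, solution, fixed_n)
    final = _metric_value(params.metric, fixed_n.values, warped.values)
    at_identity = _metric_value(
        params.metric,
        fixed_n.values,
        apply_to_image(moving_n, AffineTransform.identity(), fixed_n).values,
    )
    if final > at_identity:
        logger.warning(
            "affine registration (%s) worse than identity (%.4g > %.4g); "
            "returning identity",
            model,
            final,
            at_identity,
        )
        return AffineTransform.identity()
    return solution


# ---------------------------------------------------------------------------
# Deformable stage (demons-style elastic)
# ---------------------------------------------------------------------------


def _smooth_field(vectors: np.ndarray, sigma_um: float, spacing: np.ndarray) -> np.ndarray:
    if sigma_um <= 0:
        return vectors
    sig_vox = sigma_um / spacing
    out = np.empty_like(vectors)
    for c in range(3):
        out[c] = ndimage.gaussian_filter(vectors[c], sigma=sig_vox)
    return out


def _warp_moving(
    moving: Volume, u: np.ndarray, coords_flat: np.ndarray, init: AffineTransform, shape
) -> np.ndarray:
    """Sample moving at init(x + u(x)) for every fixed voxel x."""
    pts = coords_flat + u.reshape(3, -1).T
    pts = init.apply(pts)
    idx = (pts - moving.origin) / moving.spacing
    return ndimage.map_coordinates(
        moving.values, idx.T, order=1, mode="constant", cval=0.0
    ).reshape(shape)


def register_deformable(
    fixed: Volume,
    moving: Volume,
    init: AffineTransform | None = None,
    params: RegistrationParams | None = None,
) -> DisplacementField:
    """Demons-style elastic registration on the fixed grid.

    Starting from the affine pre-alignment ``init``, iterates the classic
    symmetric-denominator force (descent direction on SSD, normalised so the
    per-step displacement is bounded by half the voxel spacing)

        f = -(M_w - F) grad(M_w) / (|grad(M_w)|^2 + (M_w - F)^2 / s^2)

    where M_w = M(init(x + u(x))) and s is the level's mean voxel spacing,
    with Gaussian smoothing of the update field before accumulation
    (viscous-like) and of the total field after each step (elastic
    regularisation):

        u <- G_total * (u + step * (G_update * f))

    Within each pyramid level the best-SSD field seen is kept (the
    regularised iteration is not SSD-monotone step to step); a level that
    fails to improve on its starting SSD stops with a warning. The returned
    field is the deformable component only; the full pull-back transform is
    ``CompositeTransform.of(field, init)`` (field applied first). SSD at
    full resolution never increases relative to the initialisation.
    """
    params = params or RegistrationParams()
    init = init or AffineTransform.identity()
    fixed_n = _prepare(fixed, params)
    moving_n = _prepare(moving, params)

    u_prev: DisplacementField | None = None
    for factor, iters in zip(params.pyramid_factors, params.iterations_per_level):
        f_lvl = _downsample(fixed_n, factor)
        m_lvl = _downsample(moving_n, factor)
        shape = f_lvl.shape
        spacing = f_lvl.spacing
        sig_update, sig_total = params.resolved_sigmas(spacing)
        coords_flat = f_lvl.coordinate_grid().reshape(3, -1).T

        if u_prev is None:
            u = np.zeros((3, *shape))
        else:
            u = np.stack(
                [
                    sample_field(u_prev, coords_flat)[:, c].reshape(shape)
                    for c in range(3)
                ]
            )
        u_prev = None

        axes_coords = [
            f_lvl.origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)
        ]
        mean_sp2 = float(np.mean(spacing)) ** 2
        ssd_start = None
        best_ssd = np.inf
        best_u = u.copy()
        for it in range(iters):
            mw = _warp_moving(m_lvl, u, coords_flat, init, shape)
            diff = mw - f_lvl.values
            ssd = float(np.mean(diff**2))
            if ssd_start is None:
                ssd_start = ssd
            if ssd < best_ssd:
                best_ssd = ssd
                best_u = u.copy()
            grad = np.stack(np.gradient(mw, *axes_coords))
            denom = (grad**2).sum(axis=0) + diff**2 / mean_sp2
            force = -diff * grad / np.maximum(denom, _EPS)
            force = _smooth_field(force, sig_update, spacing)
            u = _smooth_field(u + params.step * force, sig_total, spacing)
        # final candidate after the last update
        mw = _warp_moving(m_lvl, u, coords_flat, init, shape)
        ssd = float(np.mean((mw - f_lvl.values) ** 2))
        if ssd < best_ssd:
            best_ssd = ssd
            best_u = u
        if ssd_start is not None and best_ssd >= ssd_start and iters > 0:
            warnings.warn(
                f"SSD did not improve over pyramid level (factor {factor}); "
                "keeping the level's starting field"
            )
        u_prev = DisplacementField(best_u, spacing, f_lvl.origin)

    assert u_prev is not None
    # full-resolution safety check: never worse than the affine init alone
    coords_full = fixed_n.coordinate_grid().reshape(3, -1).T
    u_full = np.stack(
        [
            sample_field(u_prev, coords_full)[:, c].reshape(fixed_n.shape)
            for c in range(3)
        ]
    )
    result = DisplacementField(u_full, fixed_n.spacing, fixed_n.origin)
    mw = _warp_moving(moving_n, u_full, coords_full, init, fixed_n.shape)
    ssd_after = float(np.mean((mw - fixed_n.values) ** 2))
    mw0 = _warp_moving(
        moving_n, np.zeros_like(u_full), coords_full, init, fixed_n.shape
    )
    ssd_before = float(np.mean((mw0 - fixed_n.values) ** 2))
    if ssd_after > ssd_before:
        warnings.warn(
            f"deformable registration increased SSD ({ssd_after:.4g} > "
            f"{ssd_before:.4g}); returning zero field"
        )
        return DisplacementField.zeros(
            fixed_n.shape, fixed_n.spacing, fixed_n.origin
        )
    logger.debug("deformable SSD %.4g -> %.4g", ssd_before, ssd_after)
    return result
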