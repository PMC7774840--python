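"""Phantom cohorts with known ground truth.

Generates a population of "brains" as smooth random deformations of a shared
mean shape, emulating the two-channel structure of the evaluation data: a
reference channel with dense neuropil-like contrast (smooth ellipsoidal
compartments, mirror-symmetric about the mid-x plane by construction) and a
neuron channel of tubular structures rendered around random smooth paths,
with the paths also returned as SWC skeletons.

Every subject carries its exact ground-truth transform, so registration and
template-construction error are directly measurable, and the zero-mean
deformation construction makes the true mean shape known — the property
groupwise template building is supposed to recover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import (
    AffineTransform,
    CompositeTransform,
    DisplacementField,
    Skeleton,
    Volume,
    write_dfield_h5,
    write_swc,
    write_volume,
)
from .transforms import apply_to_image, apply_to_points, invert_dfield

logger = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "MeanBrain", "SubjectData", "make_mean_brain", "make_subject", "make_population"]


@dataclass
class PhantomSpec:
    """Study conditions for a phantom cohort.

    Defaults give a cohort a full pipeline can process in minutes on one
    CPU while leaving registration non-trivial: 96 x 96 x 48 voxels at
    1 um/px, six subjects, 3 um RMS deformations smoothed over 8 um,
    5% intensity noise.
    """

    grid_shape: tuple = (96, 96, 48)
    spacing: float = 1.0
    n_subjects: int = 6
    deform_amplitude: float = 3.0
    deform_smoothness: float = 8.0
    noise_sd: float = 0.05
    n_neurons: int = 3
    tube_radius: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if min(self.grid_shape) < 8:
            raise ValueError("grid too small")
        for name in ("spacing", "deform_amplitude", "deform_smoothness", "tube_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        extent = min(self.grid_shape) * self.spacing
        if self.deform_amplitude >= extent / 4:
            raise ValueError("deform_amplitude must be < grid extent / 4")


@dataclass
class MeanBrain:
    reference: Volume
    neuron_channel: Volume
    skeletons: list


@dataclass
class SubjectData:
    reference: Volume
    neuron_channel: Volume
    skeletons: list
    truth: CompositeTransform  # pull-back: subject grid -> mean space


def _symmetric_compartments(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Sum of smooth ellipsoidal blobs, exactly mirror-symmetric in x."""
    nx, ny, nz = spec.grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx = (nx - 1) / 2.0
    vals = np.zeros(spec.grid_shape)

    # central body
    vals += 1.0 * np.exp(
        -(
            ((x - cx) / (0.32 * nx)) ** 2
            + ((y - 0.5 * ny) / (0.30 * ny)) ** 2
            + ((z - 0.5 * nz) / (0.30 * nz)) ** 2
        )
        ** 2
    )
    # paired lateral lobes and dorsal blobs at rng-jittered offsets
    for intensity, fy, fz, sx, sy, sz in [
        (0.9, 0.45, 0.45, 0.12, 0.18, 0.20),
        (0.7, 0.62, 0.55, 0.10, 0.12, 0.16),
        (0.5, 0.38, 0.62, 0.08, 0.10, 0.12),
    ]:
        dx = (0.18 + 0.08 * rng.random()) * nx
        q = (
            ((x - (cx + dx)) / (sx * nx)) ** 2
            + ((y - fy * ny) / (sy * ny)) ** 2
            + ((z - fz * nz) / (sz * nz)) ** 2
        )
        vals += intensity * np.exp(-(q**2))
        q2 = (
            ((x - (cx - dx)) / (sx * nx)) ** 2
            + ((y - fy * ny) / (sy * ny)) ** 2
            + ((z - fz * nz) / (sz * nz)) ** 2
        )
        vals += intensity * np.exp(-(q2**2))

    # enforce exact mirror symmetry about mid-x
    vals = 0.5 * (vals + vals[::-1, :, :])
    return vals


def _random_paths(
    foreground: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> list:
    """Random smooth polylines through the foreground, as (n, 3) voxel coords."""
    fg_idx = np.argwhere(foreground)
    paths = []
    shape = np.array(spec.grid_shape, dtype=float)
    for _ in range(spec.n_neurons):
        start = fg_idx[rng.integers(len(fg_idx))].astype(float)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pts = [start.copy()]
        pos = start.copy()
        step = 1.5  # voxels between nodes
        for _ in range(200):
            # persistent random walk with gentle turning
            turn = rng.normal(scale=0.35, size=3)
            direction = direction + turn
            direction /= np.linalg.norm(direction)
            nxt = pos + step * direction
            idx = np.rint(nxt).astype(int)
            ok = np.all(idx >= 1) and np.all(idx < shape - 1) and foreground[tuple(idx)]
            if not ok:
                # reflect back toward the centre of the foreground
                centre = fg_idx.mean(axis=0)
                direction = centre - pos
                direction /= np.linalg.norm(direction)
                nxt = pos + step * direction
                idx = np.rint(nxt).astype(int)
                if not (np.all(idx >= 1) and np.all(idx < shape - 1) and foreground[tuple(idx)]):
                    break
            pos = nxt
            pts.append(pos.copy())
        if len(pts) >= 5:
            paths.append(np.array(pts))
    return paths


def _paths_to_skeletons(paths: list, spacing: float, tube_radius: float) -> list:
    skels = []
    for p in paths:
        n = len(p)
        ids = np.arange(1, n + 1)
        parents = np.concatenate([[-1], ids[:-1]])
        positions = p * spacing
        skels.append(Skeleton(ids, positions, np.full(n, tube_radius), parents))
    return skels


def _render_tubes(paths: list, spec: PhantomSpec) -> np.ndarray:
    """Tube channel: 1 inside tube_radius of any path, softly shouldered."""
    marks = np.zeros(spec.grid_shape, dtype=bool)
    for p in paths:
        # densify segments to half-voxel steps
        for a, b in zip(p[:-1], p[1:]):
            seg = np.linalg.norm(b - a)
            n_steps = max(int(np.ceil(seg / 0.5)), 1)
            t = np.linspace(0, 1, n_steps + 1)[:, None]
            pts = a[None] * (1 - t) + b[None] * t
            idx = np.rint(pts).astype(int)
            idx = idx[np.all((idx >= 0) & (idx < np.array(spec.grid_shape)), axis=1)]
            marks[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if not marks.any():
        return np.zeros(spec.grid_shape)
    dist = ndimage.distance_transform_edt(~marks, sampling=spec.spacing)
    tubes = (dist <= spec.tube_radius).astype(float)
    return ndimage.gaussian_filter(tubes, sigma=0.5)


def make_mean_brain(spec: PhantomSpec) -> MeanBrain:
    """Deterministic (per seed) mean anatomy: reference channel, neuron
    channel, and the neuron paths as SWC skeletons in world um."""
    rng = np.random.default_rng(spec.seed)
    ref_vals = _symmetric_compartments(spec, rng)
    reference = Volume(ref_vals, spec.spacing, 0.0)
    foreground = ref_vals > 0.15 * ref_vals.max()
    paths = _random_paths(foreground, spec, rng)
    skeletons = _paths_to_skeletons(paths, spec.spacing, spec.tube_radius)
    neuron = Volume(_render_tubes(paths, spec), spec.spacing, 0.0)
    return MeanBrain(reference=reference, neuron_channel=neuron, skeletons=skeletons)


def _random_smooth_field(
    spec: PhantomSpec, amplitude: float, smoothness: float, rng: np.random.Generator
) -> DisplacementField:
    """Smoothed white-noise vector field scaled to the requested RMS (um)."""
    vectors = rng.normal(size=(3, *spec.grid_shape))
    sigma_vox = smoothness / spec.spacing
    for c in range(3):
        vectors[c] = ndimage.gaussian_filter(vectors[c], sigma=sigma_vox)
    rms = np.sqrt(np.mean(vectors**2))
    if rms > 0 and amplitude > 0:
        vectors *= amplitude / (rms * np.sqrt(3))  # per-point vector RMS = amplitude
    else:
        vectors[:] = 0.0
    return DisplacementField(vectors, spec.spacing, 0.0)


def _random_similarity(
    spec: PhantomSpec, amplitude: float, rng: np.random.Generator
) -> AffineTransform:
    """Small random similarity, with magnitude proportional to amplitude
    (identity when amplitude == 0)."""
    from scipy.spatial.transform import Rotation

    scale_knob = amplitude / 3.0  # unit knob at the default 3 um amplitude
    rotvec = rng.normal(scale=0.01 * scale_knob, size=3)
    log_s = rng.normal(scale=0.01 * scale_knob)
    t = rng.normal(scale=1.0 * scale_knob, size=3)
    R = Rotation.from_rotvec(rotvec).as_matrix() * np.exp(log_s)
    centre = (np.array(spec.grid_shape) - 1) * spec.spacing / 2.0
    b = centre + t - R @ centre
    if amplitude == 0:
        return AffineTransform.identity()
    return AffineTransform(R, b)


def make_subject(
    mean: MeanBrain,
    spec: PhantomSpec,
    seed: int,
    amplitude: float | None = None,
    smoothness: float | None = None,
    noise_sd: float | None = None,
) -> SubjectData:
    """One phantom individual: both channels warped by a random smooth field
    plus a small random similarity, skeletons transported by the exact
    inverse of the truth transform, Gaussian intensity noise added.

    The truth transform is the pull-back map from the subject's grid into
    mean space, i.e. exactly what a perfect registration of the subject to
    the mean-shaped template would recover.
    """
    amplitude = spec.deform_amplitude if amplitude is None else amplitude
    smoothness = spec.deform_smoothness if smoothness is None else smoothness
    noise_sd = spec.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)

    for attempt in range(5):
        field = _random_smooth_field(spec, amplitude, smoothness, rng)
        inv, residual = invert_dfield(field, full_output=True)
        if residual <= 0.1 or amplitude == 0:
            break
        logger.warning(
            "truth-field inversion residual %.3g um > 0.1 um; regenerating with "
            "amplitude %.3g um",
            residual,
            amplitude * 0.8,
        )
        amplitude *= 0.8
    affine = _random_similarity(spec, amplitude, rng)
    truth = CompositeTransform.of(field, affine)

    grid = mean.reference
    ref = apply_to_image(mean.reference, truth, grid)
    neuron = apply_to_image(mean.neuron_channel, truth, grid)
    if noise_sd > 0:
        peak = float(mean.reference.values.max())
        ref = ref.like(ref.values + rng.normal(scale=noise_sd * peak, size=ref.shape))
        npk = float(mean.neuron_channel.values.max()) or 1.0
        neuron = neuron.like(
            neuron.values + rng.normal(scale=noise_sd * npk, size=neuron.shape)
        )
    skeletons = [
        s.with_positions(apply_to_points(s.positions, truth, direction="forward"))
        for s in mean.skeletons
    ]
    return SubjectData(reference=ref, neuron_channel=neuron, skeletons=skeletons, truth=truth)


def make_population(spec: PhantomSpec, out_dir) -> pd.DataFrame:
    """Write a full phantom cohort to disk; returns the manifest.

    Per subject: reference channel and neuron channel (NRRD), merged
    skeleton SWC, and the truth displacement field with its similarity
    folded in (HDF5). Plus the ground-truth mean (both channels + SWCs) and
    ``manifest.csv`` with one line group. Fully reproducible from the seed.
    """
    from .transforms import total_displacement

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mean = make_mean_brain(spec)
    write_volume(mean.reference, out_dir / "mean_reference.nrrd")
    write_volume(mean.neuron_channel, out_dir / "mean_neuron.nrrd")
    for k, s in enumerate(mean.skeletons):
        write_swc(s, out_dir / f"mean_neuron_{k:02d}.swc")

    rows = []
    for i in range(spec.n_subjects):
        sid = f"sub-{i:02d}"
        sub = make_subject(mean, spec, seed=spec.seed + 1000 + i)
        ref_path = out_dir / f"{sid}_reference.nrrd"
        neu_path = out_dir / f"{sid}_neuron.nrrd"
        swc_path = out_dir / f"{sid}.swc"
        truth_path = out_dir / f"{sid}_truth.h5"
        write_volume(sub.reference, ref_path)
        write_volume(sub.neuron_channel, neu_path)
        write_swc(_merge_skeletons(sub.skeletons), swc_path)
        write_dfield_h5(
            total_displacement(sub.truth, mean.reference), truth_path, levels=1
        )
        rows.append(
            {
                "subject_id": sid,
                "group_id": "group-0",
                "image_path": str(ref_path),
                "swc_path": str(swc_path),
                "truth_path": str(truth_path),
            }
        )
    manifest = pd.DataFrame(rows)
    # the on-disk manifest uses paths relative to its own directory, so a
    # population written with the same seed is byte-identical anywhere
    relative = manifest.copy()
    for col in ("image_path", "swc_path", "truth_path"):
        relative[col] = [str(Path(p).name) for p in relative[col]]
    relative.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def _merge_skeletons(skeletons: list) -> Skeleton:
    """Concatenate trees into one SWC with disjoint id ranges."""
    if len(skeletons) == 0:
        return Skeleton(np.empty(0, int), np.empty((0, 3)), np.empty(0), np.empty(0, int))
    ids, pos, rad, par, typ = [], [], [], [], []
    offset = 0
    for s in skeletons:
        ids.append(s.ids + offset)
        pos.append(s.positions)
        rad.append(s.radii)
        par.append(np.where(s.parents == -1, -1, s.parents + offset))
        typ.append(s.types)
        offset += int(s.ids.max()) if s.n_nodes else 0
    return Skeleton(
        np.concatenate(ids),
        np.concatenate(pos),
        np.concatenate(rad),
        np.concatenate(par),
        np.concatenate(typ),
    )
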