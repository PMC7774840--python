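"""Canonical in-memory data model and on-disk formats.

All spatial interfaces speak world micrometres with (x, y, z) axis order.
Voxel indices are 0-based and map to world coordinates as

    world = origin + index * spacing

Scalar grids are stored with memory axes (x, y, z), i.e. ``values[ix, iy, iz]``.
Displacement-field vector grids are stored as ``vectors[c, ix, iy, iz]`` where
``c`` indexes the (x, y, z) world components of the displacement in um.

Supported formats: NRRD and NIfTI-1 volumes, 7-column SWC skeletons, CSV
line-group tables, and a multiscale quantized HDF5 dialect for displacement
fields (documented in :func:`write_dfield_h5`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

__all__ = [
    "Volume",
    "AffineTransform",
    "DisplacementField",
    "CompositeTransform",
    "Skeleton",
    "LabelVolume",
    "coordinate_grid",
    "read_volume",
    "write_volume",
    "read_swc",
    "write_swc",
    "read_line_groups",
    "write_line_groups",
    "write_dfield_h5",
    "read_dfield_h5",
]


def _as_triple(x, dtype=float) -> np.ndarray:
    a = np.asarray(x, dtype=dtype).reshape(-1)
    if a.size == 1:
        a = np.repeat(a, 3)
    if a.size != 3:
        raise ValueError(f"expected a scalar or 3-vector, got shape {a.shape}")
    return a


def coordinate_grid(shape: Sequence[int], spacing, origin) -> np.ndarray:
    """World coordinates of every voxel centre: array of shape (3, nx, ny, nz)."""
    spacing = _as_triple(spacing)
    origin = _as_triple(origin)
    axes = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)


@dataclass
class Volume:
    """3D scalar grid with physical spacing and origin (um).

    Holds subject images and templates. ``values[ix, iy, iz]`` lives at world
    position ``origin + (ix, iy, iz) * spacing``.
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"Volume values must be 3D, got {self.values.ndim}D")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume values must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def world_extent(self) -> np.ndarray:
        """(2, 3) array of min/max world coordinates of voxel centres."""
        lo = self.origin
        hi = self.origin + (np.array(self.shape) - 1) * self.spacing
        return np.stack([lo, hi])

    def coordinate_grid(self) -> np.ndarray:
        return coordinate_grid(self.shape, self.spacing, self.origin)

    def like(self, values: np.ndarray) -> "Volume":
        """New Volume with the same geometry and different values."""
        return Volume(values, self.spacing.copy(), self.origin.copy())

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.spacing.copy(), self.origin.copy())


@dataclass
class LabelVolume:
    """Integer-labelled 3D grid (0 = background) with Volume geometry."""

    labels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelVolume labels must be integer")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be >= 0")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple:
        return self.labels.shape


@dataclass
class AffineTransform:
    """World-space affine map x -> matrix @ x + translation (um)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = _as_triple(self.translation)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("affine matrix is singular (|det| <= 1e-12)")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @classmethod
    def from_translation(cls, t) -> "AffineTransform":
        return cls(np.eye(3), t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array (or a (3,) point) of world coordinates."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.matrix.T + self.translation
        return out.reshape(np.shape(points))

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    def compose_with(self, inner: "AffineTransform") -> "AffineTransform":
        """Affine equal to self(inner(x))."""
        return AffineTransform(
            self.matrix @ inner.matrix,
            self.matrix @ inner.translation + self.translation,
        )


@dataclass
class DisplacementField:
    """Dense vector grid u(x) in um over the fixed image's world grid.

    The full spatial map is phi(x) = x + u(x). ``vectors`` has shape
    (3, nx, ny, nz): component c of the displacement at voxel (ix, iy, iz).
    """

    vectors: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[0] != 3:
            raise ValueError(
                f"vectors must have shape (3, nx, ny, nz), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement components must be finite")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")

    @property
    def grid_shape(self) -> tuple:
        return self.vectors.shape[1:]

    @classmethod
    def zeros(cls, shape, spacing=1.0, origin=0.0) -> "DisplacementField":
        return cls(np.zeros((3, *shape)), spacing, origin)

    def coordinate_grid(self) -> np.ndarray:
        return coordinate_grid(self.grid_shape, self.spacing, self.origin)

    def copy(self) -> "DisplacementField":
        return DisplacementField(
            self.vectors.copy(), self.spacing.copy(), self.origin.copy()
        )


@dataclass
class CompositeTransform:
    """Ordered sequence of affine / displacement-field components.

    Components are applied left-to-right to a world point: for components
    [c1, c2] the total map is x -> c2(c1(x)). Used for bridging chains and for
    (affine, deformable) registration results.
    """

    components: list

    def __post_init__(self):
        if len(self.components) == 0:
            raise ValueError("CompositeTransform must have at least one component")
        for c in self.components:
            if not isinstance(c, (AffineTransform, DisplacementField)):
                raise TypeError(f"unsupported component type {type(c)}")

    @classmethod
    def identity(cls) -> "CompositeTransform":
        return cls([AffineTransform.identity()])

    @classmethod
    def of(cls, *components) -> "CompositeTransform":
        return cls(list(components))


@dataclass
class Skeleton:
    """SWC-semantics neuron skeleton: nodes in world um.

    Parallel arrays over nodes: integer ``ids``, (n, 3) ``positions`` (um),
    ``radii`` (um), integer ``parents`` (-1 = root), integer SWC ``types``.
    """

    ids: np.ndarray
    positions: np.ndarray
    radii: np.ndarray
    parents: np.ndarray
    types: np.ndarray | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int).reshape(-1)
        n = self.ids.size
        self.positions = np.asarray(self.positions, dtype=float).reshape(n, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        self.parents = np.asarray(self.parents, dtype=int).reshape(-1)
        if self.types is None:
            self.types = np.zeros(n, dtype=int)
        self.types = np.asarray(self.types, dtype=int).reshape(-1)
        if not (self.radii.size == n and self.parents.size == n and self.types.size == n):
            raise ValueError("skeleton arrays must have equal length")
        if n != np.unique(self.ids).size:
            raise ValueError("skeleton node ids must be unique")
        id_set = set(self.ids.tolist())
        for p in self.parents:
            if p != -1 and p not in id_set:
                raise ValueError(f"dangling parent id {p}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("skeleton positions must be finite")

    @property
    def n_nodes(self) -> int:
        return self.ids.size

    def edges(self) -> np.ndarray:
        """(m, 2) array of (child_id, parent_id) for all non-root nodes."""
        mask = self.parents != -1
        return np.stack([self.ids[mask], self.parents[mask]], axis=1)

    def with_positions(self, positions: np.ndarray) -> "Skeleton":
        return Skeleton(
            self.ids.copy(),
            np.asarray(positions, dtype=float),
            self.radii.copy(),
            self.parents.copy(),
            self.types.copy(),
        )


# ---------------------------------------------------------------------------
# Volume I/O (NRRD via SimpleITK, NIfTI via nibabel)
# ---------------------------------------------------------------------------

_NRRD_SUFFIXES = {".nrrd", ".nhdr"}
_NIFTI_SUFFIXES = {".nii"}


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_volume(path: PathLike) -> Volume:
    """Read a 3D scalar NRRD or NIfTI volume.

    Spacing and origin are taken from the header; a header without spacing
    information yields 1.0 um/voxel with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        return _read_nifti(path)
    if path.suffix.lower() in _NRRD_SUFFIXES:
        return _read_nrrd(path)
    raise ValueError(f"unsupported volume format: {path.name}")


def write_volume(volume: Union[Volume, LabelVolume], path: PathLike) -> None:
    """Write a Volume or LabelVolume as NRRD or NIfTI, chosen by extension."""
    path = Path(path)
    if isinstance(volume, LabelVolume):
        volume = Volume(volume.labels.astype(np.int32), volume.spacing, volume.origin)
    if _is_nifti(path):
        _write_nifti(volume, path)
    elif path.suffix.lower() in _NRRD_SUFFIXES:
        _write_nrrd(volume, path)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def _nrrd_header_declares_spacing(path: Path) -> bool:
    """Peek at the NRRD text header for a spacing declaration.

    The backend reader silently defaults missing spacing to 1.0; we inspect
    the raw header so the default is warned about, never silent.
    """
    spacing_keys = ("spacings:", "space directions:", "axis mins:")
    with open(path, "rb") as f:
        for raw in f:
            line = raw.decode("latin-1", errors="replace").strip().lower()
            if line == "":  # end of header
                break
            if line.startswith(spacing_keys):
                return True
    return False


def _read_nrrd(path: Path) -> Volume:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as e:  # pragma: no cover - backend message passthrough
        raise ValueError(f"could not read NRRD file {path}: {e}") from e
    if img.GetDimension() != 3:
        raise ValueError(
            f"expected 3 spatial dimensions, got {img.GetDimension()} in {path.name}"
        )
    # SimpleITK arrays are (z, y, x); transpose to (x, y, z)
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.array(img.GetSpacing())
    origin = np.array(img.GetOrigin())
    if not _nrrd_header_declares_spacing(path):
        warnings.warn(f"{path.name}: header declares no spacing; using 1.0 um/voxel")
        spacing = np.ones(3)
    return Volume(values, spacing, origin)


def _write_nrrd(volume: Volume, path: Path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))


def _read_nifti(path: Path) -> Volume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim > 3:
        data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"expected 3 spatial dimensions in {path.name}, got {data.ndim}")
    affine = img.affine
    if affine is None:
        warnings.warn(f"{path.name}: no affine header; assuming 1.0 um spacing")
        return Volume(data, 1.0, 0.0)
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    if np.any(spacing <= 0):
        warnings.warn(f"{path.name}: degenerate header spacing; defaulting to 1.0 um")
        spacing = np.ones(3)
    origin = affine[:3, 3]
    return Volume(data, spacing, origin)


def _write_nifti(volume: Volume, path: Path) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.values, affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# SWC skeleton I/O
# ---------------------------------------------------------------------------


def read_swc(path: PathLike) -> Skeleton:
    """Read a standard 7-column SWC file (coordinates interpreted as world um)."""
    path = Path(path)
    ids, types, xyz, radii, parents = [], [], [], [], []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise ValueError(f"{path.name}:{lineno}: expected 7 SWC columns")
            ids.append(int(parts[0]))
            types.append(int(parts[1]))
            xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
            radii.append(float(parts[5]))
            parents.append(int(parts[6]))
    if not ids:
        return Skeleton(
            np.empty(0, int), np.empty((0, 3)), np.empty(0), np.empty(0, int)
        )
    return Skeleton(
        np.array(ids), np.array(xyz), np.array(radii), np.array(parents), np.array(types)
    )


def write_swc(skeleton: Skeleton, path: PathLike) -> None:
    path = Path(path)
    with open(path, "w") as f:
        f.write("# id type x y z radius parent\n")
        for i in range(skeleton.n_nodes):
            x, y, z = skeleton.positions[i]
            f.write(
                f"{skeleton.ids[i]} {skeleton.types[i]} "
                f"{x:.6f} {y:.6f} {z:.6f} "
                f"{skeleton.radii[i]:.6f} {skeleton.parents[i]}\n"
            )


# ---------------------------------------------------------------------------
# Line-group tables
# ---------------------------------------------------------------------------


def read_line_groups(path: PathLike) -> pd.DataFrame:
    """Read a CSV with columns (subject_id, group_id)."""
    df = pd.read_csv(path, dtype=str)
    missing = {"subject_id", "group_id"} - set(df.columns)
    if missing:
        raise ValueError(f"line-group table missing columns: {sorted(missing)}")
    return df


def write_line_groups(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Multiscale quantized HDF5 displacement fields
# ---------------------------------------------------------------------------
#
# Dialect (normative for this package):
#   group "/dfield/{level}" holds a 4D dataset "data" ordered (component, z, y, x)
#   with attributes:
#     spacing                 (3,) um for that level, (x, y, z) order
#     origin                  (3,) um, (x, y, z) order
#     quantization_multiplier scalar m, present iff stored as int16 with
#                             q = round(u / m), m = max|u| / 32766
#   level L+1 is level L block-averaged by factor 2 per axis, spacing doubled.

_QUANT_MAX = 32766  # int16 full scale minus headroom for round()


def write_dfield_h5(
    field: DisplacementField, path: PathLike, levels: int = 1, quantize: bool = True
) -> None:
    """Write a displacement field as a multiscale (optionally quantized) HDF5 file."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    from skimage.measure import block_reduce

    with h5py.File(path, "w") as f:
        root = f.create_group("dfield")
        vectors = field.vectors
        spacing = field.spacing.copy()
        origin = field.origin.copy()
        for level in range(levels):
            grp = root.create_group(str(level))
            if quantize:
                m = float(np.abs(vectors).max()) / _QUANT_MAX
                if m == 0.0:
                    m = 1.0
                q = np.round(vectors / m).astype(np.int16)
                data = q.transpose(0, 3, 2, 1)  # (c, x, y, z) -> (c, z, y, x)
                ds = grp.create_dataset(
                    "data", data=data, compression="gzip", track_times=False
                )
                ds.attrs["quantization_multiplier"] = m
            else:
                data = vectors.transpose(0, 3, 2, 1)
                ds = grp.create_dataset(
                    "data", data=data, compression="gzip", track_times=False
                )
            ds.attrs["spacing"] = spacing
            ds.attrs["origin"] = origin
            if level < levels - 1:
                # voxel centre of the 2x2x2 block sits half a (new) voxel
                # further from the origin along each axis
                origin = origin + spacing / 2.0
                vectors = block_reduce(vectors, (1, 2, 2, 2), np.mean)
                spacing = spacing * 2.0


def read_dfield_h5(path: PathLike, level: int = 0) -> DisplacementField:
    """Read one pyramid level of a displacement field written by write_dfield_h5."""
    with h5py.File(path, "r") as f:
        if "dfield" not in f:
            raise ValueError(f"{path}: missing /dfield group")
        root = f["dfield"]
        if str(level) not in root:
            available = sorted(int(k) for k in root.keys())
            raise IndexError(f"level {level} not stored (available: {available})")
        ds = root[str(level)]["data"]
        if "spacing" not in ds.attrs or "origin" not in ds.attrs:
            raise ValueError(f"{path}: level {level} missing spacing/origin attributes")
        data = ds[()]
        spacing = np.array(ds.attrs["spacing"])
        origin = np.array(ds.attrs["origin"])
        if "quantization_multiplier" in ds.attrs:
            data = data.astype(float) * float(ds.attrs["quantization_multiplier"])
        vectors = data.transpose(0, 3, 2, 1)  # (c, z, y, x) -> (c, x, y, z)
        return DisplacementField(vectors, spacing, origin)
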