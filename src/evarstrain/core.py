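"""Image, mask, vector-field and rigid-transform containers with physical-space
geometry, interpolation/warping, and NIfTI/MetaImage I/O.

Conventions
-----------
Voxel arrays are indexed ``voxels[i, j, k]`` along the (x, y, z) world axes.
The lattice is axis-aligned: ``world = origin + spacing * index`` (identity
direction matrix); indexing is 0-based and voxel centers are the sample
points.  Displacement fields store millimetres, not voxels, because the strain
analysis differentiates them against physical coordinates.  Files with a
non-identity direction matrix are normalized to this convention on load by
discarding the direction (a logged warning); oblique geometries are out of
scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

logger = logging.getLogger(__name__)

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _as_triple(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.asarray(x).ravel())
    if len(t) != 3:
        raise ValueError(f"expected a 3-vector, got {x!r}")
    return t  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3D scalar lattice (HU-like intensities) with physical spacing/origin."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        if any(s < 2 for s in self.voxels.shape):
            raise ValueError(f"lattice needs >= 2 voxels per axis, got {self.voxels.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def same_lattice(self, other: "ImageVolume | BinaryMask | VectorField") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy_with(self, voxels: np.ndarray) -> "ImageVolume":
        return ImageVolume(voxels, self.spacing, self.origin)


@dataclass
class BinaryMask:
    """A {0,1} lattice sharing shape/spacing/origin with its reference volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {vox.shape}")
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, got {uniq}")
        self.voxels = vox.astype(np.uint8)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    same_lattice = ImageVolume.same_lattice

    def as_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)

    @property
    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * float(np.prod(self.spacing))


@dataclass
class VectorField:
    """A per-voxel displacement field U in millimetres on a reference lattice.

    ``vectors[i, j, k]`` is the 3-vector at lattice site (i, j, k);
    ``domain`` marks where the field is considered defined (defaults to all).
    """

    vectors: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    domain: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(f"vectors must be (nx, ny, nz, 3), got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("vector components must be finite")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if self.domain is not None:
            self.domain = np.asarray(self.domain).astype(bool)
            if self.domain.shape != self.vectors.shape[:3]:
                raise ValueError("domain shape must match the vector lattice")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    same_lattice = ImageVolume.same_lattice


@dataclass
class RigidTransform3D:
    """World-space rigid map ``x -> rotation @ x + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError(f"rotation not orthonormal (max deviation {err:.2e})")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must have determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform3D":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec: Sequence[float], translation: Sequence[float],
                    center: Sequence[float] = (0.0, 0.0, 0.0)) -> "RigidTransform3D":
        """Build from an axis-angle rotation (radians) about ``center``."""
        from scipy.spatial.transform import Rotation

        R = Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()
        c = np.asarray(center, dtype=float)
        t = np.asarray(translation, dtype=float) + c - R @ c
        # Re-orthonormalize to meet the strict invariant tolerance.
        u, _, vt = np.linalg.svd(R)
        return cls(u @ vt, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform3D":
        Rinv = self.rotation.T
        return RigidTransform3D(Rinv, -Rinv @ self.translation)

    def compose(self, other: "RigidTransform3D") -> "RigidTransform3D":
        """Return self o other (apply ``other`` first)."""
        return RigidTransform3D(self.rotation @ other.rotation,
                                self.rotation @ other.translation + self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise IOError(
            f"unsupported volume format for '{path}': expected one of {_SUPPORTED_SUFFIXES}"
        )


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) scalar volume."""
    path = Path(path)
    _check_suffix(path)
    if not path.exists():
        raise IOError(f"cannot read volume: '{path}' does not exist")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - message content varies
        raise IOError(f"failed to read '{path}' as NIfTI/MetaImage: {exc}") from exc
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        logger.warning("non-identity direction matrix in %s; normalizing to axis-aligned", path)
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim == 4:  # vector volume stored as components
        arr = np.moveaxis(arr, 0, -1)
    if arr.ndim != 3:
        raise IOError(f"'{path}' is not a 3D scalar volume (shape {arr.shape})")
    # SimpleITK arrays are (z, y, x); ours are (x, y, z).
    return ImageVolume(np.ascontiguousarray(arr.transpose(2, 1, 0)),
                       img.GetSpacing(), img.GetOrigin())


def write_volume(volume: ImageVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI/MetaImage (dtype preserved)."""
    path = Path(path)
    _check_suffix(path)
    if not path.parent.is_dir():
        raise IOError(f"cannot write volume: directory '{path.parent}' does not exist")
    arr = np.ascontiguousarray(np.asarray(volume.voxels).transpose(2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    sitk.WriteImage(img, str(path))


def write_vector_field(fieldv: VectorField, path: str | Path) -> None:
    """Write a displacement field as a 3-component NIfTI/MetaImage volume."""
    path = Path(path)
    _check_suffix(path)
    arr = np.ascontiguousarray(fieldv.vectors.transpose(2, 1, 0, 3))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(fieldv.spacing)
    img.SetOrigin(fieldv.origin)
    sitk.WriteImage(img, str(path))


def read_vector_field(path: str | Path) -> VectorField:
    path = Path(path)
    _check_suffix(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise IOError(f"'{path}' is not a 3-component vector volume (shape {arr.shape})")
    return VectorField(np.ascontiguousarray(arr.transpose(2, 1, 0, 3)),
                       img.GetSpacing(), img.GetOrigin())


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def index_to_world(volume: ImageVolume | BinaryMask | VectorField,
                   index: Sequence[float] | np.ndarray) -> np.ndarray:
    """Map lattice indices to world mm: ``origin + spacing * index``.

    Accepts a single triple or an (N, 3) array.  Integer indices must lie
    within lattice bounds.
    """
    idx = np.asarray(index, dtype=float)
    shape = np.asarray(volume.shape)
    if np.any(idx < 0) or np.any(idx > shape - 1):
        raise ValueError(f"index {index!r} out of bounds for shape {tuple(shape)}")
    return np.asarray(volume.origin) + np.asarray(volume.spacing) * idx


def world_to_index(volume: ImageVolume | BinaryMask | VectorField,
                   world: Sequence[float] | np.ndarray) -> np.ndarray:
    """Inverse of :func:`index_to_world` (continuous index, not rounded)."""
    w = np.asarray(world, dtype=float)
    return (w - np.asarray(volume.origin)) / np.asarray(volume.spacing)


def _sample(volume: ImageVolume | BinaryMask, cont_index: np.ndarray,
            interpolation: str, background: float) -> np.ndarray:
    """Sample ``volume`` at continuous indices (..., 3)."""
    order = {"linear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")
    coords = np.moveaxis(cont_index, -1, 0).reshape(3, -1)
    vals = map_coordinates(np.asarray(volume.voxels, dtype=float), coords,
                           order=order, mode="constant", cval=background)
    return vals.reshape(cont_index.shape[:-1])


def _lattice_world(ref: ImageVolume | BinaryMask) -> np.ndarray:
    """World coordinates of every lattice site, shape (nx, ny, nz, 3)."""
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in ref.shape], indexing="ij")
    idx = np.stack(grids, axis=-1)
    return np.asarray(ref.origin) + np.asarray(ref.spacing) * idx


def resample(volume: ImageVolume, reference: ImageVolume,
             transform: RigidTransform3D | None = None,
             interpolation: str = "linear",
             background: float | None = None) -> ImageVolume:
    """Resample ``volume`` onto ``reference``'s lattice.

    The output value at reference lattice point x is ``volume(T(x))`` where T
    is the given world-space rigid transform (identity when None).  Positions
    outside ``volume``'s support are filled with ``background`` (default: the
    minimum of ``volume``, a data-driven stand-in for CT air).
    """
    if transform is None:
        transform = RigidTransform3D.identity()
    if background is None:
        background = float(np.min(volume.voxels))
    world = _lattice_world(reference)
    mapped = transform.apply(world.reshape(-1, 3)).reshape(world.shape)
    cont_index = (mapped - np.asarray(volume.origin)) / np.asarray(volume.spacing)
    out = _sample(volume, cont_index, interpolation, background)
    return ImageVolume(out, reference.spacing, reference.origin)


def resample_mask(mask: BinaryMask, reference: ImageVolume | BinaryMask,
                  transform: RigidTransform3D | None = None) -> BinaryMask:
    """Nearest-neighbour mask resampling; preserves the {0,1} value set."""
    vol = ImageVolume(mask.voxels.astype(float), mask.spacing, mask.origin)
    ref = ImageVolume(np.zeros(reference.shape), reference.spacing, reference.origin)
    out = resample(vol, ref, transform, interpolation="nearest", background=0.0)
    return BinaryMask(out.voxels.astype(np.uint8), reference.spacing, reference.origin)


def warp(volume: ImageVolume | BinaryMask, fieldv: VectorField,
         interpolation: str = "linear",
         background: float | None = None) -> ImageVolume:
    """Warp: ``output(x) = volume(x + U(x))`` with U in mm on the same lattice."""
    if not (volume.shape == fieldv.shape
            and np.allclose(volume.spacing, fieldv.spacing)
            and np.allclose(volume.origin, fieldv.origin)):
        raise ValueError("warp: field must live on the volume's lattice")
    if background is None:
        background = float(np.min(volume.voxels))
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in volume.shape], indexing="ij")
    idx = np.stack(grids, axis=-1)
    cont_index = idx + fieldv.vectors / np.asarray(volume.spacing)
    out = _sample(volume, cont_index, interpolation, background)
    return ImageVolume(out, volume.spacing, volume.origin)


def warp_mask(mask: BinaryMask, fieldv: VectorField) -> BinaryMask:
    vol = ImageVolume(mask.voxels.astype(float), mask.spacing, mask.origin)
    out = warp(vol, fieldv, interpolation="nearest", background=0.0)
    return BinaryMask(out.voxels.astype(np.uint8), mask.spacing, mask.origin)
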