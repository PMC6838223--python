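"""Rigid alignment of bony anatomy and straightened curved planar reformation.

The rigid stage aligns the vertebrae/hip between the two timepoints: a
landmark-based translation (lowest renal artery) initializes a 6-DOF
optimization of the mean squared intensity difference evaluated over the
fixed bone mask (dilated by 2 voxels), with a coarse-then-fine two-level
schedule.  The CPR stage resamples the volume on planes orthogonal to the
resampled centerline and stacks them into a straightened volume; straightened
volumes of the two timepoints are then aligned by an integer translation
derived from the straightened renal landmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .core import BinaryMask, ImageVolume, RigidTransform3D, _sample
from .centerline import Centerline

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Rigid registration
# ---------------------------------------------------------------------------

def init_translation(landmark_fixed: Sequence[float],
                     landmark_moving: Sequence[float]) -> RigidTransform3D:
    """Landmark-based initialization: pure translation fixed -> moving space."""
    lf = np.asarray(landmark_fixed, dtype=float)
    lm = np.asarray(landmark_moving, dtype=float)
    if not (np.all(np.isfinite(lf)) and np.all(np.isfinite(lm))):
        raise ValueError("landmarks must be finite")
    return RigidTransform3D(np.eye(3), lm - lf)


def _metric_factory(points_world, fixed_vals, moving, background):
    mv = np.asarray(moving.voxels, dtype=float)
    sp = np.asarray(moving.spacing)
    org = np.asarray(moving.origin)
    hi = (np.asarray(moving.shape) - 1).astype(float)
    worst = float(np.mean((np.ptp(fixed_vals) + np.abs(fixed_vals - background)) ** 2)) + 1.0

    def metric(transform: RigidTransform3D) -> float:
        mapped = transform.apply(points_world)
        idx = (mapped - org) / sp
        # only points landing inside the moving FOV carry information; a scan
        # pair can truncate anatomy differently, and background comparisons
        # would swamp the metric
        valid = np.all((idx >= 0.0) & (idx <= hi), axis=1)
        if valid.mean() < 0.25:
            return worst
        vals = ndimage.map_coordinates(mv, idx[valid].T, order=1,
                                       mode="constant", cval=background)
        return float(np.mean((vals - fixed_vals[valid]) ** 2))

    return metric


def register_rigid(fixed: ImageVolume, moving: ImageVolume,
                   bone_fixed: BinaryMask,
                   init: RigidTransform3D | None = None,
                   max_points: int = 16000) -> RigidTransform3D:
    """6-DOF registration minimizing MSD over the fixed bone region.

    The metric is sampled on the bone mask dilated by 2 voxels (so edges
    contribute gradient information) and optimized coarse-to-fine (smoothed,
    subsampled level first).  The returned transform maps fixed-space points
    into moving space; it never worsens the metric relative to ``init``.
    """
    if not bone_fixed.as_bool().any():
        raise ValueError("register_rigid requires a non-empty bone mask")
    if init is None:
        init = RigidTransform3D.identity()

    dil = ndimage.binary_dilation(bone_fixed.as_bool(), iterations=2)
    idx = np.argwhere(dil)
    world = np.asarray(fixed.origin) + np.asarray(fixed.spacing) * idx
    fixed_vals = np.asarray(fixed.voxels, dtype=float)[tuple(idx.T)]
    background = float(np.min(moving.voxels))
    center = world.mean(axis=0)

    rng = np.random.default_rng(0)  # deterministic subsampling

    def params_to_tf(p):
        return RigidTransform3D.from_rotvec(p[:3], p[3:], center=center)

    # init expressed in the centered parameterization
    from scipy.spatial.transform import Rotation
    r0 = Rotation.from_matrix(init.rotation).as_rotvec()
    t0 = init.rotation @ center + init.translation - center
    p0 = np.concatenate([r0, t0])

    levels = [(4, 2.0), (1, 0.0)]  # (point subsampling, volume smoothing sigma)
    p = p0
    for sub, sigma in levels:
        if sub > 1 and len(world) > max_points:
            sel = rng.choice(len(world), size=len(world) // sub, replace=False)
        elif sub > 1:
            sel = slice(None, None, sub)
        else:
            sel = slice(None)
        if len(world) > max_points and sub == 1:
            sel = rng.choice(len(world), size=max_points, replace=False)
        if sigma > 0:
            mov = moving.copy_with(ndimage.gaussian_filter(
                np.asarray(moving.voxels, dtype=float), sigma))
            fvals = ndimage.gaussian_filter(
                np.asarray(fixed.voxels, dtype=float), sigma)[tuple(idx[sel].T)]
        else:
            mov = moving
            fvals = fixed_vals[sel]
        metric = _metric_factory(world[sel], fvals, mov, background)

        def cost(q):
            return metric(params_to_tf(q))

        res = minimize(cost, p, method="Powell",
                       options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 20})
        p = res.x

    final = params_to_tf(p)
    full_metric = _metric_factory(world, fixed_vals, moving, background)
    if full_metric(final) > full_metric(init):
        logger.warning("rigid registration did not improve the metric; returning init")
        return init
    return final


# ---------------------------------------------------------------------------
# Straightened CPR
# ---------------------------------------------------------------------------

class StraightenedIndex(NamedTuple):
    slice: int
    u: float
    v: float


@dataclass
class StraightenedVolume:
    """Stacked cross-sections orthogonal to the centerline.

    ``voxels[i, j, k]``: k is the arc-length slice index, (i, j) the in-plane
    coordinates along the per-slice frame axes (u, v).  ``frames[k]`` records
    (origin point p, tangent t, u, v) of slice k in world mm.
    """

    voxels: np.ndarray
    in_plane_spacing: float
    slice_spacing: float
    frames: list = dc_field(default_factory=list)
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("straightened voxels must be 3D")
        if self.frames and len(self.frames) != self.voxels.shape[2]:
            raise ValueError("one frame per slice required")

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.in_plane_spacing, self.in_plane_spacing, self.slice_spacing)

    @property
    def center(self) -> float:
        return (self.voxels.shape[0] - 1) / 2.0

    def as_volume(self) -> ImageVolume:
        """View the straightened lattice as an axis-aligned volume at origin 0."""
        return ImageVolume(self.voxels, self.spacing, (0.0, 0.0, 0.0))


def _frames_from_centerline(cl: Centerline, projection_direction: np.ndarray):
    pts = cl.points
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    proj = projection_direction / np.linalg.norm(projection_direction)
    frames = []
    for k, (p, t) in enumerate(zip(pts, tangents)):
        cosang = abs(float(np.dot(proj, t)))
        if cosang > np.cos(np.radians(5.0)):
            raise ValueError(
                f"projection direction within 5 deg of the tangent at slice {k}")
        u = proj - np.dot(proj, t) * t
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        frames.append((p.copy(), t.copy(), u, v))
    return frames


def straighten(volume: ImageVolume, cl: Centerline,
               in_plane_extent: float = 80.0,
               in_plane_spacing: float = 1.0,
               projection_direction: Sequence[float] = (1.0, 0.0, 0.0),
               interpolation: str = "linear",
               background: float | None = None) -> StraightenedVolume:
    """Straightened CPR: stack in-plane resamplings at each centerline sample.

    For each centerline point p with unit tangent t, the in-plane axes are
    ``u = normalize(proj - (proj.t) t)`` and ``v = t x u``; slice voxel (i, j)
    samples the volume at ``p + (i - c) s u + (j - c) s v``.
    """
    if cl.sampling_distance is None:
        raise ValueError("centerline must be resampled (use resample_centerline)")
    frames = _frames_from_centerline(cl, np.asarray(projection_direction, dtype=float))
    n = int(round(in_plane_extent / in_plane_spacing)) + 1
    c = (n - 1) / 2.0
    ij = (np.stack(np.meshgrid(np.arange(n), np.arange(n), indexing="ij"), axis=-1)
          - c) * in_plane_spacing
    if background is None:
        background = float(np.min(volume.voxels))
    out = np.empty((n, n, len(frames)), dtype=float)
    sp = np.asarray(volume.spacing)
    org = np.asarray(volume.origin)
    for k, (p, t, u, v) in enumerate(frames):
        world = p + ij[..., 0:1] * u + ij[..., 1:2] * v
        cont = (world - org) / sp
        out[:, :, k] = _sample(volume, cont, interpolation, background)
    return StraightenedVolume(out, in_plane_spacing, cl.sampling_distance, frames)


def straighten_point(point: Sequence[float],
                     straightened: StraightenedVolume) -> StraightenedIndex:
    """Map a world point into straightened-space (slice, u, v) indices.

    Uses the frame of the nearest centerline sample.
    """
    p = np.asarray(point, dtype=float)
    origins = np.array([f[0] for f in straightened.frames])
    d = np.linalg.norm(origins - p, axis=1)
    k = int(np.argmin(d))
    pk, t, u, v = straightened.frames[k]
    rel = p - pk
    extent = (straightened.voxels.shape[0] - 1) * straightened.in_plane_spacing
    if np.linalg.norm(rel - np.dot(rel, t) * t) > extent / 2.0:
        raise ValueError("point lies outside the swept in-plane extent")
    c = straightened.center
    iu = float(np.dot(rel, u) / straightened.in_plane_spacing + c)
    iv = float(np.dot(rel, v) / straightened.in_plane_spacing + c)
    return StraightenedIndex(k, iu, iv)


def align_straightened(s_fixed: StraightenedVolume, s_moving: StraightenedVolume,
                       lm_fixed: StraightenedIndex, lm_moving: StraightenedIndex,
                       background: float | None = None,
                       shift: tuple[int, int, int] | None = None,
                       ) -> tuple[StraightenedVolume, tuple[int, int, int]]:
    """Integer-shift s_moving so its straightened landmark matches s_fixed's.

    Returns the shifted volume on s_fixed's lattice plus the applied
    (u, v, slice) shift so that companion volumes (masks) can be moved
    identically via the ``shift`` argument.
    """
    if not np.isclose(s_fixed.in_plane_spacing, s_moving.in_plane_spacing) or \
       not np.isclose(s_fixed.slice_spacing, s_moving.slice_spacing):
        raise ValueError("straightened volumes must share spacings")
    if shift is None:
        du = int(round(lm_fixed.u - lm_moving.u))
        dv = int(round(lm_fixed.v - lm_moving.v))
        dk = int(round(lm_fixed.slice - lm_moving.slice))
        shift = (du, dv, dk)
    if background is None:
        background = float(np.min(s_moving.voxels))
    out = np.full(s_fixed.voxels.shape, background, dtype=float)
    src = s_moving.voxels
    # destination index = source index + shift, clipped to both lattices
    slices_dst, slices_src = [], []
    for ax in range(3):
        sh = shift[ax]
        d0, d1 = max(0, sh), min(out.shape[ax], src.shape[ax] + sh)
        if d0 >= d1:
            return (StraightenedVolume(out, s_fixed.in_plane_spacing,
                                       s_fixed.slice_spacing, s_fixed.frames,
                                       {"shift": shift}), shift)
        slices_dst.append(slice(d0, d1))
        slices_src.append(slice(d0 - sh, d1 - sh))
    out[tuple(slices_dst)] = src[tuple(slices_src)]
    return (StraightenedVolume(out, s_fixed.in_plane_spacing, s_fixed.slice_spacing,
                               s_fixed.frames, {"shift": shift}), shift)
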