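"""Rigid registration, straightened CPR, and straightened-space alignment."""

import numpy as np
import pytest

from evarstrain.core import (BinaryMask, ImageVolume, RigidTransform3D,
                             resample)
from evarstrain.centerline import Centerline, resample_centerline
from evarstrain.align import (StraightenedIndex, StraightenedVolume,
                              align_straightened, init_translation,
                              register_rigid, straighten, straighten_point)


def test_init_translation():
    tf = init_translation((1.0, 2.0, 3.0), (4.0, 2.0, 1.0))
    assert np.allclose(tf.rotation, np.eye(3))
    assert np.allclose(tf.translation, (3.0, 0.0, -2.0))
    with pytest.raises(ValueError):
        init_translation((np.nan, 0, 0), (0, 0, 0))


def _bone_scene(n=48):
    """Asymmetric bright structure in a dim background (registration target)."""
    vox = np.full((n, n, n), 40.0)
    vox[10:16, 10:38, 12:40] = 1200.0        # plate
    vox[30:38, 28:36, 12:40] = 1200.0        # rod
    rng = np.random.default_rng(3)
    vox += rng.normal(0.0, 5.0, vox.shape)
    vol = ImageVolume(vox)
    bone = BinaryMask((vox > 600).astype(np.uint8))
    return vol, bone


def test_register_rigid_recovers_known_transform():
    fixed, bone = _bone_scene()
    gt = RigidTransform3D.from_rotvec([0.0, 0.0, np.radians(3.0)],
                                      [4.0, -2.5, 1.5], center=(24.0, 24.0, 24.0))
    # moving(y) = fixed(gt^-1(y)), i.e. the scene moved by gt
    moving = resample(fixed, fixed, gt.inverse())
    rec = register_rigid(fixed, moving, bone)
    dR = rec.rotation @ gt.rotation.T
    ang = np.degrees(np.arccos(np.clip((np.trace(dR) - 1) / 2, -1.0, 1.0)))
    pts = np.argwhere(bone.as_bool()).astype(float)
    terr = np.linalg.norm(rec.apply(pts) - gt.apply(pts), axis=1).max()
    assert ang < 0.5
    assert terr < 0.5


def test_register_rigid_never_worsens_init():
    fixed, bone = _bone_scene()
    rec = register_rigid(fixed, fixed, bone)   # identity is already optimal
    assert rec.rotation_angle_deg() < 0.5
    assert np.linalg.norm(rec.translation) < 0.5
    with pytest.raises(ValueError):
        register_rigid(fixed, fixed, BinaryMask(np.zeros(fixed.shape, np.uint8)))


# ---------------------------------------------------------------------------
# Straightened CPR
# ---------------------------------------------------------------------------

def _tube_volume(n=32, radius=4.0):
    g = np.meshgrid(*map(np.arange, (n, n, n)), indexing="ij")
    r = np.hypot(g[0] - n / 2, g[1] - n / 2)
    return ImageVolume(np.where(r < radius, 400.0, 40.0).astype(float))


def _axis_centerline(n=32):
    z = np.arange(4.0, n - 4.0)
    pts = np.stack([np.full_like(z, n / 2), np.full_like(z, n / 2), z], axis=1)
    return resample_centerline(Centerline(pts), delta=1.0)


def test_straighten_identity_geometry():
    n = 32
    vol = _tube_volume(n)
    cl = _axis_centerline(n)
    s = straighten(vol, cl, in_plane_extent=20.0, in_plane_spacing=1.0)
    assert s.shape == (21, 21, len(cl.points))
    # straight z-tube with +x projection: straightened slices are axis-centered
    # crops of the original axial slices
    c = int(s.center)
    for k in (0, len(cl.points) // 2, len(cl.points) - 1):
        crop = vol.voxels[n // 2 - c:n // 2 + c + 1,
                          n // 2 - c:n // 2 + c + 1, int(cl.points[k, 2])]
        assert np.abs(s.voxels[:, :, k] - crop).max() < 1e-9


def test_straighten_errors():
    vol = _tube_volume()
    raw = Centerline(np.array([[16.0, 16.0, 5.0], [16.0, 16.0, 25.0]]))
    with pytest.raises(ValueError):
        straighten(vol, raw)                  # not resampled
    cl = _axis_centerline()
    with pytest.raises(ValueError):
        straighten(vol, cl, projection_direction=(0.0, 0.0, 1.0))  # parallel


def test_straighten_point_roundtrip():
    n = 32
    s = straighten(_tube_volume(n), _axis_centerline(n),
                   in_plane_extent=20.0, in_plane_spacing=1.0)
    # a point on the centerline maps to the slice center
    idx = straighten_point((n / 2, n / 2, 10.0), s)
    assert idx.slice == 6                      # z=10 is the 7th sample (z0=4)
    assert idx.u == pytest.approx(s.center)
    assert idx.v == pytest.approx(s.center)
    # offset along +x (the projection direction) moves u only
    idx2 = straighten_point((n / 2 + 3.0, n / 2, 10.0), s)
    assert idx2.u - idx.u == pytest.approx(3.0)
    assert idx2.v == pytest.approx(idx.v)
    with pytest.raises(ValueError):
        straighten_point((n / 2 + 100.0, n / 2, 10.0), s)


def test_align_straightened_shift_and_companion():
    rng = np.random.default_rng(1)
    vox = rng.normal(size=(15, 15, 20))
    s_fixed = StraightenedVolume(vox, 1.0, 1.0)
    shifted = np.roll(vox, shift=(2, -1, 3), axis=(0, 1, 2))
    s_moving = StraightenedVolume(shifted, 1.0, 1.0)
    lm_f = StraightenedIndex(10, 7.0, 7.0)
    # content rolled by (+2, -1, +3): the landmark lands there in moving space
    lm_m = StraightenedIndex(13, 9.0, 6.0)
    out, shift = align_straightened(s_fixed, s_moving, lm_f, lm_m)
    assert shift == (-2, 1, -3)
    core = (slice(4, 12), slice(4, 12), slice(5, 15))
    assert np.allclose(out.voxels[core], vox[core])
    # companion volume moved identically via the shift argument
    out2, shift2 = align_straightened(s_fixed, s_moving, lm_f, lm_m, shift=shift)
    assert shift2 == shift
    assert np.array_equal(out2.voxels, out.voxels)
    with pytest.raises(ValueError):
        align_straightened(s_fixed, StraightenedVolume(vox, 2.0, 1.0), lm_f, lm_m)
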