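"""Container invariants, geometry, I/O roundtrips, resampling and warping."""

import numpy as np
import pytest

from evarstrain.core import (BinaryMask, ImageVolume, RigidTransform3D,
                             VectorField, index_to_world, read_vector_field,
                             read_volume, resample, resample_mask, warp,
                             warp_mask, world_to_index, write_vector_field,
                             write_volume)


# ---------------------------------------------------------------------------
# Type invariants
# ---------------------------------------------------------------------------

def test_volume_rejects_bad_inputs():
    with pytest.raises(ValueError):
        ImageVolume(np.zeros((1, 8, 8)))            # < 2 voxels on an axis
    with pytest.raises(ValueError):
        ImageVolume(np.zeros((8, 8, 8)), spacing=(0.0, 1, 1))
    bad = np.zeros((4, 4, 4))
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        ImageVolume(bad)


def test_mask_values_restricted_to_01():
    BinaryMask(np.ones((4, 4, 4), dtype=np.uint8))
    with pytest.raises(ValueError):
        BinaryMask(np.full((4, 4, 4), 2, dtype=np.uint8))


def test_vector_field_shape_and_domain():
    VectorField(np.zeros((4, 4, 4, 3)))
    with pytest.raises(ValueError):
        VectorField(np.zeros((4, 4, 4, 2)))
    with pytest.raises(ValueError):
        VectorField(np.zeros((4, 4, 4, 3)), domain=np.zeros((5, 4, 4), bool))


def test_rigid_invariants():
    with pytest.raises(ValueError):
        RigidTransform3D(np.eye(3) * 2.0, np.zeros(3))
    refl = np.diag([-1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        RigidTransform3D(refl, np.zeros(3))   # det -1


def test_rigid_apply_inverse_compose(rng):
    tf = RigidTransform3D.from_rotvec(rng.normal(size=3) * 0.1,
                                      rng.normal(size=3) * 5,
                                      center=(10.0, 5.0, -2.0))
    pts = rng.normal(size=(50, 3)) * 20
    assert np.allclose(tf.inverse().apply(tf.apply(pts)), pts, atol=1e-10)
    comp = tf.compose(tf.inverse())
    assert np.allclose(comp.rotation, np.eye(3), atol=1e-10)
    assert np.allclose(comp.translation, 0.0, atol=1e-9)


def test_from_rotvec_center_is_fixed_point():
    c = np.array([10.0, 5.0, -2.0])
    tf = RigidTransform3D.from_rotvec([0.0, 0.0, 0.3], [0.0, 0.0, 0.0], center=c)
    assert np.allclose(tf.apply(c), c, atol=1e-12)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_volume_roundtrip_exact(tmp_path, rng):
    vol = ImageVolume(rng.normal(size=(16, 16, 16)),
                      spacing=(0.8, 0.8, 1.0), origin=(10.0, 0.0, -5.0))
    for name in ("v.nii.gz", "v.nii", "v.mha"):
        path = tmp_path / name
        write_volume(vol, path)
        back = read_volume(path)
        assert np.abs(back.voxels - vol.voxels).max() == 0.0
        assert np.allclose(back.spacing, vol.spacing)
        assert np.allclose(back.origin, vol.origin)


def test_mask_roundtrip_preserves_01(tmp_path, rng):
    mask = BinaryMask((rng.random((8, 8, 8)) > 0.5).astype(np.uint8))
    path = tmp_path / "m.nii.gz"
    write_volume(mask, path)
    back = read_volume(path)
    assert set(np.unique(back.voxels)) <= {0.0, 1.0}


def test_read_errors(tmp_path):
    with pytest.raises(IOError):
        read_volume(tmp_path / "missing.nii.gz")
    with pytest.raises(IOError):
        read_volume(tmp_path / "wrong.txt")
    truncated = tmp_path / "bad.nii"
    truncated.write_bytes(b"\x00" * 40)
    with pytest.raises(IOError):
        read_volume(truncated)


def test_write_to_missing_directory(tmp_path):
    vol = ImageVolume(np.zeros((4, 4, 4)))
    with pytest.raises(IOError):
        write_volume(vol, tmp_path / "no_such_dir" / "v.nii.gz")


def test_vector_field_roundtrip(tmp_path, rng):
    fv = VectorField(rng.normal(size=(6, 7, 8, 3)), spacing=(0.8, 0.8, 1.0),
                     origin=(1.0, 2.0, 3.0))
    path = tmp_path / "f.nii.gz"
    write_vector_field(fv, path)
    back = read_vector_field(path)
    assert np.allclose(back.vectors, fv.vectors)
    assert np.allclose(back.spacing, fv.spacing)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def test_index_to_world_examples():
    vol = ImageVolume(np.zeros((8, 8, 8)), spacing=(0.8, 1.0, 1.0),
                      origin=(10.0, 0.0, -5.0))
    assert np.allclose(index_to_world(vol, (0, 0, 0)), (10.0, 0.0, -5.0))
    vol0 = ImageVolume(np.zeros((8, 8, 8)), spacing=(0.8, 1.0, 1.0))
    assert np.allclose(index_to_world(vol0, (2, 0, 0)), (1.6, 0.0, 0.0))
    with pytest.raises(ValueError):
        index_to_world(vol, (8, 0, 0))


def test_world_index_inverse(rng):
    vol = ImageVolume(np.zeros((10, 12, 14)), spacing=(0.7, 0.9, 1.1),
                      origin=(-3.0, 4.0, 5.0))
    idx = rng.integers(0, (10, 12, 14), size=(100, 3))
    back = world_to_index(vol, index_to_world(vol, idx))
    assert np.allclose(back, idx, atol=1e-12)


# ---------------------------------------------------------------------------
# Resample / warp
# ---------------------------------------------------------------------------

def test_resample_identity(rng):
    vol = ImageVolume(rng.normal(size=(10, 10, 10)), spacing=(0.8, 0.8, 1.0))
    out = resample(vol, vol, RigidTransform3D.identity())
    assert np.allclose(out.voxels, vol.voxels, atol=1e-12)


def test_resample_one_voxel_translation(rng):
    vol = ImageVolume(rng.normal(size=(10, 10, 10)), spacing=(0.8, 1.0, 1.0))
    tf = RigidTransform3D(np.eye(3), np.array([0.8, 0.0, 0.0]))  # +1 voxel in x
    out = resample(vol, vol, tf)
    assert np.allclose(out.voxels[:-1], vol.voxels[1:], atol=1e-12)


def test_resample_mask_preserves_value_set(rng):
    mask = BinaryMask((rng.random((10, 10, 10)) > 0.5).astype(np.uint8))
    tf = RigidTransform3D.from_rotvec([0, 0, 0.1], [0.3, -0.4, 0.2])
    out = resample_mask(mask, mask, tf)
    assert set(np.unique(out.voxels)) <= {0, 1}


def test_resample_forward_backward_smooth(rng):
    # T then T^-1 returns the interior within interpolation tolerance
    g = np.meshgrid(*[np.linspace(-1, 1, 24)] * 3, indexing="ij")
    smooth = np.exp(-(g[0] ** 2 + g[1] ** 2 + g[2] ** 2) * 3) * 100
    vol = ImageVolume(smooth)
    tf = RigidTransform3D.from_rotvec([0, 0, 0.05], [0.4, 0.3, -0.2],
                                      center=(11.5, 11.5, 11.5))
    back = resample(resample(vol, vol, tf), vol, tf.inverse())
    rng_dyn = smooth.max() - smooth.min()
    core = (slice(4, -4),) * 3
    assert np.abs(back.voxels - vol.voxels)[core].max() <= 0.05 * rng_dyn


def test_warp_zero_field_identity(rng):
    vol = ImageVolume(rng.normal(size=(8, 8, 8)))
    out = warp(vol, VectorField(np.zeros((8, 8, 8, 3))))
    assert np.allclose(out.voxels, vol.voxels, atol=1e-12)


def test_warp_constant_equals_resample(rng):
    vol = ImageVolume(rng.normal(size=(10, 10, 10)), spacing=(0.8, 1.0, 1.0))
    U = np.zeros((10, 10, 10, 3))
    U[..., 0] = 0.8
    out_w = warp(vol, VectorField(U, vol.spacing))
    out_r = resample(vol, vol, RigidTransform3D(np.eye(3), np.array([0.8, 0, 0])))
    assert np.allclose(out_w.voxels, out_r.voxels, atol=1e-12)


def test_warp_moves_centroid():
    n = 32
    g = np.meshgrid(*[np.arange(n, dtype=float)] * 3, indexing="ij")
    blob = np.exp(-((g[0] - 16) ** 2 + (g[1] - 16) ** 2 + (g[2] - 16) ** 2) / 18.0)
    vol = ImageVolume(blob)
    U = np.zeros((n, n, n, 3))
    U[..., 1] = -2.0   # pull from +y: output(x) = blob(x + U) shifts blob by -U
    out = warp(vol, VectorField(U))

    def centroid(v):
        w = v / v.sum()
        return np.array([np.sum(w * g[d]) for d in range(3)])

    shift = centroid(out.voxels) - centroid(blob)
    assert np.linalg.norm(shift - np.array([0.0, 2.0, 0.0])) < 0.1


def test_warp_lattice_mismatch_error(rng):
    vol = ImageVolume(rng.normal(size=(8, 8, 8)))
    with pytest.raises(ValueError):
        warp(vol, VectorField(np.zeros((8, 8, 9, 3))))


def test_warp_mask_value_set(rng):
    mask = BinaryMask((rng.random((8, 8, 8)) > 0.5).astype(np.uint8))
    U = rng.normal(size=(8, 8, 8, 3)) * 0.5
    out = warp_mask(mask, VectorField(U))
    assert set(np.unique(out.voxels)) <= {0, 1}
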