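"""Phantom generator: spec validation, determinism, ground-truth consistency,
closed-form Jacobians, cohort sampling."""

import numpy as np
import pytest

from evarstrain.phantom import (EnvelopedField, GaussianBumpField,
                                IsotropicContractionField, PhantomSpec,
                                PlaneWaveField, RadialProfileField, SumField,
                                analytic_affine_field, analytic_bulge_field,
                                generate_case, generate_cohort,
                                generate_straightened_pair)
from evarstrain.core import ImageVolume


def _fd_jacobian(model, pts, h=1e-5):
    J = np.zeros((len(pts), 3, 3))
    for b in range(3):
        dp = np.zeros(3)
        dp[b] = h
        J[..., b] = (model.displacement(pts + dp) - model.displacement(pts - dp)) / (2 * h)
    return J


@pytest.fixture
def probe_points(rng):
    return rng.uniform([20.0, 20.0, 20.0], [50.0, 50.0, 90.0], size=(60, 3))


def test_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec(label="bad")
    with pytest.raises(ValueError):
        PhantomSpec(lumen_radius=20.0, thrombus_outer_radius=16.0)
    with pytest.raises(ValueError):
        PhantomSpec(noise_sd=-1.0)
    with pytest.raises(ValueError):
        PhantomSpec(bulge_amplitude=-2.0)


def test_radial_profile_jacobian_matches_fd(probe_points):
    model = RadialProfileField(4.0, (35.0, 33.0), 60.0, 18.0, 8.0)
    J = model.jacobian(probe_points)
    assert np.abs(J - _fd_jacobian(model, probe_points)).max() < 1e-7


def test_radial_profile_finite_at_axis():
    model = RadialProfileField(4.0, (35.0, 33.0), 60.0, 18.0, 8.0)
    pts = np.array([[35.0, 33.0, 60.0]])
    assert np.all(np.isfinite(model.displacement(pts)))
    assert np.all(np.isfinite(model.jacobian(pts)))
    # displacement vanishes on the axis itself
    assert np.allclose(model.displacement(pts), 0.0, atol=1e-12)


def test_gaussian_bump_jacobian_matches_fd(rng, probe_points):
    k = 5
    centers = rng.uniform(25, 45, size=(k, 3))
    dirs = rng.normal(size=(k, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    model = GaussianBumpField(centers, rng.uniform(5, 9, k),
                              rng.normal(size=k), dirs)
    J = model.jacobian(probe_points)
    assert np.abs(J - _fd_jacobian(model, probe_points)).max() < 1e-7


def test_plane_wave_jacobian_matches_fd(rng, probe_points):
    k = 6
    kdir = rng.normal(size=(k, 3))
    kdir /= np.linalg.norm(kdir, axis=1, keepdims=True)
    dirs = rng.normal(size=(k, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    model = PlaneWaveField(kdir * (2 * np.pi / rng.uniform(15, 30, k))[:, None],
                           dirs, rng.normal(size=k), rng.uniform(0, 2 * np.pi, k))
    J = model.jacobian(probe_points)
    assert np.abs(J - _fd_jacobian(model, probe_points)).max() < 1e-7


def test_isotropic_contraction_field(probe_points):
    center = np.array([35.0, 33.0, 60.0])
    model = IsotropicContractionField(1.6, center, 16.0)
    J = model.jacobian(probe_points)
    assert np.allclose(J, -0.1 * np.eye(3))
    assert np.allclose(model.displacement(probe_points),
                       -0.1 * (probe_points - center))
    with pytest.raises(ValueError):
        IsotropicContractionField(1.0, center, 0.0)


def test_enveloped_field_jacobian_and_support(rng, probe_points):
    inner = RadialProfileField(4.0, (35.0, 33.0), 60.0, 18.0, 8.0)
    model = EnvelopedField(inner, (35.0, 33.0), r_flat=17.0, r_zero=22.0,
                           z_center=60.0, z_flat_half=26.0, z_zero_half=34.0)
    J = model.jacobian(probe_points)
    assert np.abs(J - _fd_jacobian(model, probe_points)).max() < 1e-6
    # exactly zero outside the envelope support
    far = np.array([[35.0 + 25.0, 33.0, 60.0], [35.0, 33.0, 60.0 + 40.0]])
    assert np.all(model.displacement(far) == 0.0)
    assert np.all(model.jacobian(far) == 0.0)


def test_sum_field_is_sum(probe_points):
    a = RadialProfileField(2.0, (35.0, 33.0), 60.0, 18.0, 8.0)
    b = RadialProfileField(-1.0, (30.0, 30.0), 50.0, 15.0, 9.0)
    s = SumField([a, b])
    assert np.allclose(s.displacement(probe_points),
                       a.displacement(probe_points) + b.displacement(probe_points))


def test_analytic_affine_field_closed_form(rng):
    ref = ImageVolume(np.zeros((8, 9, 10)), spacing=(0.8, 0.8, 1.0),
                      origin=(2.0, -1.0, 3.0))
    A = np.eye(3) + 0.05 * rng.normal(size=(3, 3))
    fv = analytic_affine_field(A, ref)
    g = np.meshgrid(*map(np.arange, ref.shape), indexing="ij")
    pts = np.stack(g, axis=-1) * np.asarray(ref.spacing) + np.asarray(ref.origin)
    expected = pts @ (A - np.eye(3)).T
    assert np.abs(fv.vectors - expected).max() < 1e-12
    with pytest.raises(ValueError):
        analytic_affine_field(np.eye(4), ref)


def test_analytic_bulge_jacobian_evaluator(rng):
    ref = ImageVolume(np.zeros((24, 24, 32)), spacing=(2.0, 2.0, 2.0))
    fv, jac = analytic_bulge_field(ref, amplitude=3.0)
    pts = rng.uniform(10, 36, size=(40, 3))
    # the returned evaluator must agree with finite differences of the same
    # default-parameter radial model
    model = RadialProfileField(3.0, ((24 - 1) * 2.0 / 2,) * 2,
                               (32 - 1) * 2.0 / 2, (32 - 1) * 2.0 / 3, 8.0)
    assert np.abs(jac(pts) - _fd_jacobian(model, pts)).max() < 1e-7
    with pytest.raises(ValueError):
        analytic_bulge_field(ref, amplitude=-1.0)


def test_generate_case_deterministic():
    a1, b1, _ = generate_case(PhantomSpec(seed=5, shape=(40, 40, 56)))
    a2, b2, _ = generate_case(PhantomSpec(seed=5, shape=(40, 40, 56)))
    assert np.array_equal(a1.voxels, a2.voxels)
    assert np.array_equal(b1.voxels, b2.voxels)


def test_ground_truth_consistency(unfavorable_case):
    t1, t2, gt = unfavorable_case
    # deformation vanishes at the bones (rigid-stage premise); the envelope's
    # zero radius is tangent to the vertebra surface, so allow sub-micrometer
    # residuals on boundary voxels
    bone_idx = np.argwhere(gt.masks_t1["bone"].as_bool())
    bone_pts = bone_idx * np.asarray(t1.spacing)
    assert np.abs(gt.model.displacement(bone_pts)).max() < 1e-3
    # forward field is self-consistent: x + U(x) has pre-image x
    thr_idx = np.argwhere(gt.masks_t1["thrombus"].as_bool())[::97]
    pts = thr_idx * np.asarray(t1.spacing)
    from evarstrain.phantom import _invert_forward_map
    pre = _invert_forward_map(gt.model, pts + gt.model.displacement(pts))
    assert np.abs(pre - pts).max() < 1e-8
    # rigid ground truth maps t1 landmark trajectory into t2 space
    assert gt.rigid.rotation_angle_deg() <= 5.0 + 1e-9
    assert gt.label == "unfavorable"


def test_unfavorable_grows_favorable_shrinks(unfavorable_case, favorable_case):
    _, _, gt_u = unfavorable_case
    _, _, gt_f = favorable_case
    vol = lambda gt, t: gt[f"masks_{t}"]["thrombus"].volume_mm3 \
        if isinstance(gt, dict) else getattr(gt, f"masks_{t}")["thrombus"].volume_mm3
    assert vol(gt_u, "t2") > vol(gt_u, "t1")
    assert vol(gt_f, "t2") < vol(gt_f, "t1")


def test_generate_straightened_pair_properties():
    spec = PhantomSpec(seed=3, noise_sd=0.0, bulge_amplitude=0.0)
    fixed, moving, mf, mm, field = generate_straightened_pair(spec)
    # zero amplitude: identical masks and volumes, zero field
    assert np.array_equal(mf.voxels, mm.voxels)
    assert np.array_equal(fixed.voxels, moving.voxels)
    assert np.abs(field.vectors).max() == 0.0

    fixed, moving, mf, mm, field = generate_straightened_pair(seed=2)
    assert fixed.shape == moving.shape == mf.shape == field.vectors.shape[:3]
    assert np.allclose(fixed.spacing, (1.0, 1.0, 1.0))
    # outward bulge: moving thrombus is larger than fixed
    assert mm.volume_mm3 > mf.volume_mm3
    # determinism
    fixed2, *_ = generate_straightened_pair(seed=2)
    assert np.array_equal(fixed.voxels, fixed2.voxels)


def test_generate_cohort():
    specs = generate_cohort(10, 4, seed=7)
    labels = [s.label for s in specs]
    assert labels.count("unfavorable") == 4
    assert labels.count("favorable") == 6
    assert all(0 <= s.seed < 2 ** 31 for s in specs)
    specs2 = generate_cohort(10, 4, seed=7)
    assert [s.seed for s in specs] == [s.seed for s in specs2]
    assert [s.seed for s in generate_cohort(10, 4, seed=8)] != [s.seed for s in specs]
    with pytest.raises(ValueError):
        generate_cohort(5, 6)
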