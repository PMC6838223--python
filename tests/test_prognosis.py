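"""Orientation-PCA features, cross-validated SVM, diameter baseline."""

import numpy as np
import pytest

from evarstrain.core import BinaryMask
from evarstrain.prognosis import (CaseFeatures, CVReport, build_features,
                                  case_features, diameter_difference,
                                  evaluate_cv, max_diameter, orientation_pca)


def _axial_sample(rng, axis, n=200, noise=0.05):
    """Unit vectors clustered around +/- axis (axial data)."""
    v = axis + noise * rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    signs = rng.choice([-1.0, 1.0], size=n)
    return v * signs[:, None]


def test_orientation_pca_recovers_dominant_axis(rng):
    axis = np.array([1.0, 0.0, 0.0])
    v = _axial_sample(rng, axis)
    axes, w = orientation_pca(v)
    assert abs(np.dot(axes[0], axis)) > 0.99
    assert w[0] > 0.9
    assert w.sum() == pytest.approx(1.0)
    # sign-invariant: flipping any subset of vectors changes nothing
    flipped = v * rng.choice([-1.0, 1.0], size=len(v))[:, None]
    axes2, w2 = orientation_pca(flipped)
    assert np.allclose(axes2, axes)
    assert np.allclose(w2, w)
    # axes are orthonormal
    assert np.allclose(axes @ axes.T, np.eye(3), atol=1e-10)


def test_orientation_pca_degenerate_block_is_canonicalized(rng):
    # vectors uniform on a tilted-free xy circle: the two in-plane
    # eigenvalues tie at 0.5, so the in-plane pair is statistically
    # degenerate and must come out as the coordinate axes, not an
    # arbitrary rotation of them
    th = rng.uniform(0.0, 2 * np.pi, 5000)
    v = np.stack([np.cos(th), np.sin(th), np.zeros_like(th)], axis=1)
    axes, w = orientation_pca(v)
    assert np.allclose(w[:2], 0.5, atol=0.02)
    assert np.allclose(np.abs(axes), np.eye(3), atol=1e-6)
    # fully isotropic data -> the whole basis collapses to the identity
    u = rng.normal(size=(20000, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    axes_iso, w_iso = orientation_pca(u)
    assert np.allclose(w_iso, 1 / 3, atol=0.02)
    assert np.allclose(np.abs(axes_iso), np.eye(3), atol=1e-6)


def test_orientation_pca_centered_flag_differs(rng):
    # one-sided cluster: the mean is large, so centering changes the axes
    v = np.array([0.0, 0.0, 1.0]) + 0.05 * rng.normal(size=(100, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    axes_u, _ = orientation_pca(v, centered=False)
    axes_c, _ = orientation_pca(v, centered=True)
    assert abs(np.dot(axes_u[0], [0, 0, 1])) > 0.99
    assert abs(np.dot(axes_c[0], [0, 0, 1])) < 0.5
    with pytest.raises(ValueError):
        orientation_pca(v[:2])


def test_feature_vector_dimensions(rng):
    axes = np.eye(3)
    w = np.array([0.5, 0.3, 0.2])
    full = CaseFeatures("c", "favorable", axes, w, axes, w)
    assert full.feature_vector("tensile").shape == (9,)
    assert full.feature_vector("compressive").shape == (9,)
    assert full.feature_vector("both").shape == (18,)
    partial = CaseFeatures("p", "favorable", axes, w, None, None)
    with pytest.raises(ValueError):
        partial.feature_vector("both")
    with pytest.raises(ValueError):
        full.feature_vector("nonsense")


def test_build_features_excludes_lacking_cases():
    axes = np.eye(3)
    w = np.ones(3) / 3
    cases = [CaseFeatures("a", "favorable", axes, w, axes, w),
             CaseFeatures("b", "unfavorable", axes, w, None, None)]
    X, y, ids = build_features(cases, mode="both")
    assert X.shape == (1, 18) and ids == ["a"]
    X, y, ids = build_features(cases, mode="tensile")
    assert X.shape == (2, 9)
    assert list(y) == ["favorable", "unfavorable"]
    with pytest.raises(ValueError):
        build_features(cases, mode="bad")
    with pytest.raises(ValueError):
        build_features([cases[1]], mode="compressive")


def _separable_data(rng, n_per=12, d=9):
    X0 = rng.normal(size=(n_per, d))
    X1 = rng.normal(size=(n_per, d)) + 4.0
    X = np.vstack([X0, X1])
    y = np.array(["favorable"] * n_per + ["unfavorable"] * n_per)
    return X, y


def test_evaluate_cv_separable_and_deterministic(rng):
    X, y = _separable_data(rng)
    rep = evaluate_cv(X, y, folds=4, runs=3, seed=5, mode="both")
    assert rep.fold_aucs.shape == (3, 4)
    assert rep.mean_auc > 0.95
    assert rep.mean_tpr[0] == 0.0 and rep.mean_tpr[-1] == 1.0
    rep2 = evaluate_cv(X, y, folds=4, runs=3, seed=5)
    assert np.array_equal(rep.fold_aucs, rep2.fold_aucs)


def test_evaluate_cv_errors(rng):
    X, y = _separable_data(rng, n_per=3)
    with pytest.raises(ValueError):
        evaluate_cv(X, y, folds=4)            # < folds per class
    with pytest.raises(ValueError):
        evaluate_cv(X, np.array(["favorable"] * len(X)))
    with pytest.raises(ValueError):
        CVReport(np.array([[1.5]]), 1.5, np.zeros(2), np.zeros(2),
                 np.zeros(2), np.zeros(2), 0)


def test_case_features_from_strain(clean_case):
    t1, _, gt = clean_case
    from evarstrain.strain import strain_from_displacement
    sf = strain_from_displacement(gt.aneurysm_field, gt.masks_t1["thrombus"])
    feats = case_features("c0", gt.label, sf)
    assert feats.tensile_axes.shape == (3, 3)
    assert feats.feature_vector("both").shape == (18,)


# ---------------------------------------------------------------------------
# Maximum-diameter baseline
# ---------------------------------------------------------------------------

def _cylinder_mask(radius_vox, n=40, spacing=(0.5, 0.5, 1.0)):
    g = np.meshgrid(*map(np.arange, (n, n, 10)), indexing="ij")
    r = np.hypot(g[0] - n / 2, g[1] - n / 2)
    return BinaryMask((r <= radius_vox).astype(np.uint8), spacing)


def test_max_diameter_cylinder():
    m = _cylinder_mask(radius_vox=10)
    # 10-voxel radius at 0.5 mm in-plane spacing: diameter ~10 mm
    assert max_diameter(m) == pytest.approx(10.0, abs=0.5)
    with pytest.raises(ValueError):
        max_diameter(BinaryMask(np.zeros((4, 4, 4), dtype=np.uint8)))


def test_diameter_difference_sign():
    small = _cylinder_mask(8)
    big = _cylinder_mask(12)
    assert diameter_difference(small, big) > 0   # growth positive
    assert diameter_difference(big, small) < 0
    assert diameter_difference(small, small) == 0.0
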