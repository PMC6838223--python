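# Methods

This document records the computational model behind `evarstrain`, the
parameter choices, what the synthetic phantom does and does not emulate, the
numerical decisions, and the known limitations.

## 1. Problem setting

Input: two CTA volumes of the same patient after EVAR (baseline `t1`,
follow-up `t2`), a thrombus (aneurysm sac) mask per scan spanning the lowest
renal artery to the iliac bifurcation, and the lowest-renal-artery landmark
per scan.  Output: a voxel-wise finite-strain characterization of the sac
between the two timepoints and a per-case orientation descriptor suitable for
favorable/unfavorable prognosis classification.

## 2. Pipeline

### 2.1 Bone segmentation and rigid alignment

Bones (and stent metal) are segmented by thresholding at 1100 HU with
26-connected component filtering (components < 500 voxels dropped).  The
inter-scan rigid transform is initialized by the renal-landmark translation
and refined by minimizing the mean squared intensity difference (MSD)
evaluated at the fixed-scan bone voxels (mask dilated by 2 voxels so edge
gradients contribute), using a Powell search over a centered
rotation-vector + translation parameterization, coarse-to-fine (subsampled
points on Gaussian-smoothed volumes first).  Sample points mapping outside
the moving field of view are excluded from the metric (a scan pair can
truncate anatomy differently); at least 25% of points must remain valid.
The returned transform never worsens the full metric relative to the
initialization.  The underlying assumption is that the bony anatomy is rigid
between scans; the aneurysm deformation lives in soft tissue away from bone.

### 2.2 Lumen centerline

The contrasted lumen is segmented by adaptive region growing from a seed at
the renal landmark: each iteration accepts 26-neighbour frontier voxels whose
intensity lies within mean ± 2.5·sd of the region so far (sd floored at
1 HU).  The pipeline then closes sub-voxel pinholes (morphological closing +
hole filling) before topology-preserving thinning; the skeleton is decomposed
into endpoint/junction-delimited chains, loops are reduced to a maximum
spanning forest by chain length, spurs shorter than 5 mm are pruned, and the
three longest branches are kept — the aortic trunk and the two endograft
limbs.  The two limbs are paired by arc-length fraction and replaced by their
midpoints ("combined lumen" path), concatenated with the trunk, and resampled
equidistantly at 1 mm.

### 2.3 Straightened curved planar reformation (CPR)

At every centerline sample with unit tangent `t`, in-plane axes are
`u = normalize(p - (p·t) t)` (with projection direction `p = +x`) and
`v = t × u`; each slice resamples the volume on a 64 mm × 64 mm plane at 1 mm
spacing, and slices are stacked in arc-length order.  Both timepoints are
straightened around their own centerlines and aligned by the integer shift
that superimposes the straightened renal landmarks; thrombus masks are
transported with the same frames (nearest-neighbour) and the same shift.

### 2.4 Deformable registration

The straightened pair is cropped to the thrombus bounding box (10-voxel
margin) and masked to a thrombus neighbourhood (union of both masks dilated
by half the margin; outside voxels set to the shared background median) so
that residual bone fragments in the crop cannot dominate the metric.
Registration is level-set motion: per iteration the velocity is
`v = (fixed − warped) ∇warped / (|∇warped|² + ε)` with gradients per mm,
`ε = 10⁻³ · intensity_range²`, a per-voxel step cap of 0.5 voxel, and
Gaussian regularization (σ = 1 voxel) of the accumulated field; 200
iterations by default.  The field `U` lives on the fixed lattice in mm and
satisfies `warp(moving, U) ≈ fixed` — the Lagrangian displacement of
reference-configuration points.  A zero-iteration run returns the zero field;
the best iterate is kept if the last is worse.

### 2.5 Strain analysis

From `U`, central differences against physical coordinates give
`F = ∇U + I`, the right Cauchy–Green tensor `C = FᵀF`, and its
eigen-decomposition the squared principal stretches.  Where
`√λ₁ > 1` the corresponding eigenvector is the maximum tensile direction with
magnitude `√λ₁ − 1`; where `√λ₃ < 1` its eigenvector is the maximum
compressive direction with magnitude `1 − √λ₃`.  Voxels are analyzed only
where the full 6-neighbour stencil lies inside the thrombus domain; voxels
with `det F ≤ 0` (folding) are excluded and counted.

### 2.6 Prognosis features

Strain eigenvectors are axes (sign-ambiguous), so per-case statistics use the
uncentered orientation matrix `M = Σ v vᵀ / N` over the tensile (resp.
compressive) unit vectors.  Its three principal axes, in descending
eigenvalue order with canonical signs, flattened, give 9 features per field
and 18 combined.  Within a near-degenerate eigenvalue block (gap < 0.05 of
the unit-sum eigenvalues) the individual eigenvectors are statistically
meaningless — any rotation of the block fits the data equally well — so the
block basis is canonicalized to the coordinate-axis-aligned orthonormal
basis of the same subspace, making the descriptor reproducible across
statistically equivalent inputs (this matters for axisymmetric strain
patterns, whose two in-plane orientation eigenvalues tie).  Classification: z-scoring fitted on training folds only, a
linear SVM (C = 1), 4-fold stratified CV repeated 10 times with different
shuffles, fold-wise ROC-AUC averaged.  The clinical baseline — change in the
maximum per-slice Feret diameter of the thrombus — is computed alongside.

## 3. The phantom

A phantom case is an analytic scene (bone rods with curved end caps, a curved
bifurcating contrasted lumen, an ellipsoidal thrombus sheath) sampled at
(0.8, 0.8, 1.0) mm over an 88×88×112 lattice, plus Gaussian noise (sd 5 HU).
Timepoint 2 is the scene moved by a random rigid transform (≤ 5°, ≤ 20 mm)
and deformed by a closed-form displacement field:

* **unfavorable** — an outward radial bulge `U = a g(z) h(r) r̂` with
  `h(q) = 2q/(1+q²)`, `q = r/r_p`, peaking smoothly (h = 1, h′ = 0) at the
  lumen radius and decaying slowly across the wall, `a ~ U(3, 6)` mm.
  Because `h′ < 0` over the whole sheath, the radial stretch is compressive
  and the circumferential stretch tensile everywhere in the strain domain
  (the pressurized-cylinder pattern), and because `r·h(r)` is strictly
  increasing the sheath volume strictly grows.
* **favorable** — a mild isotropic contraction of the sac (strain
  `−(a/r_ref) I`, `a ~ U(1, 2)` mm at the outer radius) plus ~10
  random-phase plane-wave harmonics (wavevector and displacement directions
  independently uniform on the sphere, wavelengths 15–30 mm) rescaled so the
  mean |U| over the thrombus is ~1.1 mm.  The contraction shrinks the sac
  without preferring any direction, so the strain orientations are selected
  entirely by the harmonics and are isotropically random — favorable cases
  carry no coherent orientation signature.

The field is multiplied by a C¹ envelope (cos² ramps in radius and z) that is
identically zero at the bones, so the rigid-stage premise holds by
construction.  t2 is rendered *exactly*: every t2 lattice point is pulled
back through the rigid motion and the deformation is inverted by vectorized
Newton iteration with the closed-form Jacobian, and the analytic scene is
evaluated at the pre-image.  The stored ground truth (rigid transform,
forward displacement field, masks, centerlines, landmarks) is therefore
consistent with the voxel data to solver precision.

**Generator scope.**  The phantom is a *stage-exercising* analog, not a
patient simulator: intensities are piecewise-constant with additive Gaussian
noise (no CT point-spread function, beam hardening, or stent artifacts), the
deformation is prescribed kinematically (no mechanics), anatomy is idealized
tubes and rods.  Cohort cases jitter the vessel geometry ±10% and draw
per-case seeds; class labels map one-to-one to deformation regime.
Consequently absolute Dice/AUC values on the phantom say that the pipeline
recovers what the generator encodes — they do not certify clinical
performance.

One rendering subtlety matters: early versions ended the hip rods on a flat
plane aligned with an integer lattice coordinate.  Binary voxelization of
such a plane quantizes its apparent position coherently by up to half a
voxel, with a different phase in each timepoint, which displaced the true
rigid-metric minimum ~0.7 mm along z (the plane was the only z-localizing
bone feature).  The rods now end in hemispherical caps; curved boundaries
voxelize incoherently and the bias averages out (rigid recovery ≤ 0.23 mm in
validation).

## 4. Numerical choices

* Resampling and warping use `scipy.ndimage.map_coordinates` (linear for
  intensities, nearest for masks), with the volume minimum as background.
* The rigid optimizer is derivative-free Powell; the accuracy contract
  (0.5 mm / 0.5°) is verified empirically, and the metric point budget
  (16,000) was chosen after checking it does not degrade accuracy.
* Strain uses second-order central differences; the grid-refinement order on
  the analytic bulge field is ≈ 2, and affine fields are exact to 1e-10.
* Deformation inversion uses Newton (8 iterations) rather than fixed-point
  iteration, whose contraction can fail at default bulge amplitudes.
* Eigen-decompositions use `numpy.linalg.eigh` on symmetrized tensors; the
  symmetry defect of `C` is checked (tolerance 1e-8).
* All stochastic steps (phantom sampling, CV shuffles, metric subsampling)
  take explicit seeds; cohort generation and evaluation are deterministic
  given a seed.

## 5. Limitations

* Thrombus masks are inputs; mask quality directly bounds strain-domain
  quality.  Mask transport through the straightening frames is
  nearest-neighbour and costs ~0.05 Dice under large rigid motions.
* Strain is derived from a mono-modal intensity registration inside
  near-homogeneous thrombus; where the sac is featureless the field is
  regularization-dominated and strain magnitudes are lower bounds.
* The rigid stage assumes truly static bones; severe patient repositioning
  (spine flexion) violates this.
* The straightened frames are built from a single fixed projection direction
  (+x); centerlines nearly parallel to +x (> 85° tilt from z) are rejected
  rather than handled by frame propagation.
* The classifier is evaluated at study scale (n = 22); fold AUCs have large
  variance, which is why the mean over 40 folds is reported.
* Level-set-motion registration recovers displacement along intensity
  gradients; tangential motion within an isointense wall is unobservable
  (aperture problem), which the orientation features partially absorb.
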