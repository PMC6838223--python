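# evarstrain

Image-based 3D strain characterization of abdominal aortic aneurysms (AAA)
after endovascular repair (EVAR), from pairs of follow-up CTA scans.

After EVAR, the excluded aneurysm sac should depressurize and shrink.  When it
instead keeps deforming — typically because of an endoleak — the sac wall
carries mechanical strain between consecutive follow-up scans.  `evarstrain`
estimates that strain directly from the images: it rigidly aligns the bony
anatomy of the two scans, extracts and straightens the aortic lumen around its
centerline, deformably registers the straightened thrombus region, and
converts the recovered displacement field into voxel-wise principal strain
directions.  The global *orientation* of the maximum tensile and compressive
strain vectors — tangential vs. normal to the sac wall, summarized by an
orientation-matrix PCA — is the prognostic signature: favorably evolving sacs
show incoherently oriented low strain, unfavorably evolving sacs show a
coherent tangential-tensile / radial-compressive pattern, the kinematic
fingerprint of a pressurized, bulging membrane.

The package ships a fully synthetic phantom generator with closed-form ground
truth (displacement field, rigid motion, masks, centerlines), so every stage
is testable without clinical data, and a linear-SVM cross-validation harness
that reproduces the study design (22 cases, 9 unfavorable, 4-fold × 10-run
stratified CV) at desk scale.

## What is in the box

| Module         | Purpose |
| -------------- | ------- |
| `core`         | Volume/mask/vector-field containers, NIfTI/MetaImage I/O, rigid transforms, resampling, warping |
| `phantom`      | Synthetic CTA pair generator with analytic deformation fields and Jacobians |
| `segmentation` | Bone thresholding, adaptive region-growing lumen segmentation |
| `centerline`   | Skeletonization, branch pruning, bifurcation merging, arc-length resampling |
| `align`        | Landmark-initialized rigid registration (MSD over bone), straightened CPR |
| `deform`       | Level-set-motion deformable registration, Dice |
| `strain`       | F = ∇U + I, C = FᵀF, principal stretches, tensile/compressive vector fields |
| `prognosis`    | Orientation-PCA features, linear-SVM repeated stratified CV, diameter baseline |
| `pipeline`     | End-to-end per-case and cohort orchestration |
| `cli`          | `evarstrain phantom | run | cohort` |
| `vtk_io`       | Legacy-ASCII VTK export for ParaView/Slicer |

Thrombus segmentation is deliberately **not** included: thrombus masks are
pipeline inputs, as in the clinical setting where they come from a dedicated
segmentation step.

## Worked example

Generate a synthetic "unfavorable" case (outward aneurysm bulge between the
two timepoints), run the full pipeline, and look at the strain orientation:

```python
import numpy as np
from evarstrain import PhantomSpec
from evarstrain.pipeline import PipelineConfig, run_phantom_case

spec = PhantomSpec(seed=7, label="unfavorable")   # bulge amplitude ~U(3,6) mm
res = run_phantom_case(spec, PipelineConfig(keep_fields=True), case_id="demo")

print(f"rigid residual : {res.rigid.rotation_angle_deg():.2f} deg")
print(f"thrombus Dice  : {res.dice:.3f}")
print(f"mean tensile   : {res.summary.mean_tensile_mag:.3f}")
print(f"diameter change: {res.diameter_difference_mm:+.1f} mm")
print(f"features (18)  : {res.features.feature_vector('both').round(2)}")
```

A favorable case (`label="favorable"`) shrinks mildly with incoherent
perturbations; its tensile orientation-PCA eigenvalues are nearly isotropic,
while the unfavorable case concentrates orientation energy in the tangential
plane.  The 9-dimensional per-field descriptor (three principal orientation
axes of the strain vectors) is what the linear SVM classifies.

The same pipeline runs on real data through the CLI:

```bash
evarstrain run --t1 t1.nii.gz --t2 t2.nii.gz \
    --thrombus-t1 thr1.nii.gz --thrombus-t2 thr2.nii.gz \
    --landmarks landmarks.json --out results/
```

where `landmarks.json` holds the lowest-renal-artery position in each scan:
`{"landmark_t1": [x, y, z], "landmark_t2": [x, y, z]}` (world mm).

More narrative walk-throughs live in `examples/`.

## Conventions

* Arrays are indexed `voxels[i, j, k]` ↔ world axes (x, y, z);
  `world = origin + spacing * index`.
* Displacement fields are Lagrangian, in mm, on the reference (t1) lattice:
  `warp(moving, U) ≈ fixed`.
* Rigid transforms map fixed-space (t1) points into moving (t2) space.
* The positive classification label is `"unfavorable"`.

See `docs/methods.md` for the underlying model, parameter choices, and known
limitations.
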