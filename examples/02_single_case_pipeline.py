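"""One phantom case through the full pipeline, step by step.

`run_phantom_case` does all of this in one call; this script unrolls the
stages so you can inspect the intermediate objects.  Runtime ~30 s.
"""

import numpy as np

from evarstrain import PhantomSpec, generate_case
from evarstrain.align import init_translation, register_rigid
from evarstrain.core import resample
from evarstrain.pipeline import CaseInputs, PipelineConfig, run_case
from evarstrain.segmentation import segment_bones

spec = PhantomSpec(seed=7, label="unfavorable")
t1, t2, gt = generate_case(spec)
print(f"ground truth: {gt.label}, rigid {gt.rigid.rotation_angle_deg():.2f} deg, "
      f"|t| {np.linalg.norm(gt.rigid.translation):.1f} mm")

# stage 1 by hand: bone segmentation + rigid registration
bones = segment_bones(t1)
rigid = register_rigid(t1, t2, bones,
                       init_translation(gt.landmark_t1, gt.landmark_t2))
err = rigid.compose(gt.rigid.inverse())
print(f"rigid recovery error: {err.rotation_angle_deg():.3f} deg")

t2_aligned = resample(t2, t1, rigid)   # follow-up in baseline space
b = bones.as_bool()
print(f"median |t2 - t1| at bones: "
      f"{np.median(np.abs(resample(t2, t1).voxels - t1.voxels)[b]):.0f} HU unaligned -> "
      f"{np.median(np.abs(t2_aligned.voxels - t1.voxels)[b]):.0f} HU aligned")

# the full pipeline (centerline, CPR, deformable registration, strain)
inputs = CaseInputs(t1, t2, gt.masks_t1["thrombus"], gt.masks_t2["thrombus"],
                    gt.landmark_t1, gt.landmark_t2)
res = run_case(inputs, PipelineConfig(), case_id="example", label=gt.label)

print(f"thrombus Dice after deformable registration: {res.dice:.3f}")
print(f"mean tensile / compressive strain: "
      f"{res.summary.mean_tensile_mag:.3f} / {res.summary.mean_compressive_mag:.3f}")
print(f"diameter change: {res.diameter_difference_mm:+.1f} mm")
print("tensile orientation eigenvalues:", res.features.tensile_eigenvalues.round(3))
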