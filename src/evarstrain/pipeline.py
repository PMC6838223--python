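"""End-to-end orchestration: phantom/clinical pair -> strain features -> CV.

Stages per case: bone segmentation -> landmark-initialized rigid registration
-> lumen segmentation & centerline extraction per timepoint -> straightened
CPR -> landmark-based straightened alignment -> level-set-motion deformable
registration on a thrombus-region crop -> strain analysis -> orientation-PCA
features and the diameter-difference baseline.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .align import (StraightenedVolume, align_straightened, init_translation,
                    register_rigid, straighten, straighten_point)
from .centerline import (Centerline, merge_bifurcation, prune_to_main_branches,
                         resample_centerline, skeletonize)
from .core import (BinaryMask, ImageVolume, RigidTransform3D, VectorField,
                   resample, resample_mask, warp_mask, world_to_index)
from .deform import DeformableParams, RegistrationResult, dice, level_set_register
from .phantom import PhantomSpec, generate_case
from .prognosis import (CaseFeatures, CVReport, build_features, case_features,
                        diameter_difference, evaluate_cv)
from .segmentation import SegmentationParams, segment_bones, segment_lumen
from .strain import StrainSummary, strain_from_displacement, strain_summary

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # The lumen frontier advances ~1 voxel per iteration, so the pipeline's
    # budget is sized to span a full abdominal lumen from the renal landmark.
    segmentation: SegmentationParams = dc_field(
        default_factory=lambda: SegmentationParams(lumen_max_iterations=250))
    deformable: DeformableParams = dc_field(default_factory=DeformableParams)
    centerline_delta: float = 1.0          # mm, CPR slice spacing
    spur_length_mm: float = 5.0
    in_plane_extent: float = 64.0          # mm, CPR slice width
    in_plane_spacing: float = 1.0          # mm
    projection_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    crop_margin_voxels: int = 10           # dilation of the thrombus bbox
    cv_folds: int = 4
    cv_runs: int = 10
    seed: int = 0
    output_dir: str | None = None
    keep_fields: bool = False              # retain displacement/strain lattices

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        de = DeformableParams(**raw.pop("deformable", {}))
        if "projection_direction" in raw:
            raw["projection_direction"] = tuple(raw["projection_direction"])
        return cls(segmentation=seg, deformable=de, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class CaseInputs:
    """One patient's pipeline inputs: the two scans, thrombus masks spanning
    the lowest renal artery to the iliac bifurcation, and the lowest-renal
    landmark per scan (world mm)."""

    t1: ImageVolume
    t2: ImageVolume
    thrombus_t1: BinaryMask
    thrombus_t2: BinaryMask
    landmark_t1: np.ndarray
    landmark_t2: np.ndarray


@dataclass
class CaseResult:
    case_id: str
    label: str | None
    rigid: RigidTransform3D
    dice: float
    initial_msd: float
    final_msd: float
    summary: StrainSummary
    features: CaseFeatures
    diameter_difference_mm: float
    timings: dict = dc_field(default_factory=dict)
    counts: dict = dc_field(default_factory=dict)
    field: VectorField | None = None
    strain = None

    def to_json_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "label": self.label,
            "dice": self.dice,
            "initial_msd": self.initial_msd,
            "final_msd": self.final_msd,
            "mean_tensile_mag": self.summary.mean_tensile_mag,
            "mean_compressive_mag": self.summary.mean_compressive_mag,
            "n_tensile": self.summary.n_tensile,
            "n_compressive": self.summary.n_compressive,
            "diameter_difference_mm": self.diameter_difference_mm,
            "rigid_rotation_deg": self.rigid.rotation_angle_deg(),
            "rigid_translation_mm": self.rigid.translation.tolist(),
            "timings_s": {k: round(v, 3) for k, v in self.timings.items()},
            "counts": self.counts,
        }


def _centerline_for(volume: ImageVolume, landmark: np.ndarray,
                    config: PipelineConfig) -> Centerline:
    seed = tuple(int(round(v)) for v in world_to_index(volume, landmark))
    params = SegmentationParams(
        bone_hu_threshold=config.segmentation.bone_hu_threshold,
        bone_min_component_voxels=config.segmentation.bone_min_component_voxels,
        lumen_seed=seed,
        lumen_multiplier=config.segmentation.lumen_multiplier,
        lumen_max_iterations=config.segmentation.lumen_max_iterations)
    lumen = segment_lumen(volume, params)
    # adaptive growth rejects isolated noise voxels inside the lumen; close
    # those pinholes so thinning yields a clean curve skeleton
    from scipy import ndimage
    closed = ndimage.binary_closing(lumen.as_bool(), structure=np.ones((3, 3, 3)))
    closed = ndimage.binary_fill_holes(closed)
    lumen = BinaryMask(closed.astype(np.uint8), lumen.spacing, lumen.origin)
    sk = skeletonize(lumen)
    branches = prune_to_main_branches(sk, n=3, spur_length_mm=config.spur_length_mm)
    if len(branches) >= 3:
        cl = merge_bifurcation(branches[:3], landmark=landmark)
    else:
        # degenerate phantom/clinical case without a visible bifurcation
        logger.warning("fewer than 3 branches; using the longest path directly")
        path = branches[0]
        if np.linalg.norm(path[0] - landmark) < np.linalg.norm(path[-1] - landmark):
            path = path[::-1]
        cl = Centerline(path)
    return resample_centerline(cl, config.centerline_delta)


def _straighten_set(volume: ImageVolume, mask: BinaryMask, landmark: np.ndarray,
                    cl: Centerline, config: PipelineConfig):
    s = straighten(volume, cl, config.in_plane_extent, config.in_plane_spacing,
                   config.projection_direction)
    mask_vol = ImageVolume(mask.voxels.astype(float), mask.spacing, mask.origin)
    sm = straighten(mask_vol, cl, config.in_plane_extent, config.in_plane_spacing,
                    config.projection_direction, interpolation="nearest",
                    background=0.0)
    lm = straighten_point(landmark, s)
    return s, sm, lm


def _bbox_crop(mask: np.ndarray, margin: int):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def run_case(inputs: CaseInputs, config: PipelineConfig | None = None,
             case_id: str = "case", label: str | None = None) -> CaseResult:
    """Run the full registration + strain pipeline on one scan pair."""
    config = config or PipelineConfig()
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}

    t0 = time.perf_counter()
    bones = segment_bones(inputs.t1, config.segmentation)
    counts["bone_voxels"] = int(bones.voxels.sum())
    timings["segment_bones"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    init = init_translation(inputs.landmark_t1, inputs.landmark_t2)
    rigid = register_rigid(inputs.t1, inputs.t2, bones, init)
    timings["rigid"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    t2a = resample(inputs.t2, inputs.t1, rigid)
    thr2a = resample_mask(inputs.thrombus_t2, inputs.t1, rigid)
    lm2a = rigid.inverse().apply(inputs.landmark_t2)
    timings["resample"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cl1 = _centerline_for(inputs.t1, inputs.landmark_t1, config)
    cl2 = _centerline_for(t2a, lm2a, config)
    counts["centerline_points_t1"] = len(cl1.points)
    counts["centerline_points_t2"] = len(cl2.points)
    timings["centerline"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    s1, sm1, slm1 = _straighten_set(inputs.t1, inputs.thrombus_t1,
                                    inputs.landmark_t1, cl1, config)
    s2, sm2, slm2 = _straighten_set(t2a, thr2a, lm2a, cl2, config)
    s2a, shift = align_straightened(s1, s2, slm1, slm2)
    sm2a, _ = align_straightened(sm1, sm2, slm1, slm2, background=0.0, shift=shift)
    timings["cpr"] = time.perf_counter() - t0

    fixed_mask = sm1.voxels > 0.5
    if not fixed_mask.any():
        raise RuntimeError(f"{case_id}: straightened thrombus mask is empty")
    crop = _bbox_crop(fixed_mask, config.crop_margin_voxels)
    sp = s1.spacing

    mfix = BinaryMask(fixed_mask[crop].astype(np.uint8), sp)
    mmov = BinaryMask((sm2a.voxels[crop] > 0.5).astype(np.uint8), sp)
    # restrict registration to the thrombus neighbourhood: unrelated bright
    # structures (bone corners) otherwise dominate the intensity residual
    from scipy import ndimage as _ndi
    roi = _ndi.binary_dilation(mfix.as_bool() | mmov.as_bool(),
                               iterations=config.crop_margin_voxels // 2 or 1)
    bg = float(np.median(s1.voxels[crop][~roi])) if (~roi).any() \
        else float(s1.voxels.min())
    fvox = np.where(roi, s1.voxels[crop], bg)
    mvox = np.where(roi, s2a.voxels[crop], bg)
    fx = ImageVolume(fvox, sp)
    mv = ImageVolume(mvox, sp)
    counts["thrombus_voxels_straightened"] = int(mfix.voxels.sum())

    counts["pre_registration_dice"] = round(dice(mfix, mmov), 4)

    t0 = time.perf_counter()
    reg = level_set_register(fx, mv, config.deformable)
    warped_mask = warp_mask(mmov, reg.field)
    reg.dice = dice(mfix, warped_mask)
    timings["deformable"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    sf = strain_from_displacement(reg.field, mfix)
    counts["valid_strain_voxels"] = int(sf.valid.sum())
    counts["tensile_voxels"] = int(sf.tensile_present.sum())
    counts["compressive_voxels"] = int(sf.compressive_present.sum())
    summ = strain_summary(sf)
    feats = case_features(case_id, label or "", sf)
    dd = diameter_difference(inputs.thrombus_t1, thr2a)
    timings["strain"] = time.perf_counter() - t0

    res = CaseResult(case_id=case_id, label=label, rigid=rigid, dice=reg.dice,
                     initial_msd=reg.initial_msd, final_msd=reg.final_msd,
                     summary=summ, features=feats, diameter_difference_mm=dd,
                     timings=timings, counts=counts)
    if config.keep_fields:
        res.field = reg.field
        res.strain = sf
    if config.output_dir:
        _write_case_outputs(res, inputs, reg, config)
    return res


def run_phantom_case(spec: PhantomSpec, config: PipelineConfig | None = None,
                     case_id: str | None = None) -> CaseResult:
    """Generate a phantom pair and push it through the pipeline.

    Thrombus masks and renal landmarks come from the phantom ground truth
    (they are pipeline inputs, as for clinical data)."""
    t1, t2, gt = generate_case(spec)
    inputs = CaseInputs(t1, t2, gt.masks_t1["thrombus"], gt.masks_t2["thrombus"],
                        gt.landmark_t1, gt.landmark_t2)
    return run_case(inputs, config, case_id or f"phantom-{spec.seed}", gt.label)


@dataclass
class CohortResult:
    cases: list
    reports: dict          # mode -> CVReport
    failed: list


def run_cohort(specs: list[PhantomSpec], config: PipelineConfig | None = None,
               modes: tuple[str, ...] = ("tensile", "compressive", "both"),
               ) -> CohortResult:
    """Run the pipeline per case, then evaluate the SVM cross-validation for
    each feature mode.  Per-case failures are logged and excluded; the run
    fails if more than 20% of cases fail."""
    config = config or PipelineConfig()
    results, failed = [], []
    for i, spec in enumerate(specs):
        cid = f"case-{i:02d}"
        try:
            results.append(run_phantom_case(spec, config, cid))
        except Exception as exc:  # noqa: BLE001 - per-case isolation
            logger.error("case %s failed: %s", cid, exc)
            failed.append((cid, str(exc)))
    if len(failed) > 0.2 * len(specs):
        raise RuntimeError(f"{len(failed)}/{len(specs)} cases failed: {failed}")

    reports = {}
    for mode in modes:
        X, y, ids = build_features([r.features for r in results], mode)
        reports[mode] = evaluate_cv(X, y, config.cv_folds, config.cv_runs,
                                    seed=config.seed, mode=mode)
    if config.output_dir:
        _write_cohort_outputs(results, reports, config)
    return CohortResult(results, reports, failed)


# ---------------------------------------------------------------------------
# Artifact writing
# ---------------------------------------------------------------------------

def _write_case_outputs(res: CaseResult, inputs: CaseInputs,
                        reg: RegistrationResult, config: PipelineConfig) -> None:
    from .core import write_vector_field
    from .vtk_io import write_structured_vector_field

    out = Path(config.output_dir) / res.case_id
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(res.to_json_dict(), fh, indent=2)
    write_vector_field(reg.field, out / "displacement.nii.gz")
    write_structured_vector_field(reg.field, out / "displacement.vtk")


def _write_cohort_outputs(results, reports, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [r.to_json_dict() for r in results]
    with open(out / "cases.json", "w") as fh:
        json.dump(rows, fh, indent=2)
    rep = {}
    for mode, r in reports.items():
        rep[mode] = {
            "mean_auc": r.mean_auc,
            "fold_aucs": r.fold_aucs.tolist(),
            "fpr_grid": r.fpr_grid.tolist(),
            "mean_tpr": r.mean_tpr.tolist(),
            "recall_grid": r.recall_grid.tolist(),
            "mean_precision": r.mean_precision.tolist(),
            "seed": r.seed,
        }
    manifest = {
        "version": _pkg_version,
        "seed": config.seed,
        "config": _jsonable(config.to_dict()),
    }
    with open(out / "cv_reports.json", "w") as fh:
        json.dump(rep, fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
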