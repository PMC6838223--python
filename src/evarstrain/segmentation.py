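"""Bone and lumen segmentation.

Bones are segmented by thresholding plus connected-component size filtering
(CT bone and stent metal are far brighter than soft tissue).  The contrasted
lumen is segmented by adaptive region growing: the acceptance interval tracks
the mean +/- k*sd of the region grown so far, so the region adapts to the
local contrast statistics.  26-connectivity is used throughout.

Thrombus segmentation is deliberately not implemented here: thrombus masks
are inputs to the pipeline, expected to span the lowest renal artery to the
iliac bifurcation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ImageVolume

logger = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    bone_hu_threshold: float = 1100.0
    bone_min_component_voxels: int = 500
    lumen_seed: tuple[int, int, int] | None = None
    lumen_multiplier: float = 2.5
    lumen_max_iterations: int = 50

    def __post_init__(self) -> None:
        if not np.isfinite(self.bone_hu_threshold):
            raise ValueError("bone threshold must be finite")
        if self.lumen_multiplier <= 0:
            raise ValueError("lumen multiplier k must be > 0")
        if self.bone_min_component_voxels < 1:
            raise ValueError("minimum component size must be >= 1")


def segment_bones(volume: ImageVolume,
                  params: SegmentationParams | None = None) -> BinaryMask:
    """Threshold + 26-connected component analysis; small components dropped."""
    params = params or SegmentationParams()
    above = volume.voxels >= params.bone_hu_threshold
    labels, n = ndimage.label(above, structure=_CONN26)
    if n == 0:
        return BinaryMask(np.zeros(volume.shape, dtype=np.uint8),
                          volume.spacing, volume.origin)
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= params.bone_min_component_voxels)
    keep = keep[keep != 0]
    mask = np.isin(labels, keep)
    return BinaryMask(mask.astype(np.uint8), volume.spacing, volume.origin)


def segment_lumen(volume: ImageVolume,
                  params: SegmentationParams) -> BinaryMask:
    """Adaptive region growing from a seed inside the contrasted lumen.

    Each iteration accepts frontier 26-neighbours whose intensity lies within
    ``[mu - k*sd, mu + k*sd]`` of the currently accepted region (sd floored at
    1 HU), until a fixed point or ``lumen_max_iterations``.  Degenerate growth
    beyond half the volume is flagged in ``mask.meta``.
    """
    if params.lumen_seed is None:
        raise ValueError("segment_lumen requires params.lumen_seed")
    seed = tuple(int(v) for v in params.lumen_seed)
    shape = volume.shape
    if any(not (0 <= seed[a] < shape[a]) for a in range(3)):
        raise ValueError(f"lumen seed {seed} outside volume of shape {shape}")

    vox = volume.voxels
    region = np.zeros(shape, dtype=bool)
    # seed with the 3x3x3 neighbourhood, not the single voxel: one noisy
    # sample gives mu equal to that draw and sd at the floor, so in a noisy
    # image every neighbour can miss the +-k*sd band and growth stalls at
    # the seed
    block = tuple(slice(max(seed[a] - 1, 0), min(seed[a] + 2, shape[a]))
                  for a in range(3))
    region[block] = True
    vals0 = vox[region].astype(float)
    total = float(vals0.sum())
    total_sq = float((vals0 ** 2).sum())
    n = int(vals0.size)
    k = params.lumen_multiplier
    converged = False
    for _ in range(params.lumen_max_iterations):
        mu = total / n
        var = max(total_sq / n - mu * mu, 0.0)
        sd = max(np.sqrt(var), 1.0)
        frontier = ndimage.binary_dilation(region, structure=_CONN26) & ~region
        accept = frontier & (vox >= mu - k * sd) & (vox <= mu + k * sd)
        cnt = int(accept.sum())
        if cnt == 0:
            converged = True
            break
        vals = vox[accept]
        total += float(vals.sum())
        total_sq += float((vals.astype(float) ** 2).sum())
        n += cnt
        region |= accept

    mask = BinaryMask(region.astype(np.uint8), volume.spacing, volume.origin)
    if n > 0.5 * region.size:
        logger.warning("lumen region growing degenerated to >50%% of the volume")
        mask.meta["degenerate_growth"] = True
    if not converged:
        mask.meta["max_iterations_reached"] = True
    return mask
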