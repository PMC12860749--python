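"""Threshold-based skeletal MTV/TLG quantification.

The segmentation threshold is the liver SUVmedian, inclusion is closed
(SUV >= threshold counts), the skull is excluded from the skeleton, and an
optional morphological erosion of the skeletal mask stands in for the
spillover-reduction step of the original pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import DegenerateMaskError, InvalidInputError
from .grids import LabelMask, VolumeGrid, require_aligned
from .pet_metrics import SuvStats


@dataclass
class VolumetricResult:
    """MTV (ml), TLG (g) = SUVmean * MTV, and the segmentation provenance."""

    mtv_ml: float
    tlg_g: float
    threshold_suv: float
    suv_mean: float
    voxel_count: int
    segmentation: Optional[LabelMask] = None


def mm_threshold(liver_stats: SuvStats) -> float:
    """Segmentation threshold: the liver SUVmedian."""
    if liver_stats is None or liver_stats.voxel_count <= 0:
        raise DegenerateMaskError("liver VOI is empty; cannot derive the SUV threshold")
    return liver_stats.suv_median


def skeletal_working_mask(
    skeleton: LabelMask, skull: LabelMask, erosion_mm: float = 2.0
) -> LabelMask:
    """Skeleton minus skull, then eroded by ``erosion_mm`` (0 disables).

    Erosion uses the Euclidean distance transform with the grid's anisotropic
    spacing, keeping voxels deeper than ``erosion_mm`` from the mask boundary.
    """
    require_aligned(skeleton, skull)
    if erosion_mm < 0:
        raise InvalidInputError("erosion_mm must be >= 0")
    base = skeleton.data & ~skull.data
    if erosion_mm > 0 and base.any():
        d = ndimage.distance_transform_edt(base, sampling=skeleton.spacing)
        base = d > erosion_mm
    if not base.any():
        raise DegenerateMaskError(
            f"skeletal mask is empty after skull exclusion and {erosion_mm} mm erosion"
        )
    return LabelMask(data=base, affine=skeleton.affine.copy(), label="skeletal_working")


def segment_and_quantify(
    suv: VolumeGrid,
    working_mask: LabelMask,
    threshold_suv: float,
    keep_segmentation: bool = False,
) -> VolumetricResult:
    """MTV = volume of working-mask voxels with SUV >= threshold; TLG = SUVmean * MTV."""
    require_aligned(suv, working_mask)
    if working_mask.voxel_count == 0:
        raise DegenerateMaskError("working mask is empty")
    seg = working_mask.data & (suv.data >= threshold_suv)
    n = int(seg.sum())
    mtv_ml = n * suv.voxel_volume_mm3 / 1000.0
    suv_mean = float(suv.data[seg].mean()) if n else 0.0
    tlg_g = suv_mean * mtv_ml
    return VolumetricResult(
        mtv_ml=mtv_ml,
        tlg_g=tlg_g,
        threshold_suv=float(threshold_suv),
        suv_mean=suv_mean,
        voxel_count=n,
        segmentation=LabelMask.like(suv, seg, "mtv_segmentation") if keep_segmentation else None,
    )
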