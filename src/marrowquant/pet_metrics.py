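"""PET SUV computation and VOI statistics.

Body-weight SUV normalization: SUV = C[kBq/ml] / (dose[kBq] / weight[g]).
Decay correction is assumed applied upstream.  Masks defined on one grid
(typically CT) are carried to another by nearest-neighbor label transfer in
world coordinates — labels are never interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateMaskError, InvalidInputError
from .grids import LabelMask, VolumeGrid, require_aligned


@dataclass
class SuvStats:
    """Max / mean / median SUV over a VOI plus its size."""

    suv_max: float
    suv_mean: float
    suv_median: float
    voxel_count: int
    volume_ml: float


def compute_suv(
    activity: VolumeGrid, injected_dose_MBq: float, body_weight_kg: float
) -> VolumeGrid:
    """Convert an activity-concentration volume (kBq/ml) to SUV (g/ml).

    SUV = concentration / (injected dose / body weight); linear in activity.
    """
    if injected_dose_MBq <= 0:
        raise InvalidInputError(f"injected dose must be positive, got {injected_dose_MBq}")
    if body_weight_kg <= 0:
        raise InvalidInputError(f"body weight must be positive, got {body_weight_kg}")
    # dose in kBq over weight in g: (MBq*1000) / (kg*1000) == MBq/kg numerically
    denom = injected_dose_MBq / body_weight_kg
    return VolumeGrid(data=activity.data / denom, affine=activity.affine.copy())


def voi_stats(suv: VolumeGrid, mask: LabelMask) -> SuvStats:
    """Exact max/mean/median over masked voxels; volume in ml."""
    require_aligned(suv, mask)
    n = mask.voxel_count
    if n == 0:
        raise DegenerateMaskError(f"VOI {mask.label or '(unnamed)'} is empty")
    vals = suv.data[mask.data]
    return SuvStats(
        suv_max=float(vals.max()),
        suv_mean=float(vals.mean()),
        suv_median=float(np.median(vals)),
        voxel_count=n,
        volume_ml=n * suv.voxel_volume_mm3 / 1000.0,
    )


def resample_mask(mask: LabelMask, target: VolumeGrid | LabelMask) -> LabelMask:
    """Nearest-neighbor transfer of a label mask onto a target grid.

    Idempotent when the grids already coincide.  If the mask lies wholly
    outside the target field of view the result is empty and a warning is
    issued; downstream VOI statistics will then raise.
    """
    if mask.same_geometry(target):
        return LabelMask(data=mask.data.copy(), affine=mask.affine.copy(), label=mask.label)

    # target voxel index -> world -> source voxel index
    xform = np.linalg.inv(mask.affine) @ target.affine
    idx = np.indices(target.shape, dtype=np.float64).reshape(3, -1)
    hom = np.vstack([idx, np.ones((1, idx.shape[1]))])
    src = (xform @ hom)[:3]
    out = ndimage.map_coordinates(
        mask.data.astype(np.uint8), src, order=0, mode="constant", cval=0
    ).reshape(target.shape)
    result = LabelMask(data=out.astype(bool), affine=np.asarray(target.affine).copy(), label=mask.label)
    if mask.voxel_count > 0 and result.voxel_count == 0:
        warnings.warn(
            f"mask {mask.label or '(unnamed)'} does not overlap the target field of view",
            stacklevel=2,
        )
    return result
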