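"""CT-based bone-marrow quantification.

Two quantification routes over the medullary cavity of long bones:

* the *manual* route — the highest mean HU over circular ROIs placed in the
  cavity, automated here as an exhaustive sweep of axial-disc (or spherical)
  ROIs over all fully-interior centers and a set of radii;
* the *semi-automated* route — a cumulative CT value (cCTv) that weights the
  mean HU of infiltrated voxels by the infiltrated-to-cavity volume ratio.

Tissue classification uses the standard HU bands for appendicular marrow:
fatty marrow [-200, -30], myelomatous infiltration (-30, 120], cortical
bone (120, inf).  Band boundaries are half-open so that every finite HU
value belongs to exactly one class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import DegenerateMaskError, InvalidInputError
from .grids import LabelMask, VolumeGrid, require_aligned

FAT_LOW = -200.0
FAT_HIGH = -30.0
CORTICAL_LOW = 120.0


class TissueClass(str, Enum):
    FAT_MARROW = "fat_marrow"
    INFILTRATED = "infiltrated"
    CORTICAL = "cortical"
    OUT_OF_RANGE = "out_of_range"


def classify_voxel(hu: float) -> TissueClass:
    """Classify a single HU value into its tissue band.

    fat_marrow iff -200 <= hu <= -30; infiltrated iff -30 < hu <= 120;
    cortical iff hu > 120; out_of_range iff hu < -200.
    """
    if not np.isfinite(hu):
        raise InvalidInputError(f"HU value must be finite, got {hu!r}")
    if hu < FAT_LOW:
        return TissueClass.OUT_OF_RANGE
    if hu <= FAT_HIGH:
        return TissueClass.FAT_MARROW
    if hu <= CORTICAL_LOW:
        return TissueClass.INFILTRATED
    return TissueClass.CORTICAL


def infiltrated_band(hu: np.ndarray) -> np.ndarray:
    """Vectorized indicator of the infiltrated band (-30, 120]."""
    hu = np.asarray(hu)
    return (hu > FAT_HIGH) & (hu <= CORTICAL_LOW)


def medullary_working_mask(
    ct: VolumeGrid, cavity: LabelMask, epiphysis: LabelMask
) -> LabelMask:
    """Cavity minus epiphyses minus cortical-density voxels (HU > 120).

    The boundary is strict: a cavity voxel at exactly 120 HU is retained.
    """
    require_aligned(ct, cavity, epiphysis)
    mask = cavity.data & ~epiphysis.data & ~(ct.data > CORTICAL_LOW)
    return LabelMask.like(ct, mask, "medullary_working")


@dataclass
class RoiSpec:
    """A circular (axial-disc) or spherical ROI."""

    center: tuple[int, int, int]  # voxel index
    radius_mm: float
    shape: str = "disc"  # "disc" | "sphere"
    plane_axis: int = 2

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise InvalidInputError("ROI radius must be positive")


@dataclass
class CtQuantResult:
    """Manual-approach output: the highest ROI-mean HU and its ROI."""

    ctv: float
    best_roi: RoiSpec
    per_radius: dict = field(default_factory=dict)  # radius_mm -> best mean at that radius
    per_bone_values: list = field(default_factory=list)


@dataclass
class CctvResult:
    """Semi-automated output: cumulative CT value and its provenance."""

    cctv: float
    cumulative_hu: float
    mm_volume_mm3: float
    cavity_volume_mm3: float
    interpretation: str = "mean_scaled"


def _disc_footprint(radius_mm: float, spacing, plane_axis: int) -> np.ndarray:
    plane_axes = [i for i in range(3) if i != plane_axis]
    s1, s2 = spacing[plane_axes[0]], spacing[plane_axes[1]]
    n1 = int(np.floor(radius_mm / s1))
    n2 = int(np.floor(radius_mm / s2))
    i, j = np.meshgrid(np.arange(-n1, n1 + 1), np.arange(-n2, n2 + 1), indexing="ij")
    disc = (i * s1) ** 2 + (j * s2) ** 2 <= radius_mm**2
    shape = [1, 1, 1]
    shape[plane_axes[0]] = disc.shape[0]
    shape[plane_axes[1]] = disc.shape[1]
    return disc.reshape(shape)


def _ball_footprint(radius_mm: float, spacing) -> np.ndarray:
    ns = [int(np.floor(radius_mm / s)) for s in spacing]
    i, j, k = np.meshgrid(
        *(np.arange(-n, n + 1) for n in ns), indexing="ij"
    )
    return (i * spacing[0]) ** 2 + (j * spacing[1]) ** 2 + (k * spacing[2]) ** 2 <= radius_mm**2


def manual_ctv(
    ct: VolumeGrid,
    working_mask: LabelMask,
    radii_mm: Sequence[float] = (3.0, 4.0, 5.0, 6.0),
    roi_shape: str = "disc",
    plane_axis: int = 2,
    stride: int = 1,
) -> CtQuantResult:
    """Exhaustive ROI sweep: the maximum ROI-mean HU over the working mask.

    Only ROIs lying entirely inside the mask are evaluated.  Ties are broken
    deterministically: earlier radius in ``radii_mm``, then lowest voxel
    index in C order.
    """
    require_aligned(ct, working_mask)
    if working_mask.voxel_count == 0:
        raise DegenerateMaskError("working mask is empty")
    if stride < 1:
        raise InvalidInputError("stride must be >= 1")

    mask = working_mask.data
    masked_ct = np.where(mask, ct.data, 0.0)

    best_mean = -np.inf
    best_roi = None
    per_radius: dict[float, float] = {}
    for r in radii_mm:
        if r <= 0:
            raise InvalidInputError("ROI radii must be positive")
        if roi_shape == "disc":
            fp = _disc_footprint(r, ct.spacing, plane_axis)
        elif roi_shape == "sphere":
            fp = _ball_footprint(r, ct.spacing)
        else:
            raise InvalidInputError(f"unknown ROI shape {roi_shape!r}")
        size = int(fp.sum())
        counts = ndimage.convolve(mask.astype(np.int64), fp.astype(np.int64), mode="constant")
        sums = ndimage.convolve(masked_ct, fp.astype(np.float64), mode="constant")
        valid = (counts == size) & mask
        if stride > 1:
            lattice = np.zeros_like(valid)
            lattice[::stride, ::stride, ::stride] = True
            valid &= lattice
        if not valid.any():
            continue
        means = np.where(valid, sums / size, -np.inf)
        flat = int(np.argmax(means))
        m = float(means.flat[flat])
        per_radius[float(r)] = m
        if m > best_mean:
            best_mean = m
            center = tuple(int(c) for c in np.unravel_index(flat, means.shape))
            best_roi = RoiSpec(center=center, radius_mm=float(r), shape=roi_shape, plane_axis=plane_axis)
    if best_roi is None:
        raise DegenerateMaskError(
            "no ROI of the requested radii fits entirely inside the working mask"
        )
    return CtQuantResult(ctv=best_mean, best_roi=best_roi, per_radius=per_radius)


def compute_cctv(
    ct: VolumeGrid, working_mask: LabelMask, interpretation: str = "mean_scaled"
) -> CctvResult:
    """Cumulative CT value over the working mask.

    MM voxels are the working-mask voxels in the infiltrated band (-30, 120].
    Default ``mean_scaled`` reading::

        cCTv = (sum of HU over MM voxels) * voxel_volume / cavity_volume
             = mean HU over MM * (V_MM / V_cavity)

    which has HU units and matches the reported magnitude of the statistic.
    The ``literal`` reading multiplies the raw HU sum by the volume ratio
    without the per-voxel normalization and is kept selectable because the
    published formula is dimensionally ambiguous.
    """
    require_aligned(ct, working_mask)
    n_cavity = working_mask.voxel_count
    if n_cavity == 0:
        raise DegenerateMaskError("working mask is empty: zero cavity volume")
    if interpretation not in ("mean_scaled", "literal"):
        raise InvalidInputError(f"unknown cCTv interpretation {interpretation!r}")

    voxvol = ct.voxel_volume_mm3
    mm = working_mask.data & infiltrated_band(ct.data)
    n_mm = int(mm.sum())
    cum_hu = float(ct.data[mm].sum())
    v_mm = n_mm * voxvol
    v_cavity = n_cavity * voxvol
    if interpretation == "mean_scaled":
        cctv = cum_hu * voxvol / v_cavity
    else:
        cctv = cum_hu * v_mm / v_cavity
    return CctvResult(
        cctv=cctv,
        cumulative_hu=cum_hu,
        mm_volume_mm3=v_mm,
        cavity_volume_mm3=v_cavity,
        interpretation=interpretation,
    )


def manual_ctv_multi(
    ct: VolumeGrid,
    working_masks: Sequence[LabelMask],
    radii_mm: Sequence[float] = (3.0, 4.0, 5.0, 6.0),
    **kwargs,
) -> CtQuantResult:
    """Manual CTv over several bones: per-bone sweeps, best ROI overall."""
    results = [manual_ctv(ct, m, radii_mm, **kwargs) for m in working_masks]
    best = max(range(len(results)), key=lambda i: results[i].ctv)
    out = results[best]
    out.per_bone_values = [r.ctv for r in results]
    return out
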