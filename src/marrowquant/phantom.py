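"""Synthetic CT/PET long-bone phantoms and cohorts with known ground truth.

The phantom is an idealized long bone: a cylinder along ``bone_axis`` with a
high-attenuation cortical shell, a medullary cavity filled with fatty marrow
(HU in [-200, -30]) and an infiltrated subset raised into (-30, 120] HU, and
epiphysis segments at both ends.  PET volumes share the grid by default and
place rectangular liver / mediastinum / skull reference regions in the
corners, with marrow uptake linear in the local infiltration indicator.

Cohorts pair a baseline and a follow-up scan per patient, apply a
multiplicative treatment effect to the infiltration fraction, and plant
monotone links from infiltration to clinical covariates (plasma-cell
infiltration %, beta-2-microglobulin) plus a logistic MRD-negativity model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import InvalidSpecError
from .grids import LabelMask, VolumeGrid

# HU band edges shared with ct_marrow.classify_voxel
FAT_HU_LOW, FAT_HU_HIGH = -200.0, -30.0
INFILTRATED_HU_HIGH = 120.0


class PhantomSpec(BaseModel):
    """Parameters of a single CT long-bone phantom."""

    model_config = ConfigDict(extra="forbid")

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bone_axis: int = Field(default=2, ge=0, le=2)
    cortical_hu: float = Field(default=800.0, gt=120.0)
    fat_hu_mean: float = Field(default=-80.0, ge=FAT_HU_LOW, le=FAT_HU_HIGH)
    fat_hu_sd: float = Field(default=10.0, ge=0.0)
    lesion_hu_mean: float = Field(default=40.0, gt=FAT_HU_HIGH, le=INFILTRATED_HU_HIGH)
    lesion_hu_sd: float = Field(default=10.0, ge=0.0)
    infiltration_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    infiltration_pattern: Literal["diffuse", "focal", "mixed"] = "diffuse"
    n_focal_lesions: int = Field(default=3, ge=1)
    epiphysis_fraction: float = Field(default=0.15, ge=0.0, lt=0.5)
    noise_sd_hu: float = Field(default=0.0, ge=0.0)
    seed: int = 0
    # geometry knobs (not part of the published tissue model)
    outer_radius_frac: float = Field(default=0.4, gt=0.0, le=0.45)
    shell_thickness_mm: float = Field(default=3.0, gt=0.0)
    background_hu: float = 20.0  # soft tissue surrounding the bone

    @model_validator(mode="after")
    def _check_grid(self):
        if any(n < 4 for n in self.grid_shape):
            raise ValueError("grid_shape axes must each be >= 4 voxels")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        return self


class PetSpec(BaseModel):
    """Parameters of the PET counterpart of a CT phantom."""

    model_config = ConfigDict(extra="forbid")

    injected_dose_MBq_per_kg: float = Field(default=3.0, gt=0.0)
    body_weight_kg: float = Field(default=75.0, gt=0.0)
    background_suv: float = Field(default=0.8, ge=0.0)
    mediastinum_suv: float = Field(default=1.5, ge=0.0)
    liver_suv_mean: float = Field(default=2.0, ge=0.0)
    liver_suv_sd: float = Field(default=0.0, ge=0.0)
    marrow_suv_slope: float = Field(default=3.0, ge=0.0)
    focal_lesion_suv: Optional[float] = Field(default=None, ge=0.0)
    skull_suv: float = Field(default=6.0, ge=0.0)
    noise_sd_suv: float = Field(default=0.0, ge=0.0)
    seed: int = 0


class CohortSpec(BaseModel):
    """A paired baseline/follow-up synthetic cohort."""

    model_config = ConfigDict(extra="forbid")

    n_patients: int = Field(default=40, ge=2)
    ct: PhantomSpec = Field(default_factory=PhantomSpec)
    pet: PetSpec = Field(default_factory=PetSpec)
    infiltration_range: tuple[float, float] = (0.1, 0.5)
    treatment_effect: float = Field(default=0.8, ge=0.0, le=1.0)
    # covariate model: monotone link + Gaussian noise from baseline infiltration
    plasma_cell_slope: float = 100.0
    plasma_cell_noise_sd: float = Field(default=0.0, ge=0.0)
    b2m_intercept: float = 1.0
    b2m_slope: float = 10.0
    b2m_noise_sd: float = Field(default=0.0, ge=0.0)
    # P(MRD negative) = logistic(mrd_intercept - mrd_slope * followup_infiltration)
    mrd_intercept: float = 2.0
    mrd_slope: float = 20.0
    seed: int = 0

    @model_validator(mode="after")
    def _check_range(self):
        lo, hi = self.infiltration_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("infiltration_range must satisfy 0 <= lo <= hi <= 1")
        return self


@dataclass
class GroundTruth:
    """Planted truth for one scan (and, in cohorts, its covariates)."""

    infiltration_fraction: float
    realized_infiltration_fraction: float
    mean_lesion_hu: float
    mm_volume_mm3: float
    cavity_volume_mm3: float
    n_focal_lesions: int = 0
    pet_volume_ml: Optional[float] = None
    covariates: dict = field(default_factory=dict)
    mrd_negative: Optional[bool] = None


def _cylinder_geometry(spec: PhantomSpec):
    shape = spec.grid_shape
    spacing = spec.voxel_spacing
    ax = spec.bone_axis
    plane_axes = [i for i in range(3) if i != ax]

    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    center = [(shape[i] - 1) / 2.0 * spacing[i] for i in range(3)]
    r = np.sqrt(
        sum(((grids[i] * spacing[i] - center[i]) ** 2) for i in plane_axes)
    )
    extent = min(shape[i] * spacing[i] for i in plane_axes)
    r_outer = spec.outer_radius_frac * extent
    r_inner = r_outer - spec.shell_thickness_mm
    max_plane_spacing = max(spacing[i] for i in plane_axes)
    if r_inner < 2.0 * max_plane_spacing:
        raise InvalidSpecError(
            "grid too small to contain a cortical shell plus a medullary cavity: "
            f"inner radius {r_inner:.2f} mm < {2 * max_plane_spacing:.2f} mm"
        )
    bone = r <= r_outer
    inner = r <= r_inner

    n_axial = shape[ax]
    n_epi = int(round(spec.epiphysis_fraction * n_axial))
    along = grids[ax]
    epi_along = (along < n_epi) | (along >= n_axial - n_epi)

    bone, inner, epi_along = np.broadcast_arrays(
        bone, inner, np.broadcast_to(epi_along, shape) & True
    )
    epiphysis = bone & epi_along
    cortical = bone & ~inner & ~epi_along
    cavity = inner & ~epi_along
    return bone, cortical, cavity, epiphysis, inner


def _focal_infiltration(
    rng: np.random.Generator,
    cavity_idx: np.ndarray,
    coords_mm: np.ndarray,
    k: int,
    n_lesions: int,
) -> np.ndarray:
    """Indices (into cavity_idx) of k voxels forming ~spherical foci.

    Seeds n_lesions random centers in the cavity and grows them jointly by
    taking the k cavity voxels closest to their nearest center.
    """
    n = len(cavity_idx)
    n_lesions = min(n_lesions, max(k, 1))
    centers = rng.choice(n, size=min(n_lesions, n), replace=False)
    d = np.min(
        np.linalg.norm(coords_mm[:, None, :] - coords_mm[centers][None, :, :], axis=2),
        axis=1,
    )
    order = np.argsort(d, kind="stable")
    return order[:k]


def make_ct_phantom(spec: PhantomSpec):
    """Generate a CT phantom.

    Returns ``(VolumeGrid, masks, GroundTruth)`` where ``masks`` holds
    ``medullary_cavity``, ``epiphysis``, ``cortical`` and the planted
    ``infiltration`` indicator (ground truth, not an analysis input).
    Identical spec and seed give bitwise-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    bone, cortical, cavity, epiphysis, inner = _cylinder_geometry(spec)
    shape = spec.grid_shape
    spacing = spec.voxel_spacing

    hu = np.full(shape, spec.background_hu, dtype=np.float64)
    hu[cortical] = spec.cortical_hu
    # epiphyses: shell stays cortical, interior is fatty marrow
    epi_shell = epiphysis & ~inner
    epi_inner = epiphysis & inner
    hu[epi_shell] = spec.cortical_hu

    def _fat(n):
        vals = rng.normal(spec.fat_hu_mean, spec.fat_hu_sd, size=n)
        return np.clip(vals, FAT_HU_LOW, FAT_HU_HIGH)

    def _lesion(n):
        vals = rng.normal(spec.lesion_hu_mean, spec.lesion_hu_sd, size=n)
        return np.clip(vals, np.nextafter(FAT_HU_HIGH, INFILTRATED_HU_HIGH), INFILTRATED_HU_HIGH)

    hu[epi_inner] = _fat(int(epi_inner.sum()))

    cavity_idx = np.flatnonzero(cavity)
    n_cavity = len(cavity_idx)
    hu.flat[cavity_idx] = _fat(n_cavity)

    f = spec.infiltration_fraction
    infiltrated = np.zeros(shape, dtype=bool)
    lesion_vals = np.empty(0)
    if f > 0 and n_cavity > 0:
        sel = np.zeros(n_cavity, dtype=bool)
        if spec.infiltration_pattern == "diffuse":
            sel = rng.random(n_cavity) < f
        else:
            coords = np.stack(np.unravel_index(cavity_idx, shape), axis=1) * np.asarray(spacing)
            if spec.infiltration_pattern == "focal":
                k = int(round(f * n_cavity))
                sel[_focal_infiltration(rng, cavity_idx, coords, k, spec.n_focal_lesions)] = True
            else:  # mixed: half the target fraction focal, remainder diffuse
                k = int(round(0.5 * f * n_cavity))
                sel[_focal_infiltration(rng, cavity_idx, coords, k, spec.n_focal_lesions)] = True
                remaining = ~sel
                frac_left = sel.mean()
                p = (f - frac_left) / (1.0 - frac_left) if frac_left < 1.0 else 0.0
                sel[remaining] = rng.random(int(remaining.sum())) < max(p, 0.0)
        lesion_vals = _lesion(int(sel.sum()))
        hu.flat[cavity_idx[sel]] = lesion_vals
        infiltrated.flat[cavity_idx[sel]] = True

    if spec.noise_sd_hu > 0:
        hu += rng.normal(0.0, spec.noise_sd_hu, size=shape)

    grid = VolumeGrid(data=hu, spacing=spacing)
    masks = {
        "medullary_cavity": LabelMask.like(grid, cavity, "medullary_cavity"),
        "epiphysis": LabelMask.like(grid, epiphysis, "epiphysis"),
        "cortical": LabelMask.like(grid, cortical, "cortical"),
        "infiltration": LabelMask.like(grid, infiltrated, "infiltration"),
    }
    voxvol = grid.voxel_volume_mm3
    n_mm = int(infiltrated.sum())
    truth = GroundTruth(
        infiltration_fraction=f,
        realized_infiltration_fraction=n_mm / n_cavity if n_cavity else 0.0,
        mean_lesion_hu=float(lesion_vals.mean()) if len(lesion_vals) else float("nan"),
        mm_volume_mm3=n_mm * voxvol,
        cavity_volume_mm3=n_cavity * voxvol,
        n_focal_lesions=(
            spec.n_focal_lesions if f > 0 and spec.infiltration_pattern in ("focal", "mixed") else 0
        ),
    )
    return grid, masks, truth


def _corner_box(shape, ax, plane_axes, plane_lo, axis_range):
    """Slices for a rectangular organ box given fractional extents."""
    sl = [None, None, None]
    for pa, (lo, hi) in zip(plane_axes, plane_lo):
        a, b = int(math.floor(lo * shape[pa])), int(math.ceil(hi * shape[pa]))
        sl[pa] = slice(max(a, 0), max(b, a + 2))
    a, b = int(math.floor(axis_range[0] * shape[ax])), int(math.ceil(axis_range[1] * shape[ax]))
    sl[ax] = slice(max(a, 0), max(b, a + 2))
    return tuple(sl)


def make_pet_phantom(spec: PetSpec, ct_masks: dict, truth: GroundTruth, bone_axis: int = 2):
    """Generate the PET counterpart of a CT phantom on the same grid.

    Marrow SUV is ``background + marrow_suv_slope * infiltrated_indicator``
    (the infiltration mask comes from the CT ground truth); liver and
    mediastinum reference boxes are placed in corners clear of the bone.
    If ``ct_masks`` already contains ``liver``/``mediastinum`` masks they are
    used instead, and must not overlap.
    """
    cavity = ct_masks["medullary_cavity"]
    epiphysis = ct_masks["epiphysis"]
    cortical = ct_masks["cortical"]
    infiltration = ct_masks.get("infiltration")
    shape = cavity.shape
    rng = np.random.default_rng(spec.seed)

    skeleton = cavity.data | epiphysis.data | cortical.data
    ax = bone_axis
    plane_axes = [i for i in range(3) if i != ax]

    if "liver" in ct_masks and "mediastinum" in ct_masks:
        liver = ct_masks["liver"].data
        mediastinum = ct_masks["mediastinum"].data
        skull = ct_masks["skull"].data if "skull" in ct_masks else np.zeros(shape, bool)
    else:
        liver = np.zeros(shape, bool)
        liver[_corner_box(shape, ax, plane_axes, [(0.02, 0.17), (0.02, 0.17)], (0.05, 0.45))] = True
        mediastinum = np.zeros(shape, bool)
        mediastinum[
            _corner_box(shape, ax, plane_axes, [(0.83, 0.98), (0.83, 0.98)], (0.05, 0.45))
        ] = True
        skull = np.zeros(shape, bool)
        skull[_corner_box(shape, ax, plane_axes, [(0.02, 0.17), (0.83, 0.98)], (0.75, 0.95))] = True

    if np.any(liver & mediastinum):
        raise InvalidSpecError("liver and mediastinum reference masks overlap")
    for name, organ in (("liver", liver), ("mediastinum", mediastinum), ("skull", skull)):
        if np.any(organ & skeleton):
            raise InvalidSpecError(f"{name} reference box overlaps the bone; grid too small")

    suv = np.full(shape, spec.background_suv, dtype=np.float64)
    if infiltration is not None and infiltration.voxel_count:
        inf = infiltration.data
        lesion_suv = (
            spec.focal_lesion_suv
            if spec.focal_lesion_suv is not None
            else spec.background_suv + spec.marrow_suv_slope
        )
        suv[inf] = lesion_suv
    suv[mediastinum] = spec.mediastinum_suv
    liver_vals = rng.normal(spec.liver_suv_mean, spec.liver_suv_sd, size=int(liver.sum()))
    suv[liver] = np.maximum(liver_vals, 0.0)
    suv[skull] = spec.skull_suv

    if spec.noise_sd_suv > 0:
        suv = np.maximum(suv + rng.normal(0.0, spec.noise_sd_suv, size=shape), 0.0)

    grid = VolumeGrid(data=suv, affine=cavity.affine.copy())
    masks = {
        "skeleton": LabelMask.like(grid, skeleton, "skeleton"),
        "skull": LabelMask.like(grid, skull, "skull"),
        "liver": LabelMask.like(grid, liver, "liver"),
        "mediastinum": LabelMask.like(grid, mediastinum, "mediastinum"),
        "lesions": LabelMask.like(
            grid, infiltration.data if infiltration is not None else np.zeros(shape, bool), "lesions"
        ),
    }
    return grid, masks


@dataclass
class PatientScan:
    """Fully specified phantom for one patient at one timepoint.

    Volumes are generated on demand (deterministically) via
    :meth:`generate` to keep whole-cohort memory bounded.
    """

    patient_id: str
    timepoint: str  # "baseline" | "followup"
    ct_spec: PhantomSpec
    pet_spec: PetSpec
    truth: GroundTruth

    def generate(self):
        ct, ct_masks, truth = make_ct_phantom(self.ct_spec)
        pet, pet_masks = make_pet_phantom(
            self.pet_spec, ct_masks, truth, bone_axis=self.ct_spec.bone_axis
        )
        return ct, ct_masks, pet, pet_masks, truth


@dataclass
class Cohort:
    spec: CohortSpec
    scans: list  # list[PatientScan], two per patient

    def truth_table(self):
        import pandas as pd

        rows = []
        for s in self.scans:
            row = {
                "patient_id": s.patient_id,
                "timepoint": s.timepoint,
                "true_infiltration_fraction": s.truth.infiltration_fraction,
                "mrd_negative": s.truth.mrd_negative,
            }
            row.update(s.truth.covariates)
            rows.append(row)
        return pd.DataFrame(rows)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def make_cohort(spec: CohortSpec) -> Cohort:
    """Build a paired baseline/follow-up cohort with planted structure.

    Follow-up infiltration = baseline * (1 - treatment_effect), before any
    imaging noise.  Covariates use strictly monotone links in the baseline
    infiltration fraction; the MRD-negativity probability is logistic and
    decreasing in follow-up infiltration.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.infiltration_range
    scans = []
    for i in range(spec.n_patients):
        pid = f"P{i + 1:03d}"
        f_base = float(rng.uniform(lo, hi))
        f_fu = f_base * (1.0 - spec.treatment_effect)
        plasma = spec.plasma_cell_slope * f_base + (
            rng.normal(0.0, spec.plasma_cell_noise_sd) if spec.plasma_cell_noise_sd > 0 else 0.0
        )
        b2m = spec.b2m_intercept + spec.b2m_slope * f_base + (
            rng.normal(0.0, spec.b2m_noise_sd) if spec.b2m_noise_sd > 0 else 0.0
        )
        arm = "isatuximab" if rng.random() < 0.5 else "control"
        p_neg = _sigmoid(spec.mrd_intercept - spec.mrd_slope * f_fu)
        mrd_negative = bool(rng.random() < p_neg)
        covariates = {
            "plasma_cell_pct": float(np.clip(plasma, 0.0, 100.0)),
            "b2m_mg_l": float(max(b2m, 0.0)),
            "arm": arm,
        }
        for timepoint, f in (("baseline", f_base), ("followup", f_fu)):
            seed_ct = int(rng.integers(0, 2**31 - 1))
            seed_pet = int(rng.integers(0, 2**31 - 1))
            ct_spec = spec.ct.model_copy(
                update={"infiltration_fraction": f, "seed": seed_ct}
            )
            pet_spec = spec.pet.model_copy(update={"seed": seed_pet})
            truth = GroundTruth(
                infiltration_fraction=f,
                realized_infiltration_fraction=float("nan"),  # known after generation
                mean_lesion_hu=float("nan"),
                mm_volume_mm3=float("nan"),
                cavity_volume_mm3=float("nan"),
                covariates=covariates,
                mrd_negative=mrd_negative,
            )
            scans.append(
                PatientScan(
                    patient_id=pid,
                    timepoint=timepoint,
                    ct_spec=ct_spec,
                    pet_spec=pet_spec,
                    truth=truth,
                )
            )
    return Cohort(spec=spec, scans=scans)
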