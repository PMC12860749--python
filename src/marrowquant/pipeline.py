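"""End-to-end pipeline driver.

``run_pipeline`` orchestrates phantom generation -> CT quantification ->
PET quantification -> rule-based scoring -> MTV/TLG -> cohort statistics,
writing a deterministic results bundle.  ``analyze_scan`` measures a single
CT/PET pair and is reusable on externally supplied volumes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .cohort_stats import run_panel
from .ct_marrow import compute_cctv, manual_ctv, medullary_working_mask
from .errors import ConfigError
from .grids import LabelMask, VolumeGrid
from .impetus import deauville, f_category, l_category
from .pet_metrics import resample_mask, voi_stats
from .phantom import Cohort, CohortSpec, make_cohort
from .volumetrics import mm_threshold, segment_and_quantify, skeletal_working_mask

log = logging.getLogger("marrowquant")

DEFAULT_PANEL = [
    {"test": "spearman", "x": "cctv", "y": "plasma_cell_pct", "timepoint": "baseline"},
    {"test": "spearman", "x": "cctv", "y": "b2m_mg_l", "timepoint": "baseline"},
    {"test": "spearman", "x": "cctv", "y": "marrow_suv_max", "timepoint": "baseline"},
    {"test": "spearman", "x": "cctv", "y": "mtv_ml", "timepoint": "baseline"},
    {"test": "spearman", "x": "cctv", "y": "tlg_g", "timepoint": "baseline"},
    {"test": "paired", "values": "cctv"},
    {"test": "paired", "values": "mtv_ml"},
    {"test": "paired", "values": "tlg_g"},
    {"test": "two_group", "values": "cctv", "group": "mrd_negative", "timepoint": "followup"},
]


class CtParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    radii_mm: tuple[float, ...] = (3.0, 4.0, 5.0, 6.0)
    roi_shape: str = "disc"
    stride: int = Field(default=1, ge=1)
    compute_manual_ctv: bool = True
    cctv_interpretation: str = "mean_scaled"


class PetParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    erosion_mm: float = Field(default=2.0, ge=0.0)
    deauville_target_stat: str = "suv_max"
    deauville_gap_score: int = Field(default=3, ge=3, le=4)


class StatsParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    panel: Optional[list[dict]] = None


class ScanPaths(BaseModel):
    """File-based single-scan inputs (NIfTI paths)."""

    model_config = ConfigDict(extra="forbid")
    ct: Optional[str] = None
    pet: Optional[str] = None
    masks: Optional[str] = None  # combined label map (io.LABEL_CODES)
    compute_mtv: bool = True

    def validate_for_run(self) -> None:
        if self.ct is None and self.pet is None:
            raise ConfigError("scan config needs at least one of 'ct' or 'pet'")
        if self.masks is None:
            raise ConfigError("scan config needs a 'masks' label map")


class PipelineConfig(BaseModel):
    """Validated before any computation; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    cohort: Optional[CohortSpec] = None
    scan: Optional[ScanPaths] = None
    ct_params: CtParams = Field(default_factory=CtParams)
    pet_params: PetParams = Field(default_factory=PetParams)
    stats: StatsParams = Field(default_factory=StatsParams)
    seed: Optional[int] = None

    def validate_for_run(self) -> None:
        if (self.cohort is None) == (self.scan is None):
            raise ConfigError("config must set exactly one of 'cohort' or 'scan'")
        if self.scan is not None:
            self.scan.validate_for_run()


def analyze_scan(
    ct: Optional[VolumeGrid],
    ct_masks: dict[str, LabelMask],
    pet: Optional[VolumeGrid],
    pet_masks: dict[str, LabelMask],
    ct_params: CtParams = CtParams(),
    pet_params: PetParams = PetParams(),
    n_focal: int = 0,
    n_lytic: int = 0,
) -> dict:
    """Measure one CT/PET pair; returns a flat metric record."""
    out: dict = {}
    working = None
    if ct is not None and "medullary_cavity" in ct_masks:
        working = medullary_working_mask(ct, ct_masks["medullary_cavity"], ct_masks["epiphysis"])
        cctv = compute_cctv(ct, working, interpretation=ct_params.cctv_interpretation)
        out.update(
            cctv=cctv.cctv,
            mm_volume_mm3=cctv.mm_volume_mm3,
            cavity_volume_mm3=cctv.cavity_volume_mm3,
        )
        if ct_params.compute_manual_ctv:
            res = manual_ctv(
                ct,
                working,
                radii_mm=ct_params.radii_mm,
                roi_shape=ct_params.roi_shape,
                stride=ct_params.stride,
            )
            out["ctv"] = res.ctv
            out["ctv_roi_radius_mm"] = res.best_roi.radius_mm

    if pet is not None:
        liver = voi_stats(pet, pet_masks["liver"])
        med = voi_stats(pet, pet_masks["mediastinum"])
        out.update(liver_suv_mean=liver.suv_mean, liver_suv_median=liver.suv_median)
        if working is not None:
            marrow_mask = working if working.same_geometry(pet) else resample_mask(working, pet)
            marrow = voi_stats(pet, marrow_mask)
            out.update(
                marrow_suv_max=marrow.suv_max,
                marrow_suv_mean=marrow.suv_mean,
                marrow_suv_median=marrow.suv_median,
            )
            out["ds_bone_marrow"] = deauville(
                marrow,
                liver,
                med,
                target_stat=pet_params.deauville_target_stat,
                gap_score=pet_params.deauville_gap_score,
            )
        lesions = pet_masks.get("lesions")
        if lesions is not None and lesions.voxel_count and n_focal > 0:
            hottest = voi_stats(pet, lesions)
            out["ds_hottest_lesion"] = deauville(
                hottest, liver, med, gap_score=pet_params.deauville_gap_score
            )
        out["f_category"] = f_category(n_focal)
        out["l_category"] = l_category(n_lytic)
        if "skeleton" in pet_masks and "skull" in pet_masks:
            skel = skeletal_working_mask(
                pet_masks["skeleton"], pet_masks["skull"], erosion_mm=pet_params.erosion_mm
            )
            thr = mm_threshold(liver)
            vol = segment_and_quantify(pet, skel, thr)
            out.update(mtv_ml=vol.mtv_ml, tlg_g=vol.tlg_g, threshold_suv=vol.threshold_suv)
    return out


def measure_cohort(
    cohort: Cohort,
    ct_params: CtParams = CtParams(),
    pet_params: PetParams = PetParams(),
    measures: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Generate and measure every scan of a cohort.

    ``measures`` may restrict work (e.g. ``("cctv", "mtv")``) to skip the
    expensive manual ROI sweep in large simulations.
    """
    if measures is not None:
        ct_params = ct_params.model_copy(update={"compute_manual_ctv": "ctv" in measures})
    pet_needed = measures is None or any(m in measures for m in ("mtv", "pet", "suv"))
    rows = []
    for scan in cohort.scans:
        ct, ct_masks, pet, pet_masks, truth = scan.generate()
        if not pet_needed:
            pet = None
        rec = {
            "patient_id": scan.patient_id,
            "timepoint": scan.timepoint,
            "true_infiltration_fraction": scan.truth.infiltration_fraction,
            "realized_infiltration_fraction": truth.realized_infiltration_fraction,
            "mrd_negative": scan.truth.mrd_negative,
            **scan.truth.covariates,
        }
        rec.update(
            analyze_scan(
                ct,
                ct_masks,
                pet,
                pet_masks,
                ct_params=ct_params,
                pet_params=pet_params,
                n_focal=truth.n_focal_lesions,
                n_lytic=0,
            )
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the configured pipeline and write a results bundle.

    Cohort mode writes ``cohort.csv`` (measured metrics joined to planted
    truth) and ``stats.csv`` (the statistics panel); scan mode writes
    ``scan.json``.  A ``manifest.json`` stamps configuration and version.
    Identical config and seed give byte-identical CSV output.
    """
    config.validate_for_run()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    if config.cohort is not None:
        spec = config.cohort
        if config.seed is not None:
            spec = spec.model_copy(update={"seed": config.seed})
        log.info("generating cohort of %d patients (seed=%d)", spec.n_patients, spec.seed)
        cohort = make_cohort(spec)
        table = measure_cohort(cohort, ct_params=config.ct_params, pet_params=config.pet_params)
        table.to_csv(out_dir / "cohort.csv", index=False, float_format="%.10g")
        panel = config.stats.panel if config.stats.panel is not None else DEFAULT_PANEL
        panel = [e for e in panel if _panel_applicable(e, table)]
        results = run_panel(table, panel, alpha=config.stats.alpha)
        results.to_csv(out_dir / "stats.csv", index=False, float_format="%.10g")
        bundle["cohort"] = table
        bundle["stats"] = results
    else:
        from .io import read_label_map, read_volume

        scan = config.scan
        ct = read_volume(scan.ct) if scan.ct else None
        pet = read_volume(scan.pet) if scan.pet else None
        masks = read_label_map(scan.masks)
        if scan.compute_mtv and pet is not None and "liver" not in masks:
            raise ConfigError("MTV requested but no liver mask present in the label map")
        rec = analyze_scan(
            ct, masks, pet, masks, ct_params=config.ct_params, pet_params=config.pet_params
        )
        (out_dir / "scan.json").write_text(json.dumps(rec, indent=2, default=float))
        bundle["scan"] = rec

    manifest = {
        "marrowquant_version": __version__,
        "config": json.loads(config.model_dump_json()),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return bundle


def _panel_applicable(entry: dict, table: pd.DataFrame) -> bool:
    cols = [v for k, v in entry.items() if k in ("x", "y", "values", "group", "a", "b")]
    return all(c in table.columns for c in cols)
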