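"""NIfTI readers/writers and configuration loading.

Volumes are exchanged as NIfTI-1, masks as unsigned-integer label maps with
the fixed label codes in :data:`LABEL_CODES`, configurations as YAML/JSON.
World coordinates are millimetres; voxel indices are 0-based in array
(i, j, k) order.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .errors import FormatError
from .grids import LabelMask, VolumeGrid

#: label codes used in combined mask label maps
LABEL_CODES = {
    "medullary_cavity": 1,
    "epiphysis": 2,
    "cortical": 3,
    "infiltration": 4,
    "skeleton": 5,
    "skull": 6,
    "liver": 7,
    "mediastinum": 8,
    "lesions": 9,
}


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI-1 volume; spacing/affine come from the header."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)):
        raise FormatError(f"{path}: missing or invalid affine")
    return VolumeGrid(data=np.asarray(data, dtype=np.float64), affine=affine)


def write_volume(grid: VolumeGrid, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(grid.data, dtype=np.float64), grid.affine), str(path))


def read_label_map(path: str | Path) -> dict[str, LabelMask]:
    """Read a label-map NIfTI into per-structure masks using LABEL_CODES."""
    grid = read_volume(path)
    labels = grid.data.astype(np.int64)
    raw = {name: labels == code for name, code in LABEL_CODES.items()}
    # nested structures are stored with the inner code winning; restore containment
    raw["medullary_cavity"] |= raw["infiltration"]
    raw["skeleton"] |= raw["lesions"]
    out = {}
    for name, m in raw.items():
        if m.any():
            out[name] = LabelMask(data=m, affine=grid.affine.copy(), label=name)
    return out


def write_label_map(masks: dict[str, LabelMask], path: str | Path) -> None:
    """Write per-structure masks into one label-map NIfTI (later codes win on overlap)."""
    first = next(iter(masks.values()))
    labels = np.zeros(first.shape, dtype=np.uint8)
    for name, mask in masks.items():
        code = LABEL_CODES.get(name)
        if code is None:
            raise FormatError(f"no label code defined for mask {name!r}")
        labels[mask.data] = code
    nib.save(nib.Nifti1Image(labels, first.affine), str(path))


def read_mask(path: str | Path, label: str = "") -> LabelMask:
    grid = read_volume(path)
    return LabelMask(data=grid.data > 0, affine=grid.affine.copy(), label=label)


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except Exception as exc:
        raise FormatError(f"could not parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"config {path} must contain a mapping")
    return data
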