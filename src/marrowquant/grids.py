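"""Volume grids and label masks.

A :class:`VolumeGrid` is a 3-D scalar field (CT in Hounsfield units, PET in
SUV or activity concentration) together with its voxel-to-world affine.
A :class:`LabelMask` is a boolean indicator on the same kind of grid with a
semantic label.  Grids are axis-aligned by default (diagonal affine built
from spacing and origin) but any 4x4 affine read from a NIfTI header is
carried through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, InvalidInputError


def _build_affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _check_geometry(data: np.ndarray, affine: np.ndarray) -> None:
    if data.ndim != 3:
        raise InvalidInputError(f"expected a 3-D array, got ndim={data.ndim}")
    if affine.shape != (4, 4):
        raise InvalidInputError("affine must be a 4x4 matrix")
    if not np.all(np.isfinite(affine)):
        raise InvalidInputError("affine contains non-finite entries")
    if np.isclose(np.linalg.det(affine[:3, :3]), 0.0):
        raise InvalidInputError("affine is singular")


@dataclass
class VolumeGrid:
    """A 3-D scalar field with voxel spacing (mm) and a voxel-to-world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.affine is None:
            if any(s <= 0 for s in self.spacing):
                raise InvalidInputError(f"spacing must be positive, got {self.spacing}")
            self.affine = _build_affine(self.spacing, self.origin)
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            self.spacing = tuple(np.linalg.norm(self.affine[:3, i]) for i in range(3))
            self.origin = tuple(self.affine[:3, 3])
        _check_geometry(self.data, self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_geometry(self, other: "VolumeGrid | LabelMask") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def world_coords(self, idx: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to world mm coordinates."""
        idx = np.atleast_2d(idx)
        hom = np.c_[idx, np.ones(len(idx))]
        return (self.affine @ hom.T).T[:, :3]


@dataclass
class LabelMask:
    """A boolean region indicator aligned to a :class:`VolumeGrid`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    label: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.affine is None:
            if any(s <= 0 for s in self.spacing):
                raise InvalidInputError(f"spacing must be positive, got {self.spacing}")
            self.affine = _build_affine(self.spacing, self.origin)
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            self.spacing = tuple(np.linalg.norm(self.affine[:3, i]) for i in range(3))
            self.origin = tuple(self.affine[:3, 3])
        _check_geometry(self.data, self.affine)

    @classmethod
    def like(cls, grid: "VolumeGrid | LabelMask", data: np.ndarray, label: str = "") -> "LabelMask":
        return cls(data=data, affine=grid.affine.copy(), label=label)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3

    def same_geometry(self, other: "VolumeGrid | LabelMask") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


def require_aligned(*grids: VolumeGrid | LabelMask) -> None:
    """Raise :class:`AlignmentError` unless all grids share shape and affine."""
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape:
            raise AlignmentError(f"shape mismatch: {ref.shape} vs {g.shape}")
        if not np.allclose(g.affine, ref.affine):
            raise AlignmentError("affine mismatch between grids")
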