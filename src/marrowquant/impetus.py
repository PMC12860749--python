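"""Rule-based IMPeTUs-style scoring.

Five-point Deauville score of a target VOI against mediastinal blood pool
and liver references, focal-lesion (Fx) and lytic-lesion (Lx) count bands,
and assembly of the per-scan report with paramedullary/extramedullary
disease and fracture flags.

Printed rules: score 1, no uptake; score 2, <= mediastinum; score 3,
> mediastinum and <= liver; score 4, > liver + 10%; score 5, > twice liver.
The rules leave (liver, liver + 10%] unassigned; by the documented gap
convention that interval scores 3 (score 4 requires exceeding liver + 10%).
"""

from __future__ import annotations

import warnings
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .errors import ConsistencyError, InvalidInputError
from .pet_metrics import SuvStats

F_CATEGORIES = ("F1", "F2", "F3", "F4")
L_CATEGORIES = ("L1", "L2", "L3", "L4")


def deauville_value(
    t: float,
    mediastinum: float,
    liver: float,
    background: Optional[float] = None,
    gap_score: int = 3,
) -> int:
    """Deauville score from raw comparison values.

    ``t`` is the target statistic, ``mediastinum``/``liver`` the reference
    means, ``background`` an optional background-VOI mean operationalizing
    "no uptake at all" (without it, score 1 requires t == 0).
    ``gap_score`` assigns the (liver, 1.1*liver] interval (3 or 4).
    """
    if t < 0 or mediastinum < 0 or liver < 0:
        raise InvalidInputError("SUV comparison values must be nonnegative")
    if gap_score not in (3, 4):
        raise InvalidInputError("gap_score must be 3 or 4")
    if background is not None:
        if t <= background:
            return 1
    elif t == 0:
        return 1
    if t <= mediastinum:
        return 2
    if t <= liver:
        return 3
    if t <= 1.1 * liver:
        return gap_score
    if t <= 2.0 * liver:
        return 4
    return 5


def deauville(
    target: SuvStats,
    liver: SuvStats,
    mediastinum: SuvStats,
    background: Optional[SuvStats] = None,
    target_stat: str = "suv_max",
    reference_stat: str = "suv_mean",
    gap_score: int = 3,
) -> int:
    """Deauville score of a target VOI against liver/mediastinum references.

    By common reading practice the target is compared by SUVmax and the
    references by SUVmean; both are configurable.
    """
    for name, stats in (("target", target), ("liver", liver), ("mediastinum", mediastinum)):
        if stats is None:
            raise InvalidInputError(f"missing {name} VOI statistics")
        if stats.voxel_count <= 0:
            raise InvalidInputError(f"{name} VOI statistics come from an empty VOI")
    t = getattr(target, target_stat)
    liv = getattr(liver, reference_stat)
    med = getattr(mediastinum, reference_stat)
    if liv < med:
        warnings.warn(
            f"liver reference ({liv:.3g}) below mediastinum ({med:.3g}); "
            "check the reference VOIs",
            stacklevel=2,
        )
    bg = getattr(background, reference_stat) if background is not None else None
    return deauville_value(t, med, liv, background=bg, gap_score=gap_score)


def _count_category(n: int, prefix: str) -> str:
    if not isinstance(n, (int,)) or isinstance(n, bool):
        raise InvalidInputError(f"lesion count must be an integer, got {n!r}")
    if n < 0:
        raise InvalidInputError(f"lesion count must be >= 0, got {n}")
    if n == 0:
        return f"{prefix}1"
    if n <= 3:
        return f"{prefix}2"
    if n <= 10:
        return f"{prefix}3"
    return f"{prefix}4"


def f_category(n_focal: int) -> str:
    """Focal-lesion band: F1 none, F2 1-3, F3 4-10, F4 >10."""
    return _count_category(n_focal, "F")


def l_category(n_lytic: int) -> str:
    """Lytic-lesion band: L1 none, L2 1-3, L3 4-10, L4 >10."""
    return _count_category(n_lytic, "L")


class ImpetusReport(BaseModel):
    """Structured per-scan scoring report; serializes losslessly to JSON."""

    model_config = ConfigDict(extra="forbid")

    schema_version: str = "1"
    ds_bone_marrow: int = Field(ge=1, le=5)
    ds_hottest_lesion: Optional[int] = Field(default=None, ge=1, le=5)
    f_category: str
    l_category: str
    pmd: bool = False
    emd: bool = False
    fracture: bool = False

    def to_json(self) -> str:
        return self.model_dump_json()

    @classmethod
    def from_json(cls, text: str) -> "ImpetusReport":
        return cls.model_validate_json(text)


def impetus_report(
    bm_stats: SuvStats,
    hottest_lesion_stats: Optional[SuvStats],
    liver: SuvStats,
    mediastinum: SuvStats,
    n_focal: int,
    n_lytic: int,
    pmd: bool = False,
    emd: bool = False,
    fracture: bool = False,
    background: Optional[SuvStats] = None,
    **deauville_kwargs,
) -> ImpetusReport:
    """Assemble the full report.

    ``hottest_lesion_stats`` must be given iff ``n_focal > 0``.
    """
    if n_focal == 0 and hottest_lesion_stats is not None:
        raise ConsistencyError("hottest-lesion stats supplied but focal-lesion count is 0")
    if n_focal > 0 and hottest_lesion_stats is None:
        raise ConsistencyError("focal lesions reported but no hottest-lesion stats supplied")
    ds_bm = deauville(bm_stats, liver, mediastinum, background=background, **deauville_kwargs)
    ds_lesion = (
        deauville(hottest_lesion_stats, liver, mediastinum, background=background, **deauville_kwargs)
        if hottest_lesion_stats is not None
        else None
    )
    return ImpetusReport(
        ds_bone_marrow=ds_bm,
        ds_hottest_lesion=ds_lesion,
        f_category=f_category(n_focal),
        l_category=l_category(n_lytic),
        pmd=pmd,
        emd=emd,
        fracture=fracture,
    )
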