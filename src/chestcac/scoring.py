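"""Agatston scoring and CAC-DRS risk categorization.

The Agatston score of a 2D slice-component of calcium is its in-plane area
(mm^2) times an integer density coefficient set by the component's peak HU:

    [130, 200) -> 1    [200, 300) -> 2    [300, 400) -> 3    [400, inf) -> 4

Half-open bins follow the standard Agatston convention. Per-vessel and total
scores are sums of slice-component scores; the total (coronary) score maps
onto the five CAC-DRS grades 0 / I / II / III / IV at boundaries
0, 1-100, 101-400, 401-1000, >1000.

No slice-thickness rescaling is applied: scores computed on 1.0-2.5 mm chest
reconstructions are reported as-is, not converted to the 3 mm gated
convention. No minimum-area floor is applied beyond the noise cascade.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "DENSITY_BINS",
    "RiskCategory",
    "AgatstonReport",
    "density_coefficient",
    "slice_component_score",
    "artery_score",
    "score_lesions",
    "categorize",
]

#: (lower bound inclusive, upper bound exclusive, weight)
DENSITY_BINS: tuple[tuple[float, float, int], ...] = (
    (130.0, 200.0, 1),
    (200.0, 300.0, 2),
    (300.0, 400.0, 3),
    (400.0, float("inf"), 4),
)

CORONARY_ARTERIES = ("RCA", "LAD", "LCX")


class RiskCategory(enum.IntEnum):
    """CAC-DRS 5-grade risk category."""

    C0 = 0
    CI = 1
    CII = 2
    CIII = 3
    CIV = 4

    def __str__(self) -> str:  # printed as the conventional roman label
        return ("0", "I", "II", "III", "IV")[int(self)]


def density_coefficient(max_hu: float) -> int:
    """Integer density weight for a slice-component's peak attenuation."""
    if max_hu < 130:
        raise ValueError(
            f"peak HU {max_hu} is below the 130 HU calcium threshold; "
            "no scoreable lesion can have such a maximum"
        )
    for lo, hi, w in DENSITY_BINS:
        if lo <= max_hu < hi:
            return w
    raise AssertionError("unreachable: density bins cover [130, inf)")


def slice_component_score(area_mm2: float, max_hu: float) -> float:
    """Agatston contribution of one 2D component: area x density coefficient."""
    if area_mm2 < 0:
        raise ValueError(f"area must be non-negative, got {area_mm2}")
    if area_mm2 == 0:
        return 0.0
    return area_mm2 * density_coefficient(max_hu)


def artery_score(lesions: Sequence) -> float:
    """Sum of slice-component scores across all lesions of one artery.

    Every lesion must carry the same artery label; each lesion exposes
    ``slice_components`` as an iterable of objects (or tuples) with
    ``area_mm2`` and ``max_hu``.
    """
    labels = {getattr(les, "artery") for les in lesions}
    if len(labels) > 1:
        raise ValueError(f"lesions carry mixed artery labels: {sorted(labels)}")
    total = 0.0
    for les in lesions:
        for comp in les.slice_components:
            total += slice_component_score(comp.area_mm2, comp.max_hu)
    return total


def categorize(total_score: float) -> RiskCategory:
    """CAC-DRS grade of a total Agatston score (rounded to nearest integer)."""
    if total_score < 0:
        raise ValueError(f"total score must be non-negative, got {total_score}")
    t = round(total_score)
    if t == 0:
        return RiskCategory.C0
    if t <= 100:
        return RiskCategory.CI
    if t <= 400:
        return RiskCategory.CII
    if t <= 1000:
        return RiskCategory.CIII
    return RiskCategory.CIV


@dataclass
class AgatstonReport:
    """Per-vessel and total Agatston scores plus the CAC-DRS grade.

    The total is RCA + LAD + LCX; aortic calcium is scored but reported
    separately and never enters the coronary total or the grade.
    """

    per_artery: dict[str, float]
    aorta: float
    total: float
    category: RiskCategory
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.per_artery.values()) or self.aorta < 0 or self.total < 0:
            raise ValueError("Agatston scores cannot be negative")

    def to_dict(self) -> dict:
        return {
            "per_artery": {k: float(v) for k, v in self.per_artery.items()},
            "aorta": float(self.aorta),
            "total": float(self.total),
            "category": str(self.category),
            "category_index": int(self.category),
            "flags": list(self.flags),
        }


def score_lesions(lesions: Iterable, flags: Sequence[str] = ()) -> AgatstonReport:
    """Build a report from attributed lesions (see :mod:`chestcac.calcium`).

    Lesions labeled AORTA are scored separately; lesions without any region
    attribution are skipped and flagged.
    """
    by_artery: dict[str, list] = {}
    n_unassigned = 0
    for les in lesions:
        if les.artery is None or les.artery == "NONE":
            n_unassigned += 1
            continue
        by_artery.setdefault(les.artery, []).append(les)

    per_artery = {a: artery_score(by_artery.get(a, [])) for a in CORONARY_ARTERIES}
    aorta = artery_score(by_artery.get("AORTA", []))
    total = sum(per_artery.values())
    all_flags = list(flags)
    if n_unassigned:
        all_flags.append(f"{n_unassigned} lesion(s) inside the cardiac mask had no region attribution")
    return AgatstonReport(per_artery, aorta, total, categorize(total), all_flags)
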