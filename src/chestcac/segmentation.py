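"""Organ-segmentation backend contract and the density/geometry reference backend.

The pipeline only requires *some* source of heart and aorta masks — the seat
a trained multi-organ network occupies in production. Two backends ship:

* :class:`ReferenceBackend` — density windows plus enclosure geometry. The
  heart is the largest soft-tissue component fully enclosed by aerated lung,
  grown by a small margin into adjacent non-aerated tissue so the epicardial
  fat envelope is included; the aorta is the largest blood-pool-window
  component. Valid on phantoms and phantom-like data; it makes no claim on
  clinical CT.
* :class:`FileBackend` — masks produced by any external model, injected from
  NIfTI files. The pipeline is bitwise indifferent to which backend produced
  a given mask set.

Epicardial fat is derived from the heart mask: voxels in the adipose HU
window inside a shell straddling the heart boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage

from .ct_io import BinaryMask, CTVolume, load_mask
from .region_split import dilate_mm, erode_mm

__all__ = [
    "OrganMaskSet",
    "SegmentationBackend",
    "ReferenceSegParams",
    "ReferenceBackend",
    "FileBackend",
    "NoHeartCandidateError",
    "segment_reference",
    "derive_epicardial_fat",
]


class NoHeartCandidateError(RuntimeError):
    """Raised when no soft-tissue component qualifies as a heart candidate."""


@dataclass
class OrganMaskSet:
    """Heart / aorta / epicardial-fat masks on the volume grid."""

    heart: BinaryMask
    aorta: BinaryMask
    epicardial_fat: BinaryMask | None = None

    def __post_init__(self) -> None:
        if self.heart.shape != self.aorta.shape:
            raise ValueError("heart and aorta masks must share one grid")
        if self.epicardial_fat is not None and self.epicardial_fat.shape != self.heart.shape:
            raise ValueError("epicardial fat mask must share the volume grid")


@runtime_checkable
class SegmentationBackend(Protocol):
    """Anything that maps a CT volume to an :class:`OrganMaskSet`."""

    name: str

    def segment(self, vol: CTVolume) -> OrganMaskSet: ...


@dataclass
class ReferenceSegParams:
    """Tunables of the density/geometry backend.

    ``heart_margin_mm`` grows the myocardium/blood-pool core outward into
    adjacent non-aerated tissue (HU above ``tissue_floor_hu``) so the
    epicardial fat layer and any surface calcium are part of the heart mask.
    """

    air_hu_max: float = -400.0
    heart_window: tuple[float, float] = (0.0, 70.0)
    aorta_window: tuple[float, float] = (71.0, 120.0)
    tissue_floor_hu: float = -400.0
    heart_margin_mm: float = 6.0
    closing_mm: float = 2.0
    min_component_voxels: int = 50
    fat_hu_range: tuple[float, float] = (-190.0, -30.0)
    fat_shell_mm: float = 10.0
    fat_min_voxels: int = 10


def _fill_holes_2d(bits: np.ndarray) -> np.ndarray:
    out = np.empty_like(bits)
    for k in range(bits.shape[2]):
        out[:, :, k] = ndimage.binary_fill_holes(bits[:, :, k])
    return out


def segment_reference(vol: CTVolume, params: ReferenceSegParams | None = None) -> OrganMaskSet:
    """Density/geometry heart + aorta segmentation (phantom-grade).

    Deterministic. Raises :class:`NoHeartCandidateError` when no enclosed
    soft-tissue component exists (e.g. an all-air volume).
    """
    p = params or ReferenceSegParams()
    hu = vol.voxels

    # 1. aerated cavity: largest low-HU component not touching the in-plane border
    air = hu < p.air_hu_max
    lab, n = ndimage.label(air)
    if n == 0:
        raise NoHeartCandidateError("no heart candidate: no enclosed aerated cavity found")
    border = np.unique(np.concatenate([
        lab[0].ravel(), lab[-1].ravel(), lab[:, 0].ravel(), lab[:, -1].ravel()]))
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    sizes[np.isin(np.arange(1, n + 1), border)] = 0
    if sizes.max() == 0:
        raise NoHeartCandidateError("no heart candidate: no enclosed aerated cavity found")
    cavity = lab == (int(np.argmax(sizes)) + 1)

    # 2. structures enclosed by the cavity (per-slice hole filling)
    filled_cavity = _fill_holes_2d(cavity)
    interior = filled_cavity & ~cavity

    # 3. heart core: largest soft-tissue-window component in the interior
    lo, hi = p.heart_window
    core_cand = interior & (hu >= lo) & (hu <= hi)
    lab, n = ndimage.label(core_cand)
    if n == 0:
        raise NoHeartCandidateError("no heart candidate: soft-tissue window empty inside cavity")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    order = int(np.argmax(sizes)) + 1
    if sizes[order - 1] < p.min_component_voxels:
        raise NoHeartCandidateError("no heart candidate: largest component below size floor")
    core = lab == order
    if p.closing_mm > 0:
        core = erode_mm(dilate_mm(core, vol.spacing, p.closing_mm), vol.spacing, p.closing_mm)
    core = _fill_holes_2d(core)

    # 4. grow into adjacent non-aerated tissue (fat envelope, surface calcium)
    grown = dilate_mm(core, vol.spacing, p.heart_margin_mm)
    heart = core | (grown & (hu > p.tissue_floor_hu) & filled_cavity)

    # 5. aorta: largest blood-pool-window component, holes filled per slice
    alo, ahi = p.aorta_window
    aorta_cand = interior & (hu >= alo) & (hu <= ahi) & ~heart
    lab, n = ndimage.label(aorta_cand)
    aorta = np.zeros_like(aorta_cand)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        if sizes.max() >= p.min_component_voxels:
            aorta = _fill_holes_2d(lab == (int(np.argmax(sizes)) + 1))

    heart_mask = BinaryMask(heart, vol.spacing)
    aorta_mask = BinaryMask(aorta & ~heart, vol.spacing)
    fat = derive_epicardial_fat(vol, heart_mask, p.fat_hu_range, p.fat_shell_mm,
                                p.fat_min_voxels)
    return OrganMaskSet(heart_mask, aorta_mask, fat)


def derive_epicardial_fat(
    vol: CTVolume,
    heart_mask: BinaryMask,
    fat_hu_range: tuple[float, float] = (-190.0, -30.0),
    shell_mm: float = 10.0,
    min_voxels: int = 10,
) -> BinaryMask:
    """Adipose-window voxels in a shell straddling the heart boundary.

    The shell is dilation(heart, shell_mm) minus erosion(heart, shell_mm);
    components below ``min_voxels`` are discarded. An empty result is legal
    (a fat-free subject, not an error).
    """
    if not heart_mask.bits.any():
        raise ValueError("heart mask is empty; cannot derive epicardial fat")
    shell = dilate_mm(heart_mask.bits, heart_mask.spacing, shell_mm) \
        & ~erode_mm(heart_mask.bits, heart_mask.spacing, shell_mm)
    lo, hi = fat_hu_range
    fat = shell & (vol.voxels >= lo) & (vol.voxels <= hi)
    if fat.any() and min_voxels > 1:
        lab, n = ndimage.label(fat)
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_voxels) + 1
        fat = np.isin(lab, keep)
    return BinaryMask(fat, heart_mask.spacing)


@dataclass
class ReferenceBackend:
    """Density/geometry reference backend (see :func:`segment_reference`)."""

    params: ReferenceSegParams = field(default_factory=ReferenceSegParams)
    name: str = "reference-density-geometry"

    def segment(self, vol: CTVolume) -> OrganMaskSet:
        return segment_reference(vol, self.params)


@dataclass
class FileBackend:
    """Masks injected from NIfTI files (any external model's output)."""

    heart_path: str | os.PathLike
    aorta_path: str | os.PathLike
    fat_path: str | os.PathLike | None = None
    name: str = "file-injection"

    def segment(self, vol: CTVolume) -> OrganMaskSet:
        heart = load_mask(self.heart_path, vol)
        aorta = load_mask(self.aorta_path, vol)
        fat = load_mask(self.fat_path, vol) if self.fat_path else None
        return OrganMaskSet(heart, aorta, fat)
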