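"""The calcium-candidate cascade: threshold, denoise, de-bone, recover, attribute.

Stages, in order:

1. ``candidate_mask`` — every voxel at or above the 130 HU calcium threshold.
2. ``suppress_noise`` — per-slice morphological opening removes speckle, then
   3D components that are both small *and* faint are dropped.
3. ``remove_bone`` — components larger than the bone-merge floor (10,000
   voxels) are dilated in 3D so satellite bone flecks merge into them, and
   the merged groups are removed together.
4. ``recover_components`` — any candidate component that still has a
   surviving voxel is restored in full (the filters may have nibbled lesion
   rims); components wiped out entirely stay excluded.
5. ``assign_lesions`` — calcium is gated to the cardiac mask and each
   component is attributed to the artery region holding the majority of its
   voxels; per-slice 2D components with areas and maxima are extracted for
   Agatston scoring.

The candidate threshold is *inclusive* (>= 130 HU), the standard Agatston
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import region_split as rs
from .ct_io import BinaryMask, CTVolume
from .region_split import ArteryRegionMap

__all__ = [
    "CalciumFilterParams",
    "SliceComponent",
    "CalciumLesion",
    "candidate_mask",
    "suppress_noise",
    "remove_bone",
    "recover_components",
    "assign_lesions",
]

_STRUCT_3D = {6: 1, 18: 2, 26: 3}
_STRUCT_2D = {4: 1, 8: 2}

#: deterministic tie-break order for artery attribution
_TIE_ORDER = (rs.RCA, rs.LAD, rs.LCX, rs.AORTA)


@dataclass
class CalciumFilterParams:
    """Cascade tunables.

    ``opening_size`` is the side of the square structuring element of the 2D
    opening: 2 removes isolated voxels and one-pixel filaments while keeping
    2x2-per-slice lesions intact. The small-and-faint filter removes a 3D
    component only when its voxel count is below ``noise_min_voxels`` *and*
    its peak is below ``noise_min_peak_hu``.
    """

    hu_min: float = 130.0
    opening_size: int = 2
    noise_min_voxels: int = 3
    noise_min_peak_hu: float = 160.0
    bone_merge_voxels: int = 10_000
    bone_dilate_radius: int = 3
    connectivity: int = 26
    connectivity_2d: int = 8

    def __post_init__(self) -> None:
        if self.hu_min < 0:
            raise ValueError(f"hu_min must be >= 0, got {self.hu_min}")
        if self.bone_merge_voxels <= self.noise_min_voxels:
            raise ValueError("bone_merge_voxels must exceed noise_min_voxels")
        if self.connectivity not in _STRUCT_3D:
            raise ValueError(f"3D connectivity must be one of {tuple(_STRUCT_3D)}")
        if self.connectivity_2d not in _STRUCT_2D:
            raise ValueError(f"2D connectivity must be one of {tuple(_STRUCT_2D)}")


def _structure3d(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, _STRUCT_3D[connectivity])


def _structure2d_in3d(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, _STRUCT_2D[connectivity])[:, :, None]


def candidate_mask(vol: CTVolume, hu_min: float = 130.0) -> BinaryMask:
    """All voxels with HU >= ``hu_min`` (inclusive threshold)."""
    return BinaryMask(vol.voxels >= hu_min, vol.spacing)


def suppress_noise(mask: BinaryMask, vol: CTVolume,
                   params: CalciumFilterParams | None = None) -> BinaryMask:
    """Per-slice opening, then drop 3D components that are small *and* faint."""
    p = params or CalciumFilterParams()
    if not mask.bits.any():
        return mask.copy()

    se = np.ones((p.opening_size, p.opening_size, 1), dtype=bool)
    opened = ndimage.binary_opening(mask.bits, structure=se)
    if not opened.any():
        return BinaryMask(opened, mask.spacing)

    lab, n = ndimage.label(opened, structure=_structure3d(p.connectivity))
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=idx)
    peaks = ndimage.maximum(vol.voxels, labels=lab, index=idx)
    drop = (sizes < p.noise_min_voxels) & (peaks < p.noise_min_peak_hu)
    if drop.any():
        opened = opened & ~np.isin(lab, idx[drop])
    return BinaryMask(opened, mask.spacing)


def remove_bone(mask: BinaryMask, vol: CTVolume,
                params: CalciumFilterParams | None = None) -> BinaryMask:
    """Eliminate bone: dilate very large groups in 3D and remove everything
    the dilation touches, large groups included.

    Components must exceed ``bone_merge_voxels`` (strictly) to count as bone
    seeds; coronary lesions are orders of magnitude smaller.
    """
    p = params or CalciumFilterParams()
    if not mask.bits.any():
        return mask.copy()

    lab, n = ndimage.label(mask.bits, structure=_structure3d(p.connectivity))
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=idx)
    big = idx[sizes > p.bone_merge_voxels]
    if big.size == 0:
        return mask.copy()

    seed = np.isin(lab, big)
    # crop to the seeds' bounding box (plus the dilation reach) for speed
    margin = (p.bone_dilate_radius + 1,) * 3
    box = rs._bbox_slices(seed, margin)
    grown = np.zeros_like(seed)
    grown[box] = ndimage.binary_dilation(
        seed[box], structure=_structure3d(p.connectivity),
        iterations=p.bone_dilate_radius)

    touched = np.unique(lab[grown & mask.bits])
    touched = touched[touched > 0]
    return BinaryMask(mask.bits & ~np.isin(lab, touched), mask.spacing)


def recover_components(filtered: BinaryMask, candidates: BinaryMask,
                       params: CalciumFilterParams | None = None) -> BinaryMask:
    """Restore, in full, every candidate component that retains a voxel.

    ``filtered`` must be a subset of ``candidates``; the recovered mask is
    always a subset of the candidate mask (pipeline monotonicity).
    """
    p = params or CalciumFilterParams()
    if (filtered.bits & ~candidates.bits).any():
        raise ValueError("filtered mask is not a subset of the candidate mask")
    if not filtered.bits.any():
        return filtered.copy()

    lab, n = ndimage.label(candidates.bits, structure=_structure3d(p.connectivity))
    survivors = np.unique(lab[filtered.bits])
    survivors = survivors[survivors > 0]
    return BinaryMask(np.isin(lab, survivors), candidates.spacing)


@dataclass
class SliceComponent:
    """One 2D connected component of a lesion on one axial slice."""

    slice_index: int
    n_pixels: int
    area_mm2: float
    max_hu: float


@dataclass
class CalciumLesion:
    """A 3D-connected calcium component attributed to an artery territory."""

    artery: str | None
    indices: tuple[np.ndarray, np.ndarray, np.ndarray]
    slice_components: list[SliceComponent]
    peak_hu: float
    voxel_volume_mm3: float
    flags: list[str] = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return len(self.indices[0])

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


def _slice_components(comp: np.ndarray, vol: CTVolume, p: CalciumFilterParams
                      ) -> list[SliceComponent]:
    px_area = vol.pixel_area
    out: list[SliceComponent] = []
    ks = np.unique(np.nonzero(comp)[2])
    st2 = ndimage.generate_binary_structure(2, _STRUCT_2D[p.connectivity_2d])
    for k in ks:
        sl = comp[:, :, k]
        lab2, n2 = ndimage.label(sl, structure=st2)
        for i in range(1, n2 + 1):
            sel = lab2 == i
            n_px = int(sel.sum())
            max_hu = float(vol.voxels[:, :, k][sel].max())
            out.append(SliceComponent(int(k), n_px, n_px * px_area, max_hu))
    return out


def assign_lesions(mask: BinaryMask, cardiac_mask: BinaryMask,
                   region_map: ArteryRegionMap, vol: CTVolume,
                   params: CalciumFilterParams | None = None) -> list[CalciumLesion]:
    """Gate calcium to the cardiac mask and attribute components to arteries.

    Each 3D component gets the region label of the majority of its voxels;
    ties break by overlap count and then the fixed order RCA < LAD < LCX <
    AORTA. Components with no region overlap at all are kept but labeled
    ``None`` (they are flagged, and excluded from every scored total).
    """
    p = params or CalciumFilterParams()
    gated = mask.bits & cardiac_mask.bits
    if not gated.any():
        return []

    lab, n = ndimage.label(gated, structure=_structure3d(p.connectivity))
    lesions: list[CalciumLesion] = []
    for obj_idx, box in enumerate(ndimage.find_objects(lab), start=1):
        if box is None:
            continue
        comp_local = lab[box] == obj_idx
        comp = np.zeros_like(gated)
        comp[box] = comp_local

        counts = np.bincount(region_map.labels[comp], minlength=5)
        best_label, best_count = None, 0
        for cand in _TIE_ORDER:
            if counts[cand] > best_count:
                best_label, best_count = cand, int(counts[cand])
        artery = rs.LABEL_NAMES[best_label] if best_label is not None else None

        idx = np.nonzero(comp)
        comps2d = _slice_components(comp, vol, p)
        lesions.append(CalciumLesion(
            artery=artery,
            indices=idx,
            slice_components=comps2d,
            peak_hu=float(vol.voxels[comp].max()),
            voxel_volume_mm3=vol.voxel_volume,
            flags=[] if artery else ["no region overlap"],
        ))
    return lesions
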