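"""Locate the coronary corridor and split the heart into vessel territories.

Axially, the ascending aorta's cross-section progresses circular ->
elliptical -> semi-elliptical before it disappears. Iterating from the most
superior slice, the first elliptical slice is the *reference*; a slice a few
millimetres further down (``offset_mm``, default 10) is the *localization*
slice from which the heart is split into AORTA / RCA / LAD / LCX regions.

The split itself is an angular-sector rule: each in-plane voxel of the
coronary corridor inside the heart is labeled by its angle around the
per-slice heart centroid, measured from the aorta-to-heart-centroid axis.
This realization is deterministic, orientation-aware (the aorta anchors
"medial"), and reproduces standard coronary territory laterality; the sector
boundaries are configurable. Left-main calcium is not a separate region and
falls into the LAD/LCX sectors.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .ct_io import BinaryMask

__all__ = [
    "BACKGROUND",
    "AORTA",
    "RCA",
    "LAD",
    "LCX",
    "LABEL_NAMES",
    "AortaShape",
    "SliceShape",
    "AortaShapeProfile",
    "ShapeThresholds",
    "SectorParams",
    "ArteryRegionMap",
    "ReferenceSliceNotFound",
    "classify_aorta_shape",
    "build_aorta_profile",
    "find_reference_slice",
    "fallback_reference_slice",
    "localization_slice",
    "coronary_corridor",
    "split_heart_regions",
    "sector_label",
]

BACKGROUND, AORTA, RCA, LAD, LCX = 0, 1, 2, 3, 4
LABEL_NAMES = {BACKGROUND: "BACKGROUND", AORTA: "AORTA", RCA: "RCA", LAD: "LAD", LCX: "LCX"}
NAME_LABELS = {v: k for k, v in LABEL_NAMES.items()}


class AortaShape(enum.Enum):
    ABSENT = "absent"
    CIRCULAR = "circular"
    ELLIPTICAL = "elliptical"
    SEMI_ELLIPTICAL = "semi_elliptical"


@dataclass
class ShapeThresholds:
    """Fitted-ellipse axis-ratio and solidity cutoffs for shape classes."""

    axis_ratio: float = 1.25
    solidity: float = 0.9


@dataclass
class SliceShape:
    slice_index: int
    shape: AortaShape
    axis_ratio: float = float("nan")
    solidity: float = float("nan")


@dataclass
class AortaShapeProfile:
    slices: list[SliceShape]

    def classes(self) -> list[AortaShape]:
        return [s.shape for s in self.slices]


class ReferenceSliceNotFound(RuntimeError):
    """No elliptical aorta slice exists; callers may fall back to the
    maximum-area aorta slice (see :func:`fallback_reference_slice`)."""


def classify_aorta_shape(
    slice_mask: np.ndarray, thresholds: ShapeThresholds | None = None
) -> SliceShape:
    """Classify one axial aorta cross-section.

    Empty -> absent. A degraded (non-convex) outline, solidity below the
    cutoff, is semi-elliptical regardless of elongation; otherwise the
    fitted-ellipse axis ratio separates circular from elliptical.
    """
    thresholds = thresholds or ShapeThresholds()
    mask = np.asarray(slice_mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("classify_aorta_shape expects a 2D mask")
    if not mask.any():
        return SliceShape(-1, AortaShape.ABSENT)

    labels = measure.label(mask, connectivity=2)
    props = max(measure.regionprops(labels), key=lambda r: r.area)
    minor = props.axis_minor_length
    major = props.axis_major_length
    ratio = float("inf") if minor == 0 else major / minor
    solidity = props.solidity

    if solidity < thresholds.solidity:
        shape = AortaShape.SEMI_ELLIPTICAL
    elif ratio >= thresholds.axis_ratio:
        shape = AortaShape.ELLIPTICAL
    else:
        shape = AortaShape.CIRCULAR
    return SliceShape(-1, shape, ratio, solidity)


def build_aorta_profile(
    aorta: BinaryMask, thresholds: ShapeThresholds | None = None
) -> AortaShapeProfile:
    out = []
    for k in range(aorta.shape[2]):
        s = classify_aorta_shape(aorta.bits[:, :, k], thresholds)
        s.slice_index = k
        out.append(s)
    return AortaShapeProfile(out)


def find_reference_slice(profile: AortaShapeProfile) -> int:
    """Smallest (most superior) slice index classified elliptical."""
    for s in profile.slices:
        if s.shape is AortaShape.ELLIPTICAL:
            return s.slice_index
    raise ReferenceSliceNotFound(
        "no elliptical aorta slice found; fall back to the maximum-area aorta "
        "slice (fallback_reference_slice) and flag the run"
    )


def fallback_reference_slice(aorta: BinaryMask) -> int:
    """Slice of maximum aorta area — used when shape classification fails."""
    areas = aorta.bits.sum(axis=(0, 1))
    if areas.max() == 0:
        raise ValueError("aorta mask is empty; cannot choose a reference slice")
    return int(np.argmax(areas))


def localization_slice(reference: int, offset_mm: float, slice_spacing_mm: float) -> int:
    """Index of the splitting slice, ``offset_mm`` below the reference."""
    return reference + math.ceil(offset_mm / slice_spacing_mm)


# ---------------------------------------------------------------------------
# corridor
# ---------------------------------------------------------------------------

def _bbox_slices(bits: np.ndarray, margin_vox: tuple[int, int, int]) -> tuple[slice, ...]:
    obj = ndimage.find_objects(bits.astype(np.uint8), max_label=1)[0]
    out = []
    for ax, sl in enumerate(obj):
        lo = max(0, sl.start - margin_vox[ax])
        hi = min(bits.shape[ax], sl.stop + margin_vox[ax])
        out.append(slice(lo, hi))
    return tuple(out)


def dilate_mm(bits: np.ndarray, spacing, radius_mm: float) -> np.ndarray:
    """Euclidean dilation by a physical radius (anisotropic grid aware)."""
    if radius_mm <= 0 or not bits.any():
        return bits.copy()
    margin = tuple(int(math.ceil(radius_mm / s)) + 1 for s in spacing)
    box = _bbox_slices(bits, margin)
    sub = bits[box]
    d = ndimage.distance_transform_edt(~sub, sampling=spacing)
    out = np.zeros_like(bits)
    out[box] = d <= radius_mm
    return out


def erode_mm(bits: np.ndarray, spacing, radius_mm: float) -> np.ndarray:
    """Euclidean erosion by a physical radius."""
    if radius_mm <= 0 or not bits.any():
        return bits.copy()
    box = _bbox_slices(bits, (1, 1, 1))
    sub = bits[box]
    d = ndimage.distance_transform_edt(sub, sampling=spacing)
    out = np.zeros_like(bits)
    out[box] = d > radius_mm
    return out


def coronary_corridor(
    fat_mask: BinaryMask, dilate_radius_mm: float = 8.0, erode_radius_mm: float = 4.0
) -> BinaryMask:
    """Morphological closing of the epicardial-fat mask.

    Dilation followed by a (not larger) erosion fills the sub-fat groove the
    coronary arteries run in; with ``erode <= dilate`` the corridor is a
    superset of the fat mask.
    """
    if erode_radius_mm > dilate_radius_mm:
        raise ValueError("erode radius must not exceed dilate radius (corridor must contain fat)")
    if not fat_mask.bits.any():
        return fat_mask.copy()
    bits = dilate_mm(fat_mask.bits, fat_mask.spacing, dilate_radius_mm)
    bits = erode_mm(bits, fat_mask.spacing, erode_radius_mm)
    return BinaryMask(bits | fat_mask.bits, fat_mask.spacing)


# ---------------------------------------------------------------------------
# sector split
# ---------------------------------------------------------------------------

@dataclass
class SectorParams:
    """Angular sectors (degrees) measured from the aorta-to-centroid axis.

    RCA and LAD are half-open [lo, hi); LCX takes the remainder of the
    circle. The three must tile 360 degrees: rca_hi == lad_lo.
    """

    rca: tuple[float, float] = (-100.0, 80.0)
    lad: tuple[float, float] = (80.0, 200.0)

    def __post_init__(self) -> None:
        if not math.isclose(self.rca[1], self.lad[0]):
            raise ValueError("sectors must be contiguous: rca upper bound must equal lad lower bound")
        span = (self.lad[1] - self.rca[0])
        if not 0 < span <= 360:
            raise ValueError("rca+lad sectors must span at most the full circle")


def sector_label(theta_deg: np.ndarray, params: SectorParams) -> np.ndarray:
    """Map angles (deg, any branch) to RCA/LAD/LCX labels."""
    lo = params.rca[0]
    t = (np.asarray(theta_deg, dtype=float) - lo) % 360.0 + lo
    out = np.full(t.shape, LCX, dtype=np.int8)
    out[(t >= params.rca[0]) & (t < params.rca[1])] = RCA
    out[(t >= params.lad[0]) & (t < params.lad[1])] = LAD
    return out


def signed_angle_deg(u0: np.ndarray, u1: np.ndarray, axis: tuple[float, float]) -> np.ndarray:
    """Signed angle (deg) of in-plane vectors ``(u0, u1)`` from ``axis``."""
    a0, a1 = axis
    cross = a0 * u1 - a1 * u0
    dot = a0 * u0 + a1 * u1
    return np.degrees(np.arctan2(cross, dot))


@dataclass
class ArteryRegionMap:
    """Exclusive voxel labels {background, AORTA, RCA, LAD, LCX}."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    reference_slice: int
    localization_slice: int
    offset_mm: float
    flags: list[str] = field(default_factory=list)

    def mask(self, name: str) -> np.ndarray:
        return self.labels == NAME_LABELS[name]


def split_heart_regions(
    heart: BinaryMask,
    aorta: BinaryMask,
    corridor: BinaryMask,
    reference_slice: int,
    offset_mm: float = 10.0,
    sectors: SectorParams | None = None,
    flags: list[str] | None = None,
) -> ArteryRegionMap:
    """Label the volume into AORTA plus angular RCA/LAD/LCX territories.

    Aorta voxels are AORTA on every slice and are never relabeled as a
    coronary territory. Corridor voxels inside the heart, on slices at or
    below the localization slice, get a sector label; slices above it carry
    only the AORTA label.
    """
    sectors = sectors or SectorParams()
    if not heart.bits.any():
        raise ValueError("heart mask is empty; cannot split regions")
    if not aorta.bits.any():
        raise ValueError("aorta mask is empty; cannot orient the sector split")

    s0, s1, s2 = heart.spacing
    loc = localization_slice(reference_slice, offset_mm, s2)

    # Orientation axis: whole-heart in-plane centroid minus the aorta
    # centroid at (the nonempty aorta slice nearest to) the localization slice.
    hc = ndimage.center_of_mass(heart.bits)
    heart_c = np.array([hc[0] * s0, hc[1] * s1])
    aorta_areas = aorta.bits.sum(axis=(0, 1))
    nonempty = np.flatnonzero(aorta_areas)
    orient_k = int(nonempty[np.argmin(np.abs(nonempty - loc))])
    ac = ndimage.center_of_mass(aorta.bits[:, :, orient_k])
    aorta_c = np.array([ac[0] * s0, ac[1] * s1])
    axis = heart_c - aorta_c
    if np.allclose(axis, 0):
        raise ValueError("aorta and heart centroids coincide; cannot orient sectors")

    labels = np.zeros(heart.shape, dtype=np.int8)
    for k in range(max(loc, 0), heart.shape[2]):
        sel = heart.bits[:, :, k] & corridor.bits[:, :, k]
        if not sel.any():
            continue
        hk = heart.bits[:, :, k]
        ck = ndimage.center_of_mass(hk)
        ii, jj = np.nonzero(sel)
        u0 = (ii - ck[0]) * s0
        u1 = (jj - ck[1]) * s1
        theta = signed_angle_deg(u0, u1, (axis[0], axis[1]))
        labels[ii, jj, k] = sector_label(theta, sectors)

    labels[aorta.bits] = AORTA
    return ArteryRegionMap(labels, heart.spacing, reference_slice, loc, offset_mm,
                           list(flags or []))
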