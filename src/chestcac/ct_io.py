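"""CT volume and mask I/O and the grid conventions shared by the whole pipeline.

Conventions
-----------
* A volume is a 3D array ``voxels[i, j, k]`` of calibrated Hounsfield units.
  Axes 0 and 1 are in-plane; axis 2 indexes axial slices, with **slice 0 the
  most superior** slice (the region-splitting stage iterates craniocaudally).
* ``spacing = (s0, s1, s2)`` gives mm per voxel along the array axes.
* Masks live on the same grid as the volume they refer to; all morphology
  happens after grid standardization so masks never need resampling.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage

HU_MIN = -1024
HU_MAX = 4000

__all__ = [
    "CTVolume",
    "BinaryMask",
    "load_ct",
    "save_ct",
    "load_mask",
    "save_mask",
    "standardize_grid",
]


@dataclass
class CTVolume:
    """A calibrated 3D HU grid with per-axis spacing in mm.

    ``voxels`` is int16; values are clipped to [-1024, 4000] at load time.
    ``slice_axis`` is fixed at 2 and slice index 0 is the most superior slice.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int = 2
    superior_first: bool = True

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be strictly positive, got {self.spacing}")
        if self.slice_axis != 2:
            raise ValueError("axial slices must lie along axis 2")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def pixel_area(self) -> float:
        """In-plane area of one voxel in mm^2."""
        return float(self.spacing[0] * self.spacing[1])

    def axial(self, k: int) -> np.ndarray:
        return self.voxels[:, :, k]

    def copy(self) -> "CTVolume":
        return CTVolume(self.voxels.copy(), self.spacing)


@dataclass
class BinaryMask:
    """A boolean grid congruent with a parent :class:`CTVolume` grid."""

    bits: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.bits.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.bits.shape

    @property
    def voxel_count(self) -> int:
        return int(self.bits.sum())

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (``s0*s1*s2``)."""
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume

    def congruent_with(self, other) -> bool:
        return self.shape == other.shape

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.bits.copy(), self.spacing)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _nifti_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # +k runs superior -> inferior, i.e. towards -z in RAS; encode that in the
    # affine so the superior-first convention round-trips.
    s0, s1, s2 = spacing
    return np.diag([s0, s1, -s2, 1.0])


def save_ct(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI (.nii / .nii.gz), int16 HU."""
    img = nib.Nifti1Image(vol.voxels.astype(np.int16), _nifti_affine(vol.spacing))
    nib.save(img, str(path))


def _load_nifti(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(not math.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"non-positive or missing pixdim in NIfTI header: {zooms}")
    data = np.asanyarray(img.dataobj)
    # Flip so slice 0 is most superior: in (approximately) RAS-aligned
    # affines, +z points superior, so a positive k->z direction means the
    # file stores inferior-first.
    if img.affine[2, 2] > 0:
        data = data[:, :, ::-1]
    # NIfTI pixdim is float32; round away its representation error
    return np.ascontiguousarray(data), tuple(round(float(z), 6) for z in zooms)


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def _load_dicom_series(directory: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    directory = Path(directory)
    datasets = []
    for p in sorted(directory.iterdir()):
        if not p.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"no readable DICOM slices in {directory}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(
            f"directory mixes {len(uids)} DICOM series (SeriesInstanceUID values: {sorted(uids)})"
        )

    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise ValueError("missing spacing metadata: PixelSpacing")
    s0, s1 = (float(v) for v in first.PixelSpacing)

    have_positions = all(hasattr(ds, "ImagePositionPatient") for ds in datasets)
    if have_positions:
        # DICOM patient +z points superior: sort descending -> superior first.
        datasets.sort(key=lambda ds: -float(ds.ImagePositionPatient[2]))
        zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
        if len(zs) > 1:
            steps = np.abs(np.diff(zs))
            s2 = float(np.median(steps))
            if s2 <= 0 or (steps.max() - steps.min()) > 0.01 * s2 + 1e-6:
                raise ValueError(
                    "contradictory spacing metadata: ImagePositionPatient slice steps "
                    f"range from {steps.min():.4g} to {steps.max():.4g} mm"
                )
        else:
            s2 = float(getattr(first, "SliceThickness", 0) or 0)
            if s2 <= 0:
                raise ValueError("missing spacing metadata: SliceThickness")
    else:
        if not all(hasattr(ds, "SliceThickness") for ds in datasets):
            raise ValueError("missing spacing metadata: ImagePositionPatient / SliceThickness")
        datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
        s2 = float(first.SliceThickness)
        if s2 <= 0:
            raise ValueError("missing spacing metadata: SliceThickness")

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float64) * slope + intercept
        slices.append(hu)
    vol = np.stack(slices, axis=2)
    return vol, (s0, s1, s2)


# ---------------------------------------------------------------------------
# public loaders
# ---------------------------------------------------------------------------

def load_ct(path: str | os.PathLike, format_hint: str | None = None) -> CTVolume:
    """Load a CT volume from a DICOM series directory or a NIfTI file.

    DICOM rescale slope/intercept are applied, slices are ordered
    superior -> inferior, and HU values are clipped to [-1024, 4000].
    """
    path = Path(path)
    fmt = format_hint
    if fmt is None:
        if path.is_dir():
            fmt = "dicom"
        elif path.suffixes and path.suffixes[-1] in (".nii", ".gz"):
            fmt = "nifti"
        else:
            raise ValueError(f"cannot infer format of {path}; pass format_hint")

    if fmt == "dicom":
        data, spacing = _load_dicom_series(path)
    elif fmt == "nifti":
        data, spacing = _load_nifti(path)
    else:
        raise ValueError(f"unknown format_hint {fmt!r}")

    data = np.clip(np.rint(data), HU_MIN, HU_MAX).astype(np.int16)
    return CTVolume(data, spacing)


def save_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a binary mask as a uint8 NIfTI carrying the parent spacing."""
    img = nib.Nifti1Image(mask.bits.astype(np.uint8), _nifti_affine(mask.spacing))
    nib.save(img, str(path))


def load_mask(path: str | os.PathLike, parent: CTVolume | BinaryMask | None = None) -> BinaryMask:
    """Reload a mask written by :func:`save_mask`; bit-exact round trip.

    If ``parent`` is given, a shape mismatch with the parent grid is an error.
    """
    data, spacing = _load_nifti(path)
    mask = BinaryMask(data > 0.5, spacing)
    if parent is not None and mask.shape != parent.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match parent grid {parent.shape}"
        )
    return mask


# ---------------------------------------------------------------------------
# grid standardization
# ---------------------------------------------------------------------------

def standardize_grid(vol: CTVolume, target_in_plane: int = 512, order: int = 1) -> CTVolume:
    """Resample the in-plane grid to ``target x target`` pixels.

    In-plane spacing is rescaled so the physical extent ``dim * spacing`` is
    conserved exactly; HU values are interpolated at the given spline order
    (default linear). Slices are never resampled along the z axis.
    """
    if target_in_plane is None:
        return vol
    t = int(target_in_plane)
    if t <= 0:
        raise ValueError(f"target in-plane size must be positive, got {target_in_plane}")
    n0, n1, _ = vol.shape
    if n0 < 32 or n1 < 32:
        raise ValueError(f"in-plane dimensions must be >= 32, got {n0}x{n1}")
    if n0 == t and n1 == t:
        return vol.copy()

    factors = (t / n0, t / n1, 1.0)
    resampled = ndimage.zoom(vol.voxels.astype(np.float32), factors, order=order,
                             mode="nearest", grid_mode=True)
    assert resampled.shape[:2] == (t, t)
    data = np.clip(np.rint(resampled), HU_MIN, HU_MAX).astype(np.int16)
    s0, s1, s2 = vol.spacing
    return CTVolume(data, (s0 * n0 / t, s1 * n1 / t, s2))
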