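"""Shared fixtures: canonical phantom runs and batch summaries.

The heavy end-to-end artifacts (a default phantom with its pipeline result,
and a 20-phantom randomized batch) are session-scoped so the oracle, bone,
attribution and property tests all reuse one computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pytest

import chestcac as cc
from chestcac import phantom as ph
from chestcac import region_split as rs
from chestcac.scoring import density_coefficient

BATCH_SEEDS = tuple(range(1, 21))


# ---------------------------------------------------------------------------
# DICOM slice factory
# ---------------------------------------------------------------------------

def write_dicom_slice(path, z, series_uid, pixels, slope=1.0, intercept=-1024.0,
                      pixel_spacing=(0.7, 0.7), thickness=2.5):
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    fm = FileMetaDataset()
    fm.MediaStorageSOPClassUID = CTImageStorage
    fm.MediaStorageSOPInstanceUID = generate_uid()
    fm.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = fm
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = fm.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "CT"
    ds.Rows, ds.Columns = pixels.shape
    ds.PixelSpacing = list(pixel_spacing)
    ds.SliceThickness = thickness
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = np.asarray(pixels, dtype=np.uint16).tobytes()
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# canonical phantom + pipeline result (full arrays kept)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_phantom():
    spec = ph.PhantomSpec.default()
    vol, truth = ph.generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def default_result(default_phantom):
    _, vol, _ = default_phantom
    return cc.run_volume(vol)


# ---------------------------------------------------------------------------
# randomized batch: compact per-phantom summaries (arrays discarded)
# ---------------------------------------------------------------------------

@dataclass
class PhantomRunRecord:
    seed: int
    expected: dict[str, float]
    measured: dict[str, float]
    tolerance: dict[str, float]
    n_lesion_voxels: int
    n_correctly_attributed: int
    bone_voxels_in_final: int
    all_guarded_lesions_retained: bool
    lesion_min_pixels: list[int]
    lesion_peaks: list[float]
    corridor_contains_fat: bool
    aorta_never_coronary: bool
    flags: list[str] = field(default_factory=list)


def run_and_summarize(seed: int) -> PhantomRunRecord:
    spec = ph.random_phantom_spec(seed)
    vol, truth = ph.generate_phantom(spec)
    res = cc.run_volume(vol)

    expected = ph.expected_agatston(truth)
    measured = dict(res.report.per_artery)
    measured["AORTA"] = res.report.aorta
    measured["TOTAL"] = res.report.total

    # rasterization tolerance: one voxel-area per slice-component, weighted
    # by that component's density coefficient
    px = vol.pixel_area
    tol = {a: 0.0 for a in ("RCA", "LAD", "LCX", "AORTA")}
    for lt in truth.lesions:
        tol[lt.artery] += sum(px * density_coefficient(r.max_hu) for r in lt.per_slice)
    tol["TOTAL"] = tol["RCA"] + tol["LAD"] + tol["LCX"]

    n_vox = n_correct = 0
    retained = True
    min_px, peaks = [], []
    final = res.final_mask.bits
    for lt in truth.lesions:
        lab = res.region_map.labels[lt.indices]
        n_correct += int((lab == rs.NAME_LABELS[lt.artery]).sum())
        n_vox += lab.size
        min_px.append(lt.min_pixels_per_slice)
        peaks.append(lt.peak_hu)
        if lt.min_pixels_per_slice >= 4 and lt.peak_hu >= 200:
            retained &= bool(final[lt.indices].all())

    corridor = rs.coronary_corridor(res.organ_masks.epicardial_fat)
    contains_fat = bool((res.organ_masks.epicardial_fat.bits & ~corridor.bits).sum() == 0)
    aorta_ok = not np.isin(res.region_map.labels[res.organ_masks.aorta.bits],
                           [rs.RCA, rs.LAD, rs.LCX]).any()

    return PhantomRunRecord(
        seed=seed,
        expected=expected,
        measured=measured,
        tolerance=tol,
        n_lesion_voxels=n_vox,
        n_correctly_attributed=n_correct,
        bone_voxels_in_final=int((final & truth.bone.bits).sum()),
        all_guarded_lesions_retained=retained,
        lesion_min_pixels=min_px,
        lesion_peaks=peaks,
        corridor_contains_fat=contains_fat,
        aorta_never_coronary=bool(aorta_ok),
        flags=list(res.flags),
    )


@pytest.fixture(scope="session")
def batch20():
    """Twenty seeded noise-free randomized phantoms, run end to end."""
    return [run_and_summarize(seed) for seed in BATCH_SEEDS]
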