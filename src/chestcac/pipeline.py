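"""End-to-end orchestration: segment -> split regions -> calcium cascade -> score.

A run executes four stages on a standardized volume:

1. multi-organ segmentation (pluggable backend, or injected mask files),
2. coronary-region segmentation (fat corridor + aorta-anchored sector split),
3. true-calcium segmentation (threshold / denoise / de-bone / recover / gate),
4. Agatston scoring and CAC-DRS categorization.

Thresholding and scoring always read the *raw* standardized HU values;
anisotropic smoothing feeds only the segmentation stage, so per-slice maxima
— and hence the Table-of-coefficients density bins — are never perturbed by
the denoiser. Identical inputs and config give identical outputs; the one
random element anywhere (phantom noise) is seeded through the config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calcium as calc
from . import region_split as rs
from .ct_io import BinaryMask, CTVolume, load_ct, save_mask, standardize_grid
from .metrics import EvalReport, build_eval_report
from .preprocess import DiffusionParams, anisotropic_smooth
from .scoring import AgatstonReport, score_lesions, slice_component_score
from .segmentation import (OrganMaskSet, ReferenceBackend, ReferenceSegParams,
                           SegmentationBackend, derive_epicardial_fat)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "PipelineStageError",
    "run_volume",
    "run",
    "evaluate",
]


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and a remediation hint."""

    def __init__(self, stage: str, hint: str, cause: Exception):
        super().__init__(f"[{stage}] {cause} — {hint}")
        self.stage = stage
        self.hint = hint


@dataclass
class PipelineConfig:
    """Every tunable of the four stages; serializable for reproducible runs."""

    target_in_plane: int | None = None
    smooth_for_segmentation: bool = True
    smoothing: DiffusionParams = field(default_factory=DiffusionParams)
    segmentation: ReferenceSegParams = field(default_factory=ReferenceSegParams)
    corridor_dilate_mm: float = 8.0
    corridor_erode_mm: float = 4.0
    offset_mm: float = 10.0
    sectors: rs.SectorParams = field(default_factory=rs.SectorParams)
    calcium: calc.CalciumFilterParams = field(default_factory=calc.CalciumFilterParams)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (("smoothing", DiffusionParams),
                         ("segmentation", ReferenceSegParams),
                         ("sectors", rs.SectorParams),
                         ("calcium", calc.CalciumFilterParams)):
            if key in d and isinstance(d[key], dict):
                sub = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in d[key].items()}
                d[key] = typ(**sub)
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


@dataclass
class PipelineResult:
    report: AgatstonReport
    lesions: list[calc.CalciumLesion]
    organ_masks: OrganMaskSet
    region_map: rs.ArteryRegionMap
    candidates: BinaryMask
    final_mask: BinaryMask
    flags: list[str]
    volume: CTVolume

    def lesion_table(self) -> pd.DataFrame:
        rows = []
        for i, les in enumerate(self.lesions):
            score = sum(slice_component_score(c.area_mm2, c.max_hu)
                        for c in les.slice_components)
            rows.append({
                "lesion": i,
                "artery": les.artery or "UNASSIGNED",
                "n_voxels": les.n_voxels,
                "volume_mm3": round(les.volume_mm3, 4),
                "peak_hu": les.peak_hu,
                "n_slices": len({c.slice_index for c in les.slice_components}),
                "agatston": round(score, 4),
            })
        return pd.DataFrame(rows, columns=["lesion", "artery", "n_voxels", "volume_mm3",
                                           "peak_hu", "n_slices", "agatston"])


def _stage(name: str, hint: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, hint, exc) from exc
            return False
    return _Ctx()


def run_volume(vol: CTVolume, config: PipelineConfig | None = None,
               masks: OrganMaskSet | None = None) -> PipelineResult:
    """Run the four stages on an in-memory volume.

    Supplying ``masks`` bypasses the segmentation backend entirely; the
    downstream stages are bitwise identical either way.
    """
    cfg = config or PipelineConfig()
    flags: list[str] = []

    with _stage("standardize", "check in-plane dimensions and target size"):
        vol_std = standardize_grid(vol, cfg.target_in_plane) if cfg.target_in_plane \
            else vol

    with _stage("segmentation", "inspect the volume HU calibration, or inject masks "
                                "from an external model via OrganMaskSet/FileBackend"):
        if masks is None or masks.epicardial_fat is None:
            seg_input = anisotropic_smooth(vol_std, cfg.smoothing) \
                if cfg.smooth_for_segmentation else vol_std
            if masks is None:
                masks = ReferenceBackend(cfg.segmentation).segment(seg_input)
            if masks.epicardial_fat is None:
                p = cfg.segmentation
                masks = OrganMaskSet(
                    masks.heart, masks.aorta,
                    derive_epicardial_fat(seg_input, masks.heart, p.fat_hu_range,
                                          p.fat_shell_mm, p.fat_min_voxels))

    with _stage("region_split", "verify the aorta mask; the reference slice needs an "
                                "elliptical aorta cross-section or the area fallback"):
        profile = rs.build_aorta_profile(masks.aorta)
        try:
            reference = rs.find_reference_slice(profile)
        except rs.ReferenceSliceNotFound:
            reference = rs.fallback_reference_slice(masks.aorta)
            flags.append("fallback reference slice (maximum aorta area) used")
        corridor = rs.coronary_corridor(masks.epicardial_fat, cfg.corridor_dilate_mm,
                                        cfg.corridor_erode_mm)
        region_map = rs.split_heart_regions(masks.heart, masks.aorta, corridor,
                                            reference, cfg.offset_mm, cfg.sectors,
                                            flags)

    with _stage("calcium", "review cascade thresholds in CalciumFilterParams"):
        cand = calc.candidate_mask(vol_std, cfg.calcium.hu_min)
        sup = calc.suppress_noise(cand, vol_std, cfg.calcium)
        boneless = calc.remove_bone(sup, vol_std, cfg.calcium)
        final = calc.recover_components(boneless, cand, cfg.calcium)
        cardiac = BinaryMask(masks.heart.bits | masks.aorta.bits, vol_std.spacing)
        final = BinaryMask(final.bits & cardiac.bits, vol_std.spacing)
        lesions = calc.assign_lesions(final, cardiac, region_map, vol_std, cfg.calcium)

    with _stage("scoring", "scores derive from lesion slice components; check "
                           "attribution flags on the report"):
        report = score_lesions(lesions, flags)

    return PipelineResult(report, lesions, masks, region_map, cand, final,
                          flags, vol_std)


def run(volume_path, config: PipelineConfig | None = None,
        out_dir=None, masks: OrganMaskSet | None = None) -> PipelineResult:
    """Load a volume (DICOM dir or NIfTI), run the pipeline, write artifacts.

    Artifacts: organ and calcium masks (NIfTI), the region label volume, the
    per-lesion table (CSV), the Agatston report (JSON) and the resolved
    config — enough to reproduce the run exactly.
    """
    cfg = config or PipelineConfig()
    with _stage("load", "expected a DICOM series directory or a NIfTI file"):
        vol = load_ct(volume_path)
    result = run_volume(vol, cfg, masks=masks)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_mask(result.organ_masks.heart, out / "heart_mask.nii.gz")
        save_mask(result.organ_masks.aorta, out / "aorta_mask.nii.gz")
        if result.organ_masks.epicardial_fat is not None:
            save_mask(result.organ_masks.epicardial_fat, out / "fat_mask.nii.gz")
        save_mask(result.final_mask, out / "calcium_mask.nii.gz")
        import nibabel as nib

        from .ct_io import _nifti_affine
        nib.save(nib.Nifti1Image(result.region_map.labels.astype(np.int8),
                                 _nifti_affine(result.volume.spacing)),
                 str(out / "region_labels.nii.gz"))
        result.lesion_table().to_csv(out / "lesions.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(result.report.to_dict(), indent=2, sort_keys=True))
        cfg.to_file(out / "config.json")
    return result


def evaluate(pairs_csv, out_path=None) -> EvalReport:
    """Evaluate a cohort CSV of paired reference/predicted Agatston results.

    The CSV needs ``reference`` and ``predicted`` total-score columns
    (``reference_grade`` / ``predicted_grade`` override derived grades).
    Malformed rows are reported with their line numbers.
    """
    path = Path(pairs_csv)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise ValueError(f"cannot read pairs file {path}: {exc}") from exc
    if df.empty:
        raise ValueError(f"pairs file {path} contains no rows")
    cols = {c.lower().strip(): c for c in df.columns}
    missing = [c for c in ("reference", "predicted") if c not in cols]
    if missing:
        raise ValueError(f"pairs file {path} lacks required column(s): {missing}")

    bad_lines = []
    for col in ("reference", "predicted"):
        vals = pd.to_numeric(df[cols[col]], errors="coerce")
        bad = vals.isna() | (vals < 0)
        bad_lines.extend((df.index[bad] + 2).tolist())  # +2: header + 1-based
        df[cols[col]] = vals
    if bad_lines:
        raise ValueError(
            f"malformed score values in {path} at line(s) {sorted(set(bad_lines))}")

    ref_grades = df[cols["reference_grade"]].astype(int).tolist() \
        if "reference_grade" in cols else None
    pred_grades = df[cols["predicted_grade"]].astype(int).tolist() \
        if "predicted_grade" in cols else None
    report = build_eval_report(df[cols["reference"]], df[cols["predicted"]],
                               ref_grades, pred_grades)
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    return report
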