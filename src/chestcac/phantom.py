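"""Synthetic non-gated chest-CT phantoms with analytic Agatston ground truth.

A phantom is built from HU compartments — air, chest-wall soft tissue, lung,
myocardium/blood pool, an epicardial-fat shell, aortic blood, cortical bone
(spine plus rib flecks) — plus calcium lesions of prescribed per-slice area,
plateau HU and a single controlled peak voxel. Because lesion geometry and
intensities are known at generation time, the per-artery Agatston scores are
computable analytically, making the phantom the independent oracle for the
whole detection-and-scoring pipeline.

The aorta's axial cross-section follows the circular -> elliptical ->
semi-elliptical -> absent progression the region-splitting stage keys on,
and the slice where it first turns elliptical is a spec field, giving the
reference-slice finder a known answer. The "semi-elliptical" (degraded,
about-to-disappear) sections are rasterized as notched ellipses so their
solidity drops below the classifier cutoff.

What the phantom does *not* emulate: beam hardening, reconstruction kernels,
motion blur, partial-volume fading at lesion rims. Compartment HU plus
additive Gaussian noise suffice to exercise every filtering rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import region_split as rs
from .ct_io import BinaryMask, CTVolume
from .scoring import RiskCategory, categorize, density_coefficient

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "LesionTruth",
    "PhantomTruth",
    "generate_phantom",
    "expected_agatston",
    "spec_level_agatston",
    "random_phantom_spec",
    "CANONICAL_ANGLES",
]

ARTERIES = ("RCA", "LAD", "LCX")
REGIONS = ("RCA", "LAD", "LCX", "AORTA")

#: default placement angle (deg, from the aorta-to-heart-centroid axis) per artery;
#: comfortably inside the default sectors RCA [-100,80), LAD [80,200), LCX [200,260)
CANONICAL_ANGLES = {"RCA": -10.0, "LAD": 140.0, "LCX": 230.0}


@dataclass
class LesionSpec:
    """One calcium lesion: artery territory, per-slice area, intensities.

    Coronary lesions are placed on the epicardial surface at ``angle_deg``
    around the heart centroid (canonical per-artery default); AORTA lesions
    sit inside the aortic lumen. ``peak_hu`` is assigned to a single voxel on
    the center slice; all other voxels get ``plateau_hu``, so every per-slice
    maximum is controlled by construction.
    """

    artery: str
    area_mm2: float = 12.0
    peak_hu: float = 450.0
    plateau_hu: float = 300.0
    center_slice: int = 38
    n_slices: int = 2
    angle_deg: float | None = None
    center_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.artery not in REGIONS:
            raise ValueError(f"artery must be one of {REGIONS}, got {self.artery!r}")
        if self.peak_hu < 130:
            raise ValueError(f"lesion peak HU must be >= 130, got {self.peak_hu}")
        if not (130 <= self.plateau_hu <= self.peak_hu):
            raise ValueError("plateau HU must lie in [130, peak_hu]")
        if self.area_mm2 <= 0 or self.n_slices < 1:
            raise ValueError("lesion needs positive area and at least one slice")

    @property
    def slice_range(self) -> range:
        start = self.center_slice - (self.n_slices - 1) // 2
        return range(start, start + self.n_slices)

    @property
    def radius_mm(self) -> float:
        return math.sqrt(self.area_mm2 / math.pi)


@dataclass
class PhantomSpec:
    """Full geometric/intensity description of a phantom.

    All geometry is in mm; position of voxel (i, j, k) is (i*s0, j*s1, k*s2).
    Slice 0 is the most superior slice. Defaults give a 256x256x60 grid at
    (0.7, 0.7, 2.5) mm — fast enough for batch runs; in-plane 512 is a matter
    of shape/spacing only.
    """

    shape: tuple[int, int, int] = (256, 256, 60)
    spacing: tuple[float, float, float] = (0.7, 0.7, 2.5)

    body_center_mm: tuple[float, float] = (89.6, 89.6)
    body_semiaxes_mm: tuple[float, float] = (80.0, 72.0)
    cavity_center_mm: tuple[float, float] = (89.6, 86.0)
    cavity_semiaxes_mm: tuple[float, float] = (68.0, 48.0)

    heart_center_mm: tuple[float, float, float] = (82.6, 91.0, 95.0)
    heart_semiaxes_mm: tuple[float, float, float] = (40.0, 35.0, 35.0)
    fat_thickness_mm: float = 4.0

    aorta_center_mm: tuple[float, float] = (120.0, 55.0)
    aorta_radius_mm: float = 9.0
    aorta_ellipse_semiaxes_mm: tuple[float, float] = (12.0, 7.5)
    first_elliptical_slice: int = 12
    first_semi_elliptical_slice: int = 20
    aorta_last_slice: int = 28

    spine_center_mm: tuple[float, float] = (89.6, 143.0)
    spine_radius_mm: float = 8.0
    #: (center0_mm, center1_mm, slice, radius_mm, hu) small bone flecks near the spine
    rib_flecks: tuple = ((99.4, 140.5, 20, 1.2, 900.0), (79.8, 140.5, 40, 1.2, 900.0))

    hu_air: float = -1000.0
    hu_body: float = 30.0
    hu_lung: float = -800.0
    hu_heart: float = 45.0
    hu_fat: float = -100.0
    hu_aorta: float = 90.0
    hu_bone: float = 1000.0

    lesions: list[LesionSpec] = field(default_factory=list)
    split_offset_mm: float = 10.0
    sectors: rs.SectorParams = field(default_factory=rs.SectorParams)
    noise_sd: float = 0.0
    seed: int = 0

    # -- convenience constructors ------------------------------------------
    @classmethod
    def default(cls) -> "PhantomSpec":
        """Three canonical coronary lesions, one per artery, noise-free."""
        return cls(lesions=[
            LesionSpec("RCA", area_mm2=12.0, peak_hu=450.0, plateau_hu=300.0,
                       center_slice=36, n_slices=2),
            LesionSpec("LAD", area_mm2=12.0, peak_hu=450.0, plateau_hu=300.0,
                       center_slice=40, n_slices=2),
            LesionSpec("LCX", area_mm2=10.0, peak_hu=300.0, plateau_hu=250.0,
                       center_slice=38, n_slices=2),
        ])

    @classmethod
    def zero_lesion(cls, noise_sd: float = 0.0, seed: int = 0) -> "PhantomSpec":
        return cls(lesions=[], noise_sd=noise_sd, seed=seed)

    def translated(self, d0_mm: float, d1_mm: float) -> "PhantomSpec":
        """Shift every in-plane center by (d0, d1) mm — equivariance probes."""
        def sh2(c):
            return (c[0] + d0_mm, c[1] + d1_mm)
        lesions = [replace(l, center_mm=None if l.center_mm is None
                           else sh2(l.center_mm)) for l in self.lesions]
        return replace(
            self,
            body_center_mm=sh2(self.body_center_mm),
            cavity_center_mm=sh2(self.cavity_center_mm),
            heart_center_mm=(self.heart_center_mm[0] + d0_mm,
                             self.heart_center_mm[1] + d1_mm,
                             self.heart_center_mm[2]),
            aorta_center_mm=sh2(self.aorta_center_mm),
            spine_center_mm=sh2(self.spine_center_mm),
            rib_flecks=tuple((c0 + d0_mm, c1 + d1_mm, k, r, hu)
                             for c0, c1, k, r, hu in self.rib_flecks),
            lesions=lesions,
        )


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class SliceRecord:
    slice_index: int
    n_pixels: int
    area_mm2: float
    max_hu: float


@dataclass
class LesionTruth:
    artery: str
    indices: tuple[np.ndarray, np.ndarray, np.ndarray]
    per_slice: list[SliceRecord]
    center_mm: tuple[float, float]

    @property
    def n_voxels(self) -> int:
        return len(self.indices[0])

    @property
    def min_pixels_per_slice(self) -> int:
        return min(r.n_pixels for r in self.per_slice)

    @property
    def peak_hu(self) -> float:
        return max(r.max_hu for r in self.per_slice)


@dataclass
class PhantomTruth:
    """Exact rasterized compartments, region labels and expected scores."""

    heart: BinaryMask
    aorta: BinaryMask
    fat: BinaryMask
    bone: BinaryMask
    region_labels: np.ndarray
    reference_slice: int
    localization_slice: int
    lesions: list[LesionTruth]
    expected_per_artery: dict[str, float]
    expected_aorta: float
    expected_total: float
    expected_category: RiskCategory
    spacing: tuple[float, float, float]


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------

def _plane_coords(shape, spacing):
    ii = np.arange(shape[0])[:, None] * spacing[0]
    jj = np.arange(shape[1])[None, :] * spacing[1]
    return ii, jj


def _ellipse2d(shape, spacing, center, semi):
    ii, jj = _plane_coords(shape, spacing)
    return ((ii - center[0]) / semi[0]) ** 2 + ((jj - center[1]) / semi[1]) ** 2 <= 1.0


def _disk2d(shape, spacing, center, radius):
    return _ellipse2d(shape, spacing, center, (radius, radius))


def _ellipsoid_rho2(shape, spacing, center, semi):
    """Squared normalized ellipsoid radius on the full grid."""
    ii, jj = _plane_coords(shape[:2], spacing[:2])
    kk = np.arange(shape[2]) * spacing[2]
    r2 = ((ii - center[0]) / semi[0]) ** 2 + ((jj - center[1]) / semi[1]) ** 2
    return r2[:, :, None] + ((kk - center[2]) / semi[2]) ** 2


def _aorta_slice_mask(spec: PhantomSpec, k: int) -> np.ndarray | None:
    shp, sp = spec.shape[:2], spec.spacing[:2]
    c = spec.aorta_center_mm
    if k > spec.aorta_last_slice:
        return None
    if k < spec.first_elliptical_slice:
        return _disk2d(shp, sp, c, spec.aorta_radius_mm)
    ell = _ellipse2d(shp, sp, c, spec.aorta_ellipse_semiaxes_mm)
    if k < spec.first_semi_elliptical_slice:
        return ell
    # degraded section: notch the ellipse with a bite so solidity drops
    bite = _disk2d(shp, sp, (c[0] + 8.0, c[1]), spec.aorta_ellipse_semiaxes_mm[1])
    return ell & ~bite


def _lesion_center(spec: PhantomSpec, les: LesionSpec) -> tuple[float, float]:
    """In-plane center of a coronary lesion on the epicardial shell."""
    if les.center_mm is not None:
        return les.center_mm
    if les.artery == "AORTA":
        return spec.aorta_center_mm
    angle = les.angle_deg if les.angle_deg is not None else CANONICAL_ANGLES[les.artery]
    hc = spec.heart_center_mm
    a = np.array([hc[0] - spec.aorta_center_mm[0], hc[1] - spec.aorta_center_mm[1]])
    a /= np.linalg.norm(a)
    th = math.radians(angle)
    u = np.array([a[0] * math.cos(th) - a[1] * math.sin(th),
                  a[0] * math.sin(th) + a[1] * math.cos(th)])
    sa, sb, sc_ = spec.heart_semiaxes_mm
    dz = les.center_slice * spec.spacing[2] - hc[2]
    rho0 = 0.93
    rhs = rho0 ** 2 - (dz / sc_) ** 2
    if rhs <= (les.radius_mm / min(sa, sb)) ** 2:
        raise ValueError(
            f"lesion at slice {les.center_slice} lies too close to the heart pole "
            "for on-shell placement; move it toward the equatorial slices"
        )
    r = math.sqrt(rhs) / math.sqrt((u[0] / sa) ** 2 + (u[1] / sb) ** 2)
    return (hc[0] + r * u[0], hc[1] + r * u[1])


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Rasterize a phantom; deterministic for a fixed spec (incl. seed).

    Raises if compartments collide (the offending pair is named) or if a
    lesion cannot be placed inside its artery territory.
    """
    shape, spacing = spec.shape, spec.spacing
    s0, s1, s2 = spacing
    px_area = s0 * s1

    body = _ellipse2d(shape[:2], spacing[:2], spec.body_center_mm, spec.body_semiaxes_mm)
    cavity = _ellipse2d(shape[:2], spacing[:2], spec.cavity_center_mm, spec.cavity_semiaxes_mm)
    if (cavity & ~body).any():
        raise ValueError("compartment collision: cavity extends outside body")

    heart_rho2 = _ellipsoid_rho2(shape, spacing, spec.heart_center_mm, spec.heart_semiaxes_mm)
    heart = heart_rho2 <= 1.0
    inner_semi = tuple(max(a - spec.fat_thickness_mm, 1.0) for a in spec.heart_semiaxes_mm)
    inner = _ellipsoid_rho2(shape, spacing, spec.heart_center_mm, inner_semi) <= 1.0
    shell = heart & ~inner

    aorta = np.zeros(shape, dtype=bool)
    for k in range(shape[2]):
        m = _aorta_slice_mask(spec, k)
        if m is not None:
            aorta[:, :, k] = m

    spine2d = _disk2d(shape[:2], spacing[:2], spec.spine_center_mm, spec.spine_radius_mm)
    bone = np.zeros(shape, dtype=bool)
    bone[:, :, :] = spine2d[:, :, None]
    fleck = np.zeros(shape, dtype=bool)
    for c0, c1, k, r, _hu in spec.rib_flecks:
        if 0 <= k < shape[2]:
            fleck[:, :, k] |= _disk2d(shape[:2], spacing[:2], (c0, c1), r)
    bone_all = bone | fleck

    for name_a, a, name_b, b in (
        ("heart", heart, "aorta", aorta),
        ("heart", heart, "bone", bone_all),
        ("aorta", aorta, "bone", bone_all),
    ):
        if (a & b).any():
            raise ValueError(f"compartment collision: {name_a} overlaps {name_b}")
    cav3 = cavity[:, :, None] & np.ones(shape, dtype=bool)
    for name, m in (("heart", heart), ("aorta", aorta)):
        if (m & ~cav3).any():
            raise ValueError(f"compartment collision: {name} extends outside the thoracic cavity")

    # --- paint -------------------------------------------------------------
    vol = np.full(shape, spec.hu_air, dtype=np.float64)
    vol[body[:, :, None] & np.ones(shape, dtype=bool)] = spec.hu_body
    vol[cav3] = spec.hu_lung
    vol[bone] = spec.hu_bone
    for c0, c1, k, r, hu in spec.rib_flecks:
        if 0 <= k < shape[2]:
            vol[:, :, k][_disk2d(shape[:2], spacing[:2], (c0, c1), r)] = hu
    vol[shell] = spec.hu_fat
    vol[inner] = spec.hu_heart
    vol[aorta] = spec.hu_aorta

    # --- lesions -----------------------------------------------------------
    lesion_truths: list[LesionTruth] = []
    lesion_union = np.zeros(shape, dtype=bool)
    for les in spec.lesions:
        # paint the values the int16 volume will actually hold, so the truth
        # records and the rasterized voxels sit in the same density bin
        plateau_hu = float(np.rint(les.plateau_hu))
        peak_hu = float(np.rint(les.peak_hu))
        center = _lesion_center(spec, les)
        disk = _disk2d(shape[:2], spacing[:2], center, les.radius_mm)
        if not disk.any():
            raise ValueError(f"lesion area {les.area_mm2} mm^2 rasterizes to zero pixels")
        per_slice: list[SliceRecord] = []
        idx0, idx1, idx2 = [], [], []
        for k in les.slice_range:
            if not (0 <= k < shape[2]):
                raise ValueError(f"lesion slice {k} outside the volume")
            if les.artery == "AORTA":
                am = _aorta_slice_mask(spec, k)
                if am is None or (disk & ~am).any():
                    raise ValueError(
                        "compartment collision: AORTA lesion does not fit inside the aortic lumen"
                    )
            if (lesion_union[:, :, k] & disk).any():
                raise ValueError("compartment collision: lesion overlaps lesion")
            lesion_union[:, :, k] |= disk
            vol[:, :, k][disk] = plateau_hu
            ii, jj = np.nonzero(disk)
            idx0.append(ii)
            idx1.append(jj)
            idx2.append(np.full(ii.shape, k))
            per_slice.append(SliceRecord(k, len(ii), len(ii) * px_area, plateau_hu))
        # single controlled peak voxel on the center slice
        ii, jj = np.nonzero(disk)
        d2 = (ii * s0 - center[0]) ** 2 + (jj * s1 - center[1]) ** 2
        pi, pj = ii[np.argmin(d2)], jj[np.argmin(d2)]
        vol[pi, pj, les.center_slice] = peak_hu
        for rec in per_slice:
            if rec.slice_index == les.center_slice:
                rec.max_hu = peak_hu
        if les.artery != "AORTA":
            rho = np.sqrt(heart_rho2[np.concatenate(idx0), np.concatenate(idx1),
                                     np.concatenate(idx2)])
            if rho.max() > 1.04 or rho.min() < 0.76:
                raise ValueError(
                    "compartment collision: coronary lesion strays off the epicardial shell"
                )
        lesion_truths.append(LesionTruth(
            les.artery,
            (np.concatenate(idx0), np.concatenate(idx1), np.concatenate(idx2)),
            per_slice, center))

    # --- noise ------------------------------------------------------------
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=shape)
    vol = np.clip(np.rint(vol), -1024, 4000).astype(np.int16)
    ct = CTVolume(vol, spacing)

    # --- truth masks and region labels ------------------------------------
    heart_mask = BinaryMask(heart, spacing)
    aorta_mask = BinaryMask(aorta, spacing)
    fat_mask = BinaryMask(shell & ~lesion_union, spacing)
    bone_mask = BinaryMask(bone_all, spacing)

    ref = spec.first_elliptical_slice
    loc = rs.localization_slice(ref, spec.split_offset_mm, s2)
    region = _truth_region_labels(spec, heart, aorta, loc)

    per_artery = {a: 0.0 for a in ARTERIES}
    exp_aorta = 0.0
    for lt in lesion_truths:
        score = sum(r.area_mm2 * density_coefficient(r.max_hu) for r in lt.per_slice)
        if lt.artery == "AORTA":
            exp_aorta += score
        else:
            per_artery[lt.artery] += score
    total = sum(per_artery.values())

    truth = PhantomTruth(
        heart=heart_mask, aorta=aorta_mask, fat=fat_mask, bone=bone_mask,
        region_labels=region, reference_slice=ref, localization_slice=loc,
        lesions=lesion_truths, expected_per_artery=per_artery,
        expected_aorta=exp_aorta, expected_total=total,
        expected_category=categorize(total), spacing=spacing)
    return ct, truth


def _truth_region_labels(spec: PhantomSpec, heart: np.ndarray, aorta: np.ndarray,
                         loc: int) -> np.ndarray:
    """Sector labels from the *true* geometric centers (no mask estimation)."""
    s0, s1, _ = spec.spacing
    hc = spec.heart_center_mm
    axis = (hc[0] - spec.aorta_center_mm[0], hc[1] - spec.aorta_center_mm[1])
    labels = np.zeros(spec.shape, dtype=np.int8)
    for k in range(max(loc, 0), spec.shape[2]):
        sel = heart[:, :, k]
        if not sel.any():
            continue
        ii, jj = np.nonzero(sel)
        theta = rs.signed_angle_deg(ii * s0 - hc[0], jj * s1 - hc[1], axis)
        labels[ii, jj, k] = rs.sector_label(theta, spec.sectors)
    labels[aorta] = rs.AORTA
    return labels


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def expected_agatston(truth: PhantomTruth) -> dict[str, float]:
    """Per-region expected Agatston scores from the rasterized truth.

    Sums, per lesion and slice, pixel-count x pixel-area x density
    coefficient of the controlled per-slice maximum. The coronary total
    excludes the aorta.
    """
    out = {a: 0.0 for a in REGIONS}
    for lt in truth.lesions:
        out[lt.artery] += sum(r.area_mm2 * density_coefficient(r.max_hu)
                              for r in lt.per_slice)
    out["TOTAL"] = out["RCA"] + out["LAD"] + out["LCX"]
    return out


def spec_level_agatston(spec: PhantomSpec) -> dict[str, float]:
    """Idealized scores straight from the spec (nominal areas, no grid)."""
    out = {a: 0.0 for a in REGIONS}
    for les in spec.lesions:
        for k in les.slice_range:
            hu = les.peak_hu if k == les.center_slice else les.plateau_hu
            out[les.artery] += les.area_mm2 * density_coefficient(hu)
    out["TOTAL"] = out["RCA"] + out["LAD"] + out["LCX"]
    return out


# ---------------------------------------------------------------------------
# randomized specs (seeded) for batch studies
# ---------------------------------------------------------------------------

def heart_aorta_clear(spec: PhantomSpec, margin_mm: float = 3.0) -> bool:
    """Analytic check that heart and aorta keep a surface gap on every slice.

    Conservative: compares center distance against the sum of the bounding
    radii of both cross-sections plus the margin.
    """
    hc = spec.heart_center_mm
    sa, sb, sc_ = spec.heart_semiaxes_mm
    ac = spec.aorta_center_mm
    a_r = max(spec.aorta_radius_mm, *spec.aorta_ellipse_semiaxes_mm)
    d = math.hypot(hc[0] - ac[0], hc[1] - ac[1])
    for k in range(0, spec.aorta_last_slice + 1):
        dz = k * spec.spacing[2] - hc[2]
        if abs(dz) >= sc_:
            continue
        scale = math.sqrt(1.0 - (dz / sc_) ** 2)
        if d < scale * max(sa, sb) + a_r + margin_mm:
            return False
    return True


def random_phantom_spec(seed: int, with_calcium: bool = True,
                        noise_sd: float = 0.0) -> PhantomSpec:
    """A jittered phantom spec; geometry varies, the invariants hold.

    Every generated lesion has at least 4 voxels per slice (area >= 4 mm^2 at
    the default 0.7 mm pixels) and peak >= 200 HU, so the cascade's
    sensitivity floor applies to every one of them. Geometry is redrawn
    (deterministically, from the same seeded stream) until the heart keeps a
    clear surface gap from the aorta.
    """
    rng = np.random.default_rng(int(seed))
    for _ in range(100):
        fe = int(rng.integers(10, 15))
        spec = PhantomSpec(
            heart_center_mm=(82.6 + rng.uniform(-4, 4),
                             91.0 + rng.uniform(0, 4),
                             rng.uniform(92, 98)),
            heart_semiaxes_mm=(rng.uniform(36, 40), rng.uniform(32, 36),
                               rng.uniform(32, 36)),
            aorta_center_mm=(120.0 + rng.uniform(-3, 3), 55.0 + rng.uniform(0, 3)),
            fat_thickness_mm=float(rng.uniform(3.5, 4.5)),
            first_elliptical_slice=fe,
            first_semi_elliptical_slice=fe + 6,
            aorta_last_slice=fe + 11,
            noise_sd=noise_sd,
            seed=int(seed),
        )
        if heart_aorta_clear(spec):
            break
    else:
        raise RuntimeError("could not draw a collision-free phantom geometry")

    if with_calcium:
        n = int(rng.integers(1, 5))
        arteries = list(rng.permutation(ARTERIES))[: min(n, 3)]
        if n == 4:
            arteries.append("AORTA")
        for artery in arteries:
            # distinct arteries sit at angles >= 60 deg apart, so lesions never
            # collide in-plane even when they share slices
            if artery == "AORTA":
                cs = fe + int(rng.integers(1, 5))
                area = float(rng.uniform(4, 12))
                nsl = 1
            else:
                cs = int(rng.integers(35, 41))
                area = float(rng.uniform(4, 16))
                nsl = int(rng.integers(1, 3))
            peak = float(rng.uniform(210, 900))
            plateau = float(rng.uniform(200, min(peak, 380)))
            angle = None
            if artery in CANONICAL_ANGLES:
                angle = CANONICAL_ANGLES[artery] + float(rng.uniform(-20, 20))
            spec.lesions.append(LesionSpec(artery, area_mm2=area, peak_hu=peak,
                                           plateau_hu=plateau, center_slice=cs,
                                           n_slices=nsl, angle_deg=angle))
    return spec
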