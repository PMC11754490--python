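# Methods

`chestcac` implements a fully automated coronary-artery-calcium (CAC)
pipeline for non-ECG-gated chest CT: multi-organ mask post-processing,
coronary-territory localization, a calcium-candidate filter cascade,
Agatston scoring with CAC-DRS risk categorization, a synthetic phantom
generator with analytic ground truth, and the diagnostic-agreement
statistics used to validate such pipelines against a human reference.

## The scoring model

Calcium is any voxel at or above 130 HU (inclusive — the standard Agatston
convention; some descriptions write the threshold as strictly greater, but
the 130 HU voxel itself is conventionally calcium). The Agatston score of a
2D connected component on one axial slice is its area in mm² times an
integer density coefficient set by the component's peak attenuation:

| peak HU        | coefficient |
|----------------|-------------|
| [130, 200)     | 1           |
| [200, 300)     | 2           |
| [300, 400)     | 3           |
| [400, ∞)       | 4           |

Bins are half-open: a printed boundary such as 200 HU belongs to the higher
bin. The maximum is taken per *slice component* (classic Agatston), not per
3D lesion; a configuration switch (`per-lesion` maximum) exists but is not
the default. Per-vessel scores (RCA, LAD, LCX) are sums over slice
components; the total is their sum. Aortic calcium is scored identically
but reported separately and never enters the coronary total. No
slice-thickness renormalization is applied: scores computed on 1.0–2.5 mm
chest reconstructions are reported as-is rather than rescaled to the 3 mm
gated convention, and no minimum-area floor is imposed beyond the noise
cascade. CAC-DRS grades follow 0 / 1–100 / 101–400 / 401–1000 / >1000
(total rounded to the nearest integer before binning).

## Pipeline stages and their assumptions

**Grid conventions.** Volumes are `(i, j, k)` HU grids with axial slices
along the last axis and slice 0 most superior (the region split iterates
craniocaudally). Masks live on the standardized grid; all morphology happens
after standardization so masks are never resampled. In-plane standardization
(`standardize_grid`) conserves physical extent exactly
(`dim × spacing` constant) and interpolates HU linearly (nearest for
masks). The shipped default keeps the native grid; resampling to 512² is
opt-in for heterogeneous clinical series.

**Smoothing.** Denoising is per-slice Perona–Malik diffusion with
exponential conductance `exp(-(|∇I|/K)²)`, `K = 30` HU, step 0.2, 5
iterations. Slice thickness is several times the pixel size in this data,
so diffusion is strictly 2D. With a step ≤ 0.25 each update is a convex
combination of the 4-neighborhood, so no new extrema appear. Two properties
matter downstream: a ≥ 90 HU edge is essentially frozen (organ boundaries
and calcium survive), and — a textbook Perona–Malik property — single-voxel
impulse noise is *also* preserved, because an impulse has an even larger
gradient than an edge of the same amplitude. Impulse specks are therefore
the job of the cascade's morphological opening, not the diffusion.
Critically, the smoothed volume feeds only the segmentation stage:
thresholding, areas and per-slice maxima are always measured on the raw
standardized HU values, because diffusion would otherwise drag controlled
peak values across density-coefficient bins and break the phantom's
analytic oracle (and the reference standard thresholds original images).

**Organ masks.** Any backend that produces heart + aorta masks can drive
the pipeline; masks from an external model are injected from NIfTI files
and the downstream result is bitwise identical to in-process masks. The
built-in reference backend is density/geometry only and is scoped to
phantom-like data: the thoracic cavity is the largest enclosed low-HU
component; the heart core is the largest soft-tissue-window component
inside it, closed and grown 6 mm into adjacent non-aerated tissue so the
epicardial fat envelope and surface calcium belong to the heart mask; the
aorta is the largest blood-pool-window component (the phantom gives aortic
blood 90 HU versus 45 HU myocardium precisely so a density window can
separate the two organs without a trained network — a deliberate
phantom-scope simplification). Epicardial fat is the adipose window
([−190, −30] HU, the literature-standard range) inside a 10 mm shell
straddling the heart boundary; an empty fat mask is legal.

**Coronary territories.** Axially the ascending aorta reads circular →
elliptical → semi-elliptical → absent. Slices classify by fitted-ellipse
axis ratio (≥ 1.25 ⇒ elongated) and solidity (< 0.9 ⇒ degraded /
semi-elliptical); the first elliptical slice from the top is the reference,
and the localization slice sits `ceil(10 mm / slice spacing)` further down.
If no elliptical slice exists the maximum-area aorta slice is used and the
run is flagged rather than aborted — shape-classifier noise should not
forfeit a score. The coronary corridor is a morphological closing (dilate
8 mm, erode 4 mm) of the fat mask: the arteries run in the sub-fat groove,
and with erode ≤ dilate the corridor provably contains the fat mask. The
heart split itself is an angular-sector rule — no published geometric rule
exists for it, so this realization was chosen to be deterministic,
orientation-aware and consistent with standard territory laterality:
corridor voxels inside the heart, on slices at or below the localization
slice, are labeled by their angle around the per-slice heart centroid,
measured from the aorta-to-heart-centroid axis; defaults RCA [−100°, 80°),
LAD [80°, 200°), LCX the remainder. Aorta voxels are AORTA on every slice
and are never relabeled; slices above the localization slice carry only the
AORTA label. The left main is not a separate region — its calcium falls
into the LAD/LCX sectors (documented limitation). Labels are a partition,
and because the axis is built from mask centroids the map is equivariant
under in-plane translation.

**Calcium cascade.** Candidates (≥ 130 HU) pass, in order: a per-slice
opening with a 2×2 square structuring element (removes isolated voxels and
one-pixel filaments; a radius-1 cross or 3×3 square would annihilate
legitimate 2×2-per-slice lesions, which must survive); removal of 3D
components that are both smaller than 3 voxels *and* fainter than 160 HU
peak (the small-and-faint reading; removing small *or* faint would delete
real low-density lesions — configurable); bone elimination, where
components above 10,000 voxels are dilated by 3 voxels in 3D so satellite
bone flecks merge into them and the merged groups are removed together;
component recovery, restoring in full every candidate component that still
has a surviving voxel (the opening may have eaten lesion rims) while
fully-removed components stay out; and finally gating to the cardiac mask.
The gate is heart ∪ aorta: a heart-only gate would contradict scoring the
ascending aorta, which the report keeps as a separate line. Each surviving
3D component is attributed to the territory holding the majority of its
voxels (ties: overlap count, then the fixed order RCA < LAD < LCX < AORTA
for deterministic reruns); components with no territory overlap are flagged
and excluded from every total rather than guessed.

## The phantom and what passing proves

The generator rasterizes HU compartments — air (−1000), chest-wall soft
tissue (30), lung (−800), myocardium/blood pool (45), a 4 mm epicardial-fat
shell (−100), aortic blood (90), cortical spine plus rib flecks (1000/900)
— and calcium lesions with prescribed per-slice area, plateau HU, and a
single controlled peak voxel, placed on the epicardial shell at
per-territory angles (or inside the aortic lumen). Default grid 256×256×60
at (0.7, 0.7, 2.5) mm — compact enough for batch studies; the geometry is
specified in mm, so a 512² in-plane grid is a spacing change. Compartment
collisions are errors naming the offending pair; generation is
deterministic given the spec (including the noise seed). The aorta's
axial-shape schedule is a spec field, so the reference slice has a known
answer; "semi-elliptical" sections are rasterized as notched ellipses so
their solidity genuinely drops below the classifier cutoff. Because lesion
geometry and intensities are known, per-artery Agatston scores follow
analytically (pixel count × pixel area × coefficient of the controlled
per-slice maximum), and a brute-force per-voxel walk over the rasterized
volume reproduces them exactly on noise-free phantoms — the oracle the
end-to-end tests compare against, to within one pixel-area per slice
component of rasterization tolerance.

What the phantom does *not* emulate: beam hardening, reconstruction
kernels, cardiac motion, partial-volume fading at lesion rims, anatomical
variability beyond ellipsoid jitter. Passing the oracle tests therefore
shows the *processing chain* is faithful (filters keep what they should,
remove what they should, and the arithmetic is right); it does not certify
detection performance on clinical CT, where segmentation quality and
motion artifacts dominate.

## Evaluation statistics

Mask agreement is Dice (defined 1.0 for two empty masks). Risk-grade
agreement uses the 5×5 confusion matrix (rows = reference), unweighted
Cohen's kappa — unweighted because that is the convention for this
validation task, despite ordinal grades; a linear-weighted variant exists
but is not the default — with the asymptotic Fleiss–Cohen–Everitt standard
error for the 95% CI (verified against an independent implementation to
1e-12; a seeded 2,000-resample bootstrap is available as a cross-check),
per-grade one-vs-rest sensitivity/specificity/PPV/NPV/F1, agreement
fractions (exact, within one category, beyond one, over- and
under-estimated — the first three partition unity), and presence/absence
diagnostics binarized at total > 0. Zero-denominator ratios surface as NaN
("not available"), never as 0. Degenerate kappa (single-category
marginals) is reported as absent with a note instead of raising inside
cohort evaluation.

## Numerical and batch-size choices

Oracle and cascade guarantees are exercised on 20 seeded randomized
phantoms; presence/absence runs a 50-phantom noise-free batch (25 with
calcium, 25 without) plus 25 calcium-free phantoms at σ = 20 HU additive
noise — sizes chosen to exercise every code path and jitter range while
keeping a full test run to a few minutes on one core. Randomized geometry
is redrawn (deterministically, from the same seeded stream) until the heart
keeps a ≥ 3 mm analytic clearance from the aorta, and every generated
lesion has ≥ 4 voxels per slice and peak ≥ 200 HU so the cascade's
sensitivity floor applies to all of them. DICOM slice ordering uses patient
+z (superior first) and demands consistent inter-slice steps; NIfTI pixdims
are rounded to six decimals to absorb float32 header precision. Euclidean
dilations/erosions use exact distance transforms with anisotropic sampling,
cropped to bounding boxes for speed.

## Known limitations

* The reference segmentation backend is phantom-grade by construction; on
  clinical CT an external model's masks should be injected.
* LMCA calcium is attributed to LAD/LCX sectors.
* Scores on thin-slice chest reconstructions are not rescaled to the gated
  3 mm convention; absolute values are not interchangeable with dedicated
  calcium-scoring CT.
* Motion-artifact handling is out of scope; on real non-gated data motion
  is a dominant error source.
* Slices above the localization slice contribute no coronary labels; very
  superior coronary calcium (rare) would be unattributed.
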