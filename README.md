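# chestcac

Automated coronary-artery-calcium (CAC) detection, Agatston quantification
and CAC-DRS risk categorization for **non-ECG-gated chest CT**.

Millions of chest CTs are acquired every year for lung-cancer screening and
other indications; the coronary arteries are always in the field of view,
yet calcium — an independent predictor of cardiovascular events — is
routinely left unreported because manual scoring on non-gated scans is slow
and reader-dependent. `chestcac` implements the full automated pipeline for
this task: multi-organ mask handling (with a pluggable segmentation
backend, so any trained model's masks can be injected), coronary-territory
localization from the epicardial fat and the aorta's axial shape
progression, a noise/bone-robust calcium filter cascade, per-vessel
Agatston scoring, and the agreement statistics (Cohen's κ, per-category
diagnostics, presence/absence sensitivity/specificity) used to validate
such pipelines against a human reference. A synthetic chest-phantom
generator with *analytic* ground-truth scores serves as the test substrate.

## The score

For each 2D connected calcium component on an axial slice,

    AS = area [mm²] × w(peak HU),   w: [130,200)→1, [200,300)→2, [300,400)→3, [400,∞)→4

summed over slices and vessels (RCA, LAD, LCX; aortic calcium is scored but
reported separately). The total maps to CAC-DRS grades
0 / I (1–100) / II (101–400) / III (401–1000) / IV (>1000).

## Worked example

```python
import chestcac as cc
from chestcac import phantom as ph

vol, truth = ph.generate_phantom(ph.PhantomSpec.default())
result = cc.run_volume(vol)
print(result.report.to_dict())
```

Running `python examples/01_phantom_and_score.py` prints:

```
phantom: 256x256x60 voxels at (0.7, 0.7, 2.5) mm, 3 lesions
  region   measured   expected
     RCA      82.32      82.32
     LAD      82.32      82.32
     LCX      49.00      49.00
   AORTA       0.00       0.00   (excluded from total)
   total     213.64     213.64
CAC-DRS category: II (expected II)
```

The phantom places one lesion per coronary territory with known per-slice
areas and controlled peak intensities, so its per-artery scores are exact
analytic quantities; the pipeline recovers them from the HU volume alone —
organ segmentation, territory split, filter cascade and scoring all have to
be right for the measured column to match. `examples/02_masks_and_regions.py`
shows the intermediate stages (organ-mask Dice, the circular → elliptical →
semi-elliptical aorta progression that anchors the territory split), and
`examples/03_cohort_evaluation.py` runs a small phantom cohort through the
agreement statistics.

A thin CLI wraps the same library calls:

```bash
chestcac phantom --out-dir /tmp/ph --seed 0
chestcac score /tmp/ph/phantom.nii.gz --out-dir /tmp/run
chestcac evaluate pairs.csv --out report.json
chestcac masks volume.nii.gz --out-dir /tmp/masks   # segmentation only
```

`score` accepts DICOM series directories or NIfTI volumes, and
`--heart-mask/--aorta-mask/--fat-mask` inject masks from any external
segmentation model.

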