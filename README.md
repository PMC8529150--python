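# elvarkit

Quantitative chest-CT analysis of interstitial lung disease (ILD):
ILD-robust lung field segmentation, curvature-based enhancement of the
lung interstitium, and the **effective lung ventilation area ratio**

```
ELVAR = (L − I) / L
```

where **L** is the number of lung voxels and **I** the number of
interstitial voxels.  ELVAR is a unitless fraction in [0, 1]: healthy
lungs score high (vessels and normal interstitium keep it below 1), and
the value falls as reticulation, septal thickening, ground-glass opacity
and consolidation occupy the lung.  The package is aimed at researchers
who need a transparent, fully classical (non-learned) pipeline for
quantifying interstitial extent on thin-slice CT, plus the ROC/Kaplan-Meier
machinery to evaluate such an index against outcomes.

## What is inside

| module | role |
| --- | --- |
| `elvarkit.image_io` | DICOM-series / NIfTI reading with Hounsfield calibration, mask I/O |
| `elvarkit.lung_segmentation` | four-stage segmentation: HU thresholding → Laplacian zero-crossing contours → contour filling → organ-hole elimination → contour shrinkage |
| `elvarkit.interstitial_enhancement` | multi-scale Hessian curvature scores + dense-disease fallback; counts I |
| `elvarkit.elvar_metrics` | whole-volume and per-slice ELVAR, CSV/JSON reports |
| `elvarkit.phantom_sim` | digital thorax phantoms with ground-truth masks; synthetic survival cohorts |
| `elvarkit.cohort_stats` | ROC with Youden-optimal cutoff, Kaplan-Meier stratification |

The segmentation is designed so that dense disease is **not** carved out
of the lung: plain thresholding loses consolidated regions, which would
silently inflate ELVAR exactly in the sickest lungs.  Filling the
Laplacian zero-crossing contour recovers dense structures, a 3-D
organ-connectivity test removes adjacent-organ "holes" near the diaphragm
without removing air-surrounded consolidation, and the contour is shrunk
back onto the zero-crossing edge.

No clinical data ship with (or are needed by) the package: everything is
validated on procedurally generated thoracic phantoms whose true lung and
interstitium masks are known exactly.

## Worked example

```bash
# a healthy phantom and one with a 20% interstitial burden
elvarkit phantom --seed 11 --out-dir phantom_healthy
printf 'disease:\n  target_fraction: 0.20\n' > ild.yaml
elvarkit phantom --spec ild.yaml --seed 11 --out-dir phantom_ild

# full pipeline: segment -> enhance -> ELVAR
elvarkit elvar phantom_healthy/volume.nii.gz --out healthy.csv
elvarkit elvar phantom_ild/volume.nii.gz --out ild.csv

# a synthetic two-group cohort, ROC cutoff and KM stratification
elvarkit cohort --seed 3 --out cohort.csv
elvarkit stratify cohort.csv --out-dir strat
```

prints

```
phantom seed 11: true ELVAR = 0.9877 -> phantom_healthy
phantom seed 11: true ELVAR = 0.7977 -> phantom_ild
ELVAR = 0.9865 (L = 82274, I = 1112) -> healthy.csv, healthy.json
ELVAR = 0.7968 (L = 82282, I = 16720) -> ild.csv, ild.json
56 subjects -> cohort.csv
AUC = 0.762, cutoff = 0.8059; 3-month mortality below/above = 63.2% / 13.5%
```

Reading this: the healthy phantom's measured ELVAR (0.9865) recovers its
ground truth (0.9877) to three decimals — the small I (1112 voxels) is
the vessel tree, which counts as interstitial compartment by convention.
Painting a 20% disease burden into the *same* phantom drops the measured
ELVAR to 0.7968 (truth 0.7977) while L stays essentially unchanged —
i.e. the segmentation did not lose the diseased tissue; the enhancement
stage found it.  The cohort commands pick an ELVAR cutoff by Youden
index and show the expected mortality split between the strata.

The same flow in Python:

```python
from elvarkit import (PhantomSpec, DiseaseSpec, generate_phantom,
                      segment_lungs, enhance_interstitium, compute_elvar)

vol, truth = generate_phantom(PhantomSpec(seed=11,
                                          disease=DiseaseSpec(target_fraction=0.2)))
seg = segment_lungs(vol)                 # seg.L = lung voxel count
imap = enhance_interstitium(vol, seg)    # imap.I = interstitial voxel count
res = compute_elvar(seg, imap)           # res.elvar, res.per_slice, ...
print(f"{res.elvar:.4f} vs truth {truth.true_elvar:.4f}")
```

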