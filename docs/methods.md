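# Methods

This note documents the models, algorithms and numerical choices behind
elvarkit, in the order the pipeline runs them.

## Data model and conventions

Volumes are 3-D arrays in `(slice, row, col)` order, slice axis
cranio-caudal, with spacing in mm per axis.  All intensities inside the
pipeline are Hounsfield units (HU), applied exactly once at load time
(`stored * slope + intercept` for DICOM; NIfTI input is assumed already
calibrated, a documented contract).  Display windowing is a rendering
concern only.  Masks live on the exact lattice of their source volume;
no resampling happens implicitly.  DICOM series are sorted by physical
slice position (never by filename), mixed series are rejected, and
inter-slice gaps larger than twice the modal spacing are rejected rather
than interpolated.

## Lung segmentation

The goal is a lung mask that *keeps dense disease inside the lung*.  A
plain HU threshold is biased in exactly the wrong direction: the more
consolidation a lung contains, the more of it the threshold removes, and
the higher (healthier) the resulting ventilation ratio looks.  The
pipeline therefore recovers the lung's outer contour and fills it.

1. **Coarse segmentation.**  Voxels below `air_threshold_hu` (default
   −500 HU, the conventional divide between aerated lung ≈ −850 HU and
   soft tissue ≈ +40 HU) are air candidates.  3-D connected components
   touching the image border (ambient air) are discarded; when
   `exclude_airways` is set, a component reaching the topmost 10 % of
   slices with in-plane centroid in the central third of both extents is
   taken to be the trachea and removed; components smaller than
   `min_lung_component_mm3` (default 10 000 mm³) are dropped.
2. **Contour detection and filling.**  Per slice, the binary mask
   indicator is smoothed with an isotropic Gaussian (`gaussian_sigma_mm`,
   default 1 mm, converted to voxels per axis, truncated at 4 σ) and a
   3×3 Laplacian is applied.  A voxel is a *zero crossing* when its
   Laplacian changes sign strictly against an in-plane face neighbour;
   both voxels of each crossing pair are marked.  The pair member with
   the higher smoothed value is assigned to the **inner** (object-side)
   boundary, the other to the **outer** boundary; exact ties go to the
   negative-Laplacian side, and a voxel claimed by both roles counts as
   inner.  This pairwise assignment is what keeps each boundary a closed
   single-voxel chain — assigning sides by an absolute 0.5 level (or
   marking only the side closer to zero) fragments the chains wherever a
   second structure distorts the smoothed field, and a fragmented outer
   contour cannot be filled.  The interior of the outer boundary is then
   filled per slice (4-connected background flood fill, so an
   8-connected chain is tight); open fragments enclose nothing.
3. **Hole elimination.**  Near the diaphragm, adjacent organs (heart,
   liver, stomach) bulge into the lung silhouette and appear as dense
   regions *enclosed* by the lung contour on axial slices.  Candidates
   are the dense voxels inside the filled contour (`filled \ coarse`).
   Region growing from the lateral background first removes candidates
   touching the contour exterior on their slice (the chest-wall rim).  A
   remaining enclosed component is classified as a *mask hole* only when
   it is (a) connected in 3-D, through the dense tissue space, to tissue
   outside the contour — i.e. it is an organ reaching in, not an island —
   and (b) at least `hole_min_volume_mm3` (default 500 mm³).  Enclosed
   dense structures surrounded by lung air in 3-D (blood vessels,
   consolidated disease) are preserved regardless of size.  A pure
   size-threshold rule was rejected because it removes large
   consolidation, defeating the purpose of the contour-filling stage.
4. **Contour shrinkage.**  The filled contour is one voxel too generous
   (it includes the outer boundary chain).  The mask is eroded one
   in-plane 4-connected layer per iteration; boundary voxels lying on
   the stopping set freeze in place, so the mask never grows and
   erosion cannot pass a closed frozen chain.  The stopping set is the
   inner boundary by default (`shrink_stop_on`): stopping on the full
   zero-crossing set would be a no-op, since the filled contour's edge
   *is* the outer zero-crossing chain.  The iteration cap (128) exceeds
   any in-plane radius because thin diagonal slivers erode only one
   voxel per pass; non-convergence is reported as a diagnostic, not an
   error.  The final mask's voxel count is **L**.

All stages are deterministic; intermediates are retained for audit.

## Interstitial enhancement

Interstitial structures are distinguished by the *direction* of their
intensity curvature: septa and reticulation are sheet-like (one dominant
second-derivative eigenvalue), vessels tubular (two dominant), aerated
parenchyma flat.  For each scale in `scales_mm` (default 0.7, 1.4,
2.8 mm, spanning septal to vessel calibre) the Hessian of the
scale-smoothed HU field is computed in physical units (so anisotropic
spacing is handled) with γ-normalisation (×σ²).  With eigenvalues sorted
by magnitude |λ₁| ≤ |λ₂| ≤ |λ₃|, bright-structure responses are

- sheet: |λ₃| · exp(−(λ₂/λ₃)² / 2α²) for λ₃ < 0,
- tube: |λ₂| · exp(−(λ₁/λ₂)² / 2α²) for λ₂, λ₃ < 0 (only when
  `include_vessels_in_I`),

with α = 0.35; the per-voxel score is the maximum over scales and
branches, max-normalised per volume to [0, 1] so the threshold
(`sheetness_threshold`, default 0.35) transfers across acquisitions.
Outside the lung the HU field is replaced by the in-lung median before
filtering, so the pleural density step does not bleed edge response into
the lung rim.

Curvature alone misses the flat interiors of consolidation and ground
glass, so any in-lung voxel at or above `density_floor_hu` (default
−700 HU; aerated lung sits ~7 σ of typical noise below it) is also
marked.  Components smaller than `min_component_voxels` (3) are
discarded as noise.  The count of the resulting mask is **I**; by
construction the mask is inside the lung, hence 0 ≤ I ≤ L.

Vessels count toward I by default.  This is a declared convention (and
switchable): normal high-density structures are part of the
non-ventilated compartment, which is why even healthy lungs score below
1 — in our phantoms about 0.985 rather than 1.0.

## ELVAR

`compute_elvar` returns (L − I)/L from the **global** counts — not a
mean of per-slice ratios — along with per-slice values (undefined on
slices without lung).  An empty lung yields an explicit undefined
marker, never NaN.  Reports round to 4 decimals; fingerprints of all
parameters make rows traceable.

## The phantom generator

The phantom emulates the features the pipeline must cope with, at
desk-scale resolution (default 40×128×128 voxels at 1 mm³):

- an elliptical soft-tissue body (+40 HU) in ambient air (−1000 HU);
- two ellipsoidal air-filled lungs (−850 HU) with ≥ 4 voxels of chest
  wall everywhere (thinner walls let lung air connect to ambient air
  under the coarse threshold);
- a connected, tapering vessel tree per lung (+50 HU, radii 1–1.8 mm)
  grown from a hilum-side root;
- disease painted as a mix of 1-voxel-thick septal sheets (−300 HU),
  ground-glass blobs (−600 HU) and consolidation blobs (+20 HU) — HU
  values inside conventional radiological ranges — added element by
  element, shrinking elements near the target, until the burden fraction
  is within ±0.01 of `target_fraction`; lesion centres are confined to
  the outer lung shell when `peripheral_bias` is set (subpleural
  predominance);
- optionally a hemispheric organ bulge at the base of one lung whose
  in-lung cap volume is bisected to `volume_mm3`: enclosed on axial
  slices, organ-connected in 3-D — the "mask hole" geometry;
- Gaussian HU noise (default σ = 20 HU) added last; truth masks are
  recorded pre-noise.

Vessels and lesions keep a 2-voxel standoff from the pleural and organ
surfaces so dense structures do not merge with extra-pulmonary tissue;
truth I counts disease plus vessels iff the analysis convention does.
All randomness flows through `numpy.random.default_rng(seed)` (PCG64),
making phantoms bit-reproducible across platforms.

**What the phantom does not emulate** — and hence what passing tests do
not show about clinical data: partial-volume edges (boundaries are
sharp), reconstruction-kernel texture and streak artifacts, airway trees
beyond the trachea heuristic, honeycombing's cystic micro-structure,
cardiac/respiratory motion, and vendor dialect differences.  Accuracy
figures on phantoms are upper bounds, not clinical claims.

## Cohort statistics

`roc_analysis` builds the empirical ROC over midpoints between
consecutive distinct scores (plus sentinels), with an explicit score
direction — for ELVAR, *low* values indicate the positive (death)
class.  AUC is trapezoidal; the best cutoff maximises Youden's J with a
deterministic tie-break (higher specificity, then lower cutoff).
`km_stratify` splits a cohort at a cutoff (below = high-risk stratum)
and fits the standard product-limit estimator per stratum (via
lifelines; an independent hand-worked-table test pins the estimator),
reporting curves, survival at 3 and 12 months, and raw mortality
proportions with a closed horizon boundary (event and time ≤ t).

The synthetic cohort draws ELVAR from clipped normals matched to each
group's median and IQR and event times from piecewise-constant hazards
(inverted cumulative hazard), censored at 12 months.  Defaults encode a
two-stratum structure — low-ELVAR: median 0.789, IQR 0.070, hazard
0.26/month for 3 months then 0; high-ELVAR: median 0.882, IQR 0.039,
hazard 0.034 then 0.004/month; 28 subjects per group — i.e. early
mortality concentrated in the low stratum (≈ 54 % by month 3, flat
thereafter) versus ≈ 10 % / 13 % at 3/12 months in the high stratum.

## Problem sizes and tolerances

Tests and the acceptance script run the full pipeline on 40×128×128
phantoms (L ≈ 80 000) across burdens 0–30 %, several seeds, with and
without the organ bulge; ELVAR recovery is asserted to ±0.05 although
measured errors are ≈ 0.005, and lung Dice floors are 0.95 (0.90 for
consolidation-heavy burdens ≥ 25 %).  Zero-crossing detection is pinned
to a brute-force per-pixel sign-scan oracle; the ROC cutoff to an
exhaustive midpoint scan; AUC to the probabilistic (Mann-Whitney)
implementation in scikit-learn.  Cohort-level quantities are averaged
over 20 replicate cohorts in the acceptance script to tame binomial
noise at n = 28 per group.

## Known limitations

- The trachea heuristic is geometric; unusual anatomy (or phantoms with
  central apical air structures) would need `exclude_airways=False`.
- Left and right lungs are not separated; ELVAR is whole-lung.
- The density fallback means vessels enter I even when the tubular
  curvature branch is disabled; disabling vessel counting entirely would
  require vessel-specific masking upstream.
- Per-pattern classification (reticulation vs GGO vs honeycombing) is
  out of scope: everything aggregates into one interstitial compartment.
- Non-contiguous scans are rejected, not interpolated.
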