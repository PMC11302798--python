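# Methods

## The problem this package addresses

When several readers or tools segment the same tumors, the usual way to ask
"how similar are these segmentations?" is geometric: the Dice similarity
coefficient (DSC), the surface Dice at a tolerance (sDSC), and the Hausdorff
distance (HD). These saturate quickly — two masks can overlap 90% by volume
and still enclose visibly different tissue — and DSC in particular cannot
distinguish a systematic bias (one tool always segments larger) from random
boundary noise. `radicc` implements the complementary, more sensitive view:
extract a standardized radiomics feature panel from every (tumor,
segmentation) pair, treat tumors as subjects and segmentations as raters,
and quantify agreement per feature with an absolute-agreement intraclass
correlation coefficient (ICC). Features whose ICC is low are precisely the
ones that respond to how a tumor was segmented; they expose differences the
geometric metrics compress into a narrow "everything above 0.8" band.

## Feature panel

Per (tumor, segmentation) the panel has 944 features:

* 14 shape descriptors of the resampled mask (mesh volume, voxel volume,
  surface area, surface/volume ratio, sphericity, 3-D and three 2-D maximum
  diameters, three PCA axis lengths, elongation, flatness);
* 93 intensity/texture features — 18 first-order statistics, 24 GLCM,
  16 GLRLM, 16 GLSZM, 14 GLDM and 5 NGTDM features — computed on each of
  10 image types: the resampled image, one Laplacian-of-Gaussian filtered
  image (sigma = 1 mm), and the eight sub-bands of a single-level
  undecimated 3-D wavelet transform (coif1 by default).

Formulas follow the public IBSI definitions in the variants popularized by
the PyRadiomics extractor (13-direction averaging for GLCM/GLRLM without
distance weighting, 26-connected zones/neighbourhoods, symmetrized GLCM).
Every texture feature and every geometric metric is pinned by an
independent exhaustive-enumeration oracle in the test suite at 1e-9
relative tolerance, so the formula variants are locked by construction,
not by documentation.

Preprocessing defaults: resample image and mask to 2 mm isotropic voxels
(image: cubic B-spline; mask: nearest-neighbour, re-binarized), then
discretize ROI intensities with a fixed bin width of 25 units anchored at
the ROI minimum (level 1 is always occupied; an `aligned` rule anchoring
edges at multiples of the width is available). Filtering happens after
resampling and every derived image shares the resampled grid, so feature
extraction never mixes grids. Note that sigma = 1 mm is under-resolved at
2 mm voxels; the package computes it (with a warning) because that is the
standard setting for this kind of CT analysis, but the LoG channel should
be read as a band-pass variant of the image rather than a faithful 1 mm
scale-space response.

### Numerical conventions

* Array axis `i` maps to physical axis `i`; a voxel center sits at
  `origin + index * spacing`. Oblique orientation matrices are rejected.
* All 1-D convolutions (LoG and wavelet) use mirror boundary handling and
  the kernel center `(len-1)//2`. The Gaussian second-derivative taps are
  normalized to sum exactly to zero, so a constant image has an exactly
  zero LoG and linear ramps a zero interior response.
* The wavelet transform is stationary (undecimated), i.e. a plain separable
  convolution with the decomposition filter pair; sub-band letter `i` names
  the filter applied along array axis `i`.
* Discretization: `level = floor((x - min) / W) + 1`; the level count `Ng`
  is the maximum level, so intermediate levels may be empty (they carry
  zero probability everywhere and are handled exactly).
* GLDM dependence count = 1 + number of 26-neighbours inside the ROI with
  `|level difference| <= alpha` (alpha = 0): the center voxel is always
  dependent on itself, so the count is at least 1 and the small-dependence
  emphases never divide by zero.
* Degenerate single-level ROIs: MCC = 1, cluster shade/prominence = 0,
  first-order entropy = 0, NGTDM complexity = 0; an eigenvalue floor of
  1e-12 keeps axis lengths of single-voxel masks finite.
* Mesh quantities come from marching cubes on the zero-padded mask at
  iso-level 0.5; rasterized sharp-edged solids therefore measure a few
  percent below their analytic area (documented tolerance in the tests).
  Diameters are measured between centers of boundary voxels (foreground
  voxels with a 6-connected background neighbour), accelerated through the
  convex hull, which is exact for a diameter.

## Geometric metrics

DSC is computed on foreground voxel sets. Surfaces for sDSC and HD are the
boundary-voxel centers defined above, with distances in physical mm via a
k-d tree; HD is the classical maximum (not a percentile), and the default
sDSC tolerance is 2 mm — one voxel at the resampled spacing — always
recorded alongside the value. Metrics are computed on the resampled grid,
consistent with feature extraction.

## Agreement model

For one feature, the complete n x k table (n tumors, k segmentations) is
decomposed by a two-way ANOVA into between-subject (MSR), between-rater
(MSC) and residual (MSE) mean squares, and the single-measure
absolute-agreement ICC — ICC(A,1) of McGraw & Wong (1996) — is

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).

The point estimate is identical under random- and mixed-rater assumptions;
only its interpretation differs. 95% bounds use the F-based interval with
Satterthwaite degrees of freedom evaluated at the point estimate. Negative
estimates are reported as computed — absolute agreement penalizes
systematic rater offsets, and that penalty is the point. A matrix with no
variance at all has no defined ICC and is returned as a flagged degenerate
result (the threshold absorbs the float dust a constant matrix leaves in
the sums of squares); a matrix with subject variance but numerically zero
rater and residual variance collapses to ICC = 1 with a degenerate [1, 1]
interval. The implementation is locked against an independently written
variance-components oracle (1e-8 on estimates and bounds over 500 random
matrices) and cross-checked against pingouin's ICC(A,1).

Two ICC views are computed per feature: ICC* (all k segmentations jointly,
one number per feature) and the 36 pairwise ICCs (n x 2 tables per
unordered segmentation pair), summarized by their mean and minimum.

## Analysis pipeline

`AgreementStudy.fit()` screens ICC* over the panel, keeps the features
inside a band (default [0.1, 0.51] — the low-reproducibility regime) and
selects the `n_select = 10` lowest; an explicit feature list can override
the rule. Features with degenerate ICC* are excluded and listed. The
selected features' pairwise ICCs fill k x k agreement maps (diagonal 1);
class discovery runs average-linkage hierarchical clustering on the
distance `1 - mean ICC` (mean across selected features; ICC floored at -1
so distances stay in [0, 2], missing cells fall back to the maximal
distance) and cuts at a requested class count. Averaging across selected
features is the minimal aggregation yielding one partition; per-feature
maps are also emitted. Rating against a reference segmentation tabulates
each candidate's pairwise ICCs against the reference over the selected
features and calls a candidate discordant when all of them (or, optionally,
their median) fall below a threshold of 0.5. The metric-comparison report
joins per-pair ICCs with tumor-averaged DSC/sDSC/HD — 36 rows per feature
— plus pooled files and range summaries; no multiple-testing adjustment is
applied anywhere because the analysis reports feature counts and ranges,
not hypothesis tests.

## Synthetic cohort generator

Real multi-institution segmentation data cannot ship with the package, so
the `phantoms` module generates the study design synthetically: 10 tumors,
each with 9 segmentations from 3 method families x 3 parameter settings.
A tumor is an ellipsoid (semi-axes drawn uniformly from 18–24 mm) on a
64^3 grid at 1 mm spacing, with a darker background (-800 HU-like), a
tumor/background contrast of 800, internal texture from Gaussian-filtered
white noise with a 3 mm correlation length and amplitude 60, and white
noise of sigma 10 everywhere. Families differ in *kind*, settings within a
family only in *level*, mirroring one tool run at three settings:

* family A — random boundary jitter: the mask's signed distance field is
  thresholded after adding a smooth random field (4 mm correlation length)
  scaled to sigma = 0.5 / 0.65 / 0.8 mm;
* family B — systematic dilation by 1.0 / 1.45 / 1.75 mm;
* family C — systematic erosion by 1.2 mm plus a rigid x-offset of
  0 / 1 / 2 mm.

Levels are deliberately placed to straddle the voxel distance quanta
(1, sqrt 2, sqrt 3, 2 mm at 1 mm spacing): sub-voxel level steps would
voxelize to identical masks. One random and two systematic families
exercise exactly the distinction absolute-agreement ICC is built to
detect. Generation checks that every within-tumor pairwise DSC exceeds
0.75 (the "all segmentations look geometrically fine" regime) and
regenerates a violating tumor with levels scaled down by 0.8, up to five
times. Everything derives from one top-level seed through hierarchical
sub-seeding per tumor/segmentation/retry, so cohorts are bit-reproducible.

What the phantom does *not* emulate: real CT noise texture and artifacts,
anatomical context (vessels, pleura), irregular tumor shapes, and human
contouring behaviour. Passing the synthetic acceptance checks therefore
shows that the pipeline detects the planted systematic/random structure
under realistic size and contrast scales — not that it reproduces any
specific clinical dataset's values.

## Problem sizes used by the shipped experiments

The acceptance experiments run the default design end to end: one 10 x 9
cohort at 64^3 / 1 mm for the fixed-seed analysis; 200 random micro-volumes
(side <= 6) for the enumeration-oracle equivalence; 500 random 10 x 9
matrices for the ICC oracle; and 100 replicate cohorts for the
class-recovery rate, re-extracting only the selected features per
replicate. The feature selection is held fixed across replicates: it
characterizes the study design rather than one noise realisation, and
re-screening all 944 features per replicate would multiply the cost of the
experiment roughly tenfold without changing what it demonstrates.

## Known limitations

* Only axis-aligned volumes are supported; DICOM series and RT-STRUCT
  conversion are out of scope (convert externally to NRRD/NIfTI).
* The 93-feature per-type membership follows the reference extractor's
  default-enabled set; other extractors enable slightly different sets and
  will not match feature-for-feature.
* HD is the maximum variant; 95th-percentile HD and average surface
  distance are not implemented.
* ICC confidence bounds assume the usual two-way ANOVA normality; for
  heavy-tailed feature distributions they are approximate.
* 2-D (per-slice) feature variants, gray-level normalization and
  fixed-bin-count discretization are intentionally not implemented.
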