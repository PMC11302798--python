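# radicc

**Radiomics-feature ICC analysis of tumor-segmentation agreement.**

When several physicians or auto-segmentation tools contour the same tumors,
the standard similarity metrics — Dice (DSC), surface Dice (sDSC) and
Hausdorff distance (HD) — often say "everything agrees": DSC above 0.8 for
every pair, sDSC above 0.7. Yet the segmentations can differ in ways that
matter. `radicc` implements the more sensitive, feature-based view of
segmentation agreement: it extracts a standardized 944-feature radiomics
panel (shape, intensity and texture on a filter bank of derived images)
from every (tumor, segmentation) pair and measures per-feature agreement
with the single-measure, absolute-agreement intraclass correlation
coefficient,

```
ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))
```

from the two-way tumors × segmentations ANOVA (MSR/MSC/MSE = between-tumor,
between-segmentation and residual mean squares; McGraw & Wong form, 95%
F-based confidence bounds, negative values reported unclamped). Features
with low ICC* are the ones sensitive to *how* a tumor was segmented; their
pairwise-ICC heat maps cluster segmentations into method families and rate
candidate methods against a gold standard — analyses the geometric metrics
cannot support, because they compress all pairs into a narrow band.

The package is aimed at medical-physics and image-analysis researchers
evaluating auto-segmentation tools or contouring skills. It ships a seeded
synthetic-cohort generator (textured ellipsoidal tumor phantoms with 9
segmentations from 3 perturbation families), so the entire pipeline runs
and is tested without any patient data.

## Worked example

```python
from radicc import AgreementStudy, PhantomSpec, make_cohort

cohort = make_cohort(PhantomSpec(seed=1))          # 10 tumors x 9 segmentations
result = AgreementStudy.from_cohort(cohort).fit()  # panel + metrics + ICCs
print(result.summary())
print(result.discover_classes(n_classes=3))
```

prints

```
Radiomics segmentation-agreement analysis
=========================================================
tumors: 10   segmentations: 9   features: 944
ICC model: A-1 two-way mixed, absolute agreement
ICC* range: [-0.044, 1.000]  (degenerate: 0)
screening band: [0.1, 0.51]  in band: 340   selected: 10

 image_type feature_class                        feature_name  icc_star  icc_average  icc_min  lower  upper
wavelet-HLL         glszm            LowGrayLevelZoneEmphasis     0.100        0.218   -0.173  0.003  0.366
wavelet-LLH         glrlm                          RunEntropy     0.101        0.303    0.034  0.025  0.315
wavelet-LLL          glcm                                 MCC     0.101        0.190   -0.438  0.016  0.340
wavelet-LHH    firstorder         RobustMeanAbsoluteDeviation     0.101        0.295    0.019  0.025  0.317
wavelet-HLL          gldm LargeDependenceLowGrayLevelEmphasis     0.101        0.222   -0.390  0.020  0.333
wavelet-HHL         glszm               SizeZoneNonUniformity     0.102        0.294    0.025  0.025  0.319
wavelet-LHH         glrlm                    ShortRunEmphasis     0.102        0.264    0.024  0.025  0.320
wavelet-LHH          gldm             SmallDependenceEmphasis     0.104        0.292    0.021  0.026  0.323
wavelet-HLH    firstorder                              Median     0.105        0.335    0.030  0.026  0.325
wavelet-LLH          glcm                  DifferenceVariance     0.106        0.273    0.032  0.026  0.330
{'A1': 2, 'A2': 2, 'A3': 2, 'B1': 3, 'B2': 3, 'B3': 3, 'C1': 1, 'C2': 1, 'C3': 1}
```

Reading this: every feature's ICC* is the agreement of all 9 segmentations
over the 10 tumors; the screen keeps features in the low-reproducibility
band [0.1, 0.51] and selects the 10 lowest — exactly the features that
react to segmentation differences. The `icc_min` column shows that some
segmentation pairs disagree outright (negative ICC) even though, on the
same cohort, every pairwise Dice exceeds 0.83. The partition at the bottom
recovers the three planted segmentation-method families (A = random
boundary jitter, B = systematic dilation, C = systematic erosion + offset)
purely from the feature-agreement maps.

The same analysis runs from the shell against any cohort described by a
manifest CSV (`tumor_id, image_path, segmentation_id, mask_path`, NRRD or
NIfTI volumes):

```bash
radicc simulate --seed 1 --out cohort/               # or bring your own data
radicc extract  --manifest cohort/manifest.csv --out features.csv
radicc metrics  --manifest cohort/manifest.csv --out metrics.csv
radicc report   --features features.csv --metrics metrics.csv \
                --reference A1 --out report/
```

`report/` then contains the ICC* screen, Table-style selected-feature
summaries, per-feature heat-map CSVs, the discovered classes, the
ICC-vs-DSC/sDSC/HD scatter tables and the reference-rating verdicts.

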