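"""First-order (intensity statistics) features of a region of interest.

Statistics are computed on the raw (possibly filtered) intensities of the
ROI voxels; Entropy and Uniformity use the fixed-bin-width histogram of the
discretized ROI.  Moments are population moments (no bias correction);
skewness and kurtosis of a constant ROI are defined as 0, and kurtosis is
not Fisher-corrected (a normal distribution scores 3).
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedROI

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def firstorder_features(droi: DiscretizedROI) -> dict[str, float]:
    x = droi.raw
    n = x.size
    mean = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    hist = droi.histogram()
    p = hist[hist > 0] / n
    if sd > 0:
        skew = ((x - mean) ** 3).mean() / sd ** 3
        kurt = ((x - mean) ** 4).mean() / var ** 2
    else:
        skew = kurt = 0.0
    energy = float((x ** 2).sum())
    feats = {
        "Energy": energy,
        "TotalEnergy": energy * float(np.prod(droi.spacing)),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float((p ** 2).sum()),
    }
    return feats
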