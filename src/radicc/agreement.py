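"""Intraclass correlation for segmentation agreement.

The engine implements the single-measure, absolute-agreement ICC of a
two-way subjects x raters layout — ICC(A,1) in the McGraw & Wong (1996)
taxonomy, equivalently ICC(2,1) of Shrout & Fleiss.  Subjects are tumors,
raters are segmentations.  The point estimate

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

uses the two-way ANOVA mean squares (MSR between subjects, MSC between
raters, MSE residual); it is identical under random- and mixed-rater
assumptions, which differ only in interpretation.  The 95% confidence
bounds use the F-based interval with Satterthwaite degrees of freedom
evaluated at the point estimate.  Negative estimates are reported as
computed, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MODEL_TAG = "A-1 two-way mixed, absolute agreement"


@dataclass(frozen=True)
class RatingMatrix:
    """Complete n subjects x k raters grid of real-valued ratings."""

    values: np.ndarray
    subjects: tuple[str, ...]
    raters: tuple[str, ...]

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2:
            raise ValueError("ratings must be a 2-D subjects x raters grid")
        n, k = vals.shape
        if n < 2 or k < 2:
            raise ValueError(f"need at least 2 subjects and 2 raters, got {n}x{k}")
        if not np.isfinite(vals).all():
            raise ValueError("ratings contain non-finite cells")
        if len(self.subjects) != n or len(self.raters) != k:
            raise ValueError("identifier counts do not match the grid shape")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "raters", tuple(self.raters))

    @classmethod
    def from_array(cls, values, subjects: Sequence[str] | None = None,
                   raters: Sequence[str] | None = None) -> "RatingMatrix":
        values = np.asarray(values, dtype=np.float64)
        n, k = values.shape
        return cls(values,
                   tuple(subjects) if subjects else tuple(f"s{i}" for i in range(n)),
                   tuple(raters) if raters else tuple(f"r{j}" for j in range(k)))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RatingMatrix":
        return cls(frame.to_numpy(dtype=np.float64),
                   tuple(map(str, frame.index)), tuple(map(str, frame.columns)))


@dataclass(frozen=True)
class AnovaMS:
    """Mean squares of the two-way subjects x raters decomposition."""

    msr: float      # between subjects (rows)
    msc: float      # between raters (columns)
    mse: float      # residual
    df_rows: int
    df_cols: int
    df_err: int


@dataclass(frozen=True)
class ICCResult:
    """Point estimate with 95% bounds and the underlying mean squares."""

    icc: float
    lower95: float
    upper95: float
    alpha: float
    n: int
    k: int
    anova: AnovaMS
    degenerate: bool = False
    model: str = MODEL_TAG

    def __repr__(self):
        if self.degenerate:
            return f"ICCResult(degenerate, n={self.n}, k={self.k})"
        return (f"ICCResult(icc={self.icc:.4f}, "
                f"95% CI [{self.lower95:.4f}, {self.upper95:.4f}], "
                f"n={self.n}, k={self.k})")


def two_way_anova(m: RatingMatrix) -> AnovaMS:
    """Closed-form mean squares of the complete two-way layout."""
    y = m.values
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    resid = y - row_means[:, None] - col_means[None, :] + grand
    ss_err = (resid ** 2).sum()
    return AnovaMS(msr=ss_rows / (n - 1), msc=ss_cols / (k - 1),
                   mse=ss_err / ((n - 1) * (k - 1)),
                   df_rows=n - 1, df_cols=k - 1, df_err=(n - 1) * (k - 1))


def icc_absolute_agreement(m: RatingMatrix, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1) with the McGraw-Wong F-based confidence interval.

    A matrix with no variance at all (all cells equal) has no defined ICC
    and returns a flagged degenerate result with NaN fields.
    """
    ms = two_way_anova(m)
    y = m.values
    n, k = y.shape
    # a constant matrix has no defined ICC; the threshold absorbs the
    # floating-point dust a constant leaves in the sums of squares
    total_ss = ((y - y.mean()) ** 2).sum()
    if total_ss <= n * k * (1e-10 * max(1.0, abs(y.mean()))) ** 2:
        return ICCResult(np.nan, np.nan, np.nan, alpha, n, k, ms, degenerate=True)

    denom = ms.msr + (k - 1) * ms.mse + (k / n) * (ms.msc - ms.mse)
    icc = (ms.msr - ms.mse) / denom

    if ms.msc + ms.mse <= 1e-12 * ms.msr:
        # perfect agreement: interval collapses
        return ICCResult(1.0, 1.0, 1.0, alpha, n, k, ms)

    # Satterthwaite df of the a*MSC + b*MSE combination, at the estimate
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isinf(a) or np.isinf(b):
        nu = np.inf
    else:
        num = (a * ms.msc + b * ms.mse) ** 2
        den = ((a * ms.msc) ** 2 / (k - 1)
               + (b * ms.mse) ** 2 / ((n - 1) * (k - 1)))
        nu = num / den if den > 0 else np.inf

    f_lo = stats.f.ppf(1.0 - alpha / 2.0, n - 1, nu)
    f_up = stats.f.ppf(1.0 - alpha / 2.0, nu, n - 1)
    lower = (n * (ms.msr - f_lo * ms.mse)
             / (f_lo * (k * ms.msc + (k * n - k - n) * ms.mse) + n * ms.msr))
    upper = (n * (f_up * ms.msr - ms.mse)
             / (k * ms.msc + (k * n - k - n) * ms.mse + n * f_up * ms.msr))
    return ICCResult(float(icc), float(lower), float(upper), alpha, n, k, ms)


# --------------------------------------------------------------------------
# Feature-table front ends


def icc_star(table, feature, alpha: float = 0.05) -> ICCResult:
    """The all-raters ICC of one feature: n tumors x k segmentations jointly."""
    frame = table.rating_matrix(feature)
    return icc_absolute_agreement(RatingMatrix.from_frame(frame), alpha)


def pairwise_icc(table, feature, alpha: float = 0.05
                 ) -> dict[tuple[str, str], ICCResult]:
    """ICC of every unordered segmentation pair (n x 2 matrices) for one
    feature; for k = 9 raters this yields 36 results."""
    frame = table.rating_matrix(feature)
    out = {}
    for i, j in combinations(frame.columns, 2):
        pair = frame[[i, j]]
        out[(str(i), str(j))] = icc_absolute_agreement(
            RatingMatrix.from_frame(pair), alpha)
    return out


def pairwise_icc_summary(results: dict[tuple[str, str], "ICCResult"]
                         ) -> tuple[float, float]:
    """(mean, min) of the pairwise ICC point estimates, ignoring degenerate."""
    vals = [r.icc for r in results.values() if not r.degenerate]
    if not vals:
        return np.nan, np.nan
    return float(np.mean(vals)), float(np.min(vals))
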