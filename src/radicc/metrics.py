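"""Pairwise segmentation similarity: Dice, surface Dice and Hausdorff.

Boundary surfaces are the sets of foreground voxels with at least one
6-connected background (or out-of-grid) neighbour; all distances are
Euclidean distances between voxel centers in physical millimetres.  The
Hausdorff distance is the classical maximum (not a percentile).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .features.shape import boundary_voxels
from .volumes import LabelMask, assert_aligned

#: default surface-Dice tolerance: one voxel at 2 mm resampled spacing
DEFAULT_SDSC_TOLERANCE_MM = 2.0


@dataclass(frozen=True)
class PairSimilarity:
    """Geometric similarity of one unordered segmentation pair on one tumor."""

    tumor_id: str
    pair: tuple[str, str]
    dsc: float
    sdsc: float
    hd_mm: float
    tolerance_mm: float

    def __post_init__(self):
        object.__setattr__(self, "pair", tuple(sorted(self.pair)))


def dice(a: LabelMask, b: LabelMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|)."""
    assert_aligned(a, b)
    fa, fb = a.astype_bool(), b.astype_bool()
    na, nb = int(fa.sum()), int(fb.sum())
    if na + nb == 0:
        raise ValueError("Dice is undefined for two empty masks")
    return 2.0 * int((fa & fb).sum()) / (na + nb)


def _surface_points(mask: LabelMask) -> np.ndarray:
    idx = np.argwhere(boundary_voxels(mask.astype_bool()))
    if len(idx) == 0:
        raise ValueError("mask has no boundary (empty mask)")
    return idx * np.asarray(mask.spacing)


def surface_dice(a: LabelMask, b: LabelMask,
                 tolerance_mm: float = DEFAULT_SDSC_TOLERANCE_MM) -> float:
    """Fraction of the two boundary surfaces within ``tolerance_mm`` of the
    other surface (symmetric)."""
    if tolerance_mm <= 0:
        raise ValueError("tolerance_mm must be positive")
    assert_aligned(a, b)
    sa, sb = _surface_points(a), _surface_points(b)
    da = cKDTree(sb).query(sa)[0]
    db = cKDTree(sa).query(sb)[0]
    return (int((da <= tolerance_mm).sum()) + int((db <= tolerance_mm).sum())) \
        / (len(sa) + len(sb))


def hausdorff(a: LabelMask, b: LabelMask) -> float:
    """Symmetric maximum Hausdorff distance between boundary voxel centers (mm)."""
    assert_aligned(a, b)
    sa, sb = _surface_points(a), _surface_points(b)
    da = cKDTree(sb).query(sa)[0]
    db = cKDTree(sa).query(sb)[0]
    return float(max(da.max(), db.max()))


def pairwise_metrics(masks: Mapping[str, LabelMask], tumor_id: str = "",
                     tolerance_mm: float = DEFAULT_SDSC_TOLERANCE_MM
                     ) -> list[PairSimilarity]:
    """All C(k,2) unordered pair similarities for one tumor's masks."""
    ids = list(masks)
    if len(ids) < 2:
        raise ValueError("need at least two segmentations to form pairs")
    out = []
    # precompute boundary trees once per mask
    points = {sid: _surface_points(m) for sid, m in masks.items()}
    trees = {sid: cKDTree(p) for sid, p in points.items()}
    for i, j in combinations(ids, 2):
        assert_aligned(masks[i], masks[j])
        d = dice(masks[i], masks[j])
        di = trees[j].query(points[i])[0]
        dj = trees[i].query(points[j])[0]
        sdsc = (int((di <= tolerance_mm).sum()) + int((dj <= tolerance_mm).sum())) \
            / (len(points[i]) + len(points[j]))
        hd = float(max(di.max(), dj.max()))
        out.append(PairSimilarity(tumor_id, (i, j), d, sdsc, hd, tolerance_mm))
    return out


def metrics_to_frame(metrics: Iterable[PairSimilarity]) -> pd.DataFrame:
    """Tidy per-pair metric table (one row per tumor and pair)."""
    return pd.DataFrame(
        [{"tumor_id": m.tumor_id, "seg_i": m.pair[0], "seg_j": m.pair[1],
          "dsc": m.dsc, "sdsc": m.sdsc, "hd_mm": m.hd_mm,
          "tolerance_mm": m.tolerance_mm} for m in metrics])
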