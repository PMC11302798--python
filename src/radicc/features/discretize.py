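"""Fixed-bin-width gray-level discretization of a region of interest."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..volumes import DegenerateROIError, ImageVolume, LabelMask, assert_aligned


@dataclass(frozen=True)
class DiscretizedROI:
    """Gray levels of the ROI voxels on a bounding-box crop of the grid.

    ``levels`` holds integer gray levels 1..ng inside the ROI and 0 on
    background voxels; ``raw`` are the corresponding (filtered) intensities
    in C order of the ROI voxels.  Level assignment follows

        level(v) = floor((x(v) - bin_origin) / bin_width) + 1

    with ``bin_origin`` the minimum ROI intensity by default, so level 1 is
    always occupied and ``ng`` is the maximum assigned level (intermediate
    levels may be empty).
    """

    levels: np.ndarray          # int32, 0 = background, cropped to ROI bbox
    raw: np.ndarray             # float64, ROI voxels only (C order)
    ng: int
    bin_width: float
    bin_origin: float
    spacing: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.raw.size)

    @property
    def roi_mask(self) -> np.ndarray:
        return self.levels > 0

    def histogram(self) -> np.ndarray:
        """Occupancy counts of levels 1..ng."""
        return np.bincount(self.levels[self.levels > 0], minlength=self.ng + 1)[1:]


def discretize(image: ImageVolume, mask: LabelMask, bin_width: float = 25.0,
               bin_origin: float | None = None) -> DiscretizedROI:
    """Discretize ROI intensities with a fixed bin width.

    ``bin_origin`` defaults to the ROI minimum; pass an explicit value to
    anchor bin edges elsewhere (e.g. at multiples of the width).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    assert_aligned(image, mask)
    roi = mask.astype_bool()
    if not roi.any():
        raise DegenerateROIError("cannot discretize an empty ROI")
    idx = np.argwhere(roi)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    crop = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    roi_c = roi[crop]
    vals = np.asarray(image.voxels)[crop]
    raw = vals[roi_c].astype(np.float64)
    origin = float(raw.min()) if bin_origin is None else float(bin_origin)
    levels = np.zeros(roi_c.shape, dtype=np.int32)
    lv = np.floor((raw - origin) / bin_width).astype(np.int64) + 1
    if lv.min() < 1:
        raise ValueError("bin_origin larger than the ROI minimum intensity")
    levels[roi_c] = lv
    return DiscretizedROI(levels=levels, raw=raw, ng=int(lv.max()),
                          bin_width=float(bin_width), bin_origin=origin,
                          spacing=image.spacing)
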