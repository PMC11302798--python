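"""The full radiomics feature panel and cohort-level extraction.

Under the default configuration the panel has exactly 944 features: 93
non-shape features (18 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM +
14 GLDM + 5 NGTDM) on each of 10 image types (original, one LoG scale,
eight wavelet sub-bands) plus 14 shape features computed once on the
original resampled mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from ..filtering import (FilterConfig, derive_images, resample_image,
                         resample_mask)
from ..volumes import Cohort, ImageVolume, LabelMask, assert_aligned
from .discretize import discretize
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .shape import SHAPE_NAMES, shape_features
from .texture import (gldm_features, glcm_features, glrlm_features,
                      glszm_features, ngtdm_features)

GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

FEATURE_CLASSES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}
#: feature classes computed per derived image type (shape is separate)
NONSHAPE_CLASSES = tuple(FEATURE_CLASSES)

_CLASS_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "gldm": gldm_features,
    "ngtdm": ngtdm_features,
}


class FeatureId(NamedTuple):
    """Fully qualified feature identifier."""

    image_type: str
    feature_class: str
    feature_name: str


@dataclass(frozen=True)
class ExtractionConfig:
    """Everything that determines a feature value besides the data."""

    filters: FilterConfig = field(default_factory=FilterConfig)
    bin_width: float = 25.0
    #: 'roi-min' anchors bin edges at the ROI minimum; 'aligned' at
    #: multiples of the bin width
    bin_origin_rule: str = "roi-min"

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.bin_origin_rule not in ("roi-min", "aligned"):
            raise ValueError(f"unknown bin_origin_rule {self.bin_origin_rule!r}")

    def to_dict(self) -> dict:
        return {"filters": self.filters.to_dict(), "bin_width": self.bin_width,
                "bin_origin_rule": self.bin_origin_rule}

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractionConfig":
        d = dict(d)
        if "filters" in d:
            d["filters"] = FilterConfig.from_dict(d["filters"])
        return cls(**d)


def all_feature_ids(config: ExtractionConfig = ExtractionConfig()) -> list[FeatureId]:
    """The ordered panel: shape first, then per image type each class."""
    ids = [FeatureId("original", "shape", n) for n in SHAPE_NAMES]
    for image_type in config.filters.image_types:
        for fclass in NONSHAPE_CLASSES:
            ids.extend(FeatureId(image_type, fclass, n)
                       for n in FEATURE_CLASSES[fclass])
    return ids


def _needed(subset: Iterable[FeatureId] | None,
            config: ExtractionConfig) -> dict[str, dict[str, set[str]]]:
    """Map image_type -> feature_class -> set of feature names to compute."""
    if subset is None:
        subset = all_feature_ids(config)
    needed: dict[str, dict[str, set[str]]] = {}
    for fid in subset:
        fid = FeatureId(*fid)
        needed.setdefault(fid.image_type, {}).setdefault(
            fid.feature_class, set()).add(fid.feature_name)
    return needed


def _extract_resampled(derived: dict[str, ImageVolume], rmask: LabelMask,
                       config: ExtractionConfig,
                       needed: dict[str, dict[str, set[str]]]
                       ) -> dict[FeatureId, float]:
    out: dict[FeatureId, float] = {}
    for image_type, classes in needed.items():
        if "shape" in classes:
            if image_type != "original":
                raise ValueError("shape features exist only for image_type 'original'")
            for name, val in shape_features(rmask).items():
                out[FeatureId("original", "shape", name)] = val
        texture_classes = {c: n for c, n in classes.items() if c != "shape"}
        if not texture_classes:
            continue
        image = derived[image_type]
        if config.bin_origin_rule == "aligned":
            roi_min = float(np.asarray(image.voxels)[rmask.astype_bool()].min())
            origin = config.bin_width * np.floor(roi_min / config.bin_width)
        else:
            origin = None
        droi = discretize(image, rmask, config.bin_width, bin_origin=origin)
        for fclass, fnames in texture_classes.items():
            if fclass == "glcm":
                vals = glcm_features(droi, names=fnames)
            elif fclass == "firstorder":
                vals = firstorder_features(droi)
            else:
                vals = _CLASS_FUNCS[fclass](droi)
            for name in fnames:
                out[FeatureId(image_type, fclass, name)] = vals[name]
    return out


def extract_features(image: ImageVolume, mask: LabelMask,
                     config: ExtractionConfig = ExtractionConfig(),
                     subset: Iterable[FeatureId] | None = None) -> pd.Series:
    """Extract the (sub)panel for one image/mask pair.

    Returns a Series indexed by (image_type, feature_class, feature_name);
    the full default panel has exactly 944 entries.
    """
    assert_aligned(image, mask)
    needed = _needed(subset, config)
    rimg = resample_image(image, config.filters)
    rmask = resample_mask(mask, config.filters)
    image_types = [t for t in needed if any(c != "shape" for c in needed[t])]
    derived = _derive_subset(rimg, config.filters, image_types)
    values = _extract_resampled(derived, rmask, config, needed)
    return _to_series(values, subset, config)


def _derive_subset(rimg: ImageVolume, filters: FilterConfig,
                   image_types: list[str]) -> dict[str, ImageVolume]:
    derived = derive_images(rimg, filters, image_types=image_types)
    derived.setdefault("original", rimg)
    return derived


def _to_series(values: dict[FeatureId, float],
               subset: Iterable[FeatureId] | None,
               config: ExtractionConfig) -> pd.Series:
    order = ([FeatureId(*f) for f in subset] if subset is not None
             else all_feature_ids(config))
    idx = pd.MultiIndex.from_tuples(order,
                                    names=["image_type", "feature_class", "feature_name"])
    return pd.Series([values[f] for f in order], index=idx, name="value")


# --------------------------------------------------------------------------
# Cohort-level extraction and the rectangular feature table


@dataclass
class FeatureTable:
    """Feature values for every (tumor, segmentation) cell of a cohort.

    ``data`` is a DataFrame with row MultiIndex (tumor_id, segmentation_id)
    and column MultiIndex (image_type, feature_class, feature_name); the
    table is rectangular by construction.
    """

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.index.nlevels != 2 or self.data.columns.nlevels != 3:
            raise ValueError("FeatureTable needs (tumor, segmentation) rows "
                             "and (image_type, class, name) columns")
        counts = self.data.groupby(level=0).size()
        if counts.nunique() != 1:
            raise ValueError("table is not rectangular: tumors have "
                             f"differing segmentation counts {dict(counts)}")

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.data.index.get_level_values(0).unique())

    @property
    def segmentation_ids(self) -> list[str]:
        return list(self.data.loc[self.tumor_ids[0]].index)

    @property
    def feature_ids(self) -> list[FeatureId]:
        return [FeatureId(*c) for c in self.data.columns]

    def rating_matrix(self, feature: FeatureId) -> pd.DataFrame:
        """Subjects (tumors) x raters (segmentations) values of one feature."""
        col = self.data[tuple(FeatureId(*feature))]
        wide = col.unstack(level=1)
        if wide.isna().any().any():
            missing = wide.stack(dropna=False)
            missing = missing[missing.isna()].index.tolist()
            raise ValueError(f"incomplete feature table for {feature}: "
                             f"missing cells {missing[:5]}")
        return wide.loc[self.tumor_ids, self.segmentation_ids]

    # -- tidy CSV round trip ------------------------------------------------

    def to_tidy(self) -> pd.DataFrame:
        tidy = self.data.stack(level=[0, 1, 2], future_stack=True).rename("value").reset_index()
        tidy.columns = ["tumor_id", "segmentation_id", "image_type",
                        "feature_class", "feature_name", "value"]
        return tidy

    def to_csv(self, path) -> None:
        self.to_tidy().to_csv(path, index=False)

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame) -> "FeatureTable":
        data = tidy.pivot_table(
            index=["tumor_id", "segmentation_id"],
            columns=["image_type", "feature_class", "feature_name"],
            values="value", sort=False)
        return cls(data)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls.from_tidy(pd.read_csv(path, dtype={"tumor_id": str,
                                                      "segmentation_id": str}))


def extract_cohort(cohort: Cohort, config: ExtractionConfig = ExtractionConfig(),
                   subset: Iterable[FeatureId] | None = None,
                   progress: bool = False) -> FeatureTable:
    """Extract the panel for every (tumor, segmentation) of a cohort.

    Derived images are computed once per tumor and shared across that
    tumor's segmentations.
    """
    needed = _needed(subset, config)
    image_types = [t for t in needed if any(c != "shape" for c in needed[t])]
    rows = {}
    for entry in cohort.tumors:
        rimg = resample_image(entry.image, config.filters)
        derived = _derive_subset(rimg, config.filters, image_types)
        for seg_id, mask in entry.segmentations.items():
            rmask = resample_mask(mask, config.filters)
            values = _extract_resampled(derived, rmask, config, needed)
            rows[(entry.tumor_id, seg_id)] = _to_series(values, subset, config)
    data = pd.DataFrame(rows).T
    data.index.names = ["tumor_id", "segmentation_id"]
    return FeatureTable(data)


def write_config_sidecar(config: ExtractionConfig, path) -> None:
    """Echo the extraction config next to a feature CSV for provenance."""
    Path(path).write_text(json.dumps(config.to_dict(), indent=2))
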