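"""Image volumes, binary masks and cohorts on axis-aligned physical grids.

Conventions used throughout the package:

* grids are 0-indexed numpy arrays with array axis ``i`` mapped to physical
  axis ``i`` (axis 0 = x, axis 1 = y, axis 2 = z of the file formats'
  physical space);
* a voxel's physical position is ``origin + index * spacing`` (voxel-center
  convention);
* only axis-aligned volumes are supported — files with oblique direction
  matrices are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk


class VolumeFormatError(ValueError):
    """Raised when a file cannot be interpreted as an axis-aligned volume."""


class AlignmentError(ValueError):
    """Raised when an image and a mask do not share the same grid."""


class DegenerateROIError(ValueError):
    """Raised when an operation receives an empty region of interest."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D scalar image with physical voxel spacing and origin (mm)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=np.float64)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValueError(f"voxels must be a 3-D grid, got shape {vox.shape}")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        """Same grid, new voxel values."""
        return ImageVolume(voxels, self.spacing, self.origin)


@dataclass(frozen=True)
class LabelMask:
    """A binary {0,1} mask aligned to a companion :class:`ImageVolume` grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValueError(f"mask must be a 3-D grid, got shape {vox.shape}")
        if vox.dtype != np.bool_ and not bool(((vox == 0) | (vox == 1)).all()):
            bad = np.unique(vox)
            raise ValueError(f"mask must contain only 0/1, found values {bad[:10]}")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        object.__setattr__(self, "voxels", vox.astype(np.uint8))
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    def astype_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)


@dataclass
class TumorEntry:
    """One tumor: its image and the segmentations drawn on it."""

    tumor_id: str
    image: ImageVolume
    segmentations: dict[str, LabelMask]


@dataclass
class Cohort:
    """An ordered collection of tumors, each with k aligned segmentations.

    Segmentation ids must be unique within a tumor and identical across
    tumors (the same k rater labels everywhere), mirroring a multi-reader
    or multi-tool segmentation study design.
    """

    tumors: list[TumorEntry]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.tumors:
            raise ValueError("cohort must contain at least one tumor")
        ref_ids = list(self.tumors[0].segmentations)
        for entry in self.tumors:
            if list(entry.segmentations) != ref_ids:
                raise ValueError(
                    f"tumor {entry.tumor_id!r} has segmentation ids "
                    f"{list(entry.segmentations)}, expected {ref_ids}"
                )
            for sid, mask in entry.segmentations.items():
                assert_aligned(entry.image, mask)

    @property
    def tumor_ids(self) -> list[str]:
        return [t.tumor_id for t in self.tumors]

    @property
    def segmentation_ids(self) -> list[str]:
        return list(self.tumors[0].segmentations)


# --------------------------------------------------------------------------
# IO via SimpleITK (handles both NRRD and NIfTI-1)

_ORIENT_TOL = 1e-6


def _from_sitk(img: sitk.Image, path) -> tuple[np.ndarray, tuple, tuple]:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=_ORIENT_TOL):
        raise VolumeFormatError(
            f"{path}: oblique or flipped orientation matrix is not supported "
            f"(direction={direction.tolist()}); resample to an axis-aligned "
            "grid before loading"
        )
    # sitk arrays are indexed (z, y, x); transpose to our (x, y, z) convention
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def _read_sitk(path, fmt: str) -> sitk.Image:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if fmt == "auto":
        fmt = "nifti" if "".join(path.suffixes).endswith((".nii", ".nii.gz")) else "nrrd"
    reader_io = {"nrrd": "NrrdImageIO", "nifti": "NiftiImageIO"}.get(fmt)
    if reader_io is None:
        raise ValueError(f"unknown format {fmt!r}; expected 'nrrd', 'nifti' or 'auto'")
    reader = sitk.ImageFileReader()
    reader.SetImageIO(reader_io)
    reader.SetFileName(str(path))
    try:
        return reader.Execute()
    except RuntimeError as exc:  # pragma: no cover - message path
        raise IOError(f"could not read {path} as {fmt}: {exc}") from exc


def read_volume(path, format: str = "auto") -> ImageVolume:
    """Read a scalar volume from NRRD or NIfTI-1.

    Spacing and origin come from the file header; voxel values are used as
    stored (after the format's own slope/intercept, which the reader applies).
    """
    arr, spacing, origin = _from_sitk(_read_sitk(path, format), path)
    return ImageVolume(arr.astype(np.float64), spacing, origin)


def read_mask(path, positive_label: int | None = None, format: str = "auto") -> LabelMask:
    """Read a binary mask; multi-label files require ``positive_label``."""
    arr, spacing, origin = _from_sitk(_read_sitk(path, format), path)
    labels = np.unique(arr)
    fg_labels = labels[labels != 0]
    if positive_label is None:
        if len(fg_labels) > 1:
            raise ValueError(
                f"{path}: multi-label image with values {labels.tolist()}; "
                "specify positive_label"
            )
        binary = arr != 0
    else:
        if len(fg_labels) and positive_label not in labels:
            warnings.warn(
                f"{path}: positive_label {positive_label} absent "
                f"(found {labels.tolist()}); returning an empty mask",
                stacklevel=2,
            )
        binary = arr == positive_label
    return LabelMask(binary.astype(np.uint8), spacing, origin)


def _to_sitk(vol: ImageVolume | LabelMask) -> sitk.Image:
    arr = np.asarray(vol.voxels)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def write_volume(vol: ImageVolume | LabelMask, path) -> None:
    """Write a volume or mask to NRRD or NIfTI-1 (chosen by extension)."""
    sitk.WriteImage(_to_sitk(vol), str(path))


# --------------------------------------------------------------------------


def assert_aligned(image: ImageVolume | LabelMask, other: ImageVolume | LabelMask,
                   tol_mm: float = 1e-3) -> None:
    """Check that two grids coincide: same shape, spacing/origin within tol."""
    if image.shape != other.shape:
        raise AlignmentError(f"shape mismatch: {image.shape} vs {other.shape}")
    for name in ("spacing", "origin"):
        a = np.asarray(getattr(image, name))
        b = np.asarray(getattr(other, name))
        if np.abs(a - b).max() > tol_mm:
            raise AlignmentError(
                f"{name} mismatch beyond {tol_mm} mm: {tuple(a)} vs {tuple(b)}"
            )


# --------------------------------------------------------------------------
# Cohort manifest: CSV with columns tumor_id, image_path, segmentation_id,
# mask_path.  One row per (tumor, segmentation); the image path repeats.

MANIFEST_COLUMNS = ["tumor_id", "image_path", "segmentation_id", "mask_path"]


def write_manifest(rows: Iterable[Sequence], path) -> None:
    pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def load_cohort(manifest_path, positive_label: int | None = None) -> Cohort:
    """Load a cohort from a manifest CSV (paths resolved against its folder)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {manifest_path} missing columns {sorted(missing)}")
    base = manifest_path.parent
    tumors: list[TumorEntry] = []
    for tumor_id, group in df.groupby("tumor_id", sort=False):
        image_paths = group["image_path"].unique()
        if len(image_paths) != 1:
            raise ValueError(f"tumor {tumor_id!r} lists multiple image paths")
        image = read_volume(base / image_paths[0])
        segs = {
            str(row.segmentation_id): read_mask(base / row.mask_path, positive_label)
            for row in group.itertuples()
        }
        tumors.append(TumorEntry(str(tumor_id), image, segs))
    return Cohort(tumors, provenance={"manifest": str(manifest_path)})
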