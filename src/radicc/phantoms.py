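"""Seeded synthetic cohorts: textured ellipsoidal tumors with k segmentations
drawn from g perturbation-method families.

The generator emulates a multi-institution segmentation study: each tumor
has one ground-truth mask, and every segmentation is a perturbed copy of it.
Perturbation families differ in *kind* (random boundary jitter vs. two
systematic deformations), the settings within a family differ only in
*level*, mirroring one tool run at three parameter settings.  Defaults give
10 tumors x (3 families x 3 settings) = 90 masks whose within-tumor pairwise
Dice stays above a configured floor (0.75), so geometric overlap looks
uniformly "good" while systematic cross-family differences remain large —
the regime the agreement analysis is designed to expose.

Everything is deterministic given the single top-level seed (hierarchical
sub-seeding per tumor / segmentation / retry).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .metrics import dice
from .volumes import Cohort, ImageVolume, LabelMask, TumorEntry, write_manifest, write_volume

JITTER = "boundary_jitter"
DILATION = "systematic_dilation"
EROSION_OFFSET = "systematic_erosion_offset"


@dataclass(frozen=True)
class PerturbationFamily:
    """One segmentation-method family; settings share the kind, not the level.

    ``levels`` means: jitter sigma in mm (boundary_jitter), dilation radius
    in mm (systematic_dilation), or rigid-offset magnitude in mm
    (systematic_erosion_offset, combined with a fixed erosion depth).
    """

    name: str
    kind: str
    levels: tuple[float, ...]
    erosion_mm: float = 0.0
    offset_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    jitter_correlation_mm: float = 4.0

    def __post_init__(self):
        if self.kind not in (JITTER, DILATION, EROSION_OFFSET):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if not self.levels:
            raise ValueError("family needs at least one setting level")


def default_families() -> tuple[PerturbationFamily, ...]:
    """One random family and two systematic families, three settings each."""
    return (
        PerturbationFamily("A", JITTER, (0.5, 0.65, 0.8)),
        PerturbationFamily("B", DILATION, (1.0, 1.45, 1.75)),
        PerturbationFamily("C", EROSION_OFFSET, (0.0, 1.0, 2.0),
                           erosion_mm=1.2, offset_direction=(1.0, 0.0, 0.0)),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Study-design parameters of the synthetic cohort."""

    n_tumors: int = 10
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    radius_range_mm: tuple[float, float] = (18.0, 24.0)
    texture_correlation_mm: float = 3.0
    texture_amplitude: float = 60.0
    contrast: float = 800.0
    background_level: float = -800.0
    noise_sigma: float = 10.0
    families: tuple[PerturbationFamily, ...] = field(default_factory=default_families)
    dsc_floor: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.n_tumors < 1:
            raise ValueError("need at least one tumor")
        for name in ("radius_range_mm", "spacing", "grid_shape"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be positive")
        k = sum(len(f.levels) for f in self.families)
        if k < 2:
            raise ValueError("families x settings must give k >= 2 segmentations")
        extent = min(g * s for g, s in zip(self.grid_shape, self.spacing))
        if 2 * self.radius_range_mm[1] + 8 > extent:
            raise ValueError(
                f"largest tumor (diameter {2*self.radius_range_mm[1]} mm) does "
                f"not fit the grid extent {extent} mm with margin")

    @property
    def segmentation_ids(self) -> list[str]:
        return [f"{fam.name}{s + 1}" for fam in self.families
                for s in range(len(fam.levels))]

    def family_of(self) -> dict[str, str]:
        """Planted truth: segmentation id -> family name."""
        return {f"{fam.name}{s + 1}": fam.name for fam in self.families
                for s in range(len(fam.levels))}


def _rng(spec: PhantomSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=tuple(key)))


def _smooth_field(rng: np.random.Generator, shape, spacing, correlation_mm) -> np.ndarray:
    """Unit-variance Gaussian-correlated random field."""
    sig = [correlation_mm / s for s in spacing]
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sig, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def make_tumor(spec: PhantomSpec, tumor_index: int) -> tuple[ImageVolume, LabelMask]:
    """One textured ellipsoidal tumor and its ground-truth mask.

    The image is a darker background plus the configured tumor/background
    contrast inside the ellipsoid, a correlated texture field inside the
    tumor, and white noise everywhere.  Fully determined by
    (spec.seed, tumor_index).
    """
    rng = _rng(spec, 0, tumor_index)
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing)
    lo, hi = spec.radius_range_mm
    semi_axes = rng.uniform(lo, hi, size=3)
    center = (np.asarray(shape) - 1) * spacing / 2.0 + rng.uniform(-2.0, 2.0, size=3)
    idx = np.indices(shape).astype(np.float64)
    phys = idx * spacing[:, None, None, None]
    r2 = sum(((phys[a] - center[a]) / semi_axes[a]) ** 2 for a in range(3))
    mask = (r2 <= 1.0).astype(np.uint8)
    texture = _smooth_field(rng, shape, spec.spacing, spec.texture_correlation_mm)
    vox = np.full(shape, spec.background_level, dtype=np.float64)
    vox += spec.contrast * mask
    vox += spec.texture_amplitude * texture * mask
    vox += spec.noise_sigma * rng.standard_normal(shape)
    return (ImageVolume(vox, spec.spacing), LabelMask(mask, spec.spacing))


def _signed_distance(fg: np.ndarray, spacing) -> np.ndarray:
    """Positive outside the mask, negative inside (mm)."""
    outside = ndimage.distance_transform_edt(~fg, sampling=spacing)
    inside = ndimage.distance_transform_edt(fg, sampling=spacing)
    return outside - inside


def perturb(mask: LabelMask, family: PerturbationFamily, level: float,
            rng: np.random.Generator,
            signed_distance: np.ndarray | None = None) -> LabelMask:
    """Apply one family's perturbation at the given level.

    ``signed_distance`` may be passed to reuse the mask's distance field
    across perturbations.  Empties are retried at half the level (up to 5
    attempts) before raising.
    """
    if mask.foreground_count == 0:
        raise ValueError("cannot perturb an empty mask")
    fg = mask.astype_bool()
    spacing = mask.spacing
    d = (signed_distance if signed_distance is not None
         else _signed_distance(fg, spacing))
    lvl = float(level)
    for _ in range(5):
        if family.kind == JITTER:
            field = _smooth_field(rng, fg.shape, spacing, family.jitter_correlation_mm)
            new = d - lvl * field <= 0
        elif family.kind == DILATION:
            new = d <= lvl
        else:  # EROSION_OFFSET
            eroded = d <= -family.erosion_mm
            direction = np.asarray(family.offset_direction, dtype=float)
            norm = np.linalg.norm(direction)
            shift_vox = (lvl * direction / norm) / np.asarray(spacing)
            new = ndimage.shift(eroded.astype(np.uint8), shift_vox, order=0,
                                mode="constant", cval=0).astype(bool)
        if new.any():
            return LabelMask(new.astype(np.uint8), spacing, mask.origin)
        import warnings
        warnings.warn(f"perturbation {family.name} level {lvl} emptied the "
                      "mask; retrying at half level", stacklevel=2)
        lvl *= 0.5
    raise RuntimeError(f"perturbation {family.name} emptied the mask after 5 attempts")


def make_cohort(spec: PhantomSpec = PhantomSpec()) -> Cohort:
    """The full synthetic cohort: n_tumors x (families x settings) masks.

    Within-tumor pairwise Dice is checked against ``spec.dsc_floor``; a
    violating tumor is regenerated with all perturbation levels scaled down
    by 0.8 (up to 5 attempts) before raising.
    """
    tumors = []
    for i in range(spec.n_tumors):
        image, true_mask = make_tumor(spec, i)
        sdt = _signed_distance(true_mask.astype_bool(), spec.spacing)
        achieved = 0.0
        for attempt in range(5):
            scale = 0.8 ** attempt
            segs: dict[str, LabelMask] = {}
            for fi, fam in enumerate(spec.families):
                for si, level in enumerate(fam.levels):
                    rng = _rng(spec, 1, i, fi, si, attempt)
                    segs[f"{fam.name}{si + 1}"] = perturb(
                        true_mask, fam, level * scale, rng, signed_distance=sdt)
            ids = list(segs)
            achieved = min(dice(segs[a], segs[b])
                           for x, a in enumerate(ids) for b in ids[x + 1:])
            if achieved > spec.dsc_floor:
                break
        else:
            raise RuntimeError(
                f"tumor {i}: pairwise DSC floor {spec.dsc_floor} not met "
                f"after 5 level reductions (achieved {achieved:.3f})")
        tumors.append(TumorEntry(f"tumor{i + 1:02d}", image, segs))
    return Cohort(tumors, provenance={
        "generator": "radicc.phantoms", "seed": spec.seed,
        "families": spec.family_of(),
        "k": len(spec.segmentation_ids), "n_tumors": spec.n_tumors})


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort as NRRD volumes/masks plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for entry in cohort.tumors:
        img_name = f"{entry.tumor_id}_image.nrrd"
        write_volume(entry.image, out_dir / img_name)
        for seg_id, mask in entry.segmentations.items():
            mask_name = f"{entry.tumor_id}_seg_{seg_id}.nrrd"
            write_volume(mask, out_dir / mask_name)
            rows.append((entry.tumor_id, img_name, seg_id, mask_name))
    manifest = out_dir / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest
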