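"""Preprocessing filter bank: isotropic resampling, Laplacian-of-Gaussian and
a single-level undecimated 3-D wavelet decomposition.

All filtering happens *after* resampling, so every derived image shares one
grid with the resampled mask and feature extraction never mixes grids.
Boundary handling is symmetric (mirror) padding for every filter, and all
1-D convolutions follow one convention: out[i] = sum_k h[k] x[i - k + c]
with the kernel centered at c = (len(h) - 1) // 2.  The wavelet transform
is undecimated (stationary), so each of the eight sub-bands keeps the input
grid.  Sub-band labels read first-letter = array axis 0: e.g.
``wavelet-HLL`` is high-pass along axis 0 and low-pass along axes 1 and 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pywt
from scipy import ndimage

from .volumes import DegenerateROIError, ImageVolume, LabelMask, assert_aligned

_INTERPOLATOR_ORDER = {"trilinear": 1, "bspline3": 3}

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


@dataclass(frozen=True)
class FilterConfig:
    """Settings of the preprocessing/filter bank.

    Defaults follow common CT radiomics practice: 2 mm isotropic resampling,
    a single LoG scale at sigma = 1 mm, and a coif1 wavelet; images are
    interpolated with a cubic B-spline and masks with nearest-neighbour.
    """

    resample_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    log_sigmas_mm: tuple[float, ...] = (1.0,)
    wavelet_name: str = "coif1"
    image_interpolator: str = "bspline3"
    mask_interpolator: str = "nearest"

    def __post_init__(self):
        if any(s <= 0 for s in self.resample_spacing_mm):
            raise ValueError("resample spacing must be positive")
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ValueError("LoG sigma must be positive")
        if self.image_interpolator not in _INTERPOLATOR_ORDER:
            raise ValueError(f"unknown image interpolator {self.image_interpolator!r}")
        if self.mask_interpolator != "nearest":
            raise ValueError("masks are resampled with nearest-neighbour only")
        try:
            pywt.Wavelet(self.wavelet_name)
        except ValueError as exc:
            raise ValueError(f"unknown wavelet {self.wavelet_name!r}") from exc

    @property
    def image_types(self) -> list[str]:
        """Ordered labels of the derived images (original first)."""
        return (["original"]
                + [log_label(s) for s in self.log_sigmas_mm]
                + [f"wavelet-{b}" for b in WAVELET_SUBBANDS])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        d = dict(d)
        for key in ("resample_spacing_mm", "log_sigmas_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def log_label(sigma_mm: float) -> str:
    """PyRadiomics-style image-type label, e.g. ``log-sigma-1-0-mm-3D``."""
    text = f"{float(sigma_mm):.10g}"
    if "." not in text:
        text += ".0"
    return f"log-sigma-{text.replace('.', '-')}-mm-3D"


def _target_coords(shape, src_sp, dst_sp):
    """Output voxel centers expressed in input index units.

    The output grid starts at the input origin and covers the input's
    physical extent at the target spacing.
    """
    shape_out = np.maximum(1, np.ceil(np.asarray(shape) * src_sp / dst_sp)).astype(int)
    return np.meshgrid(*[np.arange(n) * dst_sp[i] / src_sp[i]
                         for i, n in enumerate(shape_out)], indexing="ij")


def resample_image(image: ImageVolume, config: FilterConfig = FilterConfig()) -> ImageVolume:
    """Resample a scalar image with the configured spline order."""
    dst_sp = np.asarray(config.resample_spacing_mm, dtype=float)
    coords = _target_coords(image.shape, np.asarray(image.spacing), dst_sp)
    order = _INTERPOLATOR_ORDER[config.image_interpolator]
    out = ndimage.map_coordinates(image.voxels, coords, order=order, mode="mirror")
    return ImageVolume(out, tuple(dst_sp), image.origin)


def resample_mask(mask: LabelMask, config: FilterConfig = FilterConfig()) -> LabelMask:
    """Resample a mask with nearest-neighbour interpolation and re-binarize."""
    dst_sp = np.asarray(config.resample_spacing_mm, dtype=float)
    coords = _target_coords(mask.shape, np.asarray(mask.spacing), dst_sp)
    out = ndimage.map_coordinates(mask.voxels, coords, order=0, mode="constant", cval=0)
    out = (out > 0).astype(np.uint8)
    if mask.foreground_count > 0 and out.sum() == 0:
        raise DegenerateROIError(
            "mask became empty after resampling to "
            f"{tuple(dst_sp)} mm (was {mask.foreground_count} voxels)"
        )
    return LabelMask(out, tuple(dst_sp), mask.origin)


def resample(image: ImageVolume, mask: LabelMask,
             config: FilterConfig = FilterConfig()) -> tuple[ImageVolume, LabelMask]:
    """Resample an aligned image/mask pair onto the target spacing.

    The image uses the configured spline order, the mask nearest-neighbour;
    both land on the same grid.
    """
    assert_aligned(image, mask)
    return resample_image(image, config), resample_mask(mask, config)


def log_filter(image: ImageVolume, sigma_mm: float) -> ImageVolume:
    """Laplacian of the Gaussian-smoothed image, sigma in physical mm.

    The physical sigma is converted per axis to voxel units via the grid
    spacing; the result lives on the input grid.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    if sigma_mm < 0.5 * min(image.spacing):
        warnings.warn(
            f"LoG sigma {sigma_mm} mm is under-resolved on spacing "
            f"{image.spacing} mm; the discrete kernel is a coarse sample "
            "of the continuous operator",
            stacklevel=2,
        )
    sigma_vox = [sigma_mm / s for s in image.spacing]
    kernels = [_gaussian_derivative_kernels(s) for s in sigma_vox]
    # the Laplacian is taken in physical units: each second derivative
    # (computed in index units) is rescaled by 1/spacing^2
    out = np.zeros_like(image.voxels)
    for axis in range(3):
        d2 = image.voxels
        for a in range(3):
            kernel = kernels[a][1] if a == axis else kernels[a][0]
            d2 = ndimage.convolve1d(d2, kernel, axis=a, mode="mirror",
                                    origin=_kernel_origin(len(kernel)))
        out += d2 / image.spacing[axis] ** 2
    return image.with_voxels(out)


def _gaussian_derivative_kernels(sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Sampled Gaussian smoothing and second-derivative taps.

    The smoothing taps sum to 1 and the second-derivative taps to 0 exactly,
    so a constant image has an exactly zero Laplacian and a linear ramp a
    zero interior response.
    """
    radius = max(1, int(4.0 * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-x ** 2 / (2.0 * sigma ** 2))
    g /= g.sum()
    g2 = g * (x ** 2 - sigma ** 2) / sigma ** 4
    g2 -= g2.mean()
    return g, g2


def _separable_filter(arr: np.ndarray, axes_kind: str,
                      lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    out = arr
    for axis, letter in enumerate(axes_kind):
        kernel = lo if letter == "L" else hi
        out = ndimage.convolve1d(out, kernel, axis=axis, mode="mirror",
                                 origin=_kernel_origin(len(kernel)))
    return out


def _kernel_origin(length: int) -> int:
    # center an even-length kernel: ndimage places the kernel center at
    # index length//2; shift so taps sit symmetrically around the voxel
    return -1 if length % 2 == 0 else 0


def wavelet_decompose(image: ImageVolume, wavelet_name: str = "coif1",
                      bands: tuple[str, ...] = WAVELET_SUBBANDS) -> dict[str, ImageVolume]:
    """Single-level stationary (undecimated) separable 3-D wavelet transform.

    Returns the eight sub-bands labeled ``LLL`` ... ``HHH``; letter ``i``
    names the filter applied along array axis ``i``.  Because the transform
    is undecimated, each sub-band is a plain separable convolution with the
    wavelet's decomposition filter pair under mirror boundary handling.
    """
    try:
        wavelet = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {wavelet_name!r}") from exc
    lo = np.asarray(wavelet.dec_lo, dtype=np.float64)
    hi = np.asarray(wavelet.dec_hi, dtype=np.float64)
    unknown = set(bands) - set(WAVELET_SUBBANDS)
    if unknown:
        raise ValueError(f"unknown sub-band labels {sorted(unknown)}")
    out = {}
    for band in bands:
        out[band] = image.with_voxels(
            _separable_filter(image.voxels, band, lo, hi))
    return out


def derive_images(image: ImageVolume, config: FilterConfig = FilterConfig(),
                  image_types: list[str] | None = None) -> dict[str, ImageVolume]:
    """Derived images on the (already resampled) input grid.

    Under the default config: 1 original + 1 LoG + 8 wavelet = 10 types.
    ``image_types`` restricts computation to a subset of labels.
    """
    wanted = config.image_types if image_types is None else list(image_types)
    unknown = set(wanted) - set(config.image_types)
    if unknown:
        raise ValueError(f"unknown image types {sorted(unknown)}")
    derived = {}
    if "original" in wanted:
        derived["original"] = image
    for sigma in config.log_sigmas_mm:
        if log_label(sigma) in wanted:
            derived[log_label(sigma)] = log_filter(image, sigma)
    bands = tuple(b for b in WAVELET_SUBBANDS if f"wavelet-{b}" in wanted)
    if bands:
        for band, vol in wavelet_decompose(image, config.wavelet_name, bands).items():
            derived[f"wavelet-{band}"] = vol
    return derived
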