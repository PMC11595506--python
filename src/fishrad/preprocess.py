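"""Spacing-aware resampling, import-time resizing, normalization, discretization.

Two distinct downscaling pathways are provided on purpose, because their
numerical behaviour differs and comparing them is the point of the
stability analysis:

``resample``
    Physical-grid resampling (SimpleITK): the output grid is laid out in
    physical space using the image spacing, the image is interpolated
    with nearest-neighbor (default) or linear interpolation, and masks
    always with nearest-neighbor.
``resize``
    Plain array rescale at import time (scikit-image): bilinear for the
    image, nearest for masks, with the spacing multiplied by the factor
    so the physical extent is preserved.

Gray levels are discretized with a fixed *bin count* over the in-mask
intensity range (the default), or alternatively with a fixed *bin width*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import SimpleITK as sitk
from skimage.transform import resize as _skimage_resize

from .errors import DegenerateMaskError, NormalizationError
from .image import ImageVolume, NamedMask

__all__ = [
    "PreprocessSpec",
    "DiscretizedVolume",
    "resample",
    "resize_on_import",
    "apply_preprocessing",
    "normalize_zscore",
    "discretize",
]


@dataclass(frozen=True)
class PreprocessSpec:
    """Preprocessing settings for one extraction condition.

    Mask interpolation is *always* nearest-neighbor; only the image
    interpolator is configurable.  ``discretization="count"`` uses
    ``bin_count`` equal-width bins over the in-mask range;
    ``"width"`` uses fixed-width bins of ``bin_width`` intensity units.
    """

    mode: str = "none"  # none | resample | resize
    reduction_factor: float = 2.5
    image_interp: str = "nearest"  # nearest | linear
    normalize: str = "off"  # off | zscore
    bin_count: int = 64
    discretization: str = "count"  # count | width
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "resample", "resize"):
            raise ValueError(f"unknown preprocessing mode {self.mode!r}")
        if self.image_interp not in ("nearest", "linear"):
            raise ValueError(f"unknown image interpolator {self.image_interp!r}")
        if self.normalize not in ("off", "zscore"):
            raise ValueError(f"unknown normalization {self.normalize!r}")
        if self.discretization not in ("count", "width"):
            raise ValueError(f"unknown discretization {self.discretization!r}")
        if self.reduction_factor < 1:
            raise ValueError("reduction_factor must be >= 1")
        if self.bin_count < 1:
            raise ValueError("bin_count must be >= 1")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    def settings_fingerprint(self) -> dict:
        """Settings that must match for two studies to be mergeable."""
        fp = {
            "mode": self.mode,
            "bin_count": self.bin_count,
            "discretization": self.discretization,
        }
        if self.mode != "none":
            fp["reduction_factor"] = self.reduction_factor
        if self.discretization == "width":
            fp["bin_width"] = self.bin_width
        if self.normalize != "off":
            fp["normalize"] = self.normalize
        return fp


@dataclass(frozen=True)
class DiscretizedVolume:
    """Integer gray levels defined on the mask, undefined elsewhere.

    ``levels`` holds 1..bin_count on mask pixels and 0 outside; ``ng`` is
    the number of levels actually present in the region.
    """

    levels: np.ndarray
    mask: np.ndarray
    bin_count: int
    bin_edges: np.ndarray

    @property
    def ng(self) -> int:
        return int(np.unique(self.levels[self.mask]).size)

    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def _output_shape(shape: Sequence[int], factor: float) -> tuple[int, int]:
    return (max(1, math.floor(shape[0] / factor)), max(1, math.floor(shape[1] / factor)))


def _scaled_spacing(spacing: tuple[float, float, float], factor: float):
    return (spacing[0] * factor, spacing[1] * factor, spacing[2])


def resample(
    image: ImageVolume, masks: Iterable[NamedMask], spec: PreprocessSpec
) -> tuple[ImageVolume, list[NamedMask]]:
    """Physical-grid resampling of an image and its masks.

    Output grid dimensions are ``floor(input / factor)`` (at least 1) and
    in-plane spacing is multiplied by the factor, so the physical extent
    is preserved.  The image is interpolated per ``spec.image_interp`` on
    the physical grid; masks always with nearest-neighbor.  A mask that
    vanishes under downsampling raises :class:`DegenerateMaskError`.
    """
    masks = list(masks)
    f = spec.reduction_factor
    if f == 1:
        return image, masks

    new_shape = _output_shape(image.shape, f)
    # SimpleITK axis order is (x=col, y=row)
    in_spacing = (image.spacing[1], image.spacing[0])
    out_spacing = (image.spacing[1] * f, image.spacing[0] * f)
    out_size = (new_shape[1], new_shape[0])
    interp = sitk.sitkNearestNeighbor if spec.image_interp == "nearest" else sitk.sitkLinear

    def _run(arr: np.ndarray, interpolator) -> np.ndarray:
        img = sitk.GetImageFromArray(arr)
        img.SetSpacing(in_spacing)
        out = sitk.Resample(
            img,
            out_size,
            sitk.Transform(),
            interpolator,
            img.GetOrigin(),
            out_spacing,
            img.GetDirection(),
            0.0,
            img.GetPixelID(),
        )
        return sitk.GetArrayFromImage(out)

    new_pixels = _run(image.pixels, interp)
    new_image = ImageVolume(new_pixels, spacing=_scaled_spacing(image.spacing, f),
                            origin=image.origin)
    new_masks = []
    for m in masks:
        arr = _run(m.pixels.astype(np.uint8), sitk.sitkNearestNeighbor) > 0
        if not arr.any():
            raise DegenerateMaskError(
                f"region {m.name!r} vanished at reduction factor {f}"
            )
        new_masks.append(NamedMask(arr, name=m.name, parent_shape=new_shape))
    return new_image, new_masks


def resize_on_import(
    image: ImageVolume, masks: Iterable[NamedMask], spec: PreprocessSpec
) -> tuple[ImageVolume, list[NamedMask]]:
    """Plain array rescale (bilinear image / nearest mask) at load time.

    Same grid-dimension and spacing contract as :func:`resample`, but the
    interpolation runs on array indices rather than the physical grid —
    the second arm of the preprocessing comparison.
    """
    masks = list(masks)
    f = spec.reduction_factor
    if f == 1:
        return image, masks
    new_shape = _output_shape(image.shape, f)
    new_pixels = _skimage_resize(
        image.pixels, new_shape, order=1, anti_aliasing=False, preserve_range=True
    )
    new_image = ImageVolume(new_pixels, spacing=_scaled_spacing(image.spacing, f),
                            origin=image.origin)
    new_masks = []
    for m in masks:
        arr = _skimage_resize(
            m.pixels.astype(np.float64), new_shape, order=0,
            anti_aliasing=False, preserve_range=True,
        ) > 0.5
        if not arr.any():
            raise DegenerateMaskError(
                f"region {m.name!r} vanished at reduction factor {f}"
            )
        new_masks.append(NamedMask(arr, name=m.name, parent_shape=new_shape))
    return new_image, new_masks


def apply_preprocessing(
    image: ImageVolume, masks: Iterable[NamedMask], spec: PreprocessSpec
) -> tuple[ImageVolume, list[NamedMask]]:
    """Dispatch on ``spec.mode`` (geometric step only; joint over masks)."""
    masks = list(masks)
    if spec.mode == "none":
        return image, masks
    if spec.mode == "resample":
        return resample(image, masks, spec)
    return resize_on_import(image, masks, spec)


def normalize_zscore(image: ImageVolume, mask: NamedMask) -> ImageVolume:
    """Standardize in-mask intensities to mean 0, population SD 1.

    Off-mask pixels are left untouched.  Raises on a constant region.
    """
    values = image.pixels[mask.pixels]
    if values.size < 2:
        raise NormalizationError("need at least 2 mask pixels to normalize")
    mu = values.mean()
    sd = values.std()  # population SD
    if sd == 0:
        raise NormalizationError("zero intensity variance in region")
    out = image.pixels.copy()
    out[mask.pixels] = (values - mu) / sd
    return image.with_pixels(out)


def discretize(
    image: ImageVolume,
    mask: NamedMask,
    bin_count: int = 64,
    *,
    mode: str = "count",
    bin_width: float = 1.0,
) -> DiscretizedVolume:
    """Map in-mask intensities to integer gray levels.

    Fixed bin count (default): ``[min, max]`` of the in-mask intensities
    is split into ``bin_count`` equal-width bins and
    ``level(x) = min(floor((x - min) / width) + 1, bin_count)``.  With a
    constant region (or ``bin_count = 1``) every level is 1.

    Fixed bin width: ``level(x) = floor(x / w) - floor(min / w) + 1``,
    which preserves absolute intensity resolution instead of a fixed
    number of levels.
    """
    if bin_count < 1:
        raise ValueError("bin_count must be >= 1")
    values = image.pixels[mask.pixels]
    vmin, vmax = float(values.min()), float(values.max())
    levels = np.zeros(image.shape, dtype=np.int64)
    if mode == "width":
        base = math.floor(vmin / bin_width)
        lv = np.floor(image.pixels[mask.pixels] / bin_width).astype(np.int64) - base + 1
        levels[mask.pixels] = lv
        n_edges = int(lv.max()) + 1
        edges = vmin + bin_width * np.arange(n_edges)
        return DiscretizedVolume(levels, mask.pixels.copy(), int(lv.max()), edges)
    if vmax == vmin:
        levels[mask.pixels] = 1
        edges = np.array([vmin, vmax])
        return DiscretizedVolume(levels, mask.pixels.copy(), bin_count, edges)
    width = (vmax - vmin) / bin_count
    lv = np.floor((values - vmin) / width).astype(np.int64) + 1
    np.minimum(lv, bin_count, out=lv)
    levels[mask.pixels] = lv
    edges = vmin + width * np.arange(bin_count + 1)
    return DiscretizedVolume(levels, mask.pixels.copy(), bin_count, edges)
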