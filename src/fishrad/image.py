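"""Image and mask containers and file loading.

2D optical images (JPG/TIFF/PNG) are represented as single-slice volumes:
a 2D pixel grid plus a physical spacing triple ``(row, column, slice)``.
Optical formats carry no physical metadata, so spacing defaults to unit
values on every axis — the convention used throughout preclinical studies
where the true pixel pitch is unknown.  Region masks are binary grids tied
to a parent image and carry a user-assigned region name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import AlignmentError, EmptyMaskError, FormatError, LoadError

__all__ = [
    "ImageVolume",
    "NamedMask",
    "MaskRegistry",
    "load_image",
    "load_mask",
    "subtract_masks",
    "register_mask_name",
    "list_mask_names",
    "LUMA_WEIGHTS",
    "SUPPORTED_EXTENSIONS",
]

#: ITU-R BT.601 luma weights used for RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

SUPPORTED_EXTENSIONS = {".jpg", ".jpeg", ".png", ".tif", ".tiff"}


@dataclass(frozen=True)
class ImageVolume:
    """A single-slice scalar volume: 2D intensities with physical spacing.

    Parameters
    ----------
    pixels:
        2D array of finite real intensities, shape ``(rows, cols)``.
    spacing:
        Physical length per axis ``(row, column, slice)``; strictly positive.
        The slice spacing doubles as the extrusion thickness used by the
        shape features.
    origin:
        Physical coordinate of the first pixel (bookkeeping only).
    """

    pixels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D grid")
        if not np.all(np.isfinite(px)):
            raise ValueError("all intensities must be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area(self) -> float:
        return self.spacing[0] * self.spacing[1]

    @property
    def thickness(self) -> float:
        return self.spacing[2]

    @property
    def voxel_volume(self) -> float:
        return self.pixel_area * self.thickness

    def with_pixels(self, pixels: np.ndarray) -> "ImageVolume":
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class NamedMask:
    """A binary region aligned to an :class:`ImageVolume`.

    Masks must be non-empty and match the parent grid exactly; both are
    enforced at construction so downstream code never sees a degenerate
    region.
    """

    pixels: np.ndarray
    name: str
    parent_shape: tuple[int, int]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if not self.name:
            raise ValueError("mask name must be non-empty")
        if px.shape != tuple(self.parent_shape):
            raise AlignmentError(
                f"mask {self.name!r} has shape {px.shape}, parent is {tuple(self.parent_shape)}"
            )
        if not px.any():
            raise EmptyMaskError(f"mask {self.name!r} has no foreground pixels")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "parent_shape", tuple(int(s) for s in self.parent_shape))

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass
class MaskRegistry:
    """Ordered, unique list of region names persisted with a study."""

    names: list[str] = field(default_factory=list)

    def register(self, name: str) -> "MaskRegistry":
        if not name:
            raise ValueError("region name must be non-empty")
        if name not in self.names:
            self.names.append(name)
        return self

    def merge(self, other: "MaskRegistry") -> "MaskRegistry":
        """Union of registries; local order first, new names appended."""
        merged = MaskRegistry(list(self.names))
        for name in other.names:
            merged.register(name)
        return merged

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


def register_mask_name(registry: MaskRegistry, name: str) -> MaskRegistry:
    """Add ``name`` to the registry (idempotent, order-preserving)."""
    return registry.register(name)


def list_mask_names(registry: MaskRegistry) -> list[str]:
    """Ordered region labels currently registered."""
    return list(registry.names)


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) array to one gray channel with BT.601 luma."""
    if arr.ndim == 2:
        return arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        w = np.asarray(LUMA_WEIGHTS)
        return rgb @ w
    raise LoadError(f"unsupported channel layout with shape {arr.shape}")


def _read_array(path: Path) -> np.ndarray:
    ext = path.suffix.lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise FormatError(f"unsupported image extension {ext!r} for {path}")
    try:
        with Image.open(path) as im:
            return np.asarray(im)
    except (UnidentifiedImageError, OSError) as exc:
        raise LoadError(f"cannot read image file {path}") from exc


def load_image(path, spacing: tuple[float, float, float] | None = None) -> ImageVolume:
    """Load a JPG/TIFF/PNG image as a single-slice volume.

    RGB inputs are converted to one gray channel with BT.601 luma weights
    (0.299, 0.587, 0.114); values are otherwise preserved exactly as read.
    When no spacing is supplied, unit spacing ``(1, 1, 1)`` is assigned —
    the standard fallback when the source format carries no physical
    metadata.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"image file does not exist: {path}")
    gray = _to_gray(_read_array(path))
    return ImageVolume(gray, spacing=spacing or (1.0, 1.0, 1.0))


def _dtype_threshold(arr: np.ndarray) -> float:
    """Binarization threshold: half of the source dtype's maximum.

    Tolerates JPEG compression speckle (values near 0 / near max survive
    binarization unchanged).  Float sources are assumed in [0, 1].
    """
    if np.issubdtype(arr.dtype, np.integer):
        return np.iinfo(arr.dtype).max / 2.0
    if arr.dtype == bool:
        return 0.5
    return 0.5


def load_mask(path, name: str, parent: ImageVolume) -> NamedMask:
    """Load a binary region mask (JPG/PNG) aligned to ``parent``.

    Pixels are binarized at half the source dtype maximum; the mask must
    match the parent grid and contain at least one foreground pixel.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"mask file does not exist: {path}")
    arr = _read_array(path)
    thresh = _dtype_threshold(arr)
    gray = _to_gray(arr)
    binary = gray > thresh
    if binary.shape != parent.shape:
        raise AlignmentError(
            f"mask {path.name} shape {binary.shape} does not match image shape {parent.shape}"
        )
    if not binary.any():
        raise EmptyMaskError(f"mask {path} is empty after binarization")
    return NamedMask(binary, name=name, parent_shape=parent.shape)


def subtract_masks(a: NamedMask, b: NamedMask, name: str) -> NamedMask:
    """Set difference ``a \\ b`` as a new named region.

    The canonical use is removing an organ from the whole-animal region
    (e.g. whole fish minus heart).  Raises if the grids differ or the
    result is empty.
    """
    if a.parent_shape != b.parent_shape:
        raise AlignmentError(
            f"masks {a.name!r} and {b.name!r} have different parent shapes"
        )
    result = a.pixels & ~b.pixels
    if not result.any():
        raise EmptyMaskError(f"subtraction {a.name!r} - {b.name!r} leaves no pixels")
    return NamedMask(result, name=name, parent_shape=a.parent_shape)
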