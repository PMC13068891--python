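"""Pixel-domain primitives: RGB images, binary masks, soft labels, file I/O.

Every operation in the package works on floats in [0, 1]; files on disk are
8-bit PNG/JPEG (masks are 0/255 PNG).  Coordinates are 0-based, row-major
``(row, col)``; rectangles are half-open ``[r0, r1) x [c0, c1)``.  Grayscale
inputs are promoted to three channels rather than rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "FormatError",
    "RgbImage",
    "BinaryMask",
    "SoftLabel",
    "LabeledImage",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "resize_image",
    "resize_mask",
    "luminance",
]

#: Rec. 601 luma weights, used wherever a scalar brightness is needed.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class FormatError(ValueError):
    """An image file is missing, unreadable, or malformed."""


@dataclass(frozen=True, eq=False)
class RgbImage:
    """An H x W x 3 array of channel intensities, floats in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 array, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("image dimensions must be >= 1")
        if arr.min() < -1e-9 or arr.max() > 1.0 + 1e-9:
            raise ValueError("channel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", np.clip(arr, 0.0, 1.0))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @classmethod
    def from_array(cls, arr: np.ndarray, clip: bool = False) -> "RgbImage":
        """Build from an array, optionally clipping out-of-range values."""
        arr = np.asarray(arr, dtype=np.float64)
        if clip:
            arr = np.clip(arr, 0.0, 1.0)
        return cls(arr)

    def allclose(self, other: "RgbImage", atol: float = 1e-12) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.pixels, other.pixels, atol=atol, rtol=0.0)
        )


@dataclass(frozen=True, eq=False)
class BinaryMask:
    """An H x W boolean array; ``area`` is the count of true pixels."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.dtype != bool:
            arr = arr.astype(bool)
        if arr.ndim != 2:
            raise ValueError(f"expected H x W boolean array, got shape {arr.shape}")
        object.__setattr__(self, "values", arr)

    @property
    def area(self) -> int:
        return int(self.values.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool(np.array_equal(self.values, other.values))


@dataclass(frozen=True, eq=False)
class SoftLabel:
    """Per-class weights, non-negative and summing to 1 (within 1e-9)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("weights must be a non-empty vector")
        if w.min() < -1e-12:
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
        object.__setattr__(self, "weights", w)

    @classmethod
    def one_hot(cls, index: int, n_classes: int = 2) -> "SoftLabel":
        w = np.zeros(n_classes)
        w[index] = 1.0
        return cls(w)

    @classmethod
    def mix(cls, a: "SoftLabel", b: "SoftLabel", lam: float) -> "SoftLabel":
        """Convex combination ``lam * a + (1 - lam) * b``."""
        return cls(lam * a.weights + (1.0 - lam) * b.weights)

    def allclose(self, other: "SoftLabel", atol: float = 1e-12) -> bool:
        return self.weights.shape == other.weights.shape and bool(
            np.allclose(self.weights, other.weights, atol=atol, rtol=0.0)
        )


@dataclass(frozen=True, eq=False)
class LabeledImage:
    """An image with its class label and optional pixel annotation."""

    image: RgbImage
    label: SoftLabel
    annotation: BinaryMask | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.annotation is not None and self.annotation.shape != self.image.shape:
            raise ValueError(
                f"annotation shape {self.annotation.shape} != image shape {self.image.shape}"
            )


# --------------------------------------------------------------------------
# File I/O (8-bit PNG / JPEG; masks 0/255 PNG)


def read_image(path: str | Path) -> RgbImage:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except FormatError:
        raise
    except Exception as exc:  # PIL raises a zoo of types for bad files
        raise FormatError(f"unreadable image file {path}: {exc}") from exc
    if arr.size == 0:
        raise FormatError(f"zero-sized image: {path}")
    return RgbImage(arr)


def write_image(img: RgbImage, path: str | Path) -> None:
    arr = np.rint(img.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(Path(path))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a mask file; a pixel is true iff its luminance exceeds half scale."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such mask file: {path}")
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
    return BinaryMask(arr > 0.5)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    arr = np.where(mask.values, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def resize_image(img: RgbImage, target: tuple[int, int]) -> RgbImage:
    """Bilinear resize to ``(height, width)``; values clipped to [0, 1]."""
    th, tw = int(target[0]), int(target[1])
    if th < 1 or tw < 1:
        raise ValueError(f"target dimensions must be >= 1, got {(th, tw)}")
    if (th, tw) == img.shape:
        return img
    shrinking = th < img.height or tw < img.width
    out = _sk_resize(
        img.pixels, (th, tw), order=1, mode="reflect",
        anti_aliasing=shrinking, preserve_range=True,
    )
    return RgbImage(np.clip(out, 0.0, 1.0))


def resize_mask(mask: BinaryMask, target: tuple[int, int]) -> BinaryMask:
    """Nearest-neighbour resize of a boolean mask."""
    th, tw = int(target[0]), int(target[1])
    if th < 1 or tw < 1:
        raise ValueError(f"target dimensions must be >= 1, got {(th, tw)}")
    if (th, tw) == mask.shape:
        return mask
    out = _sk_resize(
        mask.values.astype(np.float64), (th, tw), order=0,
        mode="constant", anti_aliasing=False, preserve_range=True,
    )
    return BinaryMask(out > 0.5)


def luminance(pixels: np.ndarray) -> np.ndarray:
    """Rec. 601 luma of an H x W x 3 array, in [0, 1]."""
    return pixels @ LUMA_WEIGHTS
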