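"""Lesion instances: extraction from annotated images, geometric augmentation,
rescaling policy, and a simple on-disk bank format.

A lesion instance is the tight bounding crop of an annotated lesion together
with its mask and mean colour; it is the unit that gets matched against
candidate mucosal sub-regions and pasted/blended into normal images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .image import (
    BinaryMask,
    RgbImage,
    read_image,
    read_mask,
    resize_image,
    resize_mask,
    write_image,
    write_mask,
)

__all__ = [
    "LesionInstance",
    "GeometricTransform",
    "TransformConfig",
    "extract_lesion",
    "sample_transform",
    "apply_transform",
    "geometric_augment",
    "rescale_to_fit",
    "save_lesion_bank",
    "load_lesion_bank",
]

RIGHT_ANGLES = (0.0, 90.0, 180.0, 270.0)


@dataclass(frozen=True, eq=False)
class LesionInstance:
    """A cropped lesion patch with a tight mask and its mean colour."""

    patch: RgbImage
    mask: BinaryMask
    mean_colour: np.ndarray
    source_id: str = ""
    fold_tag: int | None = None

    def __post_init__(self) -> None:
        if self.mask.shape != self.patch.shape:
            raise ValueError("mask and patch dimensions differ")
        if self.mask.area == 0:
            raise ValueError("lesion mask is empty")
        v = self.mask.values
        if not (v[0].any() and v[-1].any() and v[:, 0].any() and v[:, -1].any()):
            raise ValueError("mask is not tight: it must touch all four crop edges")
        object.__setattr__(
            self, "mean_colour", np.asarray(self.mean_colour, dtype=np.float64)
        )


@dataclass(frozen=True)
class GeometricTransform:
    """A concrete flip/rotation draw, recorded for provenance."""

    flip_h: bool = False
    flip_v: bool = False
    rotation_deg: float = 0.0


@dataclass(frozen=True)
class TransformConfig:
    """Distribution the geometric draws come from.

    Flips are Bernoulli(1/2) each; the rotation angle is uniform over
    ``angles``.  Right angles (the default set) transform the mask without
    interpolation so its area is preserved exactly; arbitrary angles use
    nearest-neighbour masks.
    """

    flip_probability: float = 0.5
    angles: tuple[float, ...] = RIGHT_ANGLES


def _mean_over_mask(pixels: np.ndarray, values: np.ndarray) -> np.ndarray:
    return pixels[values].mean(axis=0)


def extract_lesion(img: RgbImage, annotation: BinaryMask, source_id: str = "") -> LesionInstance:
    """Crop an annotated lesion to its tight bounding box."""
    if annotation.shape != img.shape:
        raise ValueError("annotation dimensions differ from the image")
    if annotation.area == 0:
        raise ValueError("annotation is empty")
    rows = np.flatnonzero(annotation.values.any(axis=1))
    cols = np.flatnonzero(annotation.values.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    patch = RgbImage(img.pixels[r0:r1, c0:c1])
    mask = BinaryMask(annotation.values[r0:r1, c0:c1])
    mean = _mean_over_mask(patch.pixels, mask.values)
    return LesionInstance(patch, mask, mean, source_id=source_id)


def sample_transform(rng: np.random.Generator, cfg: TransformConfig | None = None) -> GeometricTransform:
    cfg = cfg or TransformConfig()
    flip_h = bool(rng.random() < cfg.flip_probability)
    flip_v = bool(rng.random() < cfg.flip_probability)
    angle = float(cfg.angles[int(rng.integers(len(cfg.angles)))])
    return GeometricTransform(flip_h=flip_h, flip_v=flip_v, rotation_deg=angle)


def apply_transform(les: LesionInstance, t: GeometricTransform) -> LesionInstance:
    """Apply flips then rotation; re-crop so the mask stays tight."""
    pix = les.patch.pixels
    msk = les.mask.values
    if t.flip_h:
        pix = pix[:, ::-1]
        msk = msk[:, ::-1]
    if t.flip_v:
        pix = pix[::-1]
        msk = msk[::-1]
    angle = float(t.rotation_deg) % 360.0
    if angle in RIGHT_ANGLES:
        k = int(angle // 90)
        pix = np.rot90(pix, k)
        msk = np.rot90(msk, k)
    elif angle != 0.0:
        # Arbitrary angle: bilinear patch, nearest-neighbour mask.  Pixels
        # falling outside the original support take the lesion's mean colour
        # to avoid spurious dark gradients at the crop corners.
        pix = _sk_rotate(pix, angle, resize=True, order=1, mode="constant", cval=0.0)
        msk_f = _sk_rotate(
            msk.astype(np.float64), angle, resize=True, order=0, mode="constant", cval=0.0
        )
        inside = _sk_rotate(
            np.ones_like(les.mask.values, dtype=np.float64), angle,
            resize=True, order=0, mode="constant", cval=0.0,
        ) > 0.5
        pix = np.where(inside[..., None], pix, les.mean_colour)
        msk = msk_f > 0.5
    img = RgbImage.from_array(np.ascontiguousarray(pix), clip=True)
    out = extract_lesion(img, BinaryMask(np.ascontiguousarray(msk)), source_id=les.source_id)
    return replace(out, fold_tag=les.fold_tag)


def geometric_augment(
    les: LesionInstance,
    rng: np.random.Generator,
    cfg: TransformConfig | None = None,
) -> tuple[LesionInstance, GeometricTransform]:
    """Draw a random flip/rotation and apply it."""
    t = sample_transform(rng, cfg)
    return apply_transform(les, t), t


def rescale_to_fit(
    les: LesionInstance,
    frame_shape: tuple[int, int],
    max_fraction: float = 0.5,
) -> LesionInstance:
    """Downscale a lesion so its longer side is at most ``max_fraction`` of
    the frame's shorter side.  Never upscales; returns the input untouched
    when it already fits."""
    if not 0.0 < max_fraction <= 1.0:
        raise ValueError("max_fraction must lie in (0, 1]")
    limit = max(1, int(max_fraction * min(frame_shape)))
    ph, pw = les.patch.shape
    longest = max(ph, pw)
    if longest <= limit:
        return les
    scale = limit / longest
    th = max(1, int(round(ph * scale)))
    tw = max(1, int(round(pw * scale)))
    patch = resize_image(les.patch, (th, tw))
    mask = resize_mask(les.mask, (th, tw))
    if mask.area == 0:
        raise ValueError("lesion mask vanished under the required downscale")
    out = extract_lesion(patch, mask, source_id=les.source_id)
    return replace(out, fold_tag=les.fold_tag)


# --------------------------------------------------------------------------
# On-disk bank: patch/mask PNG pairs plus a JSON index.


def save_lesion_bank(bank: list[LesionInstance], out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = []
    for i, les in enumerate(bank):
        patch_name = f"lesion_{i:04d}.png"
        mask_name = f"lesion_{i:04d}_mask.png"
        write_image(les.patch, out_dir / patch_name)
        write_mask(les.mask, out_dir / mask_name)
        index.append(
            {
                "patch": patch_name,
                "mask": mask_name,
                "source_id": les.source_id,
                "fold_tag": les.fold_tag,
                "mean_colour": [round(float(c), 8) for c in les.mean_colour],
            }
        )
    (out_dir / "index.json").write_text(json.dumps(index, indent=1, sort_keys=True))
    return out_dir


def load_lesion_bank(bank_dir: str | Path) -> list[LesionInstance]:
    bank_dir = Path(bank_dir)
    index = json.loads((bank_dir / "index.json").read_text())
    bank = []
    for entry in index:
        patch = read_image(bank_dir / entry["patch"])
        mask = read_mask(bank_dir / entry["mask"])
        les = extract_lesion(patch, mask, source_id=entry["source_id"])
        bank.append(replace(les, fold_tag=entry["fold_tag"]))
    return bank
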