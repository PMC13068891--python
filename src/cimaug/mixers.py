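"""Baseline multi-image augmentations: MixUp, CutMix, random copy-paste.

MixUp forms ``x_new = lam * x_a + (1 - lam) * x_b`` with the labels mixed by
the same coefficient, ``lam ~ Beta(beta, beta)`` when not given.  CutMix cuts
a rectangular patch from one image into the other and mixes the labels by the
realised patch-area fraction.  Random copy-paste composites an annotated
lesion instance at a uniformly random position with no blending — the naive
instance-level baseline the region-aware pipeline is compared against.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .image import (
    BinaryMask,
    LabeledImage,
    RgbImage,
    SoftLabel,
    resize_image,
    resize_mask,
)
from .lesions import LesionInstance, extract_lesion

__all__ = ["MixMethod", "MixResult", "mixup", "cutmix", "random_copy_paste"]

#: Default Beta-distribution parameter for the MixUp coefficient.
DEFAULT_MIXUP_BETA = 0.2


class MixMethod(str, enum.Enum):
    MIXUP = "mixup"
    CUTMIX = "cutmix"
    RANDOM_PASTE = "random_paste"


@dataclass(frozen=True, eq=False)
class MixResult:
    """Output of a baseline mixer.

    ``mix_coefficient`` is the weight of source ``a`` in the label; for
    CutMix it equals the clipped patch area divided by the frame area
    exactly.  ``patch_rect`` is the half-open ``(r0, r1, c0, c1)`` rectangle
    of the pasted patch where one exists.
    """

    image: RgbImage
    label: SoftLabel
    mix_coefficient: float
    method: MixMethod
    patch_rect: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mix_coefficient <= 1.0:
            raise ValueError("mix_coefficient must lie in [0, 1]")


def _check_same_dims(a: LabeledImage, b: LabeledImage) -> None:
    if a.image.shape != b.image.shape:
        raise ValueError(f"dimension mismatch: {a.image.shape} vs {b.image.shape}")


def mixup(
    a: LabeledImage,
    b: LabeledImage,
    lam: float | None = None,
    rng: np.random.Generator | None = None,
    beta: float = DEFAULT_MIXUP_BETA,
) -> MixResult:
    """Linear interpolation of two images and their labels."""
    _check_same_dims(a, b)
    if lam is None:
        if rng is None:
            raise ValueError("either lam or rng must be provided")
        lam = float(rng.beta(beta, beta))
    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must lie in [0, 1], got {lam}")
    pixels = lam * a.image.pixels + (1.0 - lam) * b.image.pixels
    label = SoftLabel.mix(a.label, b.label, lam)
    return MixResult(RgbImage.from_array(pixels, clip=True), label, lam, MixMethod.MIXUP)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def cutmix(a: LabeledImage, b: LabeledImage, rng: np.random.Generator) -> MixResult:
    """Cut a random rectangle from ``a`` into ``b``; labels mixed by area.

    Sampling: draw ``lam0 ~ Uniform(0, 1)``, set patch dims
    ``(H*sqrt(lam0), W*sqrt(lam0))`` rounded half up, centre the patch
    uniformly over the frame, clip to bounds, then recompute the mixing
    coefficient from the realised (clipped) area so that the label mix is
    exact.
    """
    _check_same_dims(a, b)
    h, w = a.image.shape
    lam0 = float(rng.uniform(0.0, 1.0))
    ph = min(_round_half_up(h * math.sqrt(lam0)), h)
    pw = min(_round_half_up(w * math.sqrt(lam0)), w)
    rc = int(rng.integers(0, h))
    cc = int(rng.integers(0, w))
    r0 = max(0, min(rc - ph // 2, h))
    c0 = max(0, min(cc - pw // 2, w))
    r1 = min(r0 + ph, h)
    c1 = min(c0 + pw, w)
    area = max(0, r1 - r0) * max(0, c1 - c0)
    lam = area / (h * w)
    pixels = b.image.pixels.copy()
    pixels[r0:r1, c0:c1] = a.image.pixels[r0:r1, c0:c1]
    label = SoftLabel.mix(a.label, b.label, lam)
    return MixResult(
        RgbImage(pixels), label, lam, MixMethod.CUTMIX, patch_rect=(r0, r1, c0, c1)
    )


def random_copy_paste(
    background: LabeledImage,
    lesion: LesionInstance,
    rng: np.random.Generator,
    label: SoftLabel | None = None,
) -> MixResult:
    """Hard-paste a lesion instance at a uniformly random valid position.

    The output label is the pure lesion class (one-hot on class index 1
    unless ``label`` is given).  A lesion larger than the frame is downscaled
    by the minimal factor that makes it fit; it is never upscaled.
    """
    h, w = background.image.shape
    ph, pw = lesion.patch.shape
    scale = min(1.0, h / ph, w / pw)
    if scale < 1.0:
        th = max(1, min(h, int(math.floor(ph * scale))))
        tw = max(1, min(w, int(math.floor(pw * scale))))
        patch = resize_image(lesion.patch, (th, tw))
        mask = resize_mask(lesion.mask, (th, tw))
        if mask.area == 0:
            raise ValueError("lesion mask vanished under the required downscale")
        lesion = extract_lesion(patch, mask, source_id=lesion.source_id)
    ph, pw = lesion.patch.shape
    if ph > h or pw > w:
        raise ValueError("lesion does not fit inside the background")
    r0 = int(rng.integers(0, h - ph + 1))
    c0 = int(rng.integers(0, w - pw + 1))
    pixels = background.image.pixels.copy()
    sub = pixels[r0 : r0 + ph, c0 : c0 + pw]
    sub[lesion.mask.values] = lesion.patch.pixels[lesion.mask.values]
    if label is None:
        label = SoftLabel.one_hot(1, background.label.weights.size)
    return MixResult(
        RgbImage(pixels), label, 1.0, MixMethod.RANDOM_PASTE,
        patch_rect=(r0, r0 + ph, c0, c0 + pw),
    )


def paste_support(result: MixResult, lesion: LesionInstance) -> BinaryMask:
    """Full-frame support mask of a pasted lesion (for bookkeeping)."""
    if result.patch_rect is None:
        raise ValueError("result carries no patch rectangle")
    r0, r1, c0, c1 = result.patch_rect
    h, w = result.image.shape
    values = np.zeros((h, w), dtype=bool)
    values[r0:r1, c0:c1] = lesion.mask.values[: r1 - r0, : c1 - c0]
    return BinaryMask(values)
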