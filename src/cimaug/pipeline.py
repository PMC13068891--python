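"""Dataset protocol and full augmentation orchestration.

Implements the study protocol: an 80/20 stratified split per class, 5-fold
tags over the training portion, and synthetic lesion generation at a 1:1
ratio with the normal training images (one synthetic lesion-bearing image
per real normal training image), applied only to the training split.  Each
augmentation variant (plain mixers, random paste, region-aware paste with or
without blending, and the blend-weight sweep) produces its own manifest over
identical real-image splits.

Fold hygiene: every synthetic sample inherits the fold tag of its background
image and may only draw lesion sources carrying the same fold tag, so that
whichever fold is held out, no held-out image ever contributed pixels to a
training sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blending import BlendMode, BlendParams, match_superpixel, place_lesion, poisson_blend
from .image import (
    BinaryMask,
    LabeledImage,
    RgbImage,
    SoftLabel,
    resize_image,
    resize_mask,
    write_image,
    write_mask,
)
from .lesions import (
    LesionInstance,
    TransformConfig,
    extract_lesion,
    geometric_augment,
    rescale_to_fit,
)
from .mixers import cutmix, mixup, paste_support, random_copy_paste
from .regions import (
    EmptyRegionError,
    RegionConfig,
    mean_shift_segment,
    select_relevant_region,
    slic_superpixels,
    superpixel_stats,
)
from .seeding import seed_for, substream

__all__ = [
    "CLASSES",
    "NORMAL",
    "LESION",
    "ProtocolConfig",
    "Provenance",
    "AugmentedSample",
    "ManifestRecord",
    "DatasetManifest",
    "ZeroLesionSourcesError",
    "cim_augment",
    "stratified_split",
    "build_augmented_dataset",
    "variant_sweep",
    "sweep_variant_names",
]

logger = logging.getLogger("cimaug")

CLASSES = ("normal", "lesion")
NORMAL, LESION = CLASSES
NORMAL_LABEL = SoftLabel.one_hot(0, 2)
LESION_LABEL = SoftLabel.one_hot(1, 2)

#: Variants that need annotated lesion instances (not whole lesion images).
_INSTANCE_VARIANTS = ("random_paste", "cim_hard", "cim")
#: Default maximum lesion size as a fraction of the shorter frame side.
MAX_LESION_FRACTION = 0.5


class ZeroLesionSourcesError(RuntimeError):
    """A fold has no lesion sources to draw from."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Split / synthesis protocol parameters.

    ``explicit_test_counts`` pins per-class test sizes where a printed
    protocol table must be matched exactly; otherwise the test size per
    class is ``round_half_up(test_fraction * n)``.
    """

    test_fraction: float = 0.2
    n_folds: int = 5
    synthesis_ratio: float = 1.0
    explicit_test_counts: Mapping[str, int] | None = None
    resize_to: tuple[int, int] = (224, 224)
    alpha_sweep: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if any(not 0.0 <= a <= 1.0 for a in self.alpha_sweep):
            raise ValueError("alpha_sweep values must lie in [0, 1]")


@dataclass(frozen=True)
class Provenance:
    """Everything needed to regenerate a synthetic sample bit-exactly."""

    seed: int
    variant: str
    background_source: str
    lesion_source: str = ""
    alpha: float | None = None
    mode: str | None = None
    superpixel_id: int | None = None
    transform: str | None = None
    lam: float | None = None


@dataclass(frozen=True, eq=False)
class AugmentedSample:
    """A generated training image with its label and synthetic-lesion support."""

    image: RgbImage
    label: SoftLabel
    synthetic_mask: BinaryMask
    provenance: Provenance


@dataclass(frozen=True)
class ManifestRecord:
    path: str | None
    cls: str
    split: str | None
    fold: int | None
    origin: str
    source_id: str
    mask_path: str | None = None
    provenance: Provenance | None = None


@dataclass
class DatasetManifest:
    """Bookkeeping of one dataset variant: real/synthetic, splits, folds."""

    records: list[ManifestRecord] = field(default_factory=list)
    variant: str = "default"
    seed: int | None = None
    #: generated samples, populated only when built with ``keep_images=True``
    samples: list[AugmentedSample] = field(default_factory=list)

    def count(self, *, cls: str | None = None, split: str | None = None,
              origin: str | None = None, fold: int | None = None) -> int:
        n = 0
        for r in self.records:
            if cls is not None and r.cls != cls:
                continue
            if split is not None and r.split != split:
                continue
            if origin is not None and r.origin != origin:
                continue
            if fold is not None and r.fold != fold:
                continue
            n += 1
        return n

    def sources(self, *, split: str, cls: str | None = None) -> set[str]:
        out = set()
        for r in self.records:
            if r.split != split or r.origin != "real":
                continue
            if cls is not None and r.cls != cls:
                continue
            out.add(r.source_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            p = r.provenance
            rows.append(
                {
                    "path": r.path or "",
                    "class": r.cls,
                    "split": r.split or "",
                    "fold": "" if r.fold is None else r.fold,
                    "origin": r.origin,
                    "source_id": r.source_id,
                    "mask_path": r.mask_path or "",
                    "seed": "" if p is None else p.seed,
                    "lesion_source": "" if p is None else p.lesion_source,
                    "alpha": "" if p is None or p.alpha is None else p.alpha,
                    "mode": "" if p is None or p.mode is None else p.mode,
                    "superpixel_id": ""
                    if p is None or p.superpixel_id is None
                    else p.superpixel_id,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "path", "class", "split", "fold", "origin", "source_id",
                "mask_path", "seed", "lesion_source", "alpha", "mode",
                "superpixel_id",
            ],
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
# CIM augmentation of a single background image.


def cim_augment(
    background: LabeledImage,
    bank: Sequence[LesionInstance],
    params: BlendParams,
    region_cfg: RegionConfig | None = None,
    rng: np.random.Generator | None = None,
    transform_cfg: TransformConfig | None = None,
    max_lesion_fraction: float = MAX_LESION_FRACTION,
    _seed: int | None = None,
    variant: str = "cim",
) -> AugmentedSample:
    """Run the full region-aware paste-and-blend chain on one normal image.

    Steps: mean-shift clustering -> relevance filtering -> SLIC superpixels
    -> per-superpixel stats -> uniform lesion draw -> geometric augmentation
    -> rescale-to-fit -> colour matching -> centre placement -> blending.
    Raises :class:`EmptyRegionError` when no plausible region exists.
    """
    if not bank:
        raise ValueError("lesion bank is empty")
    region_cfg = region_cfg or RegionConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    img = background.image

    clusters = mean_shift_segment(
        img,
        spatial_bandwidth=region_cfg.spatial_bandwidth,
        range_bandwidth=region_cfg.range_bandwidth,
        max_iter=region_cfg.ms_max_iter,
        max_samples=region_cfg.ms_max_samples,
    )
    region = select_relevant_region(clusters, img, region_cfg.criteria)
    sp = slic_superpixels(
        img, region,
        n_segments=region_cfg.n_segments,
        compactness=region_cfg.compactness,
        iterations=region_cfg.slic_iterations,
    )
    stats = superpixel_stats(img, sp)

    lesion = bank[int(rng.integers(len(bank)))]
    lesion, transform = geometric_augment(lesion, rng, transform_cfg)
    lesion = rescale_to_fit(lesion, img.shape, max_fraction=max_lesion_fraction)
    sp_id = match_superpixel(lesion, stats)
    placement = place_lesion(lesion, img, stats, sp_id)
    blended = poisson_blend(img, lesion, placement, params)

    prov = Provenance(
        seed=-1 if _seed is None else _seed,
        variant=variant,
        background_source=background.source_id,
        lesion_source=lesion.source_id,
        alpha=params.alpha,
        mode=params.mode.value,
        superpixel_id=sp_id,
        transform=(
            f"flip_h={transform.flip_h},flip_v={transform.flip_v},"
            f"rot={transform.rotation_deg:g}"
        ),
    )
    return AugmentedSample(blended, LESION_LABEL, placement.omega, prov)


# --------------------------------------------------------------------------
# Split / fold arithmetic.


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    class_counts: Mapping[str, int],
    cfg: ProtocolConfig,
    rng: np.random.Generator,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-class (train_ids, test_ids) by seeded shuffle without replacement."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cls in sorted(class_counts):
        n = int(class_counts[cls])
        if cfg.explicit_test_counts is not None and cls in cfg.explicit_test_counts:
            k = int(cfg.explicit_test_counts[cls])
            if k > n:
                raise ValueError(f"explicit test count {k} exceeds class total {n}")
        else:
            k = _round_half_up(cfg.test_fraction * n)
        perm = rng.permutation(n)
        test = np.sort(perm[:k])
        train = np.sort(perm[k:])
        out[cls] = (train, test)
    return out


def _assign_folds(ids: np.ndarray, n_folds: int, rng: np.random.Generator) -> dict[int, int]:
    order = rng.permutation(len(ids))
    return {int(ids[j]): int(i % n_folds) for i, j in enumerate(order)}


# --------------------------------------------------------------------------
# Dataset building.


def _resized(item: LabeledImage, size: tuple[int, int]) -> LabeledImage:
    img = resize_image(item.image, size)
    ann = None if item.annotation is None else resize_mask(item.annotation, size)
    return LabeledImage(img, item.label, ann, item.source_id)


def _seed_label(variant: str, alpha: float) -> str:
    return f"cim:{alpha:g}" if variant == "cim" else variant


def build_augmented_dataset(
    normals: Sequence[LabeledImage],
    lesions: Sequence[LabeledImage],
    cfg: ProtocolConfig,
    variant: str,
    seed: int,
    alpha: float = 0.8,
    region_cfg: RegionConfig | None = None,
    externals: Sequence[LabeledImage] = (),
    out_dir: str | Path | None = None,
    keep_images: bool = False,
) -> DatasetManifest:
    """Build one dataset variant under the balancing protocol.

    Generates exactly ``floor(synthesis_ratio * n_normal_train)`` synthetic
    lesion samples, cycling the normal training images as backgrounds in
    shuffled order and restricting lesion sources to same-fold training
    lesions.  ``variant`` is one of ``default, mixup, cutmix, random_paste,
    cim_hard, cim`` (``cim`` uses ``alpha`` with gradient-domain mixing).
    The split and fold assignment depend on ``seed`` only, never on the
    variant, so all variants share identical real-image splits.
    """
    known = ("default", "mixup", "cutmix", "random_paste", "cim_hard", "cim")
    if variant not in known:
        raise ValueError(f"unknown variant {variant!r}; expected one of {known}")
    label = _seed_label(variant, alpha)
    size = cfg.resize_to

    split = stratified_split(
        {NORMAL: len(normals), LESION: len(lesions)}, cfg, substream(seed, "split")
    )
    n_train, n_test = split[NORMAL]
    l_train, l_test = split[LESION]
    folds_rng = substream(seed, "folds")
    n_folds_map = _assign_folds(n_train, cfg.n_folds, folds_rng)
    l_folds_map = _assign_folds(l_train, cfg.n_folds, folds_rng)

    manifest = DatasetManifest(variant=label if variant == "cim" else variant, seed=seed)
    for cls, items, tr, te, fmap in (
        (NORMAL, normals, n_train, n_test, n_folds_map),
        (LESION, lesions, l_train, l_test, l_folds_map),
    ):
        for i in tr:
            manifest.records.append(
                ManifestRecord(None, cls, "train", fmap[int(i)], "real", items[int(i)].source_id)
            )
        for i in te:
            manifest.records.append(
                ManifestRecord(None, cls, "test", None, "real", items[int(i)].source_id)
            )
    for item in externals:
        cls = LESION if item.label.weights[1] >= 0.5 else NORMAL
        manifest.records.append(
            ManifestRecord(None, cls, "external_test", None, "real", item.source_id)
        )

    n_syn = int(math.floor(cfg.synthesis_ratio * len(n_train)))
    if variant == "default" or n_syn == 0:
        if out_dir is not None:
            _write_outputs(manifest, [], out_dir)
            manifest.write_csv(Path(out_dir) / "manifest.csv")
        return manifest

    # Same-fold lesion pools (resized once, extracted once).
    lesion_train_by_fold: dict[int, list[LabeledImage]] = {f: [] for f in range(cfg.n_folds)}
    for i in l_train:
        lesion_train_by_fold[l_folds_map[int(i)]].append(_resized(lesions[int(i)], size))
    bank_by_fold: dict[int, list[LesionInstance]] = {}
    if variant in _INSTANCE_VARIANTS:
        for f, items in lesion_train_by_fold.items():
            bank = []
            for item in items:
                if item.annotation is None or item.annotation.area == 0:
                    continue
                les = extract_lesion(item.image, item.annotation, source_id=item.source_id)
                bank.append(replace(les, fold_tag=f))
            bank_by_fold[f] = bank
    empty = [
        f
        for f in range(cfg.n_folds)
        if not (bank_by_fold.get(f) if variant in _INSTANCE_VARIANTS else lesion_train_by_fold[f])
    ]
    if empty:
        raise ZeroLesionSourcesError(f"folds without lesion sources: {empty}")

    bg_order = substream(seed, "backgrounds", label).permutation(len(n_train))
    cycle = [int(n_train[j]) for j in bg_order]
    params = _variant_blend_params(variant, alpha)

    samples: list[tuple[AugmentedSample, int]] = []
    attempts = 0
    pos = 0
    while len(samples) < n_syn:
        if attempts >= n_syn + len(cycle):
            raise RuntimeError("too many unusable backgrounds; cannot reach the synthesis count")
        bg_idx = cycle[pos % len(cycle)]
        pos += 1
        i = len(samples)
        s = seed_for(seed, "sample", label, i, attempts)
        rng = np.random.default_rng(s)
        fold = n_folds_map[bg_idx]
        background = _resized(normals[bg_idx], size)
        try:
            sample = _make_synthetic(
                variant, background, lesion_train_by_fold[fold],
                bank_by_fold.get(fold, []), params, region_cfg, rng, s, label,
            )
        except EmptyRegionError:
            logger.warning(
                "skipping background %s: no relevant region", background.source_id
            )
            attempts += 1
            continue
        attempts += 1
        samples.append((sample, fold))

    paths = _write_outputs(manifest, samples, out_dir) if out_dir is not None else [None] * len(samples)
    for (sample, fold), path in zip(samples, paths):
        manifest.records.append(
            ManifestRecord(
                path=None if path is None else str(path),
                cls=LESION,
                split="train",
                fold=fold,
                origin="synthetic",
                source_id=sample.provenance.background_source,
                provenance=sample.provenance,
            )
        )
    if keep_images:
        manifest.samples = [s for s, _ in samples]
    if out_dir is not None:
        manifest.write_csv(Path(out_dir) / "manifest.csv")
    return manifest


def _variant_blend_params(variant: str, alpha: float) -> BlendParams | None:
    if variant == "cim_hard":
        return BlendParams(alpha=1.0, mode=BlendMode.HARD)
    if variant == "cim":
        return BlendParams(alpha=alpha, mode=BlendMode.GRADIENT_MIX)
    return None


def _make_synthetic(
    variant: str,
    background: LabeledImage,
    lesion_images: Sequence[LabeledImage],
    bank: Sequence[LesionInstance],
    params: BlendParams | None,
    region_cfg: RegionConfig | None,
    rng: np.random.Generator,
    seed: int,
    label: str,
) -> AugmentedSample:
    h, w = background.image.shape
    if variant in ("mixup", "cutmix"):
        partner = lesion_images[int(rng.integers(len(lesion_images)))]
        if variant == "mixup":
            res = mixup(partner, background, lam=None, rng=rng)
        else:
            res = cutmix(partner, background, rng)
        mask = np.zeros((h, w), dtype=bool)
        if res.patch_rect is not None:
            r0, r1, c0, c1 = res.patch_rect
            mask[r0:r1, c0:c1] = True
        else:
            mask[:] = True  # mixup touches every pixel
        prov = Provenance(
            seed=seed, variant=label,
            background_source=background.source_id,
            lesion_source=partner.source_id,
            lam=res.mix_coefficient,
        )
        return AugmentedSample(res.image, res.label, BinaryMask(mask), prov)
    if variant == "random_paste":
        lesion = bank[int(rng.integers(len(bank)))]
        res = random_copy_paste(background, lesion, rng)
        prov = Provenance(
            seed=seed, variant=label,
            background_source=background.source_id,
            lesion_source=lesion.source_id,
        )
        return AugmentedSample(res.image, res.label, paste_support(res, lesion), prov)
    # cim / cim_hard
    assert params is not None
    sample = cim_augment(
        background, bank, params, region_cfg=region_cfg, rng=rng,
        _seed=seed, variant=label,
    )
    return sample


def _write_outputs(
    manifest: DatasetManifest,
    samples: Sequence[tuple[AugmentedSample, int]],
    out_dir: str | Path,
) -> list[Path]:
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    stem = manifest.variant.replace(":", "_a")
    for i, (sample, _fold) in enumerate(samples):
        name = f"{stem}_syn_{i:04d}"
        path = img_dir / f"{name}.png"
        write_image(sample.image, path)
        write_mask(sample.synthetic_mask, img_dir / f"{name}_mask.png")
        paths.append(path.relative_to(out_dir))
    return paths


# --------------------------------------------------------------------------
# Variant sweep.


def sweep_variant_names(cfg: ProtocolConfig) -> list[str]:
    return ["default", "mixup", "cutmix", "random_paste", "cim_hard"] + [
        f"cim:{a:g}" for a in cfg.alpha_sweep
    ]


def variant_sweep(
    normals: Sequence[LabeledImage],
    lesions: Sequence[LabeledImage],
    cfg: ProtocolConfig,
    seed: int,
    region_cfg: RegionConfig | None = None,
) -> dict[str, DatasetManifest]:
    """One manifest per training variant; identical real splits throughout."""
    out: dict[str, DatasetManifest] = {}
    for name in sweep_variant_names(cfg):
        if name.startswith("cim:"):
            variant, alpha = "cim", float(name.split(":")[1])
        else:
            variant, alpha = name, 0.8
        out[name] = build_augmented_dataset(
            normals, lesions, cfg, variant, seed, alpha=alpha, region_cfg=region_cfg
        )
    return out
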