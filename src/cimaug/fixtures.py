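"""Synthetic endoscopy-style fixtures: mucosa backgrounds and lesion/mask pairs.

Every stage of the augmentation chain is testable without clinical data.
The generator emulates the qualitative structure of endoscopic frames:
smooth band-limited mucosal texture mapped into a reddish-pink palette, a
radial illumination vignette, dark corners outside the circular field of
view, a few specular highlights, and — for lesion images — one irregular
blob (a smoothed radial polygon) whose interior colour is shifted and
retextured, with the exact blob support as the annotation mask.

It does not model device optics, photorealistic mucosal microstructure, or
multi-lesion frames; what passes on these fixtures demonstrates the
machinery, not clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as _sk_polygon

from .image import BinaryMask, LabeledImage, RgbImage, read_image, read_mask, write_image, write_mask
from .pipeline import DatasetManifest, LESION, LESION_LABEL, ManifestRecord, NORMAL, NORMAL_LABEL
from .seeding import substream

__all__ = [
    "FixtureConfig",
    "make_mucosa_image",
    "make_lesion_image",
    "make_dataset",
    "make_labeled_sets",
    "load_fixture_dataset",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Tunables of the fixture generator.

    ``border_corner_radius`` and ``lesion_radius_range`` are in pixels;
    ``None`` means size-proportional defaults (0.68 and (0.10, 0.22) of the
    shorter image side).  ``mucosa_palette`` is a per-channel (low, high)
    band the texture is mapped into; ``lesion_colour_shift`` is added to the
    blob interior.
    """

    image_size: tuple[int, int] = (224, 224)
    mucosa_palette: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.55, 0.25, 0.25),
        (0.85, 0.50, 0.50),
    )
    texture_scale: float = 12.0
    vignette_strength: float = 0.35
    border_corner_radius: float | None = None
    specular_count: int = 3
    lesion_radius_range: tuple[float, float] | None = None
    lesion_colour_shift: tuple[float, float, float] = (-0.15, -0.02, 0.05)
    lesion_irregularity: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = (np.asarray(b) for b in self.mucosa_palette)
        if low.min() < 0 or high.max() > 1 or (low > high).any():
            raise ValueError("mucosa palette bands must be ordered and within [0, 1]")
        r = self.resolved_radius_range()
        if r[0] <= 0 or r[1] < r[0] or 2 * r[1] > min(self.image_size):
            raise ValueError("lesion radius range must be positive and fit the frame")

    def resolved_border_radius(self) -> float:
        if self.border_corner_radius is not None:
            return float(self.border_corner_radius)
        return 0.68 * min(self.image_size)

    def resolved_radius_range(self) -> tuple[float, float]:
        if self.lesion_radius_range is not None:
            return (float(self.lesion_radius_range[0]), float(self.lesion_radius_range[1]))
        s = min(self.image_size)
        return (0.10 * s, 0.22 * s)


def _band_noise(shape: tuple[int, int], scale: float, rng: np.random.Generator) -> np.ndarray:
    """Low-pass filtered white noise, min-max normalised to [0, 1]."""
    noise = gaussian_filter(rng.standard_normal(shape), sigma=max(scale, 1e-6))
    lo, hi = noise.min(), noise.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5)
    return (noise - lo) / (hi - lo)


def _radial_distance(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return np.hypot(rr - (h - 1) / 2.0, cc - (w - 1) / 2.0)


def make_mucosa_image(cfg: FixtureConfig, rng: np.random.Generator) -> RgbImage:
    """A normal-tissue frame: textured mucosa, vignette, dark border, speculars."""
    h, w = cfg.image_size
    low, high = (np.asarray(b, dtype=np.float64) for b in cfg.mucosa_palette)
    pixels = np.empty((h, w, 3))
    for ch in range(3):
        t = _band_noise((h, w), cfg.texture_scale, rng)
        pixels[..., ch] = low[ch] + t * (high[ch] - low[ch])

    dist = _radial_distance((h, w))
    dmax = dist.max()
    if dmax > 0 and cfg.vignette_strength > 0:
        pixels *= (1.0 - cfg.vignette_strength * (dist / dmax) ** 2)[..., None]

    border = dist > cfg.resolved_border_radius()
    pixels[border] *= 0.05  # endoscope mount: near-black corners

    spec_r = max(1.5, 0.02 * min(h, w))
    for _ in range(cfg.specular_count):
        # rejection-free placement inside the field of view
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, max(cfg.resolved_border_radius() - 2 * spec_r, 1.0))
        r0 = (h - 1) / 2.0 + rad * np.sin(ang)
        c0 = (w - 1) / 2.0 + rad * np.cos(ang)
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        spot = np.hypot(rr - r0, cc - c0)
        pixels[spot <= spec_r] = 0.98
    return RgbImage(np.clip(pixels, 0.0, 1.0))


def _blob_mask(
    cfg: FixtureConfig, shape: tuple[int, int], rng: np.random.Generator
) -> BinaryMask:
    """Irregular blob: radial polygon with smoothed perturbed vertex radii."""
    h, w = shape
    r_lo, r_hi = cfg.resolved_radius_range()
    radius = float(rng.uniform(r_lo, r_hi))
    border = cfg.resolved_border_radius()
    margin = radius * (1.0 + cfg.lesion_irregularity) + 2.0
    max_off = max(border - margin, 1.0)
    ang0 = rng.uniform(0, 2 * np.pi)
    off = rng.uniform(0, max_off)
    cy = (h - 1) / 2.0 + off * np.sin(ang0)
    cx = (w - 1) / 2.0 + off * np.cos(ang0)

    n_vertices = 48
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    perturb = rng.uniform(-1.0, 1.0, n_vertices)
    # circular moving average smooths the radius sequence
    kernel = np.ones(7) / 7.0
    perturb = np.convolve(np.tile(perturb, 3), kernel, mode="same")[n_vertices : 2 * n_vertices]
    radii = radius * (1.0 + cfg.lesion_irregularity * perturb)
    rr, cc = _sk_polygon(cy + radii * np.sin(theta), cx + radii * np.cos(theta), shape)
    values = np.zeros(shape, dtype=bool)
    values[rr, cc] = True
    return BinaryMask(values)


def make_lesion_image(
    cfg: FixtureConfig, rng: np.random.Generator
) -> tuple[RgbImage, BinaryMask]:
    """A lesion frame: mucosa background plus one colour-shifted blob."""
    background = make_mucosa_image(cfg, rng)
    mask = _blob_mask(cfg, cfg.image_size, rng)
    pixels = background.pixels.copy()
    shift = np.asarray(cfg.lesion_colour_shift)
    retexture = gaussian_filter(
        rng.standard_normal(cfg.image_size), sigma=max(cfg.texture_scale / 2.0, 1e-6)
    )
    scale = max(np.abs(retexture).max(), 1e-12)
    retexture = 0.02 * retexture / scale
    pixels[mask.values] += shift + retexture[mask.values, None]
    return RgbImage(np.clip(pixels, 0.0, 1.0)), mask


def make_dataset(
    cfg: FixtureConfig,
    n_normal: int,
    n_lesion: int,
    out_dir: str | Path,
) -> DatasetManifest:
    """Write a fixture dataset (PNGs + masks + manifest CSV), seeded by cfg.seed."""
    if n_normal < 0 or n_lesion < 0:
        raise ValueError("counts must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = DatasetManifest(variant="fixtures", seed=cfg.seed)
    for i in range(n_normal):
        rng = substream(cfg.seed, "fixtures", NORMAL, i)
        img = make_mucosa_image(cfg, rng)
        name = f"normal_{i:04d}.png"
        write_image(img, out_dir / name)
        manifest.records.append(
            ManifestRecord(name, NORMAL, None, None, "real", f"normal_{i:04d}")
        )
    for i in range(n_lesion):
        rng = substream(cfg.seed, "fixtures", LESION, i)
        img, mask = make_lesion_image(cfg, rng)
        name = f"lesion_{i:04d}.png"
        mask_name = f"lesion_{i:04d}_mask.png"
        write_image(img, out_dir / name)
        write_mask(mask, out_dir / mask_name)
        manifest.records.append(
            ManifestRecord(name, LESION, None, None, "real", f"lesion_{i:04d}", mask_path=mask_name)
        )
    manifest.write_csv(out_dir / "manifest.csv")
    return manifest


def make_labeled_sets(
    cfg: FixtureConfig, n_normal: int, n_lesion: int
) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """In-memory (normals, lesions) lists, seeded identically to make_dataset."""
    normals = []
    for i in range(n_normal):
        rng = substream(cfg.seed, "fixtures", NORMAL, i)
        normals.append(
            LabeledImage(make_mucosa_image(cfg, rng), NORMAL_LABEL, None, f"normal_{i:04d}")
        )
    lesions = []
    for i in range(n_lesion):
        rng = substream(cfg.seed, "fixtures", LESION, i)
        img, mask = make_lesion_image(cfg, rng)
        lesions.append(LabeledImage(img, LESION_LABEL, mask, f"lesion_{i:04d}"))
    return normals, lesions


def load_fixture_dataset(
    in_dir: str | Path,
) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """Read a fixture directory back into (normals, lesions) image lists."""
    import pandas as pd

    in_dir = Path(in_dir)
    frame = pd.read_csv(in_dir / "manifest.csv", keep_default_na=False)
    normals: list[LabeledImage] = []
    lesions: list[LabeledImage] = []
    for _, row in frame.iterrows():
        img = read_image(in_dir / row["path"])
        if row["class"] == NORMAL:
            normals.append(LabeledImage(img, NORMAL_LABEL, None, row["source_id"]))
        else:
            ann = read_mask(in_dir / row["mask_path"]) if row["mask_path"] else None
            lesions.append(LabeledImage(img, LESION_LABEL, ann, row["source_id"]))
    return normals, lesions
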