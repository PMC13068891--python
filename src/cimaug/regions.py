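"""Region proposal: mean-shift tissue clustering, biologically relevant
region selection, and SLIC superpixel placement candidates.

The placement side of the augmentation needs anatomically plausible target
regions.  The chain is: (1) mean-shift clustering on joint spatial+colour
features delineates homogeneous tissue regions; (2) clusters are filtered by
rule-based relevance criteria (a luminance band that drops the dark endoscope
border and specular glare, an optional mucosa colour gamut, and a minimum
area fraction); (3) the surviving region is subdivided into SLIC superpixels
that serve as candidate paste locations; (4) per-superpixel appearance
statistics feed the colour-matching step.

Mean shift runs at unit bandwidth on features pre-scaled by a spatial
bandwidth (pixels) and a range bandwidth (colour units in CIELAB/100, a
perceptually uniform space), which realises independent spatial and range
bandwidths with a single isotropic kernel.  For speed the modes are found on
a regular pixel subgrid and every pixel is then assigned to its nearest mode;
both steps are deterministic for fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2lab
from skimage.segmentation import slic as _sk_slic
from sklearn.cluster import MeanShift

from .image import BinaryMask, RgbImage, luminance

__all__ = [
    "ClusterMap",
    "SuperpixelMap",
    "SuperpixelStats",
    "RelevanceCriteria",
    "RegionConfig",
    "EmptyRegionError",
    "mean_shift_segment",
    "select_relevant_region",
    "slic_superpixels",
    "superpixel_stats",
]


class EmptyRegionError(RuntimeError):
    """No cluster passed the relevance criteria; the image is unusable for pasting."""


@dataclass(frozen=True, eq=False)
class ClusterMap:
    """Mean-shift clustering of an image.

    ``labels`` holds a cluster id >= 0 for every pixel (-1 marks excluded
    pixels, unused by the segmentation itself); per-cluster mean colours are
    in RGB for downstream appearance rules.
    """

    labels: np.ndarray
    n_clusters: int
    cluster_mean_colour: np.ndarray
    cluster_area: np.ndarray

    def __post_init__(self) -> None:
        valid = self.labels >= 0
        if valid.any() and self.labels[valid].max() >= self.n_clusters:
            raise ValueError("cluster label exceeds n_clusters")
        if int(self.cluster_area.sum()) != int(valid.sum()):
            raise ValueError("cluster areas do not partition the labelled pixels")


@dataclass(frozen=True, eq=False)
class SuperpixelMap:
    """SLIC partition of the relevant region; -1 outside it."""

    labels: np.ndarray
    n_superpixels: int


@dataclass(frozen=True, eq=False)
class SuperpixelStats:
    """Per-superpixel mean colour (RGB), centroid (row, col) and area."""

    mean_colour: np.ndarray
    centroid: np.ndarray
    area: np.ndarray

    def __len__(self) -> int:
        return self.mean_colour.shape[0]


@dataclass(frozen=True)
class RelevanceCriteria:
    """Rule-based cluster filter standing in for 'biological relevance'.

    Defaults drop the dark endoscope border (low luminance), specular
    highlights (high luminance) and fragments below 5% of the frame.  The
    optional colour gamut bounds the cluster mean RGB (useful to pin the
    reddish mucosa band when backgrounds are more varied).
    """

    min_luminance: float = 0.15
    max_luminance: float = 0.92
    min_area_fraction: float = 0.05
    colour_low: tuple[float, float, float] | None = None
    colour_high: tuple[float, float, float] | None = None


@dataclass(frozen=True)
class RegionConfig:
    """All tunables of the region-proposal chain in one place."""

    spatial_bandwidth: float = 16.0
    range_bandwidth: float = 0.12
    ms_max_iter: int = 300
    ms_max_samples: int = 1500
    criteria: RelevanceCriteria = field(default_factory=RelevanceCriteria)
    n_segments: int = 64
    compactness: float = 10.0
    slic_iterations: int = 10


def _colour_features(pixels: np.ndarray) -> np.ndarray:
    """CIELAB scaled by 1/100 so one unit is roughly the full lightness range."""
    return rgb2lab(pixels) / 100.0


def mean_shift_segment(
    img: RgbImage,
    spatial_bandwidth: float = 16.0,
    range_bandwidth: float = 0.12,
    max_iter: int = 300,
    max_samples: int = 1500,
) -> ClusterMap:
    """Cluster pixels by mode seeking on joint (row, col, colour) features.

    After mode seeking, spatially adjacent clusters whose mean colours are
    closer than the range bandwidth are merged, so a flat region fragmented
    by the spatial term collapses to a single cluster.
    """
    if spatial_bandwidth <= 0 or range_bandwidth <= 0:
        raise ValueError("bandwidths must be positive")
    h, w = img.shape
    lab = _colour_features(img.pixels)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    feats = np.concatenate(
        [
            rr[..., None] / spatial_bandwidth,
            cc[..., None] / spatial_bandwidth,
            lab / range_bandwidth,
        ],
        axis=-1,
    ).reshape(-1, 5)

    # Deterministic regular-grid subsample for the mode search.
    stride = 1
    while (h // stride + 1) * (w // stride + 1) > max_samples and stride < min(h, w):
        stride += 1
    sub_idx = (rr[::stride, ::stride] * w + cc[::stride, ::stride]).ravel()
    ms = MeanShift(bandwidth=1.0, bin_seeding=True, max_iter=max_iter, cluster_all=True)
    ms.fit(feats[sub_idx])
    labels = ms.predict(feats).reshape(h, w).astype(np.int64)

    labels = _merge_similar_adjacent(labels, lab, range_bandwidth)
    n = int(labels.max()) + 1
    flat = labels.ravel()
    area = np.bincount(flat, minlength=n)
    mean_colour = np.zeros((n, 3))
    for ch in range(3):
        mean_colour[:, ch] = np.bincount(
            flat, weights=img.pixels[..., ch].ravel(), minlength=n
        ) / np.maximum(area, 1)
    return ClusterMap(labels, n, mean_colour, area)


def _merge_similar_adjacent(
    labels: np.ndarray, colour: np.ndarray, threshold: float
) -> np.ndarray:
    """Union spatially adjacent labels with mean-colour distance < threshold."""
    n = int(labels.max()) + 1
    if n <= 1:
        return labels
    flat = labels.ravel()
    area = np.bincount(flat, minlength=n)
    means = np.zeros((n, colour.shape[-1]))
    for ch in range(colour.shape[-1]):
        means[:, ch] = np.bincount(
            flat, weights=colour[..., ch].ravel(), minlength=n
        ) / np.maximum(area, 1)

    pairs = set()
    for a, b in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        diff = a != b
        pairs.update(zip(a[diff].tolist(), b[diff].tolist()))

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in sorted(pairs):
        if np.linalg.norm(means[a] - means[b]) < threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    roots = np.array([find(i) for i in range(n)])
    _, compact = np.unique(roots, return_inverse=True)
    return compact[labels]


def select_relevant_region(
    clusters: ClusterMap,
    img: RgbImage,
    criteria: RelevanceCriteria | None = None,
) -> BinaryMask:
    """Union of clusters passing all relevance rules, minus out-of-band pixels.

    Pixels below the low-luminance bound (endoscope border) or above the
    high bound (specular highlights) are excluded regardless of their
    cluster's verdict.
    """
    criteria = criteria or RelevanceCriteria()
    lum = luminance(img.pixels)
    total = img.height * img.width
    cluster_lum = luminance(clusters.cluster_mean_colour)

    keep = (cluster_lum >= criteria.min_luminance) & (cluster_lum <= criteria.max_luminance)
    keep &= clusters.cluster_area / total >= criteria.min_area_fraction
    if criteria.colour_low is not None:
        keep &= (clusters.cluster_mean_colour >= np.asarray(criteria.colour_low)).all(axis=1)
    if criteria.colour_high is not None:
        keep &= (clusters.cluster_mean_colour <= np.asarray(criteria.colour_high)).all(axis=1)

    values = keep[clusters.labels]
    values &= (lum >= criteria.min_luminance) & (lum <= criteria.max_luminance)
    if not values.any():
        raise EmptyRegionError("no cluster passes the relevance criteria")
    return BinaryMask(values)


def slic_superpixels(
    img: RgbImage,
    region: BinaryMask,
    n_segments: int = 64,
    compactness: float = 10.0,
    iterations: int = 10,
) -> SuperpixelMap:
    """Partition the relevant region into at most ``n_segments`` superpixels.

    Wraps masked SLIC (k-means alternation in joint colour+position space
    with compactness weighting, seeds on a regular grid, connectivity
    enforced); the raw output is then relabelled consecutively and, if the
    segment budget is exceeded, the smallest segments are merged into their
    most similar spatial neighbours.
    """
    if region.shape != img.shape:
        raise ValueError("region dimensions differ from the image")
    if region.area == 0:
        raise EmptyRegionError("empty region mask")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments == 1:
        labels = np.where(region.values, 0, -1)
        return SuperpixelMap(labels, 1)

    raw = _sk_slic(
        img.pixels,
        n_segments=n_segments,
        compactness=compactness,
        max_num_iter=iterations,
        mask=region.values,
        start_label=1,
        channel_axis=-1,
    )
    labels = raw.astype(np.int64) - 1
    labels[~region.values] = -1
    # Safety: masked SLIC can leave stray region pixels unlabelled (label 0
    # inside the mask maps to -1 here); give them to the nearest labelled
    # neighbour by a small dilation loop.
    labels = _fill_unlabelled(labels, region.values)
    labels = _relabel_consecutive(labels)
    labels = _enforce_budget(labels, img.pixels, n_segments)
    return SuperpixelMap(labels, int(labels.max()) + 1)


def _fill_unlabelled(labels: np.ndarray, region: np.ndarray) -> np.ndarray:
    missing = region & (labels < 0)
    guard = 0
    while missing.any() and guard < labels.size:
        guard += 1
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            shifted = np.roll(labels, (dr, dc), axis=(0, 1))
            if dr == 1:
                shifted[0, :] = -1
            if dr == -1:
                shifted[-1, :] = -1
            if dc == 1:
                shifted[:, 0] = -1
            if dc == -1:
                shifted[:, -1] = -1
            take = missing & (shifted >= 0)
            labels[take] = shifted[take]
            missing = region & (labels < 0)
        if not missing.any():
            break
    if missing.any():  # isolated region pixels with no labelled neighbour
        labels[missing] = labels.max() if labels.max() >= 0 else 0
    return labels


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    inside = labels >= 0
    if not inside.any():
        return labels
    uniq, inv = np.unique(labels[inside], return_inverse=True)
    out = np.full_like(labels, -1)
    out[inside] = inv
    return out


def _enforce_budget(labels: np.ndarray, pixels: np.ndarray, n_segments: int) -> np.ndarray:
    """Merge smallest labels into their closest-colour spatial neighbour
    until the label count fits the budget."""
    while int(labels.max()) + 1 > n_segments:
        n = int(labels.max()) + 1
        flat = labels.ravel()
        valid = flat >= 0
        area = np.bincount(flat[valid], minlength=n)
        means = np.zeros((n, 3))
        for ch in range(3):
            means[:, ch] = np.bincount(
                flat[valid], weights=pixels[..., ch].ravel()[valid], minlength=n
            ) / np.maximum(area, 1)
        smallest = int(np.argmin(np.where(area > 0, area, np.iinfo(np.int64).max)))
        neighbours = set()
        for a, b in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
            sel = (a == smallest) & (b != smallest) & (b >= 0)
            neighbours.update(b[sel].tolist())
            sel = (b == smallest) & (a != smallest) & (a >= 0)
            neighbours.update(a[sel].tolist())
        if not neighbours:
            # No spatial neighbour (disjoint fragment): merge into the
            # globally closest-colour label.
            candidates = [i for i in range(n) if i != smallest and area[i] > 0]
            target = min(candidates, key=lambda i: float(np.linalg.norm(means[i] - means[smallest])))
        else:
            target = min(
                sorted(neighbours),
                key=lambda i: float(np.linalg.norm(means[i] - means[smallest])),
            )
        labels = labels.copy()
        labels[labels == smallest] = target
        labels = _relabel_consecutive(labels)
    return labels


def superpixel_stats(img: RgbImage, sp: SuperpixelMap) -> SuperpixelStats:
    """Exact per-superpixel mean colour, centroid and area."""
    if sp.labels.shape != img.shape:
        raise ValueError("superpixel map dimensions differ from the image")
    n = sp.n_superpixels
    flat = sp.labels.ravel()
    valid = flat >= 0
    lab = flat[valid]
    area = np.bincount(lab, minlength=n)
    if (area == 0).any():
        raise ValueError("superpixel map contains empty labels")
    mean_colour = np.zeros((n, 3))
    for ch in range(3):
        mean_colour[:, ch] = np.bincount(
            lab, weights=img.pixels[..., ch].ravel()[valid], minlength=n
        ) / area
    rr, cc = np.meshgrid(np.arange(img.height), np.arange(img.width), indexing="ij")
    centroid = np.stack(
        [
            np.bincount(lab, weights=rr.ravel()[valid], minlength=n) / area,
            np.bincount(lab, weights=cc.ravel()[valid], minlength=n) / area,
        ],
        axis=1,
    )
    return SuperpixelStats(mean_colour, centroid, area)
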