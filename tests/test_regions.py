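"""Region proposal: clustering, relevance filtering, superpixel partitions."""

import numpy as np
import pytest

from cimaug import (
    BinaryMask,
    RgbImage,
    mean_shift_segment,
    select_relevant_region,
    slic_superpixels,
    superpixel_stats,
)
from cimaug.regions import EmptyRegionError, RelevanceCriteria


@pytest.fixture(scope="module")
def mucosa_clusters(mucosa):
    return mean_shift_segment(mucosa, max_samples=600)


class TestMeanShift:
    def test_constant_image_single_cluster(self):
        img = RgbImage(np.full((40, 40, 3), 0.5))
        cm = mean_shift_segment(img)
        assert cm.n_clusters == 1
        assert (cm.labels == 0).all()
        assert cm.cluster_area[0] == 1600

    def test_two_flat_halves_split_at_midline(self):
        # oracle: connected components of the colour-quantised image are the
        # two halves, so the cluster boundary must be the colour midline
        px = np.zeros((40, 40, 3))
        px[:, :20] = [0.8, 0.2, 0.2]
        px[:, 20:] = [0.2, 0.2, 0.8]
        cm = mean_shift_segment(RgbImage(px))
        assert cm.n_clusters == 2
        assert np.unique(cm.labels[:, :20]).size == 1
        assert np.unique(cm.labels[:, 20:]).size == 1
        assert cm.labels[0, 0] != cm.labels[0, 39]

    def test_deterministic(self, mucosa):
        a = mean_shift_segment(mucosa, max_samples=600)
        b = mean_shift_segment(mucosa, max_samples=600)
        assert np.array_equal(a.labels, b.labels)

    def test_cluster_areas_partition_frame(self, mucosa_clusters, mucosa):
        assert mucosa_clusters.cluster_area.sum() == mucosa.height * mucosa.width
        # brute-force recount
        for k in range(mucosa_clusters.n_clusters):
            assert mucosa_clusters.cluster_area[k] == int((mucosa_clusters.labels == k).sum())

    def test_rejects_nonpositive_bandwidth(self, mucosa):
        with pytest.raises(ValueError):
            mean_shift_segment(mucosa, spatial_bandwidth=0.0)


class TestRelevantRegion:
    def test_dark_corners_excluded(self, mucosa, mucosa_clusters):
        from cimaug.image import luminance

        region = select_relevant_region(mucosa_clusters, mucosa)
        dark = luminance(mucosa.pixels) < 0.15
        assert dark.any()  # the fixture has dark border pixels
        assert not (region.values & dark).any()

    def test_specular_pixels_excluded(self, mucosa, mucosa_clusters):
        from cimaug.image import luminance

        region = select_relevant_region(mucosa_clusters, mucosa)
        bright = luminance(mucosa.pixels) > 0.92
        assert bright.any()
        assert not (region.values & bright).any()

    def test_all_dark_image_raises(self):
        img = RgbImage(np.full((30, 30, 3), 0.02))
        cm = mean_shift_segment(img)
        with pytest.raises(EmptyRegionError):
            select_relevant_region(cm, img)

    def test_small_cluster_dropped_by_area_fraction(self):
        # one large pink cluster and one tiny distinct cluster
        px = np.tile(np.array([0.8, 0.4, 0.4]), (50, 50, 1))
        px[:3, :3] = [0.2, 0.6, 0.2]
        img = RgbImage(px)
        cm = mean_shift_segment(img)
        region = select_relevant_region(cm, img, RelevanceCriteria(min_area_fraction=0.05))
        assert not region.values[:3, :3].any()
        assert region.values[10:, 10:].all()
        # brute-force check that the surviving clusters all clear the bar
        for k in np.unique(cm.labels[region.values]):
            assert int((cm.labels == k).sum()) >= 0.05 * 2500

    def test_monotone_in_area_threshold(self, mucosa, mucosa_clusters):
        loose = select_relevant_region(
            mucosa_clusters, mucosa, RelevanceCriteria(min_area_fraction=0.01)
        )
        strict = select_relevant_region(
            mucosa_clusters, mucosa, RelevanceCriteria(min_area_fraction=0.2)
        )
        assert not (strict.values & ~loose.values).any()


class TestSlic:
    def test_constant_image_near_square_cells(self):
        img = RgbImage(np.full((100, 100, 3), 0.5))
        region = BinaryMask(np.ones((100, 100), bool))
        sp = slic_superpixels(img, region, n_segments=25, compactness=50.0)
        areas = np.bincount(sp.labels.ravel(), minlength=sp.n_superpixels)
        assert sp.n_superpixels <= 25
        # regular-grid oracle: 25 cells of 400 px; allow 2x spread
        assert areas.min() >= 200 and areas.max() <= 800

    def test_single_segment_equals_region(self, mucosa, mucosa_clusters):
        region = select_relevant_region(mucosa_clusters, mucosa)
        sp = slic_superpixels(mucosa, region, n_segments=1)
        assert sp.n_superpixels == 1
        assert np.array_equal(sp.labels >= 0, region.values)

    def test_mask_respected_and_partition(self, mucosa, mucosa_clusters):
        region = select_relevant_region(mucosa_clusters, mucosa)
        sp = slic_superpixels(mucosa, region, n_segments=32)
        assert (sp.labels[~region.values] == -1).all()
        assert (sp.labels[region.values] >= 0).all()
        assert sp.n_superpixels <= 32
        # every label non-empty
        areas = np.bincount(sp.labels[region.values], minlength=sp.n_superpixels)
        assert (areas > 0).all()

    def test_empty_region_raises(self, mucosa):
        with pytest.raises(EmptyRegionError):
            slic_superpixels(mucosa, BinaryMask(np.zeros(mucosa.shape, bool)))

    def test_higher_compactness_more_spatially_coherent(self, mucosa, mucosa_clusters):
        region = select_relevant_region(mucosa_clusters, mucosa)

        def coherence(sp):
            stats = superpixel_stats(mucosa, sp)
            rr, cc = np.meshgrid(
                np.arange(mucosa.height), np.arange(mucosa.width), indexing="ij"
            )
            total = 0.0
            for k in range(sp.n_superpixels):
                sel = sp.labels == k
                d = np.hypot(rr[sel] - stats.centroid[k, 0], cc[sel] - stats.centroid[k, 1])
                total += d.sum()
            return total / region.area

        loose = coherence(slic_superpixels(mucosa, region, n_segments=16, compactness=1.0))
        tight = coherence(slic_superpixels(mucosa, region, n_segments=16, compactness=100.0))
        assert tight <= loose + 1e-9


class TestSuperpixelStats:
    def test_uniform_superpixel_mean_colour(self):
        img = RgbImage(np.tile(np.array([0.3, 0.6, 0.9]), (10, 10, 1)))
        region = BinaryMask(np.ones((10, 10), bool))
        sp = slic_superpixels(img, region, n_segments=4)
        stats = superpixel_stats(img, sp)
        assert np.allclose(stats.mean_colour, [0.3, 0.6, 0.9])

    def test_two_pixel_arithmetic(self):
        from cimaug.regions import SuperpixelMap

        px = np.zeros((1, 2, 3))
        px[0, 1] = 1.0
        sp = SuperpixelMap(np.zeros((1, 2), dtype=np.int64), 1)
        stats = superpixel_stats(RgbImage(px), sp)
        assert np.allclose(stats.mean_colour[0], 0.5)
        assert np.allclose(stats.centroid[0], [0.0, 0.5])

    def test_brute_force_agreement(self, mucosa, mucosa_clusters):
        region = select_relevant_region(mucosa_clusters, mucosa)
        sp = slic_superpixels(mucosa, region, n_segments=16)
        stats = superpixel_stats(mucosa, sp)
        assert stats.area.sum() == region.area
        for k in range(sp.n_superpixels):
            sel = sp.labels == k
            assert stats.area[k] == int(sel.sum())
            assert np.allclose(stats.mean_colour[k], mucosa.pixels[sel].mean(axis=0))
            rr, cc = np.nonzero(sel)
            assert np.allclose(stats.centroid[k], [rr.mean(), cc.mean()])
            # centroid inside the superpixel's bounding box
            assert rr.min() <= stats.centroid[k, 0] <= rr.max()
            assert cc.min() <= stats.centroid[k, 1] <= cc.max()
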