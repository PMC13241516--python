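"""Segmentation tests: rolling-ball oracle, droplet/condensate detection,
mother-child assignment."""

import numpy as np
import pytest

import ceodquant as cq
from ceodquant.segment import ORPHAN, SegmentationError


def brute_force_opening(img: np.ndarray, radius: int) -> np.ndarray:
    """Independent oracle: per-pixel min-then-max over the in-bounds disk."""
    h, w = img.shape
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    eroded = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            eroded[y, x] = min(
                img[y + dy, x + dx]
                for dy, dx in offsets
                if 0 <= y + dy < h and 0 <= x + dx < w
            )
    opened = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            opened[y, x] = max(
                eroded[y + dy, x + dx]
                for dy, dx in offsets
                if 0 <= y + dy < h and 0 <= x + dx < w
            )
    return opened


class TestRollingBall:
    def test_constant_image_maps_to_zero(self):
        grid = cq.PixelGrid(np.full((40, 40), 123.0), 1.0, 8)
        out = cq.subtract_background_rolling_ball(grid, 5)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    @pytest.mark.parametrize("radius", [2, 3, 5])
    @pytest.mark.parametrize("rep", range(3))
    def test_matches_brute_force_opening_residual(self, radius, rep):
        """The rolling-ball residual equals image minus brute-force grayscale
        opening on random 32x32 images (oracle equivalence)."""
        rng = np.random.default_rng(1000 * radius + rep)
        img = rng.uniform(0.0, 255.0, (32, 32))
        got = cq.subtract_background_rolling_ball(cq.PixelGrid(img, 1.0, 8), radius)
        want = img - brute_force_opening(img, radius)
        np.testing.assert_allclose(got.values, np.clip(want, 0, None), atol=1e-9)

    def test_offset_invariance(self):
        """f and f + c produce identical residuals (background absorbs offsets)."""
        rng = np.random.default_rng(0)
        img = rng.uniform(0.0, 100.0, (32, 32))
        a = cq.subtract_background_rolling_ball(cq.PixelGrid(img, 1.0, 8), 4)
        b = cq.subtract_background_rolling_ball(cq.PixelGrid(img + 55.0, 1.0, 8), 4)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_narrow_peak_preserved(self):
        """A 3-px-wide peak survives a radius-25 ball with its full height."""
        img = np.full((101, 101), 10.0)
        img[49:52, 49:52] = 210.0
        out = cq.subtract_background_rolling_ball(cq.PixelGrid(img, 1.0, 8), 25)
        assert out.values[50, 50] == pytest.approx(200.0, rel=0.05)

    def test_output_bounded_by_input(self):
        rng = np.random.default_rng(9)
        img = rng.uniform(0.0, 255.0, (48, 48))
        out = cq.subtract_background_rolling_ball(cq.PixelGrid(img, 1.0, 8), 6)
        assert np.all(out.values <= img + 1e-12)
        assert np.all(out.values >= 0)

    def test_oversized_radius_rejected(self):
        grid = cq.PixelGrid(np.zeros((10, 10)), 1.0, 8)
        with pytest.raises(SegmentationError):
            cq.subtract_background_rolling_ball(grid, 100)


class TestSegmentDroplets:
    def test_blank_image_yields_empty_map(self):
        rng = np.random.default_rng(2)
        noise = rng.normal(500.0, 50.0, (128, 128)).clip(0, 65535)
        labels = cq.segment_droplets(
            cq.PixelGrid(noise, 0.65, 16), cq.SegmentationParams()
        )
        assert labels.n_labels == 0

    def test_recovers_ground_truth_droplets(self, segmented_scene):
        """Every generated droplet is found, with centroid within 1 px."""
        labels = segmented_scene["droplet_labels"]
        truth = segmented_scene["droplets"]
        records = segmented_scene["droplet_records"]
        assert labels.n_labels == len(truth)
        px = segmented_scene["config"].pixel_size_um
        for rec in records:
            best = min(
                truth,
                key=lambda d: (d.center_x_um - rec.centroid_x_um) ** 2
                + (d.center_y_um - rec.centroid_y_um) ** 2,
            )
            err_px = np.hypot(
                best.center_x_um - rec.centroid_x_um,
                best.center_y_um - rec.centroid_y_um,
            ) / px
            assert err_px <= 1.0

    def test_border_droplet_excluded(self):
        """A disc clipped by the field edge is dropped when exclude_border is on."""
        img = np.full((128, 128), 500.0)
        yy, xx = np.ogrid[:128, :128]
        img[np.hypot(yy - 64, xx - 64) < 20] = 10000.0    # interior droplet
        img[np.hypot(yy - 0, xx - 90) < 20] = 10000.0     # clipped droplet
        grid = cq.PixelGrid(img, 0.65, 16)
        on = cq.segment_droplets(grid, cq.SegmentationParams(exclude_border=True))
        off = cq.segment_droplets(grid, cq.SegmentationParams(exclude_border=False))
        assert on.n_labels == 1
        assert off.n_labels == 2

    def test_labels_consecutive_from_one(self, segmented_scene):
        for labels in (segmented_scene["droplet_labels"],
                       segmented_scene["condensate_labels"]):
            present = np.unique(labels.labels)
            present = present[present > 0]
            np.testing.assert_array_equal(present, np.arange(1, present.size + 1))

    def test_out_of_range_threshold_rejected(self):
        grid = cq.PixelGrid(np.zeros((32, 32)), 1.0, 8)
        with pytest.raises(SegmentationError):
            cq.segment_droplets(
                grid, cq.SegmentationParams(droplet_threshold=5000.0)
            )


class TestSegmentCondensates:
    def test_uniform_image_below_threshold_gives_nothing(self):
        img = np.full((64, 64), 59.0)
        labels = cq.segment_condensates(
            cq.PixelGrid(img, 0.65, 8), cq.SegmentationParams(rolling_ball_radius_px=20)
        )
        assert labels.n_labels == 0

    def test_single_bright_blob_detected(self):
        img = np.full((64, 64), 10.0)
        img[30:35, 30:34] = 200.0
        labels = cq.segment_condensates(
            cq.PixelGrid(img, 0.65, 8),
            cq.SegmentationParams(rolling_ball_radius_px=20,
                                  condensate_denoise_radius_px=1),
        )
        assert labels.n_labels == 1

    def test_recall_against_ground_truth(self, segmented_scene):
        """>= 95% of generated condensates are recovered with >= 50% overlap."""
        truth = segmented_scene["condensates"]
        found = segmented_scene["condensate_labels"].labels
        assert truth
        n_hit = 0
        for cond in truth:
            rows = np.array([p[0] for p in cond.pixel_mask])
            cols = np.array([p[1] for p in cond.pixel_mask])
            labels_under = found[rows, cols]
            hits = labels_under[labels_under > 0]
            if hits.size and np.bincount(hits).max() >= 0.5 * len(cond.pixel_mask):
                n_hit += 1
        assert n_hit / len(truth) >= 0.95

    def test_threshold_rescaled_for_16bit(self):
        """Value 60 on the 8-bit scale maps to 60 * 257 on 16-bit data."""
        params = cq.SegmentationParams()
        grid8 = cq.PixelGrid(np.zeros((8, 8)), 1.0, 8)
        grid16 = cq.PixelGrid(np.zeros((8, 8)), 1.0, 16)
        assert params.condensate_threshold_for(grid8) == 60.0
        assert params.condensate_threshold_for(grid16) == pytest.approx(60.0 * 257)


class TestAssignCondensates:
    def _maps(self, drop, cond):
        return (cq.LabelMap(drop, 1.0), cq.LabelMap(cond, 1.0))

    def test_contained_condensate_assigned_to_its_droplet(self):
        drop = np.zeros((20, 20), int)
        drop[2:18, 2:18] = 3
        cond = np.zeros((20, 20), int)
        cond[8:12, 8:12] = 1
        parents = cq.assign_condensates(*self._maps(drop, cond))
        assert parents.parent_of(1) == 3

    def test_disjoint_condensate_is_orphan(self):
        drop = np.zeros((20, 20), int)
        drop[:8, :8] = 1
        cond = np.zeros((20, 20), int)
        cond[14:18, 14:18] = 1
        parents = cq.assign_condensates(*self._maps(drop, cond))
        assert parents.parent_of(1) == ORPHAN

    def test_straddling_condensate_follows_centroid(self):
        """A child crossing the droplet edge goes to the droplet holding its
        centroid; the expected pixel-overlap answer is recomputed by brute
        force on the same 20x20 example."""
        drop = np.zeros((20, 20), int)
        drop[:, :10] = 1
        cond = np.zeros((20, 20), int)
        cond[8:12, 6:13] = 1   # centroid column 9 -> inside droplet 1
        parents = cq.assign_condensates(*self._maps(drop, cond))
        rows, cols = np.nonzero(cond == 1)
        centroid = (round(rows.mean()), round(cols.mean()))
        assert drop[centroid] == 1
        assert parents.parent_of(1) == 1

    def test_centroid_outside_falls_back_to_largest_overlap(self):
        """A C-shaped child whose centroid pixel is background is attributed
        to the droplet covering most of its pixels."""
        drop = np.zeros((20, 20), int)
        drop[2:18, 2:9] = 1
        drop[2:18, 11:18] = 2
        cond = np.zeros((20, 20), int)
        cond[4:6, 4:16] = 1    # bar overlapping both droplets and the gap
        cond[6:14, 4:6] = 1    # heavier limb inside droplet 1
        parents = cq.assign_condensates(*self._maps(drop, cond))
        rows, cols = np.nonzero(cond == 1)
        overlap1 = int(np.sum(drop[rows, cols] == 1))
        overlap2 = int(np.sum(drop[rows, cols] == 2))
        assert overlap1 > overlap2
        assert parents.parent_of(1) == 1

    def test_every_child_mapped_exactly_once(self, segmented_scene):
        parents = segmented_scene["parents"]
        n_children = segmented_scene["condensate_labels"].n_labels
        assert sorted(parents.child_to_parent) == list(range(1, n_children + 1))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(SegmentationError):
            cq.assign_condensates(
                cq.LabelMap(np.zeros((10, 10), int), 1.0),
                cq.LabelMap(np.zeros((12, 12), int), 1.0),
            )
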