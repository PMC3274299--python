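"""Segmentation front end against brute-force oracles and stated edge cases."""

import numpy as np
import pytest

from benthoscan.preprocess import (
    DegenerateInputWarning,
    channel_distance_map,
    extract_objects,
    median_filter,
    percentile_threshold,
    run_front_end,
    top_hat,
)


def naive_median(channel: np.ndarray, window: int) -> np.ndarray:
    """Sort-and-pick-middle median with edge replication."""
    r = window // 2
    padded = np.pad(channel, r, mode="edge")
    out = np.empty_like(channel)
    for i in range(channel.shape[0]):
        for j in range(channel.shape[1]):
            out[i, j] = np.median(padded[i : i + window, j : j + window])
    return out


def naive_tophat(channel: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """White top-hat via min/max scans (erosion then dilation, reflected borders)."""
    r = footprint.shape[0] // 2
    fp = footprint.astype(bool)

    def scan(img, reducer):
        padded = np.pad(img, r, mode="symmetric")
        out = np.empty_like(img)
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                out[i, j] = reducer(padded[i : i + 2 * r + 1, j : j + 2 * r + 1][fp])
        return out

    opening = scan(scan(channel, np.min), np.max)
    return channel - opening


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32, 3), 77, dtype=np.uint8)
        assert np.array_equal(median_filter(img), img)

    def test_single_impulse_removed_in_one_pass(self):
        img = np.full((21, 21, 3), 50, dtype=np.uint8)
        img[10, 10] = 255
        out = median_filter(img, window=7, passes=1)
        assert (out == 50).all()

    def test_matches_naive_sort_oracle(self, rng):
        """7x7 median of a random patch equals the brute-force oracle per channel."""
        img = rng.integers(0, 256, size=(9, 9, 3)).astype(np.uint8)
        out = median_filter(img, window=7, passes=1)
        for c in range(3):
            assert np.array_equal(out[..., c], naive_median(img[..., c], 7))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_filter(np.zeros((8, 8, 3), dtype=np.uint8), window=6)

    def test_pass_changes_shrink_on_impulse_noise(self, rng):
        """Each extra pass alters no more pixels than the one before it."""
        img = np.full((64, 64, 3), 100, dtype=np.uint8)
        noise = rng.random((64, 64)) < 0.05
        img[noise] = 255
        prev = img
        changed = []
        for _ in range(3):
            nxt = median_filter(prev, window=7, passes=1)
            changed.append(int((nxt != prev).sum()))
            prev = nxt
        assert changed[0] >= changed[1] >= changed[2]


class TestTopHat:
    def test_constant_maps_to_zero(self):
        img = np.full((40, 40), 120, dtype=np.uint8)
        assert (top_hat(img, 25) == 0).all()

    def test_small_bright_square_preserved(self):
        img = np.full((60, 60), 30, dtype=np.uint8)
        img[20:30, 20:30] = 200  # side 10 < elem 25
        out = top_hat(img, 25)
        assert (out[22:28, 22:28] == 170).all()

    def test_matches_min_max_scan_oracle(self, rng):
        from skimage.morphology import disk

        img = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
        for shape, fp in [("disc", disk(3)), ("square", np.ones((7, 7), bool))]:
            out = top_hat(img, elem_size=7, shape=shape)
            oracle = naive_tophat(img.astype(int), fp)
            assert np.array_equal(out.astype(int), oracle)

    def test_smooth_ramp_residual_bounded(self):
        """A linear ramp leaves residual at most the rise across the element."""
        ramp = np.tile(np.arange(0, 200, 2, dtype=np.uint8), (100, 1))
        out = top_hat(ramp, elem_size=11)
        assert out.max() <= 2 * 11

    def test_output_non_negative(self, rng):
        img = rng.integers(0, 256, size=(30, 30)).astype(np.uint8)
        assert (top_hat(img, 9).astype(int) >= 0).all()

    def test_oversized_element_rejected(self):
        with pytest.raises(ValueError):
            top_hat(np.zeros((20, 20), dtype=np.uint8), elem_size=25)


class TestChannelDistanceMap:
    def test_equal_channels_give_zero(self):
        img = np.dstack([np.full((8, 8), 90)] * 3).astype(np.uint8)
        assert (channel_distance_map(img) == 0).all()

    def test_single_pixel_arithmetic(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[0, 0] = (200, 50, 0)
        assert channel_distance_map(img)[0, 0] == 150

    def test_no_uint8_wraparound(self, rng):
        img = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
        expected = np.abs(img[..., 0].astype(np.int64) - img[..., 1].astype(np.int64))
        assert np.array_equal(channel_distance_map(img), expected)


class TestPercentileThreshold:
    def test_hundred_distinct_values(self):
        """Values 0..99 at q=95: exactly the four pixels above the 95th percentile."""
        grid = np.arange(100).reshape(10, 10)
        mask = percentile_threshold(grid, 95)
        assert mask.sum() == 4
        assert set(grid[mask]) == {96, 97, 98, 99}

    def test_constant_map_warns_and_returns_empty(self):
        with pytest.warns(DegenerateInputWarning):
            mask = percentile_threshold(np.full((10, 10), 5))
        assert not mask.any()

    def test_true_fraction_bounded_for_distinct_values(self, rng):
        vals = rng.permutation(400).reshape(20, 20)
        mask = percentile_threshold(vals, 95)
        assert mask.mean() <= 0.05

    def test_matches_sort_oracle(self, rng):
        """The threshold is the next-higher order statistic of the sorted values."""
        grid = rng.normal(size=(25, 25))
        mask = percentile_threshold(grid, 95)
        srt = np.sort(grid.ravel())
        thr = srt[int(np.ceil(0.95 * (grid.size - 1)))]
        assert np.array_equal(mask, grid > thr)


class TestExtractObjects:
    def test_empty_mask_gives_empty_list(self):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        assert extract_objects(np.zeros((20, 20), bool), img) == []

    def test_area_gate(self):
        mask = np.zeros((60, 60), bool)
        mask[2:17, 2:22] = True  # 300 px
        mask[40:50, 40:55] = True  # 150 px
        img = np.zeros((60, 60, 3), dtype=np.uint8)
        objs = extract_objects(mask, img, min_area=200, max_area=150_000)
        assert len(objs) == 1
        assert objs[0].area == 300

    def test_mean_rgb_on_constant_colour(self):
        mask = np.zeros((30, 30), bool)
        mask[5:25, 5:25] = True
        img = np.empty((30, 30, 3), dtype=np.uint8)
        img[...] = (10, 200, 30)
        (obj,) = extract_objects(mask, img)
        assert obj.mean_rgb == (10.0, 200.0, 30.0)

    def test_contour_closed_and_centroid_in_bbox(self):
        mask = np.zeros((40, 40), bool)
        mask[10:30, 8:28] = True
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        (obj,) = extract_objects(mask, img)
        assert np.allclose(obj.contour[0], obj.contour[-1])
        rows = obj.contour[:, 0]
        cols = obj.contour[:, 1]
        assert rows.min() <= obj.centroid[0] <= rows.max()
        assert cols.min() <= obj.centroid[1] <= cols.max()

    def test_eight_connectivity(self):
        mask = np.zeros((40, 40), bool)
        mask[:20, :20] = True
        mask[20:, 20:] = True  # touch only diagonally at (19,19)/(20,20)
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        objs = extract_objects(mask, img, min_area=1)
        assert len(objs) == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_objects(np.zeros((5, 5), bool), np.zeros((6, 6, 3), dtype=np.uint8))

    def test_component_count_matches_flood_fill_oracle(self, rng):
        mask = rng.random((64, 64)) < 0.35
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        objs = extract_objects(mask, img, min_area=1, max_area=10**9)
        assert len(objs) == flood_fill_count(mask)


def flood_fill_count(mask: np.ndarray) -> int:
    """8-connected component count by explicit stack-based flood fill."""
    seen = np.zeros_like(mask, bool)
    count = 0
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return count


def test_front_end_returns_intermediates():
    from benthoscan.scene_synthesis import make_background, plant_animals

    img = make_background(256, 256, seed=5)
    img, _ = plant_animals(img, 1, seed=6)
    objs, inter = run_front_end(img, return_intermediates=True)
    assert set(inter) == {"filtered", "tophat", "distance_map", "mask"}
    assert inter["mask"].dtype == bool
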