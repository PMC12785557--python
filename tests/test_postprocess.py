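"""Binarization, morphology and dot counting vs a flood-fill oracle."""

import numpy as np
import pandas as pd
import pytest

from rishquant.postprocess import (
    MorphConfig,
    binarize,
    count_dots,
    morph_clean,
    quantify_counts,
    quantify_sample,
)


def flood_fill_count(mask: np.ndarray, connectivity: int, min_area: int) -> int:
    """Independent oracle: iterative stack-based flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = mask.shape
    count = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                area = 0
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    r, c = stack.pop()
                    area += 1
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                if area >= min_area:
                    count += 1
    return count


class TestBinarize:
    def test_below_threshold_empty(self):
        assert binarize(np.full((4, 4), 0.4)).sum() == 0

    def test_above_threshold_full(self):
        assert binarize(np.full((4, 4), 0.6)).sum() == 16

    def test_binary_map_is_fixed_point(self):
        m = (np.random.default_rng(0).random((6, 6)) > 0.5).astype(float)
        for thr in (0.1, 0.5, 0.9):
            assert np.array_equal(
                binarize(m, MorphConfig(binarize_threshold=thr)), m.astype(np.uint8)
            )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.full((2, 2), 1.5))


class TestMorphClean:
    def test_opening_removes_isolated_pixel(self):
        m = np.zeros((7, 7), np.uint8)
        m[3, 3] = 1
        assert morph_clean(m).sum() == 0

    def test_opening_preserves_solid_square(self):
        m = np.zeros((14, 14), np.uint8)
        m[2:12, 2:12] = 1
        assert np.array_equal(morph_clean(m), m)

    def test_closing_fills_single_pixel_hole(self):
        # 7x7 blob with a central hole; dilation bridges it, erosion
        # restores the outline: hole filled (hand-derived on the grid)
        m = np.ones((7, 7), np.uint8)
        m[3, 3] = 0
        closed = morph_clean(m, MorphConfig(operation_sequence=("dilate", "erode")))
        assert closed[3, 3] == 1

    def test_unknown_operation_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            MorphConfig(operation_sequence=("erode", "open"))


class TestCountDots:
    def test_empty_mask(self):
        assert count_dots(np.zeros((10, 10), np.uint8)) == 0

    def test_three_disjoint_squares(self):
        m = np.zeros((12, 12), np.uint8)
        for r, c in ((0, 0), (0, 8), (8, 0)):
            m[r : r + 3, c : c + 3] = 1
        assert count_dots(m) == 3

    def test_diagonal_touch_depends_on_connectivity(self):
        m = np.zeros((4, 4), np.uint8)
        m[1, 1] = m[2, 2] = 1
        assert count_dots(m, MorphConfig(connectivity=8, min_dot_area=1)) == 1
        assert count_dots(m, MorphConfig(connectivity=4, min_dot_area=1)) == 2

    def test_min_area_filters_specks(self):
        m = np.zeros((8, 8), np.uint8)
        m[0, 0] = 1  # area 1 < min_dot_area 2
        m[4:6, 4:6] = 1
        assert count_dots(m) == 1

    def test_matches_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(77)
        for i in range(200):
            mask = (rng.random((64, 64)) > rng.uniform(0.5, 0.95)).astype(np.uint8)
            conn = 8 if i % 2 == 0 else 4
            cfg = MorphConfig(connectivity=conn, min_dot_area=1 + i % 3)
            assert count_dots(mask, cfg) == flood_fill_count(
                mask, conn, 1 + i % 3
            ), f"mismatch at iteration {i}"

    def test_adding_disjoint_blob_increments_count(self):
        rng = np.random.default_rng(5)
        m = (rng.random((32, 32)) > 0.9).astype(np.uint8)
        m[:8, 28:] = 0  # reserve an empty corner
        before = count_dots(m)
        m[2:5, 29:32] = 1  # a 3x3 blob, disjoint by construction
        assert count_dots(m) == before + 1


class TestQuantify:
    def test_mean_of_two_fields(self):
        df = pd.DataFrame(
            {"sample_id": ["a", "a"], "field_index": [0, 1],
             "blue_count": [10, 20], "red_count": [1, 2]}
        )
        out = quantify_counts(df)
        assert out.loc[0, "mean_blue"] == 15.0

    def test_single_field_passthrough(self):
        df = pd.DataFrame(
            {"sample_id": ["a"], "field_index": [0], "blue_count": [7], "red_count": [3]}
        )
        out = quantify_counts(df)
        assert out.loc[0, "mean_blue"] == 7.0 and out.loc[0, "mean_red"] == 3.0

    def test_four_field_red_mean(self):
        df = pd.DataFrame(
            {"sample_id": ["s"] * 4, "field_index": range(4),
             "blue_count": [0] * 4, "red_count": [1, 2, 3, 4]}
        )
        assert quantify_counts(df).loc[0, "mean_red"] == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quantify_sample(pd.DataFrame(columns=["blue_count", "red_count"]))
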