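import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribseg.postprocess import (DetectionBox, binarize, mask_to_boxes,
                                match_to_truth, merge_boxes, render_overlay)

# ---------------------------------------------------------------------------
# brute-force oracles, independent of scipy


def flood_fill_components(mask, connectivity=8):
    """BFS component labelling on a 2D grid."""
    mask = np.asarray(mask) > 0
    h, w = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)]
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for y in range(h):
        for x in range(w):
            if mask[y, x] and labels[y, x] == 0:
                current += 1
                queue = [(y, x)]
                labels[y, x] = current
                while queue:
                    cy, cx = queue.pop()
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] \
                                and labels[ny, nx] == 0:
                            labels[ny, nx] = current
                            queue.append((ny, nx))
    return labels, current


def brute_force_boxes(mask, connectivity=8, min_area=0):
    labels, n = flood_fill_components(mask, connectivity)
    out = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(ys) < max(min_area, 1):
            continue
        out.append((int(xs.min()), int(ys.min()), int(xs.max()) + 1,
                    int(ys.max()) + 1, len(ys)))
    return sorted(out)


def boxes_as_tuples(boxes):
    return sorted((b.x_min, b.y_min, b.x_max, b.y_max, b.area) for b in boxes)


def random_mask(rng, size=64, density=0.1):
    return (rng.uniform(0, 1, (size, size)) < density).astype(np.uint8)


# ---------------------------------------------------------------------------


class TestBinarize:
    def test_all_zero(self):
        assert binarize(np.zeros((4, 4))).sum() == 0

    def test_threshold_boundary_is_foreground(self):
        assert binarize(np.full((3, 3), 0.5), 0.5).all()

    def test_idempotent(self, rng):
        m = binarize(rng.uniform(0, 1, (8, 8)))
        np.testing.assert_array_equal(binarize(m.astype(float)), m)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), threshold=0.0)


class TestDetectionBoxInvariants:
    def test_degenerate_extent(self):
        with pytest.raises(ValueError):
            DetectionBox(3, 0, 3, 5, area=1)

    def test_area_exceeding_box(self):
        with pytest.raises(ValueError):
            DetectionBox(0, 0, 2, 2, area=5)


class TestMaskToBoxes:
    def test_empty_mask(self):
        assert mask_to_boxes(np.zeros((8, 8))) == []

    def test_single_block(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[2:5, 5:8] = 1
        boxes = mask_to_boxes(m)
        assert boxes_as_tuples(boxes) == [(5, 2, 8, 5, 9)]

    def test_diagonal_touch_connectivity(self):
        m = np.zeros((6, 6), dtype=np.uint8)
        m[1, 1] = m[2, 2] = 1
        assert len(mask_to_boxes(m, connectivity=8)) == 1
        assert len(mask_to_boxes(m, connectivity=4)) == 2

    def test_min_area_filters(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[0, 0] = 1
        m[4:7, 4:7] = 1
        assert len(mask_to_boxes(m, min_area=2)) == 1

    def test_bad_connectivity(self):
        with pytest.raises(ValueError):
            mask_to_boxes(np.zeros((4, 4)), connectivity=6)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_brute_force_on_random_masks(self, rng, connectivity):
        for _ in range(25):
            m = random_mask(rng, size=32, density=rng.uniform(0.05, 0.4))
            assert boxes_as_tuples(mask_to_boxes(m, connectivity)) == \
                brute_force_boxes(m, connectivity)

    def test_boxes_cover_mask(self, rng):
        m = random_mask(rng, 32, 0.2)
        boxes = mask_to_boxes(m)
        cover = np.zeros_like(m)
        for b in boxes:
            cover[b.y_min:b.y_max, b.x_min:b.x_max] = 1
        assert (cover[m > 0] == 1).all()


class TestMergeBoxes:
    def test_far_apart_unchanged(self):
        boxes = [DetectionBox(0, 0, 2, 2, 4), DetectionBox(10, 10, 12, 12, 4)]
        assert len(merge_boxes(boxes, gap=0)) == 2

    def test_gap_two_merges_neighbors(self):
        boxes = [DetectionBox(0, 0, 4, 4, 16), DetectionBox(5, 0, 9, 4, 16)]
        merged = merge_boxes(boxes, gap=2)
        assert len(merged) == 1
        b = merged[0]
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (0, 0, 9, 4)
        assert b.area == 32  # sum of member areas

    def test_gap_zero_does_not_merge_touching(self):
        boxes = [DetectionBox(0, 0, 4, 4, 16), DetectionBox(4, 0, 8, 4, 16)]
        assert len(merge_boxes(boxes, gap=0)) == 2

    def test_transitive_chain(self):
        boxes = [DetectionBox(i * 5, 0, i * 5 + 4, 4, 16) for i in range(4)]
        merged = merge_boxes(boxes, gap=2)
        assert len(merged) == 1
        assert merged[0].x_max == 19

    def test_idempotent(self, rng):
        boxes = []
        for _ in range(12):
            x, y = rng.integers(0, 40, 2)
            w, h = rng.integers(1, 8, 2)
            boxes.append(DetectionBox(int(x), int(y), int(x + w), int(y + h),
                                      int(w * h)))
        once = merge_boxes(boxes, gap=3)
        twice = merge_boxes(once, gap=3)
        assert boxes_as_tuples(once) == boxes_as_tuples(twice)

    def test_never_increases_count_and_covers_inputs(self, rng):
        boxes = []
        for _ in range(10):
            x, y = rng.integers(0, 30, 2)
            w, h = rng.integers(1, 6, 2)
            boxes.append(DetectionBox(int(x), int(y), int(x + w), int(y + h),
                                      int(w * h)))
        merged = merge_boxes(boxes, gap=1)
        assert len(merged) <= len(boxes)
        for b in boxes:
            assert any(m.x_min <= b.x_min and m.y_min <= b.y_min
                       and m.x_max >= b.x_max and m.y_max >= b.y_max
                       for m in merged)

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_boxes([], gap=-1)


class TestMatchToTruth:
    def test_exact_predictions(self, rng):
        truth = np.zeros((20, 20), dtype=np.uint8)
        truth[2:5, 2:5] = 1
        truth[10:14, 10:13] = 1
        boxes = mask_to_boxes(truth)
        tp, fp, fn = match_to_truth(boxes, truth)
        assert (tp, fp, fn) == (2, 0, 0)
        assert all(b.matched for b in boxes)

    def test_no_predictions(self):
        truth = np.zeros((20, 20), dtype=np.uint8)
        truth[0, 0] = truth[5, 5] = truth[10, 10] = 1
        assert match_to_truth([], truth) == (0, 0, 3)

    def test_half_coverage_passes_quarter_overlap(self):
        truth = np.zeros((10, 10), dtype=np.uint8)
        truth[2:6, 2:6] = 1  # 16 px component
        box = DetectionBox(2, 2, 6, 4, area=8)  # covers 8/16 = 0.5
        assert match_to_truth([box], truth, min_overlap=0.25) == (1, 0, 0)
        assert match_to_truth([box], truth, min_overlap=0.75) == (0, 1, 1)

    def test_one_to_one_greedy(self):
        truth = np.zeros((10, 20), dtype=np.uint8)
        truth[2:4, 2:6] = 1
        truth[2:4, 10:14] = 1
        big = DetectionBox(0, 0, 20, 10, area=150)  # covers both
        tp, fp, fn = match_to_truth([big], truth)
        assert (tp, fp, fn) == (1, 0, 1)  # one box matches only one lesion

    def test_bad_min_overlap(self):
        with pytest.raises(ValueError):
            match_to_truth([], np.zeros((4, 4)), min_overlap=0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_tp_plus_fn_equals_truth_components(self, seed):
        rng = np.random.default_rng(seed)
        truth = random_mask(rng, 32, 0.15)
        pred = random_mask(rng, 32, 0.15)
        boxes = mask_to_boxes(pred)
        tp, fp, fn = match_to_truth(boxes, truth)
        _, n_truth = flood_fill_components(truth)
        assert tp + fn == n_truth
        assert tp + fp == len(boxes)


def test_render_overlay_colors(rng):
    img = rng.uniform(0, 1, (16, 16))
    truth = np.zeros((16, 16), dtype=np.uint8)
    truth[4:8, 4:8] = 1
    boxes = [DetectionBox(10, 10, 14, 14, area=4)]
    rgb = render_overlay(img, truth, boxes)
    assert rgb.shape == (16, 16, 3)
    assert tuple(rgb[4, 4]) == (0, 255, 0)      # truth contour green
    assert tuple(rgb[10, 10]) == (255, 0, 0)    # prediction box red
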