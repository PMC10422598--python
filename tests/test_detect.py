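"""Otsu thresholding, connectivity semantics and the detection chain."""

import numpy as np
import pytest

from soyemerge.detect import (
    DetectParams,
    FieldImage,
    annotate,
    binarize,
    detect_seedlings,
    filter_components,
    label_components,
    mask_to_color,
    min_bounding_rect,
    otsu_threshold,
    to_gray,
)
from soyemerge.synthetic import SceneConfig, generate_scene, scene_to_count_truth


def brute_force_otsu(gray):
    """Independent exhaustive scan of the between-class variance."""
    gray = np.asarray(gray).ravel().astype(float)
    n = gray.size
    mu = gray.mean()
    best_k, best_s = 0, -1.0
    for k in range(256):
        bg = gray[gray <= k]
        fg = gray[gray > k]
        w1, w0 = len(bg) / n, len(fg) / n
        mu1 = bg.mean() if len(bg) else 0.0
        mu0 = fg.mean() if len(fg) else 0.0
        s = w0 * (mu - mu0) ** 2 + w1 * (mu - mu1) ** 2
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    return best_k, best_s


def bfs_components(mask, connectivity):
    """Independent flood-fill labelling oracle."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                stack, comp = [(y, x)], set()
                seen[y, x] = True
                while stack:
                    cy, cx = stack.pop()
                    comp.add((cx, cy))
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(frozenset(comp))
    return comps


class TestToGray:
    @pytest.mark.parametrize("rgb,expected", [
        ((0, 255, 0), 255),    # excess green clips at 255 (2*255 = 510)
        ((100, 100, 100), 0),  # achromatic pixel has zero excess green
        ((50, 100, 30), 120),  # 200 - 50 - 30
    ])
    def test_excess_green_pixels(self, rgb, expected):
        img = np.array(rgb, dtype=np.uint8).reshape(1, 1, 3)
        assert to_gray(img, "exg")[0, 0] == expected

    def test_green_channel_rule(self):
        img = np.array([10, 200, 30], dtype=np.uint8).reshape(1, 1, 3)
        assert to_gray(img, "green")[0, 0] == 200

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            to_gray(np.zeros((2, 2, 3), np.uint8), "hue")


class TestOtsu:
    def test_bimodal_smallest_maximiser(self):
        # 50 px at 10 and 50 px at 200: any k in [10, 199] separates the
        # classes equally well; the tie must break to k = 10.
        gray = np.concatenate([np.full(50, 10), np.full(50, 200)]).astype(np.uint8)
        res = otsu_threshold(gray.reshape(10, 10))
        bk, bs = brute_force_otsu(gray)
        assert res.k == 10 == bk
        assert res.sigma2 == pytest.approx(bs, rel=1e-12)

    def test_constant_image_degenerate(self):
        res = otsu_threshold(np.full((8, 8), 128, np.uint8))
        assert res.degenerate and res.k == 128 and res.sigma2 == pytest.approx(0.0)

    def test_matches_exhaustive_scan_on_random_images(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            gray = rng.integers(0, 256, (32, 32)).astype(np.uint8)
            res = otsu_threshold(gray)
            bk, bs = brute_force_otsu(gray)
            assert res.k == bk
            assert res.sigma2 == pytest.approx(bs, rel=1e-9)

    def test_class_bookkeeping_invariants(self):
        rng = np.random.default_rng(4)
        gray = rng.integers(0, 256, (40, 40)).astype(np.uint8)
        res = otsu_threshold(gray)
        assert res.w0 + res.w1 == pytest.approx(1.0, abs=1e-9)
        assert res.mu == pytest.approx(res.w0 * res.mu0 + res.w1 * res.mu1, abs=1e-6)
        assert res.histogram.sum() == gray.size

    def test_printed_form_equals_product_form(self):
        # w0(mu-mu0)^2 + w1(mu-mu1)^2 == w0*w1*(mu0-mu1)^2
        rng = np.random.default_rng(5)
        gray = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        res = otsu_threshold(gray)
        product = res.w0 * res.w1 * (res.mu0 - res.mu1) ** 2
        assert res.sigma2 == pytest.approx(product, rel=1e-9)

    def test_skimage_agreement(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(6)
        for _ in range(10):
            gray = rng.integers(0, 256, (48, 48)).astype(np.uint8)
            res = otsu_threshold(gray)
            # skimage returns the left class's upper level under <= semantics
            assert abs(res.k - threshold_otsu(gray)) <= 1


class TestBinarize:
    def test_strict_inequality(self):
        mask = binarize(np.array([[10, 200]], np.uint8), 10)
        assert mask.pixels.tolist() == [[False, True]]

    def test_all_zero(self):
        assert not binarize(np.zeros((4, 4), np.uint8), 0).pixels.any()

    def test_true_fraction_matches_histogram(self):
        rng = np.random.default_rng(7)
        gray = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        res = otsu_threshold(gray)
        mask = binarize(gray, res)
        above = int(res.histogram[res.k + 1:].sum())
        assert int(mask.pixels.sum()) == above
        assert mask.pixels.sum() / gray.size == pytest.approx(res.w0, abs=1e-9)


class TestMaskToColor:
    def test_identity_and_blackout(self, dense_scene):
        image, _ = dense_scene
        from soyemerge.detect import BinaryMask

        full = mask_to_color(image, BinaryMask(np.ones(image.shape, bool)))
        assert np.array_equal(full.pixels, image.pixels)
        empty = mask_to_color(image, BinaryMask(np.zeros(image.shape, bool)))
        assert not empty.pixels.any()

    def test_foreground_count_matches_mask(self, dense_scene):
        image, _ = dense_scene
        gray = to_gray(image)
        mask = binarize(gray, otsu_threshold(gray))
        masked = mask_to_color(image, mask)
        # non-black pixels in the masked colour image == mask true count
        assert int(masked.pixels.any(axis=2).sum()) == int(mask.pixels.sum())

    def test_shape_mismatch_rejected(self, dense_scene):
        image, _ = dense_scene
        from soyemerge.detect import BinaryMask

        with pytest.raises(ValueError):
            mask_to_color(image, BinaryMask(np.ones((3, 3), bool)))


class TestComponents:
    def test_diagonal_pixels_connectivity_semantics(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(label_components(mask, connectivity=8)) == 1
        assert len(label_components(mask, connectivity=4)) == 2

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(8)
        for conn in (4, 8):
            for _ in range(10):
                mask = rng.random((24, 24)) < 0.35
                comps = label_components(mask, connectivity=conn)
                oracle = bfs_components(mask, conn)
                got = {frozenset(map(tuple, c.pixel_set)) for c in comps}
                assert got == set(oracle)

    def test_eight_connected_never_more_than_four(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            mask = rng.random((32, 32)) < rng.uniform(0.2, 0.6)
            n8 = len(label_components(mask, 8))
            n4 = len(label_components(mask, 4))
            assert n8 <= n4

    def test_labels_in_raster_scan_order(self):
        mask = np.zeros((6, 6), bool)
        mask[0, 4] = True   # first row, later column
        mask[3, 0] = True
        comps = label_components(mask, 8)
        assert [tuple(c.pixel_set[0]) for c in comps] == [(4, 0), (0, 3)]

    def test_empty_mask(self):
        assert label_components(np.zeros((5, 5), bool)) == []

    def test_scene_components_match_plant_count(self, dense_scene):
        image, truth = dense_scene
        gray = to_gray(image)
        mask = binarize(gray, otsu_threshold(gray))
        comps = filter_components(label_components(mask, 8), min_area=25)
        assert len(comps) == len(truth)


class TestFilterComponents:
    def _comps(self, areas):
        return [type("C", (), {"area": a})() for a in areas]

    def test_band_filter(self):
        kept = filter_components(self._comps([3, 50, 900]), min_area=10)
        assert [c.area for c in kept] == [50, 900]

    def test_identity_filter(self):
        comps = self._comps([1, 2, 3])
        assert filter_components(comps, min_area=1) == comps

    def test_monotone_in_min_area(self):
        rng = np.random.default_rng(10)
        areas = rng.integers(1, 500, 50).tolist()
        prev = len(areas)
        for lo in range(1, 500, 25):
            n = len(filter_components(self._comps(areas), min_area=lo))
            assert n <= prev
            prev = n

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            filter_components([], min_area=10, max_area=5)


class TestMinBoundingRect:
    def test_single_pixel(self):
        assert min_bounding_rect(np.array([[5, 7]])) == (5, 7, 1, 1)

    def test_two_corners(self):
        assert min_bounding_rect(np.array([[0, 0], [3, 1]])) == (0, 0, 4, 2)

    def test_random_component_against_minmax(self):
        rng = np.random.default_rng(11)
        pts = rng.integers(0, 50, (30, 2))
        x0, y0, w, h = min_bounding_rect(pts)
        assert (x0, y0) == (pts[:, 0].min(), pts[:, 1].min())
        assert (w, h) == (np.ptp(pts[:, 0]) + 1, np.ptp(pts[:, 1]) + 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            min_bounding_rect(np.empty((0, 2)))


class TestDetectSeedlings:
    def test_counts_match_truth_on_clean_scene(self, dense_scene):
        image, truth = dense_scene
        _, count = detect_seedlings(image)
        _, total = scene_to_count_truth(truth)
        assert count == total

    def test_all_soil_scene(self):
        cfg = SceneConfig(seed=2, n_rows=0)
        image, truth = generate_scene(cfg)
        _, count = detect_seedlings(image)
        assert len(truth) == 0 and count == 0

    def test_distractors_do_not_change_count(self):
        for seed in (21, 22):
            with_d, _ = generate_scene(SceneConfig(seed=seed, distractor_density=6,
                                                   stage_mix=(0.5, 0.3, 0.2)))
            without, _ = generate_scene(SceneConfig(seed=seed, distractor_density=0,
                                                    stage_mix=(0.5, 0.3, 0.2)))
            _, n_with = detect_seedlings(with_d)
            _, n_without = detect_seedlings(without)
            assert n_with == n_without

    def test_indices_contiguous_from_one(self, dense_scene):
        image, _ = dense_scene
        detections, count = detect_seedlings(image)
        assert [d.index for d in detections] == list(range(1, count + 1))


class TestAnnotate:
    def test_no_detections_is_identity(self, dense_scene):
        image, _ = dense_scene
        out = annotate(image, [])
        assert np.array_equal(out.pixels, image.pixels)

    def test_red_rectangle_present(self, dense_scene):
        image, _ = dense_scene
        detections, _ = detect_seedlings(image)
        out = annotate(image, detections[:1])
        x0, y0, w, h = detections[0].rect
        top = out.pixels[y0, x0:x0 + w]
        assert (top == (255, 0, 0)).all(axis=1).all()

    def test_each_detection_gets_an_index_label(self, dense_scene):
        image, _ = dense_scene
        detections, count = detect_seedlings(image)
        out, boxes = annotate(image, detections, return_label_boxes=True)
        assert len(boxes) == count
        # blue pixels exist inside each reported label box
        for (x, y, w, h) in boxes[:10]:
            patch = out.pixels[max(y, 0):y + h + 1, max(x, 0):x + w + 1]
            assert ((patch == (0, 0, 255)).all(axis=2)).any()

    def test_original_pixels_untouched_away_from_marks(self, dense_scene):
        image, _ = dense_scene
        detections, _ = detect_seedlings(image)
        out = annotate(image, detections)
        diff = (out.pixels != image.pixels).any(axis=2)
        changed = int(diff.sum())
        # marks are sparse: far fewer changed pixels than the image area
        assert 0 < changed < 0.1 * diff.size
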