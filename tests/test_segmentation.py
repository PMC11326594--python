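"""Segmentation: FCM fixed points, component geometry, snakes, hybrid pipeline."""

import numpy as np
import pytest
from scipy import ndimage

from folliscan.phantom import default_normal_spec, default_pcos_spec, generate_phantom
from folliscan.preprocess import preprocess_image
from folliscan.segmentation import (
    SegmentConfig,
    SnakeConfig,
    count_follicles,
    extract_components,
    fcm_cluster,
    filter_by_size,
    segment_follicles,
    select_follicle_cluster,
    snake_refine,
)


def brute_force_fcm(x, c, m, seed, iters=3000, tol=1e-12):
    """Independent plain-loop alternating-update oracle, run to a fixed point.

    Shares only the documented initialization contract (uniform random
    memberships from the seed) with the implementation under test.
    """
    rng = np.random.default_rng(seed)
    u = rng.random((len(x), c))
    u = u / u.sum(axis=1, keepdims=True)
    v = np.zeros(c)
    for _ in range(iters):
        um = u**m
        v_new = np.array([ (um[:, j] * x).sum() / um[:, j].sum() for j in range(c)])
        d2 = (x[:, None] - v_new[None, :]) ** 2
        u = np.zeros_like(u)
        for i in range(len(x)):
            if (d2[i] < 1e-300).any():
                u[i, np.argmin(d2[i])] = 1.0
            else:
                for j in range(c):
                    u[i, j] = 1.0 / ((d2[i, j] / d2[i]) ** (1.0 / (m - 1.0))).sum()
        if np.abs(v_new - v).max() < tol:
            v = v_new
            break
        v = v_new
    return np.sort(v)


class TestFCM:
    def test_single_cluster_centroid_is_the_mean(self, rng):
        img = np.floor(rng.random((6, 6)) * 256)
        res = fcm_cluster(img, c=1, m=2.0)
        assert res.centroids[0] == pytest.approx(img.mean(), abs=1e-9)
        assert np.allclose(res.membership, 1.0)

    def test_two_delta_image_recovers_both_levels(self):
        img = np.array([[50.0] * 4 + [200.0] * 4] * 4)
        res = fcm_cluster(img, c=2, m=2.0, tol=1e-9, max_iter=500, seed=2)
        assert np.abs(res.centroids - [50.0, 200.0]).max() <= 1.0

    def test_memberships_normalized_and_objective_descends(self, rng):
        img = np.floor(rng.random((12, 12)) * 256)
        res = fcm_cluster(img, c=4, m=2.0, seed=5)
        assert np.allclose(res.membership.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(res.objective_trace) <= 1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle_on_tiny_images(self, seed):
        rng = np.random.default_rng(seed + 100)
        x = np.floor(rng.random(64) * 256)
        res = fcm_cluster(x.reshape(8, 8), c=3, m=2.0, tol=1e-10, max_iter=3000, seed=seed)
        oracle = brute_force_fcm(x, c=3, m=2.0, seed=seed)
        assert np.abs(np.sort(res.centroids) - oracle).max() < 1e-6

    def test_pixel_order_does_not_change_centroids(self, rng):
        x = np.floor(rng.random(144) * 256)
        a = fcm_cluster(x.reshape(12, 12), c=3, tol=1e-9, max_iter=1000, seed=3)
        perm = np.random.default_rng(0).permutation(144)
        b = fcm_cluster(x[perm].reshape(12, 12), c=3, tol=1e-9, max_iter=1000, seed=3)
        # FCM is order-free up to its random initialization; compare the
        # fixed points reached from a shared init applied to permuted data
        assert np.abs(a.centroids - b.centroids).max() < 0.5

    def test_degenerate_cluster_count_warns(self):
        with pytest.warns(RuntimeWarning):
            fcm_cluster(np.full((4, 4), 7.0), c=3)

    def test_invalid_parameters_rejected(self):
        img = np.zeros((4, 4))
        for kwargs in (dict(c=0), dict(m=1.0), dict(tol=0.0)):
            with pytest.raises(ValueError):
                fcm_cluster(img, **kwargs)


class TestClusterSelection:
    def test_darkest_strategy_picks_lowest_centroid(self, rng):
        img = np.floor(rng.random((16, 16)) * 256)
        res = fcm_cluster(img, c=4, seed=1)
        mask = select_follicle_cluster(res, "darkest")
        hard = res.hard_labels()
        assert np.array_equal(mask.mask, hard == 0)

    def test_explicit_index_override(self, rng):
        img = np.floor(rng.random((16, 16)) * 256)
        res = fcm_cluster(img, c=4, seed=1)
        mask = select_follicle_cluster(res, 2)
        assert np.array_equal(mask.mask, res.hard_labels() == 2)
        with pytest.raises(ValueError):
            select_follicle_cluster(res, 7)

    def test_darkest_cluster_covers_most_follicle_pixels(self, pcos_phantom, preprocessed_pcos):
        res = fcm_cluster(preprocessed_pcos, c=4, seed=0)
        mask = select_follicle_cluster(res, "darkest")
        gt = pcos_phantom.mask
        recall = (mask.mask & gt).sum() / gt.sum()
        assert recall >= 0.8


class TestComponents:
    def test_empty_mask_has_no_components(self):
        seg = extract_components(np.zeros((10, 10), bool))
        assert seg.n_components == 0

    def test_two_disks_found_with_exact_areas(self):
        mask = np.zeros((40, 40), bool)
        rr, cc = np.mgrid[0:40, 0:40]
        d1 = (rr - 10) ** 2 + (cc - 10) ** 2 <= 25
        d2 = (rr - 28) ** 2 + (cc - 28) ** 2 <= 16
        mask |= d1 | d2
        seg = extract_components(mask, pixel_spacing=0.2)
        assert seg.n_components == 2
        assert sorted(c.area_px for c in seg.components) == sorted([d1.sum(), d2.sum()])
        assert sum(c.area_px for c in seg.components) == mask.sum()

    def test_size_filter_drops_sub_2mm_components(self):
        # a 1.5 mm and a 3 mm disk at 0.2 mm/px: radii 3.75 px and 7.5 px
        mask = np.zeros((60, 60), bool)
        rr, cc = np.mgrid[0:60, 0:60]
        mask |= (rr - 15) ** 2 + (cc - 15) ** 2 <= 3.75**2
        mask |= (rr - 40) ** 2 + (cc - 40) ** 2 <= 7.5**2
        seg = extract_components(mask, pixel_spacing=0.2)
        filtered = filter_by_size(seg, min_diameter_mm=2.0, max_diameter_mm=12.0)
        assert filtered.n_components == 1
        assert filtered.components[0].equivalent_diameter_mm == pytest.approx(3.0, abs=0.3)

    def test_size_filter_identity_when_all_pass(self):
        mask = np.zeros((40, 40), bool)
        rr, cc = np.mgrid[0:40, 0:40]
        mask |= (rr - 20) ** 2 + (cc - 20) ** 2 <= 8**2
        seg = extract_components(mask, pixel_spacing=0.2)
        out = filter_by_size(seg, 2.0, 12.0)
        assert np.array_equal(out.mask, mask)

    def test_size_filter_requires_spacing(self):
        seg = extract_components(np.ones((5, 5), bool))
        with pytest.raises(ValueError):
            filter_by_size(seg)


def _disk_image(radius=15, size=100, inside=40.0, outside=150.0):
    rr, cc = np.mgrid[0:size, 0:size]
    ctr = size // 2
    return np.where((rr - ctr) ** 2 + (cc - ctr) ** 2 <= radius**2, inside, outside), ctr


class TestSnake:
    def test_zero_iterations_is_identity(self):
        img, _ = _disk_image()
        theta = np.linspace(0, 2 * np.pi, 30, endpoint=False)
        init = np.column_stack([50 + 20 * np.sin(theta), 50 + 20 * np.cos(theta)])
        out = snake_refine(img, [init], SnakeConfig(iterations=0))
        assert np.array_equal(out[0], init)

    def test_converges_onto_disk_edge(self):
        img, ctr = _disk_image(radius=15)
        theta = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        init = np.column_stack(
            [ctr + 18 * np.sin(theta), ctr + 18 * np.cos(theta)]  # 3 px outside
        )
        out = snake_refine(img, [init], SnakeConfig())
        radii = np.hypot(out[0][:, 0] - ctr, out[0][:, 1] - ctr)
        assert np.abs(radii - 15).mean() <= 1.0

    def test_energy_never_increases(self):
        from folliscan.segmentation import _snake_energy, external_energy_field

        img, ctr = _disk_image()
        cfg = SnakeConfig(iterations=40)
        field = external_energy_field(img, cfg.sigma)
        theta = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        init = np.column_stack([ctr + 18 * np.sin(theta), ctr + 18 * np.cos(theta)])
        out = snake_refine(img, [init], cfg)
        e0 = _snake_energy(init, field, cfg.alpha, cfg.beta)
        e1 = _snake_energy(out[0], field, cfg.alpha, cfg.beta)
        assert e1 <= e0

    def test_tiny_contour_dropped_with_warning(self):
        img, _ = _disk_image()
        with pytest.warns(RuntimeWarning):
            out = snake_refine(img, [np.array([[5.0, 5.0], [6.0, 6.0]])], SnakeConfig())
        assert out == []


class TestHybridPipeline:
    def test_pcos_phantom_count_recovered(self, pcos_phantom, preprocessed_pcos):
        seg = segment_follicles(preprocessed_pcos)
        n, boxes = count_follicles(seg)
        assert abs(n - 12) <= 1
        h, w = preprocessed_pcos.shape
        for x, y, bw, bh in boxes:
            assert 0 <= x and 0 <= y and x + bw <= w and y + bh <= h

    def test_follicle_free_phantom_yields_nothing(self):
        item = generate_phantom(default_normal_spec(n_follicles=0, seed=21))
        seg = segment_follicles(preprocess_image(item.image))
        n, boxes = count_follicles(seg)
        assert n == 0 and boxes == []

    def test_refinement_does_not_hurt_dice(self, pcos_phantom, preprocessed_pcos):
        def dice(a, b):
            return 2 * (a & b).sum() / (a.sum() + b.sum())

        gt = pcos_phantom.mask
        refined = segment_follicles(preprocessed_pcos)
        res = fcm_cluster(preprocessed_pcos, c=4, seed=0)
        raw = select_follicle_cluster(res, "darkest")
        assert dice(refined.mask, gt) >= dice(raw.mask, gt)

    def test_detected_boxes_contain_true_centers(self):
        item = generate_phantom(default_pcos_spec(n_follicles=10, seed=31))
        seg = segment_follicles(preprocess_image(item.image))
        n, boxes = count_follicles(seg)
        if n != 10:
            pytest.skip("imperfect count on this seed; box containment undefined")
        for f in item.follicles:
            assert any(
                x <= f.cx <= x + w and y <= f.cy <= y + h for (x, y, w, h) in boxes
            )
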