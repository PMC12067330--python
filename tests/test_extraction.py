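"""Reference-point extraction: normalization, segmentation, profiles."""

import numpy as np
import pytest

import gridcal.extraction as ex
from gridcal.synthetic import (GridSpec, GroundTruth, distort_points,
                               make_undistorted_grid, render_chessboard,
                               render_dot_pattern, render_line_pattern)


def _two_level(shape=(64, 64), bg=0.2, fg=0.8, n_dots=4, r=4):
    img = np.full(shape, bg)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    centers = [(16, 16), (16, 48), (48, 16), (48, 48)][:n_dots]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = fg
    return img, centers


class TestNormalize:
    def test_constant_image_maps_to_ones(self):
        out = ex.normalize_background(np.full((64, 64), 3.7), "gaussian", 21)
        assert np.allclose(out, 1.0, atol=1e-6)

    def test_linear_ramp_contrast_preserved(self):
        spec = GridSpec(n_hlines=5, n_vlines=5, spacing=40, dot_radius=5,
                        image_height=256, image_width=256)
        pts, _, _ = make_undistorted_grid(spec)
        flat, _ = render_dot_pattern(pts, spec, rng=0)
        ramped, _ = render_dot_pattern(pts, spec, rng=0, background_gradient=0.5)

        def contrast(img):
            n = ex.normalize_background(img, "gaussian", 61)
            return np.median(n) - n.min()

        assert abs(contrast(ramped) - contrast(flat)) < 0.05 * contrast(flat)

    def test_zero_background_region_stays_finite(self):
        img = np.ones((64, 64))
        img[:32] = 0.0
        out = ex.normalize_background(img, "median", 9)
        assert np.all(np.isfinite(out))

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            ex.normalize_background(np.ones((64, 64)), "median", 64)


class TestBinarize:
    def test_two_level_otsu_threshold_and_area(self):
        img, _ = _two_level()
        mask, med = ex.binarize(img, "otsu")
        # dots are the bright minority phase here
        assert mask.sum() == (img > 0.5).sum()
        assert med == pytest.approx(np.median([49, 49, 49, 49]))

    def test_sorting_matches_rank_statistic_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64)) * 0.2
        img[10:20, 10:20] = 0.9
        ratio = 0.95
        flat = np.sort(img.ravel())
        thr_oracle = flat[int(round(ratio * (flat.size - 1)))]
        mask, _ = ex.binarize(img, "sorting", ratio=ratio)
        oracle_dark = img < thr_oracle
        oracle = oracle_dark if oracle_dark.mean() <= 0.5 else ~oracle_dark
        assert np.array_equal(mask, oracle)

    def test_inverted_contrast_with_flag_gives_same_mask(self):
        img, _ = _two_level()
        m1, _ = ex.binarize(img, "otsu", invert=True)
        m2, _ = ex.binarize(1.0 - img, "otsu", invert=False)
        assert np.array_equal(m1, m2)

    def test_uniform_image_rejected(self):
        with pytest.raises(ValueError, match="bimodal"):
            ex.binarize(np.full((64, 64), 0.5))


class TestCentroids:
    def test_symmetric_square_centroid(self):
        mask = np.zeros((40, 40), bool)
        mask[10:13, 20:23] = True
        pts, sizes = ex.get_dot_centroids(mask)
        assert np.allclose(pts, [[21.0, 11.0]])
        assert sizes.tolist() == [9]

    def test_two_discs_recovered(self):
        img, centers = _two_level(n_dots=2)
        mask, _ = ex.binarize(img, "otsu")
        pts, _ = ex.get_dot_centroids(mask)
        assert len(pts) == 2
        for cy, cx in centers:
            assert min(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)) < 0.1

    def test_full_frame_foreground_gives_center(self):
        mask = np.ones((21, 31), bool)
        pts, _ = ex.get_dot_centroids(mask)
        assert np.allclose(pts, [[15.0, 10.0]])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ex.get_dot_centroids(np.zeros((32, 32), bool))


class TestFilters:
    def test_size_filter_drops_outlier(self):
        pts = np.arange(8, dtype=float).reshape(4, 2)
        kept, _ = ex.filter_by_size(pts, [50, 52, 48, 300], 0.3)
        assert len(kept) == 3

    def test_size_filter_keeps_equal_sizes(self):
        pts = np.arange(8, dtype=float).reshape(4, 2)
        kept, _ = ex.filter_by_size(pts, [50, 50, 50, 50], 0.3)
        assert len(kept) == 4

    def test_size_filter_idempotent(self):
        pts = np.arange(10, dtype=float).reshape(5, 2)
        sizes = np.array([50.0, 52, 48, 51, 300])
        k1, s1 = ex.filter_by_size(pts, sizes, 0.3)
        k2, s2 = ex.filter_by_size(k1, s1, 0.3)
        assert np.array_equal(k1, k2)

    def test_ellipticity_keeps_disc_drops_bar(self):
        mask = np.zeros((64, 64), bool)
        yy, xx = np.mgrid[0:64, 0:64]
        mask[(yy - 16) ** 2 + (xx - 16) ** 2 <= 36] = True   # disc
        mask[40:42, 10:30] = True                            # 20x2 bar
        pts, _ = ex.get_dot_centroids(mask)
        kept = ex.filter_by_ellipticity(mask, pts, max_ratio=2.0)
        assert len(kept) == 1
        assert np.hypot(kept[0, 0] - 16, kept[0, 1] - 16) < 0.5
        # independent moment oracle for the bar's axis ratio
        ys, xs = np.nonzero(np.zeros_like(mask) | (yy >= 40) & (yy < 42)
                            & (xx >= 10) & (xx < 30))
        mu_xx = np.var(xs) + 1 / 12
        mu_yy = np.var(ys) + 1 / 12
        assert np.sqrt(mu_xx / mu_yy) > 2.0

    def test_misplaced_dot_removed_but_lattice_kept(self):
        spec = GridSpec(n_hlines=7, n_vlines=7, spacing=20,
                        image_height=200, image_width=200)
        pts, _, _ = make_undistorted_grid(spec)
        bad = pts[24] + [10.0, 10.0]   # half-spacing diagonal displacement
        cloud = np.vstack([np.delete(pts, 24, axis=0), bad])
        kept = ex.remove_misplaced_dots(cloud, 0.25)
        assert len(kept) == len(cloud) - 1
        assert not any(np.allclose(p, bad) for p in kept)

    def test_perfect_lattice_untouched_including_corners(self):
        spec = GridSpec(n_hlines=6, n_vlines=6, spacing=20,
                        image_height=160, image_width=160)
        pts, _, _ = make_undistorted_grid(spec)
        assert len(ex.remove_misplaced_dots(pts, 0.3)) == len(pts)


class TestProfileDetection:
    def test_line_pattern_points_near_truth(self):
        spec = GridSpec(n_hlines=5, n_vlines=5, spacing=40, line_width=3,
                        image_height=256, image_width=256)
        pts, rows, cols = make_undistorted_grid(spec)
        img = render_line_pattern(pts, rows, cols, spec)
        found = ex.detect_points_on_lines(img, "horizontal", 10, 7)
        true_ys = np.unique(pts[:, 1])
        in_span = found[(found[:, 0] > pts[:, 0].min()) & (found[:, 0] < pts[:, 0].max())]
        assert len(in_span) >= 5 * 10
        err = np.abs(in_span[:, 1][:, None] - true_ys[None, :]).min(axis=1)
        assert err.max() < 0.5

    def test_constant_image_raises(self):
        with pytest.raises(ValueError):
            ex.detect_points_on_lines(np.full((128, 128), 0.4), "horizontal")

    def test_rotated_pattern_detection_count_stable(self):
        spec = GridSpec(n_hlines=5, n_vlines=5, spacing=40, line_width=3,
                        image_height=256, image_width=256)
        p0, r0, c0 = make_undistorted_grid(spec)
        pr, rr, cr = make_undistorted_grid(spec, slope=0.05)
        n0 = len(ex.detect_points_on_lines(render_line_pattern(p0, r0, c0, spec),
                                           "horizontal", 10, 7))
        nr = len(ex.detect_points_on_lines(render_line_pattern(pr, rr, cr, spec),
                                           "horizontal", 10, 7))
        assert abs(nr - n0) <= 0.05 * n0


class TestValidateExtremum:
    def test_exact_gaussian_mean_recovered(self):
        x = np.arange(40, dtype=float)
        prof = 1.0 - 0.6 * np.exp(-0.5 * ((x - 17.3) / 2.0) ** 2)
        loc = ex.validate_extremum(prof, 17, window=11)
        assert loc is not None and abs(loc - 17.3) < 0.05

    def test_single_sample_spike_rejected(self):
        prof = np.full(40, 0.5)
        prof[20] = 0.1
        assert ex.validate_extremum(prof, 20, window=9) is None

    def test_noisy_gaussian_monte_carlo(self):
        # line-profile dip of width 1.5 samples, noise at 10% of amplitude
        rng = np.random.default_rng(123)
        x = np.arange(48, dtype=float)
        hits = 0
        for _ in range(200):
            prof = (1.0 - 0.6 * np.exp(-0.5 * ((x - 20.4) / 1.5) ** 2)
                    + rng.normal(0, 0.06, 48))
            loc = ex.validate_extremum(prof, 20, window=11,
                                       quality_threshold=0.5)
            if loc is not None and abs(loc - 20.4) < 0.3:
                hits += 1
        assert hits >= 0.95 * 200


class TestChessboardOps:
    def test_gradient_of_constant_is_zero(self):
        grad = ex.chessboard_to_line_image(np.full((64, 64), 0.3))
        assert np.allclose(grad, 0.0, atol=1e-12)

    def test_gradient_ridges_near_boundaries(self):
        spec = GridSpec(n_hlines=5, n_vlines=5, spacing=40,
                        image_height=256, image_width=256)
        img = render_chessboard(spec, supersample=4)
        grad = ex.chessboard_to_line_image(img)
        pts, _, _ = make_undistorted_grid(spec)
        for ty in np.unique(pts[:, 1])[1:-1]:
            col = grad[:, 100]
            peak = np.argmax(col[int(ty) - 3:int(ty) + 4]) + int(ty) - 3
            assert abs(peak - ty) <= 1

    def test_inverted_board_same_gradient_magnitude(self):
        spec = GridSpec(n_hlines=5, n_vlines=5, spacing=40,
                        image_height=256, image_width=256)
        img = render_chessboard(spec, supersample=4)
        g1 = ex.chessboard_to_line_image(img)
        g2 = ex.chessboard_to_line_image(spec.background_level
                                         + spec.feature_level - img)
        assert np.allclose(g1, g2, atol=1e-12)

    def test_ideal_step_edge_located(self):
        prof = np.where(np.arange(80) < 40, 0.2, 0.8)
        pos = [ex.validate_extremum(np.abs(ex._sliding_slope(prof, 7)), 39,
                                    window=11)]
        # slope peak of a step between samples 39 and 40 -> ~39.5
        assert pos[0] is not None and abs(pos[0] - 39.5) <= 0.5

    def test_constant_profile_gives_no_edge_points(self):
        img = np.full((128, 128), 0.5)
        assert len(ex.chessboard_edge_points(img, "horizontal", 10, 7)) == 0

    def test_rendered_board_corners_recovered(self):
        spec = GridSpec(n_hlines=5, n_vlines=5, spacing=40,
                        image_height=256, image_width=256)
        img = render_chessboard(spec)
        found = ex.chessboard_edge_points(img, "horizontal", 10, 7)
        pts, _, _ = make_undistorted_grid(spec)
        in_span = found[(found[:, 0] > pts[:, 0].min()) & (found[:, 0] < pts[:, 0].max())]
        assert len(in_span) > 0
        true_ys = np.unique(pts[:, 1])
        err = np.abs(in_span[:, 1][:, None] - true_ys[None, :]).min(axis=1)
        assert err.max() < 0.5


class TestSupportingOps:
    def test_grid_slope_zero_for_axis_aligned(self):
        spec = GridSpec(n_hlines=7, n_vlines=7, spacing=20,
                        image_height=200, image_width=200)
        pts, _, _ = make_undistorted_grid(spec)
        sh, sv = ex.calc_grid_slope(pts)
        assert abs(sh) < 1e-3 and abs(sv) < 1e-3

    @pytest.mark.parametrize("slope", [0.05, -0.05])
    def test_grid_slope_recovers_rotation(self, slope):
        spec = GridSpec(n_hlines=7, n_vlines=7, spacing=20,
                        image_height=220, image_width=220)
        pts, _, _ = make_undistorted_grid(spec, slope=slope)
        sh, _ = ex.calc_grid_slope(pts)
        assert abs(sh - slope) < 5e-3

    def test_parabolic_mask_full_and_empty(self):
        pts = np.random.default_rng(0).random((50, 2)) * 100
        assert len(ex.mask_points_parabolic(pts, (0, 0, 50), np.inf)) == 50
        assert len(ex.mask_points_parabolic(pts, (0, 0, -500), 1.0)) == 0

    def test_halfplane_mask_exact_count(self):
        spec = GridSpec(n_hlines=6, n_vlines=6, spacing=20,
                        image_height=160, image_width=160)
        pts, _, _ = make_undistorted_grid(spec)
        # keep points below the horizontal line through the grid middle
        cut = np.median(np.unique(pts[:, 1]))
        kept = ex.mask_points_parabolic(pts, (0, 0, cut + 1), side="below")
        assert len(kept) == 18

    def test_remove_subset_box(self):
        pts = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
        out = ex.remove_subset(pts, (4, 6, 4, 6))
        assert len(out) == 2 and not any((p == [5.0, 5.0]).all() for p in out)


class TestFullDotPipeline:
    def test_recovery_rate_and_accuracy(self, dot_image):
        from scipy.spatial import cKDTree
        from gridcal.pipeline import extract_points
        pts, _ = extract_points(dot_image["image"], dot_image["config"])
        truth_pts = dot_image["distorted"]
        tree = cKDTree(truth_pts)
        d, _ = tree.query(pts)
        assert len(pts) >= 0.99 * len(truth_pts)
        assert (d < 0.2).mean() >= 0.99
        assert np.sqrt((d ** 2).mean()) < 0.2

    def test_defective_dots_filtered(self):
        spec = GridSpec(n_hlines=12, n_vlines=12, spacing=40, dot_radius=5,
                        image_height=520, image_width=520, defect_rate=0.08)
        pts, _, _ = make_undistorted_grid(spec)
        img, ledger = render_dot_pattern(pts, spec, rng=5)
        norm = ex.normalize_background(img, "gaussian", 31)
        mask, _ = ex.binarize(norm)
        found, sizes = ex.get_dot_centroids(mask)
        found, sizes = ex.filter_by_size(found, sizes, 0.3)
        found = ex.filter_by_ellipticity(mask, found, 2.0)
        from scipy.spatial import cKDTree
        good = np.delete(pts, ledger.all_defective, axis=0)
        d, back = cKDTree(found).query(good)
        # every non-defective dot is recovered accurately, and dots the
        # ledger removed yield no spurious detection at their old position
        assert (d < 0.2).mean() >= 0.99
        removed_pos = pts[ledger.removed]
        if len(removed_pos):
            dr, _ = cKDTree(found).query(removed_pos)
            assert dr.min() > 2.0
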