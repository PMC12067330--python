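"""Perspective model: detection, homography solve, quad correspondences."""

import numpy as np
import pytest

from gridcal.center import find_center_coarse, find_center_vanishing_general
from gridcal.grouping import group_points_slope_guided, shift_origin
from gridcal.perspective import (PerspectiveModel, apply_perspective,
                                 build_correspondences,
                                 correct_parabola_coeffs, detect_perspective,
                                 make_tilt_homography, solve_homography)
from gridcal.synthetic import (GridSpec, GroundTruth, distort_points,
                               make_undistorted_grid)


def _center_origin_groups(points, spacing=60.0):
    gh = group_points_slope_guided(points, "horizontal", 0.0, spacing)
    gv = group_points_slope_guided(points, "vertical", 0.0, spacing)
    c = find_center_coarse(gh, gv)
    return shift_origin(gh, c), shift_origin(gv, c)


def _symmetric_mild_grid():
    """Even line count, center mid-grid, barely-there barrel: curvature
    signs are defined but intercepts are metrically exact."""
    spec = GridSpec(n_hlines=20, n_vlines=20, spacing=60,
                    image_height=1400, image_width=1400)
    pts, _, _ = make_undistorted_grid(spec)
    truth = GroundTruth(center=(700.0, 700.0), backward_coeffs=[1.0, -1e-7],
                        _domain=1400)
    return distort_points(pts, truth)


def _tilted_grid(tilt, center=(700.0, 650.0), k1=-4e-5, spacing=60.0):
    spec = GridSpec(n_hlines=21, n_vlines=21, spacing=spacing,
                    image_height=1400, image_width=1400)
    pts, _, _ = make_undistorted_grid(spec)
    persp = make_tilt_homography(center, tilt, -tilt / 2) if tilt else None
    truth = GroundTruth(center=center, backward_coeffs=[1.0, k1],
                        perspective=persp, _domain=1400)
    return distort_points(pts, truth)


class TestSolveHomography:
    SQUARE = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 100.0], [0.0, 100.0]])

    def test_identity_from_identical_quads(self):
        m = solve_homography(self.SQUARE, self.SQUARE)
        assert np.allclose(m.coeffs, [1, 0, 0, 0, 1, 0, 0, 0], atol=1e-12)

    def test_pure_translation_closed_form(self):
        m = solve_homography(self.SQUARE + [5.0, -3.0], self.SQUARE)
        assert np.allclose(m.coeffs, [1, 0, 5, 0, 1, -3, 0, 0], atol=1e-10)

    def test_random_quads_match_linear_solve_oracle(self):
        rng = np.random.default_rng(3)
        src = self.SQUARE + rng.normal(0, 10, (4, 2))
        dst = self.SQUARE + rng.normal(0, 10, (4, 2))
        model = solve_homography(src, dst)
        # independent 8x8 solve
        a = np.zeros((8, 8))
        b = np.zeros(8)
        for k, ((xs, ys), (xd, yd)) in enumerate(zip(src, dst)):
            a[2 * k] = [xd, yd, 1, 0, 0, 0, -xd * xs, -yd * xs]
            a[2 * k + 1] = [0, 0, 0, xd, yd, 1, -xd * ys, -yd * ys]
            b[2 * k], b[2 * k + 1] = xs, ys
        oracle = np.linalg.solve(a, b)
        assert np.abs(model.coeffs - oracle).max() < 1e-8
        assert np.abs(apply_perspective(dst, model) - src).max() < 1e-8

    def test_degenerate_correspondences_rejected(self):
        collinear = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            solve_homography(collinear, collinear)


class TestApplyPerspective:
    def test_identity_model(self):
        pts = np.random.default_rng(0).random((30, 2)) * 100
        out = apply_perspective(pts, PerspectiveModel.identity())
        assert np.array_equal(out, pts)

    def test_defining_quad_maps_exactly(self):
        src = np.array([[0.0, 0], [90, 5], [95, 102], [-4, 98]])
        dst = np.array([[0.0, 0], [100, 0], [100, 100], [0, 100]])
        m = solve_homography(src, dst)
        assert np.abs(apply_perspective(dst, m) - src).max() < 1e-9

    def test_composition_with_inverse_is_identity(self):
        m = make_tilt_homography((50.0, 60.0), 4.0, -2.5)
        pts = np.random.default_rng(1).random((100, 2)) * 120
        back = apply_perspective(apply_perspective(pts, m), m.invert())
        assert np.abs(back - pts).max() < 1e-6

    def test_cross_ratio_preserved(self):
        m = make_tilt_homography((0.0, 0.0), 5.0, 3.0, focal_px=500)
        t = np.array([0.0, 0.3, 0.7, 1.0])
        line = np.column_stack([10 + 80 * t, 20 + 50 * t])
        out = apply_perspective(line, m)

        def cross_ratio(p):
            d = lambda i, j: np.hypot(*(p[i] - p[j]))
            return (d(0, 2) * d(1, 3)) / (d(1, 2) * d(0, 3))

        assert abs(cross_ratio(line) - cross_ratio(out)) < 1e-9


class TestDetect:
    def test_no_perspective_flag_false(self):
        gh, gv = _center_origin_groups(_tilted_grid(0.0))
        trend, flag = detect_perspective(gh.coeffs, gv.coeffs)
        assert not flag
        assert abs(trend.slope_bc_h) * trend.c_span_h < 0.01
        assert abs(trend.slope_bc_v) * trend.c_span_v < 0.01

    def test_tilted_grid_flag_true(self):
        gh, gv = _center_origin_groups(_tilted_grid(4.0))
        _, flag = detect_perspective(gh.coeffs, gv.coeffs)
        assert flag

    def test_b_drift_monotone_in_tilt(self):
        drifts = []
        for tilt in (1.0, 2.5, 4.0):
            gh, gv = _center_origin_groups(_tilted_grid(tilt))
            trend, _ = detect_perspective(gh.coeffs, gv.coeffs)
            drifts.append(max(abs(trend.slope_bc_h) * trend.c_span_h,
                              abs(trend.slope_bc_v) * trend.c_span_v))
        assert drifts[0] < drifts[1] < drifts[2]


class TestCoefficientCorrection:
    def test_isotropic_grid_unchanged_except_b(self):
        gh, gv = _center_origin_groups(_symmetric_mild_grid())
        hp, vp, hc, vc = correct_parabola_coeffs(gh.groups, gv.groups,
                                                 gh.coeffs, gv.coeffs)
        assert np.abs(hc[:, 0] - gh.coeffs[:, 0]).max() < 1e-12
        assert np.abs(hc[:, 2] - gh.coeffs[:, 2]).max() < 1e-9

    def test_anisotropic_spacing_rescaled_exactly(self):
        spec = GridSpec(n_hlines=15, n_vlines=15, spacing=40,
                        image_height=800, image_width=800)
        pts, _, _ = make_undistorted_grid(spec)
        pts_aniso = pts.copy()
        pts_aniso[:, 1] = (pts_aniso[:, 1] - 400) / 1.2 + 400  # v-spacing 40, h-spacing 40/1.2
        gh = group_points_slope_guided(pts_aniso, "horizontal", 0.0, 33.0)
        gv = group_points_slope_guided(pts_aniso, "vertical", 0.0, 40.0)
        hp, vp, hc, vc = correct_parabola_coeffs(gh.groups, gv.groups,
                                                 gh.coeffs, gv.coeffs)
        dch = np.mean(np.diff(np.sort(hc[:, 2])))
        dcv = np.mean(np.diff(np.sort(vc[:, 2])))
        assert dch == pytest.approx(40.0, abs=1e-9)
        assert dcv == pytest.approx(40.0, abs=1e-9)

    def test_detection_clears_after_correction_on_anisotropic_grid(self):
        spec = GridSpec(n_hlines=15, n_vlines=15, spacing=40,
                        image_height=800, image_width=800)
        pts, _, _ = make_undistorted_grid(spec)
        center = (400.0, 400.0)
        truth = GroundTruth(center=center, backward_coeffs=[1.0, -6e-5],
                            _domain=800)
        d = distort_points(pts, truth)
        d[:, 1] = (d[:, 1] - 400) / 1.15 + 400
        gh = group_points_slope_guided(d, "horizontal", 0.0, 34.0)
        gv = group_points_slope_guided(d, "vertical", 0.0, 40.0)
        c = find_center_coarse(gh, gv)
        hs, vs = shift_origin(gh, c), shift_origin(gv, c)
        _, flag_before = detect_perspective(hs.coeffs, vs.coeffs)
        hp, vp, hc, vc = correct_parabola_coeffs(hs.groups, vs.groups,
                                                 hs.coeffs, vs.coeffs)
        _, flag_after = detect_perspective(hc, vc)
        assert flag_before and not flag_after


class TestBuildCorrespondences:
    def test_perspective_free_quads_coincide(self):
        gh, gv = _center_origin_groups(_tilted_grid(0.0))
        dist, und = build_correspondences(gh.coeffs, gv.coeffs)
        assert np.abs(dist - und).max() < 0.5

    def test_tilted_grid_gives_exact_rectangle(self):
        gh, gv = _center_origin_groups(_tilted_grid(4.0))
        _, und = build_correspondences(gh.coeffs, gv.coeffs)
        # ordering (H+V+, H+V-, H-V+, H-V-): angles at every corner are right
        e1 = und[1] - und[0]
        e2 = und[2] - und[0]
        cosang = e1 @ e2 / (np.linalg.norm(e1) * np.linalg.norm(e2))
        assert abs(cosang) < 1e-6

    def test_explicit_scale_sets_side_lengths(self):
        # symmetric grid: the averaged +/- quad lines sit an integer number
        # of line spacings apart, so the scaled quad sides are multiples of
        # the requested 20 px per line
        gh, gv = _center_origin_groups(_symmetric_mild_grid())
        _, und = build_correspondences(gh.coeffs, gv.coeffs, scale=20.0)
        width = np.linalg.norm(und[1] - und[0])
        height = np.linalg.norm(und[2] - und[0])
        assert min(width % 20.0, 20.0 - width % 20.0) < 0.05
        assert min(height % 20.0, 20.0 - height % 20.0) < 0.05
        assert width == pytest.approx(200.0, abs=0.05)


class TestRoundTripProperty:
    def test_solve_recovers_applied_model_over_domain(self):
        m = make_tilt_homography((100.0, 80.0), 3.0, -4.0, focal_px=900)
        rng = np.random.default_rng(6)
        pts = rng.random((50, 2)) * 400 - 100
        mapped = apply_perspective(pts, m)
        est = solve_homography(mapped[:4], pts[:4])
        assert np.abs(apply_perspective(pts, est) - mapped).max() < 1e-6

    def test_model_json_roundtrip(self, tmp_path):
        m = make_tilt_homography((10.0, 20.0), 2.0, 1.0)
        path = tmp_path / "persp.json"
        m.to_json(path)
        m2 = PerspectiveModel.from_json(path)
        assert np.allclose(m.coeffs, m2.coeffs)
        assert m2.direction == m.direction
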