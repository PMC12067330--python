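"""End-to-end calibration workflow.

extraction -> grouping -> distortion center -> perspective correction ->
radial polynomial, with before/after straightness reports.  The stages are
all importable on their own; this module only sequences them and keeps the
bookkeeping (coordinate frames, group ordering, logging of per-stage
counts) in one place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import extraction as ex
from .config import CalibConfig
from .center import (find_center_coarse, find_center_vanishing_general,
                     refine_center_iterative)
from .grouping import (LineGroups, group_points_middle_out,
                       group_points_slope_guided, remove_residual_outliers,
                       shift_origin)
from .perspective import (PerspectiveModel, apply_perspective,
                          correct_parabola_coeffs, detect_perspective)
from .postproc import ResidualReport, evaluate_straightness
from .radial import (RadialModel, calc_coeffs, compute_undistorted_intercepts,
                     refine_spacing, unwarp_points)

log = logging.getLogger("gridcal")

__all__ = ["CalibrationResult", "extract_points", "calibrate_points",
           "calibrate_image", "correct_points"]


@dataclass
class CalibrationResult:
    """Everything the calibration of one image produces."""

    center: tuple[float, float]
    radial_backward: RadialModel
    radial_forward: RadialModel
    perspective_forward: PerspectiveModel | None
    perspective_flag: bool
    groups_h: LineGroups
    groups_v: LineGroups
    corrected_h: LineGroups
    corrected_v: LineGroups
    residual_before: ResidualReport
    residual_after: ResidualReport

    def perspective_backward_image_frame(self) -> PerspectiveModel | None:
        """Backward homography for image resampling (the stored forward
        model already lives in image coordinates)."""
        if self.perspective_forward is None:
            return None
        return self.perspective_forward.invert()

    def summary(self) -> dict:
        return {
            "center": [self.center[0], self.center[1]],
            "perspective_detected": bool(self.perspective_flag),
            "n_hlines": len(self.groups_h),
            "n_vlines": len(self.groups_v),
            "residual_before_max": self.residual_before.max,
            "residual_before_rms": self.residual_before.rms,
            "residual_after_max": self.residual_after.max,
            "residual_after_rms": self.residual_after.rms,
        }


def extract_points(image: np.ndarray, config: CalibConfig):
    """Reduce a calibration image to reference points.

    Returns (points_for_horizontal_grouping, points_for_vertical_grouping);
    for dot patterns the two sets are identical, for line/chessboard
    patterns each orientation has its own profile-cast points.
    """
    cfg = config
    if cfg.pattern_type == "dot":
        norm = ex.normalize_background(image, cfg.normalization_method,
                                       cfg.normalization_size)
        mask, _ = ex.binarize(norm, cfg.binarization_method, cfg.binarization_ratio)
        # dots clipped by the image border have biased centroids
        from skimage.segmentation import clear_border
        mask = clear_border(mask)
        # center of mass of each dot: weighted by contrast against the
        # normalized background (~1) by default, plain binary on request
        weights = np.abs(norm - 1.0) if cfg.centroid_method == "weighted" else None
        pts, sizes = ex.get_dot_centroids(mask, weights=weights)
        n0 = len(pts)
        pts, sizes = ex.filter_by_size(pts, sizes, cfg.size_tolerance)
        n1 = len(pts)
        pts = ex.filter_by_ellipticity(mask, pts, cfg.ellipticity_max_ratio)
        n2 = len(pts)
        if cfg.misplaced_tolerance is not None:
            pts = ex.remove_misplaced_dots(pts, cfg.misplaced_tolerance)
        log.info("extraction: %d dots, %d after size filter, %d after "
                 "ellipticity, %d final", n0, n1, n2, len(pts))
        return pts, pts
    if cfg.pattern_type == "chessboard":
        # square boundaries as step edges -> sliding linear-fit peaks
        pts_h = ex.chessboard_edge_points(image, "horizontal",
                                          cfg.profile_spacing, cfg.search_radius)
        pts_v = ex.chessboard_edge_points(image, "vertical",
                                          cfg.profile_spacing, cfg.search_radius)
    else:
        pts_h = ex.detect_points_on_lines(image, "horizontal", cfg.profile_spacing,
                                          cfg.search_radius, "auto",
                                          cfg.quality_threshold)
        pts_v = ex.detect_points_on_lines(image, "vertical", cfg.profile_spacing,
                                          cfg.search_radius, "auto",
                                          cfg.quality_threshold)
    # a genuine line/chessboard pattern yields regularly spaced points on
    # most cast profiles; irregular or sparse per-profile spacing means the
    # image is probably a different pattern type (e.g. dots)
    for pts, orientation, extent in ((pts_h, "horizontal", image.shape[1]),
                                     (pts_v, "vertical", image.shape[0])):
        n_profiles = len(range(cfg.profile_spacing // 2, extent,
                               cfg.profile_spacing))
        pos_axis = 0 if orientation == "horizontal" else 1
        regular = 0
        for u in np.unique(pts[:, pos_axis]):
            ords = np.sort(pts[pts[:, pos_axis] == u, 1 - pos_axis])
            if len(ords) >= 4:
                gaps = np.diff(ords)
                if gaps.max() <= 1.8 * np.median(gaps):
                    regular += 1
        if regular < 0.5 * n_profiles:
            raise ValueError(
                f"only {regular}/{n_profiles} {orientation} profiles show "
                f"regular line structure; the image does not look like a "
                f"{cfg.pattern_type!r} pattern - check pattern_type")
    log.info("extraction: %d horizontal-line points, %d vertical-line points",
             len(pts_h), len(pts_v))
    return pts_h, pts_v


def _group(points: np.ndarray, orientation: str, cfg: CalibConfig,
           slope: float) -> LineGroups:
    if cfg.grouping_mode == "middle_out":
        nominal = cfg.nominal_distance
        if nominal is None:
            raise ValueError("middle_out grouping needs nominal_distance")
        g = group_points_middle_out(points, orientation, nominal)
    else:
        g = group_points_slope_guided(points, orientation, slope,
                                      cfg.nominal_distance,
                                      cfg.grouping_tolerance, cfg.max_missing)
    return remove_residual_outliers(g, cfg.residual_threshold)


def _refine_perspective_with_radial(ch: LineGroups, cv: LineGroups,
                                    persp, radial_center, center,
                                    cfg: CalibConfig, n_pass: int = 5):
    """Iteratively flatten the grid onto its ideal lattice lines.

    Each pass fits a radial model to the current perspective-corrected
    groups, radially unwarps the grouped points (making the lines straight
    up to the residual perspective), solves the incremental homography
    that flattens the straightened points onto their ideal equidistant
    lattice lines (one linear equation per point), and composes the
    correction into the perspective model.  The iteration is not monotone
    (the coarse center re-estimate is noisy), so the best state by its own
    straightness objective is kept.  A Levenberg-Marquardt polish
    (:func:`_lm_polish_perspective`) then removes what the fixed-point
    iteration cannot.
    """
    from .perspective import solve_homography_from_lines

    best = None
    for _ in range(n_pass + 1):
        hs, vs = shift_origin(ch, radial_center), shift_origin(cv, radial_center)
        table_h = compute_undistorted_intercepts(hs.coeffs, cfg.n_near)
        table_v = compute_undistorted_intercepts(vs.coeffs, cfg.n_near)
        try:
            fwd = calc_coeffs(hs.groups, vs.groups, table_h, table_v,
                              cfg.poly_order, "forward", radial_center)
        except ValueError:
            break
        origin = np.asarray(radial_center)
        uh = [unwarp_points(g + origin, fwd) - origin for g in hs.groups]
        uv = [unwarp_points(g + origin, fwd) - origin for g in vs.groups]
        resid = evaluate_straightness(uh + uv).max
        if best is None or resid < best[0]:
            best = (resid, ch, cv, persp, radial_center, center)
        try:
            delta = solve_homography_from_lines(uh, table_h.c_und,
                                                uv, table_v.c_und,
                                                direction="forward")
        except ValueError:
            break
        span = np.abs(np.vstack(uh)).max()
        probe = np.array([[span, span], [-span, span], [span, -span],
                          [-span, -span], [0.0, 0.0]])
        move = np.abs(apply_perspective(probe, delta) - probe).max()
        if move > 0.05 * span:
            break
        delta_img = delta.with_origin(radial_center)
        ch = LineGroups("horizontal", [apply_perspective(g, delta_img)
                                       for g in ch.groups]).refit().sort_by_intercept()
        cv = LineGroups("vertical", [apply_perspective(g, delta_img)
                                     for g in cv.groups]).refit().sort_by_intercept()
        persp = delta_img.compose(persp) if persp is not None else delta_img
        try:
            radial_center = find_center_coarse(ch, cv)
        except ValueError:
            pass
        pre = apply_perspective(np.asarray(radial_center)[None, :],
                                persp.invert())[0]
        center = (float(pre[0]), float(pre[1]))
        if move < 0.02:
            break
    if best is not None:
        _, ch, cv, persp, radial_center, center = best
    # alternate the LM polish (which co-adapts the homography to a fixed
    # center, but can drift the grid's true center by a couple of px along
    # its flat direction) with the model-corrected center estimate, until
    # the post-polish center estimate stops moving
    for _ in range(3):
        ch, cv, persp, radial_center, center = _lm_polish_perspective(
            ch, cv, persp, radial_center, center, cfg)
        try:
            cand = _model_corrected_center(ch, cv, radial_center, cfg)
        except (ValueError, np.linalg.LinAlgError):
            break
        shift = np.hypot(cand[0] - radial_center[0], cand[1] - radial_center[1])
        radial_center = cand
        if persp is not None:
            pre = apply_perspective(np.asarray(radial_center)[None, :],
                                    persp.invert())[0]
            center = (float(pre[0]), float(pre[1]))
        else:
            center = radial_center
        if shift < 0.3:
            break
    # closing polish with the grid pinned to the center (no translation
    # freedom): restores straightness without disturbing the center
    return _lm_polish_perspective(ch, cv, persp, radial_center, center, cfg,
                                  allow_shift=False)


def _lm_polish_perspective(ch: LineGroups, cv: LineGroups,
                           persp, radial_center, center,
                           cfg: CalibConfig, max_nfev: int = 120,
                           allow_shift: bool = True):
    """Polish the perspective model against the radial-fit straightness.

    The four-corner homography estimated from curved lines carries a small
    projective bias, and removing it by re-estimating quads on straightened
    lines converges slowly for strong tilt.  Instead, the eight incremental
    homography coefficients are optimized directly by Levenberg-Marquardt:
    for each candidate the radial polynomial is refitted to the corrected
    points (with intercept tables re-anchored at the fixed center) and the
    residual vector is every point's signed distance to its group's
    straight line after radial correction.  The similarity components of
    the increment are flat directions of this objective and are handled by
    the damping; the projective/shear components converge in a few dozen
    evaluations.
    """
    from scipy.optimize import least_squares
    from .postproc import _line_residuals
    from .perspective import PerspectiveModel

    origin = np.asarray(radial_center, dtype=float)
    hs, vs = shift_origin(ch, radial_center), shift_origin(cv, radial_center)
    groups0 = hs.groups + vs.groups
    n_h = len(hs.groups)
    n_pts = sum(len(g) for g in groups0)
    # nine parameters: traceless affine block (anisotropic scale, shear,
    # rotation), translation, projective row, plus a redundant center
    # shift.  Uniform scale is a flat direction of the straightness
    # objective (the radial polynomial absorbs it) and is excluded.  The
    # center shift duplicates the translation exactly; the redundancy is
    # deliberate — it preconditions the damped solve, which otherwise
    # stalls in a shallow local minimum — and is folded back into the
    # homography afterwards, so the reported center stays unique.
    scales = np.array([1e-3, 1e-3, 1e-3, 1.0, 1.0, 1e-6, 1e-6, 1.0, 1.0])
    n_par = 9 if allow_shift else 5

    def delta_model(p):
        if not allow_shift:
            # translation and the redundant shift frozen: the closing
            # polish must not move the grid relative to the center
            p = np.concatenate([p[:3], [0.0, 0.0], p[3:5], [0.0, 0.0]])
        q = p * scales
        coeffs = np.array([1 + q[0], q[1], q[3], q[2], 1 - q[0], q[4],
                           q[5], q[6]])
        # absorb the redundant shift (dcx, dcy) exactly:
        # (num - dc*den)/den is again a homography
        coeffs[0] -= q[7] * q[5]
        coeffs[1] -= q[7] * q[6]
        coeffs[2] -= q[7]
        coeffs[3] -= q[8] * q[5]
        coeffs[4] -= q[8] * q[6]
        coeffs[5] -= q[8]
        return PerspectiveModel(coeffs, "forward")

    def residuals(p):
        delta = delta_model(p)
        try:
            tg = [apply_perspective(g, delta) for g in groups0]
        except ValueError:
            return np.full(n_pts, 1e3)
        lgh = LineGroups("horizontal", tg[:n_h]).refit().sort_by_intercept()
        lgv = LineGroups("vertical", tg[n_h:]).refit().sort_by_intercept()
        table_h = compute_undistorted_intercepts(lgh.coeffs, cfg.n_near)
        table_v = compute_undistorted_intercepts(lgv.coeffs, cfg.n_near)
        try:
            fwd = calc_coeffs(lgh.groups, lgv.groups, table_h, table_v,
                              cfg.poly_order, "forward", (0.0, 0.0))
        except (ValueError, np.linalg.LinAlgError):
            return np.full(n_pts, 1e3)
        return np.concatenate([_line_residuals(unwarp_points(g, fwd))
                               for g in lgh.groups + lgv.groups])

    try:
        sol = least_squares(residuals, np.zeros(n_par), method="lm",
                            max_nfev=max_nfev)
    except Exception:
        return ch, cv, persp, radial_center, center
    if allow_shift:
        step_ok = (np.all(np.isfinite(sol.x))
                   and np.abs(sol.x[:3]).max() < 50   # |scale/shear/rot| < 0.05
                   and np.abs(sol.x[3:5]).max() < 60  # |translation| < 60 px
                   and np.abs(sol.x[5:7]).max() < 100  # |projective| < 1e-4
                   and np.abs(sol.x[7:]).max() < 60)  # |center shift| < 60 px
    else:
        step_ok = (np.all(np.isfinite(sol.x))
                   and np.abs(sol.x[:3]).max() < 50
                   and np.abs(sol.x[3:]).max() < 100)
    if (not step_ok
            or np.abs(residuals(sol.x)).max()
            >= np.abs(residuals(np.zeros(n_par))).max()):
        return ch, cv, persp, radial_center, center
    delta_img = delta_model(sol.x).with_origin(radial_center)
    ch = LineGroups("horizontal", [apply_perspective(g, delta_img)
                                   for g in ch.groups]).refit().sort_by_intercept()
    cv = LineGroups("vertical", [apply_perspective(g, delta_img)
                                 for g in cv.groups]).refit().sort_by_intercept()
    persp = delta_img.compose(persp) if persp is not None else delta_img
    # the optimized increment is tuned to the current center (the lattice
    # targets were anchored there), so the center is NOT re-estimated here
    pre = apply_perspective(np.asarray(radial_center)[None, :],
                            persp.invert())[0]
    center = (float(pre[0]), float(pre[1]))
    return ch, cv, persp, radial_center, center


def _model_corrected_center(ch: LineGroups, cv: LineGroups, rc0,
                            cfg: CalibConfig, window: int = 3):
    """Refine the radial center of a perspective-corrected grid.

    The two-line a = 0 interpolation is noise-limited (the curvature step
    between adjacent lines is small), while a linear fit of a(c) over a
    window of lines is noise-averaged but biased when the radial model has
    higher-order terms.  The bias, however, is fully determined by the
    fitted model: ideal lines generated from it at the same intercepts
    yield the same windowed-root offset.  Subtracting that predicted
    offset gives a noise-averaged, curvature-unbiased center.
    """
    from .grouping import fit_parabola

    rc0 = (float(rc0[0]), float(rc0[1]))
    hs, vs = shift_origin(ch, rc0), shift_origin(cv, rc0)
    table_h = compute_undistorted_intercepts(hs.coeffs, cfg.n_near)
    table_v = compute_undistorted_intercepts(vs.coeffs, cfg.n_near)
    backward = calc_coeffs(hs.groups, vs.groups, table_h, table_v,
                           cfg.poly_order, "backward", rc0)

    def axis_shift(groups_centered, orientation):
        co = groups_centered.coeffs
        a, c = co[:, 0], co[:, 2]
        pairs = [(i, i + 1) for i in range(len(a) - 1) if a[i] * a[i + 1] < 0]
        if not pairs:
            raise ValueError("no curvature sign change")
        i, j = min(pairs, key=lambda p: abs(a[p[0]]) + abs(a[p[1]]))
        lo, hi = max(0, i - window), min(len(a), j + 1 + window)
        if hi - lo < 5:
            raise ValueError("window too small")
        cw, aw = c[lo:hi], a[lo:hi]
        m, q = np.polyfit(cw, aw, 1)
        measured = -q / m
        ind = 0 if orientation == "horizontal" else 1
        span = groups_centered.all_points()[:, ind]
        xs = np.linspace(span.min(), span.max(), 41)
        a_pred = []
        for cu in cw:
            if orientation == "horizontal":
                pts_u = np.column_stack([xs, np.full_like(xs, cu)])
            else:
                pts_u = np.column_stack([np.full_like(xs, cu), xs])
            d = unwarp_points(pts_u + np.asarray(rc0), backward) - np.asarray(rc0)
            a_pred.append(fit_parabola(d, orientation)[0])
        mp, qp = np.polyfit(cw, np.array(a_pred), 1)
        bias = -qp / mp
        shift = measured - bias
        if not np.isfinite(shift) or abs(shift) > 80.0:
            raise ValueError("implausible center shift")
        return shift

    dy = axis_shift(hs, "horizontal")
    dx = axis_shift(vs, "vertical")
    return (rc0[0] + dx, rc0[1] + dy)


def calibrate_points(points_h: np.ndarray, points_v: np.ndarray,
                     config: CalibConfig | None = None) -> CalibrationResult:
    """Calibrate distortion from reference points.

    ``points_h`` / ``points_v`` are the point sets to group into horizontal
    and vertical lines (identical for dot patterns).
    """
    cfg = (config or CalibConfig()).validate()
    slope_h, slope_v = ex.calc_grid_slope(points_h)
    gh = _group(points_h, "horizontal", cfg, slope_h)
    gv = _group(points_v, "vertical", cfg, slope_v)
    log.info("grouping: %d horizontal lines (%d outliers), %d vertical (%d)",
             len(gh), len(gh.ungrouped), len(gv), len(gv.ungrouped))

    # provisional center for perspective detection (coarse preferred: its
    # a = 0 interpolation is local and nearly unbiased with the center
    # inside the grid; vanishing points cover off-grid centers)
    try:
        c0 = find_center_coarse(gh, gv)
    except ValueError:
        c0 = find_center_vanishing_general(gh, gv)
    h0, v0 = shift_origin(gh, c0), shift_origin(gv, c0)
    trend, flag = detect_perspective(h0.coeffs, v0.coeffs)

    mode = cfg.perspective_correction
    persp = None
    if mode == "auto":
        # the homography route is self-calibrating: on a perspective-free
        # grid it converges to the identity, so it always runs; the flag
        # from the coefficient trends is reported for diagnostics.  Tilts
        # just below the detection threshold still bias the radial fit by
        # more than the pipeline's accuracy, so correction is not gated on
        # the flag.
        mode = "homography"
    radial_center = center = c0
    if mode == "homography":
        center, ch, cv, persp, radial_center = refine_center_iterative(
            gh, gv, cfg.center_iterations)
    elif mode == "coeffs":
        hp, vp, hc, vc = correct_parabola_coeffs(h0.groups, v0.groups,
                                                 h0.coeffs, v0.coeffs)
        ch = LineGroups("horizontal", [g + np.asarray(c0) for g in hp]).refit().sort_by_intercept()
        cv = LineGroups("vertical", [g + np.asarray(c0) for g in vp]).refit().sort_by_intercept()
        radial_center = center = find_center_coarse(ch, cv)
    elif mode == "off":
        ch, cv = gh, gv
    else:
        raise ValueError(f"unknown perspective_correction mode {mode!r}")
    log.info("center: (%.2f, %.2f), perspective %s", center[0], center[1],
             "corrected" if mode != "off" else "absent")

    if mode == "homography":
        # The quad homography estimated on curved lines carries a small
        # projective bias.  Refine it against the fitted radial model: once
        # curvature is removed, the four-line construction is unbiased.
        ch, cv, persp, radial_center, center = _refine_perspective_with_radial(
            ch, cv, persp, radial_center, center, cfg)

    hs, vs = shift_origin(ch, radial_center), shift_origin(cv, radial_center)
    table_h = compute_undistorted_intercepts(hs.coeffs, cfg.n_near)
    table_v = compute_undistorted_intercepts(vs.coeffs, cfg.n_near)
    if cfg.refine_steps > 0:
        # the spacing search minimizes the sum of squared residuals; keep
        # the refined tables only if the worst-point residual also improves
        rt_h = refine_spacing(hs.groups, vs.groups, table_h, table_v, "h",
                              cfg.refine_fraction, cfg.refine_steps,
                              cfg.poly_order)
        rt_v = refine_spacing(hs.groups, vs.groups, rt_h, table_v, "v",
                              cfg.refine_fraction, cfg.refine_steps,
                              cfg.poly_order)

        def _max_resid(th, tv):
            fwd = calc_coeffs(hs.groups, vs.groups, th, tv,
                              cfg.poly_order, "forward", radial_center)
            corr = [unwarp_points(g + np.asarray(radial_center), fwd)
                    for g in hs.groups + vs.groups]
            return evaluate_straightness(corr).max

        if _max_resid(rt_h, rt_v) < _max_resid(table_h, table_v):
            table_h, table_v = rt_h, rt_v
    backward = calc_coeffs(hs.groups, vs.groups, table_h, table_v,
                           cfg.poly_order, "backward", radial_center)
    forward = calc_coeffs(hs.groups, vs.groups, table_h, table_v,
                          cfg.poly_order, "forward", radial_center)

    before = evaluate_straightness(list(gh.groups) + list(gv.groups), center)
    corr = [unwarp_points(g, forward) for g in list(ch.groups) + list(cv.groups)]
    after = evaluate_straightness(corr, radial_center)
    log.info("straightness: max %.3f px before, %.3f px after",
             before.max, after.max)
    return CalibrationResult(center, backward, forward, persp, flag,
                             gh, gv, ch, cv, before, after)


def calibrate_image(image: np.ndarray, config: CalibConfig | None = None) -> CalibrationResult:
    """Full calibration of a single grid image."""
    cfg = (config or CalibConfig()).validate()
    pts_h, pts_v = extract_points(image, cfg)
    return calibrate_points(pts_h, pts_v, cfg)


def correct_points(points: np.ndarray, result: CalibrationResult) -> np.ndarray:
    """Map distorted reference points into the undistorted space."""
    pts = np.asarray(points, dtype=float)
    if result.perspective_forward is not None:
        pts = apply_perspective(pts, result.perspective_forward)
    return unwarp_points(pts, result.radial_forward)
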