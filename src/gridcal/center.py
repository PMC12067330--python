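"""Distortion-center estimation from grouped grid lines.

The center of radial distortion is the fixed point of the radial map and
must be located before the polynomial coefficients can be fitted.  Three
estimators are provided, in increasing generality:

* coarse — intersection of the two straight "axis" lines built from the
  parabola pairs whose curvature coefficient a changes sign; valid when
  perspective distortion is negligible.
* vanishing-point, barrel variant — all pairwise intersections between
  opposite-curvature parabolas of one orientation lie near a straight
  (vanishing) line; the two orientations' fitted lines intersect at the
  center.  Tolerates perspective; assumes barrel distortion.
* vanishing-point, general variant — intersects the flattest parabola of
  each orientation with all others; works for barrel and pincushion.

An iterative refinement alternates center estimation with perspective
correction, which removes the bias perspective introduces into all of the
above.
"""

from __future__ import annotations

import numpy as np

from .grouping import LineGroups, shift_origin
from .perspective import apply_perspective, build_correspondences, solve_homography

__all__ = [
    "find_center_coarse",
    "find_center_vanishing_barrel",
    "find_center_vanishing_general",
    "refine_center_iterative",
]


def _sign_straddle_line(coeffs: np.ndarray, window: int = 0) -> tuple[float, float]:
    """Straight line (slope b, intercept c) from the a-sign-change pair.

    Parabolas are scanned in intercept order; among adjacent pairs whose a
    coefficients have opposite signs the pair with the smallest combined
    |a| is selected, and b and c are averaged with weights that place the
    line at the a = 0 crossing (plain averaging would bias the center by
    up to half a line spacing when it does not sit midway between grid
    lines; the a-weighted average is exact for a locally linear a-vs-c
    trend and reduces to the plain average in the symmetric case).
    """
    a = coeffs[:, 0]
    pairs = [(i, i + 1) for i in range(len(a) - 1) if a[i] * a[i + 1] < 0]
    if not pairs:
        raise ValueError("center outside grid: no sign change in a-coefficients")
    i, j = min(pairs, key=lambda p: abs(a[p[0]]) + abs(a[p[1]]))
    if window > 0:
        # average the per-line noise of the a estimates over a small window
        # of lines around the crossing; only sound once the grid is
        # perspective-corrected AND a(c) is locally linear — a
        # statistically significant quadratic term (higher-order radial
        # coefficients) would bias the pooled root, so fall back to the
        # two-line interpolation in that case
        lo, hi = max(0, i - window), min(len(a), j + 1 + window)
        n_w = hi - lo
        if n_w >= 5:
            cw, aw = coeffs[lo:hi, 2], a[lo:hi]
            design = np.column_stack([cw ** 2, cw, np.ones(n_w)])
            sol, *_ = np.linalg.lstsq(design, aw, rcond=None)
            rss = float(np.sum((aw - design @ sol) ** 2))
            sigma2 = rss / max(n_w - 3, 1)
            cov = np.linalg.inv(design.T @ design) * sigma2
            t_quad = abs(sol[0]) / max(np.sqrt(cov[0, 0]), 1e-30)
            if t_quad < 3.0:
                m, q = np.polyfit(cw, aw, 1)
                if m != 0.0:
                    c_star = -q / m
                    if coeffs[i, 2] - 30 <= c_star <= coeffs[j, 2] + 30:
                        mb, qb = np.polyfit(cw, coeffs[lo:hi, 1], 1)
                        return float(mb * c_star + qb), float(c_star)
    t = a[i] / (a[i] - a[j])
    b = (1 - t) * coeffs[i, 1] + t * coeffs[j, 1]
    c = (1 - t) * coeffs[i, 2] + t * coeffs[j, 2]
    return float(b), float(c)


def _intersect_hv(bh: float, ch: float, bv: float, cv: float) -> tuple[float, float]:
    # y = bh x + ch intersected with x = bv y + cv
    denom = 1.0 - bh * bv
    if abs(denom) < 1e-12:
        raise ValueError("axis lines are parallel")
    x = (bv * ch + cv) / denom
    return x, bh * x + ch


def find_center_coarse(h_groups: LineGroups, v_groups: LineGroups,
                       window: int = 0) -> tuple[float, float]:
    """Center as the intersection of the two sign-change axis lines.

    Valid when perspective distortion is negligible; errors when no
    curvature sign change exists in an orientation (center outside grid).
    ``window`` > 0 fits the a = 0 crossing linearly over that many lines
    on each side (noise averaging; appropriate only for
    perspective-corrected grids).
    """
    bh, ch = _sign_straddle_line(h_groups.coeffs, window)
    bv, cv = _sign_straddle_line(v_groups.coeffs, window)
    return _intersect_hv(bh, ch, bv, cv)


def _parabola_intersections(c1: np.ndarray, c2: np.ndarray,
                            allow_complex: bool = False):
    """Intersection abscissae of two same-orientation parabolas.

    Both real roots are returned: for mild distortion the two intersection
    points of an opposite-curvature pair lie far outside the field of view
    on either side of the center, and the vanishing-line fit relies on the
    full symmetric pair.  With ``allow_complex`` a non-crossing pair
    (nested parabolas, the pincushion case) contributes its
    closest-approach abscissa -db/(2*da) — the real part of the complex
    root pair, which for a radially symmetric grid lies exactly on the
    symmetry axis.  Near-degenerate pairs (equal curvature) are skipped.
    """
    da, db, dc = c1 - c2
    if abs(da) < 1e-8:
        return []
    disc = db * db - 4 * da * dc
    if disc < 0:
        return [-db / (2 * da)] if allow_complex else []
    sq = np.sqrt(disc)
    return [(-db - sq) / (2 * da), (-db + sq) / (2 * da)]


def _vanishing_line(coeffs: np.ndarray, pair_iter,
                    allow_complex: bool = False) -> tuple[float, float]:
    """Fit indep = m * dep + q through parabola-pair intersection points.

    For horizontal parabolas the vanishing line is near-vertical, so the
    regression is x on y (and symmetrically for vertical parabolas); both
    orientations share this code because coefficients are expressed in
    their own (indep, dep) frame.
    """
    us, vs = [], []
    for i, j in pair_iter:
        for u in _parabola_intersections(coeffs[i], coeffs[j], allow_complex):
            us.append(u)
            vs.append(np.polyval(coeffs[i], u))
    if len(us) < 2:
        raise ValueError("not enough real parabola intersections for a line fit")
    import warnings
    with warnings.catch_warnings():
        # a near-vertical vanishing line (us ~ constant) is expected here
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        m, q = np.polyfit(vs, us, 1)
    return float(m), float(q)


def _center_from_lines(mh, qh, mv, qv) -> tuple[float, float]:
    """Intersect x = mh y + qh (from horizontal parabolas) with
    y = mv x + qv (from vertical ones)."""
    denom = 1.0 - mh * mv
    angle = np.arctan2(abs(denom), abs(mh + mv))  # ~angle between the lines
    if abs(denom) < 1e-12 or angle < 1e-4:
        raise ValueError("vanishing lines are near-parallel; center undetermined")
    x = (mh * qv + qh) / denom
    return x, mv * x + qv


def find_center_vanishing_barrel(h_groups: LineGroups,
                                 v_groups: LineGroups) -> tuple[float, float]:
    """Vanishing-point center from opposite-curvature parabola pairs.

    Works well for barrel distortion, with or without perspective.
    """
    ch, cv = h_groups.coeffs, v_groups.coeffs
    pairs_h = [(i, j) for i in np.flatnonzero(ch[:, 0] > 0)
               for j in np.flatnonzero(ch[:, 0] < 0)]
    pairs_v = [(i, j) for i in np.flatnonzero(cv[:, 0] > 0)
               for j in np.flatnonzero(cv[:, 0] < 0)]
    if not pairs_h or not pairs_v:
        raise ValueError("center outside grid: no opposite-curvature pairs")
    mh, qh = _vanishing_line(ch, pairs_h)
    mv, qv = _vanishing_line(cv, pairs_v)
    return _center_from_lines(mh, qh, mv, qv)


def find_center_vanishing_general(h_groups: LineGroups,
                                  v_groups: LineGroups) -> tuple[float, float]:
    """Vanishing-point center from the flattest parabola of each orientation.

    The parabola with minimum |a| is intersected with every other line of
    its orientation; valid for barrel and pincushion distortion.
    """
    ch, cv = h_groups.coeffs, v_groups.coeffs
    kh = int(np.argmin(np.abs(ch[:, 0])))
    kv = int(np.argmin(np.abs(cv[:, 0])))
    pairs_h = [(kh, j) for j in range(len(ch)) if j != kh]
    pairs_v = [(kv, j) for j in range(len(cv)) if j != kv]
    mh, qh = _vanishing_line(ch, pairs_h, allow_complex=True)
    mv, qv = _vanishing_line(cv, pairs_v, allow_complex=True)
    return _center_from_lines(mh, qh, mv, qv)


def refine_center_iterative(h_groups: LineGroups, v_groups: LineGroups,
                            n_iter: int = 3):
    """Alternate center estimation and perspective correction.

    Each iteration: shift the origin to the current center estimate o,
    refit parabolas, build the four-point correspondences, solve the
    forward homography H and apply it to all grouped points; the coarse
    center c1 of the corrected grid is the radial center in the corrected
    frame, and its preimage H^-1(c1) + o is the center expressed in the
    original image — the next iteration's origin.  Mapping the center back
    through H cancels the translation ambiguity of the quad construction
    exactly, so the image-frame center converges even though the corrected
    frame is only defined up to a similarity.

    Returns (image-frame center, corrected h groups, corrected v groups,
    forward perspective model in image coordinates, radial center in the
    corrected frame).  Corrected group coordinates live in the corrected
    frame (origin restored, i.e. comparable to image coordinates).
    """
    try:
        origin = find_center_coarse(h_groups, v_groups)
    except ValueError:
        origin = find_center_vanishing_general(h_groups, v_groups)
    persp_img = None
    h_corr, v_corr = h_groups, v_groups
    center_img = origin
    radial_center = origin
    for _ in range(max(n_iter, 1)):
        o = np.asarray(origin, dtype=float)
        h0 = shift_origin(h_groups, origin)
        v0 = shift_origin(v_groups, origin)
        try:
            dist_quad, und_quad = build_correspondences(h0.coeffs, v0.coeffs)
            persp = solve_homography(und_quad, dist_quad, direction="forward")
        except ValueError:
            break
        ch = LineGroups("horizontal", [apply_perspective(g, persp) + o
                                       for g in h0.groups]).refit().sort_by_intercept()
        cv = LineGroups("vertical", [apply_perspective(g, persp) + o
                                     for g in v0.groups]).refit().sort_by_intercept()
        persp_img = persp.with_origin(origin)
        h_corr, v_corr = ch, cv
        try:
            c1 = np.asarray(find_center_coarse(ch, cv), dtype=float)
        except ValueError:
            c1 = o
        radial_center = (float(c1[0]), float(c1[1]))
        pre = apply_perspective(c1[None, :] - o, persp.invert())[0] + o
        new_center = (float(pre[0]), float(pre[1]))
        shift = np.hypot(new_center[0] - center_img[0], new_center[1] - center_img[1])
        center_img = new_center
        origin = new_center
        if shift < 1e-3:
            break
    return center_img, h_corr, v_corr, persp_img, radial_center
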