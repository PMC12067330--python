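"""Perspective (projective) distortion: detection, calibration and correction.

Perspective distortion arises when the calibration target, lens and sensor
planes are not parallel.  It is modelled by an eight-coefficient rational
map (a plane homography)::

    x' = (c1*x + c2*y + c3) / (c7*x + c8*y + 1)
    y' = (c4*x + c5*y + c6) / (c7*x + c8*y + 1)

On a grid target, perspective shows up in the parabolic coefficients of the
fitted grid lines (with the coordinate origin at the distortion center): the
a-vs-c trends of the two orientations acquire different slopes and the
b-coefficients drift with c instead of staying constant.  Those trends are
used both to detect perspective and to build the four point correspondences
from which the homography is solved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PerspectiveModel",
    "CoefficientTrend",
    "solve_homography",
    "apply_perspective",
    "detect_perspective",
    "correct_parabola_coeffs",
    "build_correspondences",
    "make_tilt_homography",
]

IDENTITY_COEFFS = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0)


@dataclass
class PerspectiveModel:
    """Eight-coefficient projective map.

    direction : 'backward' maps undistorted -> distorted coordinates (the
    direction used for image resampling); 'forward' the reverse.
    """

    coeffs: np.ndarray
    direction: str = "backward"

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (8,):
            raise ValueError("PerspectiveModel needs exactly 8 coefficients")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")

    @classmethod
    def identity(cls, direction: str = "backward") -> "PerspectiveModel":
        return cls(np.array(IDENTITY_COEFFS), direction)

    @property
    def matrix(self) -> np.ndarray:
        c = self.coeffs
        return np.array([[c[0], c[1], c[2]], [c[3], c[4], c[5]], [c[6], c[7], 1.0]])

    def invert(self) -> "PerspectiveModel":
        """Analytic inverse (swaps the mapping direction)."""
        m = np.linalg.inv(self.matrix)
        m = m / m[2, 2]
        coeffs = np.array([m[0, 0], m[0, 1], m[0, 2], m[1, 0], m[1, 1], m[1, 2], m[2, 0], m[2, 1]])
        other = "forward" if self.direction == "backward" else "backward"
        return PerspectiveModel(coeffs, other)

    def compose(self, inner: "PerspectiveModel") -> "PerspectiveModel":
        """Model equivalent to applying ``inner`` first, then this one."""
        m = self.matrix @ inner.matrix
        m = m / m[2, 2]
        coeffs = np.array([m[0, 0], m[0, 1], m[0, 2], m[1, 0], m[1, 1], m[1, 2],
                           m[2, 0], m[2, 1]])
        return PerspectiveModel(coeffs, self.direction)

    def with_origin(self, origin: tuple[float, float]) -> "PerspectiveModel":
        """Re-express a model whose coordinates are relative to ``origin``
        in absolute (image) coordinates."""
        ox, oy = origin
        t = np.array([[1, 0, ox], [0, 1, oy], [0, 0, 1.0]])
        t_inv = np.array([[1, 0, -ox], [0, 1, -oy], [0, 0, 1.0]])
        m = t @ self.matrix @ t_inv
        m = m / m[2, 2]
        coeffs = np.array([m[0, 0], m[0, 1], m[0, 2], m[1, 0], m[1, 1], m[1, 2],
                           m[2, 0], m[2, 1]])
        return PerspectiveModel(coeffs, self.direction)

    def to_dict(self) -> dict:
        names = ["c1", "c2", "c3", "c4", "c5", "c6", "c7", "c8"]
        d = {k: float(v) for k, v in zip(names, self.coeffs)}
        d["direction"] = self.direction
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PerspectiveModel":
        coeffs = [d[f"c{i}"] for i in range(1, 9)]
        return cls(np.array(coeffs, dtype=float), d.get("direction", "backward"))

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    @classmethod
    def from_json(cls, path) -> "PerspectiveModel":
        with open(path) as f:
            return cls.from_dict(json.load(f))


@dataclass
class CoefficientTrend:
    """Linear trends of parabola coefficients a and b against intercept c.

    One straight line is fitted per orientation to the (c, a) scatter and one
    to the (c, b) scatter.  Under pure radial distortion the a-vs-c slopes of
    the two orientations agree and the b-vs-c slopes are ~0; deviations from
    that signal perspective distortion.  The vertical-orientation b values
    are sign-flipped before fitting so both orientations share a convention.
    """

    slope_ac_h: float
    intercept_ac_h: float
    slope_ac_v: float
    intercept_ac_v: float
    slope_bc_h: float
    intercept_bc_h: float
    slope_bc_v: float
    intercept_bc_v: float
    c_span_h: float
    c_span_v: float


def apply_perspective(points: np.ndarray, model: PerspectiveModel) -> np.ndarray:
    """Evaluate the rational map on an (N, 2) array of (x, y) points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    c = model.coeffs
    x, y = pts[:, 0], pts[:, 1]
    denom = c[6] * x + c[7] * y + 1.0
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("perspective map denominator vanishes inside the point set")
    xn = (c[0] * x + c[1] * y + c[2]) / denom
    yn = (c[3] * x + c[4] * y + c[5]) / denom
    return np.column_stack([xn, yn])


def solve_homography(src: np.ndarray, dst: np.ndarray,
                     direction: str = "backward") -> PerspectiveModel:
    """Solve the 8-unknown linear system of the projective map.

    The returned model maps ``dst`` onto ``src``:
    ``apply_perspective(dst, model) == src``.  With four pairs the system is
    square; with more it is solved in the least-squares sense.

    Raises
    ------
    ValueError
        If the correspondences are degenerate (three of four collinear or
        coincident points), detected through the conditioning of the system.
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape or src.shape[0] < 4:
        raise ValueError("need at least four point pairs of equal count")
    n = src.shape[0]
    a = np.zeros((2 * n, 8))
    rhs = np.zeros(2 * n)
    xs, ys = src[:, 0], src[:, 1]
    xd, yd = dst[:, 0], dst[:, 1]
    a[0::2, 0] = xd
    a[0::2, 1] = yd
    a[0::2, 2] = 1.0
    a[0::2, 6] = -xd * xs
    a[0::2, 7] = -yd * xs
    rhs[0::2] = xs
    a[1::2, 3] = xd
    a[1::2, 4] = yd
    a[1::2, 5] = 1.0
    a[1::2, 6] = -xd * ys
    a[1::2, 7] = -yd * ys
    rhs[1::2] = ys
    # scale columns for conditioning; detect genuine degeneracy afterwards
    col_scale = np.maximum(np.abs(a).max(axis=0), 1e-12)
    sol, _, rank, sv = np.linalg.lstsq(a / col_scale, rhs, rcond=None)
    if rank < 8 or sv[-1] < 1e-10 * sv[0]:
        raise ValueError("degenerate correspondences")
    return PerspectiveModel(sol / col_scale, direction)


def solve_homography_from_lines(h_groups: list[np.ndarray], y_targets: np.ndarray,
                                v_groups: list[np.ndarray], x_targets: np.ndarray,
                                direction: str = "forward") -> PerspectiveModel:
    """Least-squares homography that flattens grouped grid points onto
    their ideal lattice lines.

    Every point of horizontal group i must map onto the horizontal line
    y = y_targets[i], and every point of vertical group j onto
    x = x_targets[j].  Each point contributes one equation that is linear
    in the eight coefficients, so no cross-orientation point matching is
    needed and all reference points constrain the solution — a far better
    conditioned estimate than four corner correspondences.
    """
    rows, rhs = [], []
    for pts, t in zip(h_groups, y_targets):
        pts = np.asarray(pts, dtype=float)
        x, y = pts[:, 0], pts[:, 1]
        block = np.zeros((len(pts), 8))
        block[:, 3] = x
        block[:, 4] = y
        block[:, 5] = 1.0
        block[:, 6] = -t * x
        block[:, 7] = -t * y
        rows.append(block)
        rhs.append(np.full(len(pts), t))
    for pts, t in zip(v_groups, x_targets):
        pts = np.asarray(pts, dtype=float)
        x, y = pts[:, 0], pts[:, 1]
        block = np.zeros((len(pts), 8))
        block[:, 0] = x
        block[:, 1] = y
        block[:, 2] = 1.0
        block[:, 6] = -t * x
        block[:, 7] = -t * y
        rows.append(block)
        rhs.append(np.full(len(pts), t))
    a = np.vstack(rows)
    b = np.concatenate(rhs)
    if a.shape[0] < 8:
        raise ValueError("not enough points for a homography fit")
    col_scale = np.maximum(np.abs(a).max(axis=0), 1e-12)
    sol, _, rank, sv = np.linalg.lstsq(a / col_scale, b, rcond=None)
    if rank < 8 or sv[-1] < 1e-10 * sv[0]:
        raise ValueError("degenerate line constraints")
    return PerspectiveModel(sol / col_scale, direction)


def make_tilt_homography(center: tuple[float, float], tilt_x_deg: float = 0.0,
                         tilt_y_deg: float = 0.0,
                         focal_px: float = 2400.0) -> PerspectiveModel:
    """Homography of a small target tilt that fixes ``center``.

    A pure projective row (g1, g2) in coordinates centered on the distortion
    center, with g = tan(tilt)/focal.  Because the affine block is the
    identity, the fixed point of the map is exactly ``center`` — convenient
    for synthetic ground truth where the radial center must survive the
    perspective map.
    """
    g1 = np.tan(np.deg2rad(tilt_x_deg)) / focal_px
    g2 = np.tan(np.deg2rad(tilt_y_deg)) / focal_px
    xc, yc = center
    t_in = np.array([[1, 0, -xc], [0, 1, -yc], [0, 0, 1.0]])
    t_out = np.array([[1, 0, xc], [0, 1, yc], [0, 0, 1.0]])
    h_c = np.array([[1, 0, 0], [0, 1, 0], [g1, g2, 1.0]])
    m = t_out @ h_c @ t_in
    m = m / m[2, 2]
    coeffs = np.array([m[0, 0], m[0, 1], m[0, 2], m[1, 0], m[1, 1], m[1, 2], m[2, 0], m[2, 1]])
    return PerspectiveModel(coeffs, "backward")


def _trend_fit(c_vals: np.ndarray, y_vals: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(c_vals, y_vals, 1)
    return float(slope), float(intercept)


def detect_perspective(h_coeffs: np.ndarray, v_coeffs: np.ndarray,
                       rel_tol: float = 0.2,
                       b_var_tol: float = 0.01) -> tuple[CoefficientTrend, bool]:
    """Fit coefficient trends and flag perspective distortion.

    Parameters take parabola coefficient arrays of shape (n_lines, 3) fitted
    with the origin at the distortion center.  Perspective is flagged when
    the a-vs-c slopes of the two orientations differ by more than ``rel_tol``
    relative to their magnitude, or when the b coefficients drift across the
    grid by more than ``b_var_tol`` (|slope_bc| * c-span).
    """
    h = np.asarray(h_coeffs, dtype=float)
    v = np.asarray(v_coeffs, dtype=float)
    if h.shape[0] < 3 or v.shape[0] < 3:
        raise ValueError("need at least 3 lines per orientation for trends")
    s_ah, i_ah = _trend_fit(h[:, 2], h[:, 0])
    s_av, i_av = _trend_fit(v[:, 2], v[:, 0])
    # flip vertical b sign so both orientations share the horizontal convention
    s_bh, i_bh = _trend_fit(h[:, 2], h[:, 1])
    s_bv, i_bv = _trend_fit(v[:, 2], -v[:, 1])
    span_h = float(np.ptp(h[:, 2]))
    span_v = float(np.ptp(v[:, 2]))
    trend = CoefficientTrend(s_ah, i_ah, s_av, i_av, s_bh, i_bh, s_bv, i_bv,
                             span_h, span_v)
    scale = max(abs(s_ah), abs(s_av))
    slope_differ = scale > 0 and abs(s_ah - s_av) > rel_tol * scale
    b_drift = max(abs(s_bh) * span_h, abs(s_bv) * span_v) > b_var_tol
    return trend, bool(slope_differ or b_drift)


def correct_parabola_coeffs(h_points: list[np.ndarray], v_points: list[np.ndarray],
                            h_coeffs: np.ndarray, v_coeffs: np.ndarray):
    """Coefficient-ratio perspective correction (small-to-medium distortion).

    The horizontal family's a and c coefficients are rescaled by the ratio of
    the cross-orientation mean intercept spacings (mean dc_vertical / mean
    dc_horizontal), which makes the grid isotropic again.  The rescale is
    realised as a y-scale of the point cloud so points and coefficients stay
    consistent; the vertical family is refit accordingly.  The b coefficient
    of every line is replaced by the value at the intersection of the fitted
    b-vs-c trend lines.

    Returns (h_points, v_points, h_coeffs, v_coeffs) corrected.
    """
    from .grouping import fit_parabola

    h = np.array(h_coeffs, dtype=float, copy=True)
    v = np.array(v_coeffs, dtype=float, copy=True)
    dch = float(np.mean(np.diff(np.sort(h[:, 2]))))
    dcv = float(np.mean(np.diff(np.sort(v[:, 2]))))
    if dch <= 0 or dcv <= 0:
        raise ValueError("intercepts are not strictly ordered")
    ratio = dcv / dch

    h_new = [np.column_stack([g[:, 0], g[:, 1] * ratio]) for g in h_points]
    v_new = [np.column_stack([g[:, 0], g[:, 1] * ratio]) for g in v_points]
    hc = np.array([fit_parabola(g, "horizontal") for g in h_new])
    vc = np.array([fit_parabola(g, "vertical") for g in v_new])

    # b harmonization: intersection of the b-vs-c trend lines of the two
    # orientations (vertical b sign-flipped to the shared convention)
    s_bh, i_bh = _trend_fit(hc[:, 2], hc[:, 1])
    s_bv, i_bv = _trend_fit(vc[:, 2], -vc[:, 1])
    if abs(s_bh - s_bv) > 1e-12:
        c_star = (i_bv - i_bh) / (s_bh - s_bv)
        b_star = s_bh * c_star + i_bh
    else:
        b_star = 0.5 * (np.mean(hc[:, 1]) + np.mean(-vc[:, 1]))
    hc[:, 1] = b_star
    vc[:, 1] = -b_star
    return h_new, v_new, hc, vc


def _avg_line(coeffs: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Average b and c of the selected parabolas -> straight line (b, c)."""
    if not np.any(mask):
        raise ValueError("no parabolas with the required curvature sign")
    return float(np.mean(coeffs[mask, 1])), float(np.mean(coeffs[mask, 2]))


def build_correspondences(h_coeffs: np.ndarray, v_coeffs: np.ndarray,
                          scale: float | None = None,
                          scale_x: float | None = None,
                          scale_y: float | None = None):
    """Four distorted / four undistorted corner correspondences.

    Works on parabola coefficients fitted with the origin at the distortion
    center.  Two representative straight lines per orientation are formed by
    averaging b and c over the positive-a and the negative-a parabolas; their
    four pairwise intersections give the distorted quad.  The undistorted
    quad comes from regularized lines: a single grid rotation (mean of both
    orientations' line angles, so the orientations are exactly
    perpendicular) and intercepts rescaled to the target spacing.

    ``scale`` sets the undistorted px-per-line spacing isotropically;
    ``scale_x``/``scale_y`` override per axis.  Default keeps the measured
    mean spacing of each orientation's intercepts.

    Returns (distorted_quad, undistorted_quad) as (4, 2) arrays ordered
    (H+, V+), (H+, V-), (H-, V+), (H-, V-).
    """
    h = np.asarray(h_coeffs, dtype=float)
    v = np.asarray(v_coeffs, dtype=float)
    bh_p, ch_p = _avg_line(h, h[:, 0] > 0)
    bh_n, ch_n = _avg_line(h, h[:, 0] < 0)
    bv_p, cv_p = _avg_line(v, v[:, 0] > 0)
    bv_n, cv_n = _avg_line(v, v[:, 0] < 0)

    def cross(bh, ch, bv, cv):
        # y = bh x + ch ; x = bv y + cv
        x = (bv * ch + cv) / (1.0 - bh * bv)
        return x, bh * x + ch

    dist = np.array([cross(bh_p, ch_p, bv_p, cv_p),
                     cross(bh_p, ch_p, bv_n, cv_n),
                     cross(bh_n, ch_n, bv_p, cv_p),
                     cross(bh_n, ch_n, bv_n, cv_n)])

    # common rotation: horizontal line angle atan(b); vertical line angle from
    # the y axis is atan(b) as well, with opposite sense in (x, y) frame
    theta_h = 0.5 * (np.arctan(bh_p) + np.arctan(bh_n))
    theta_v = 0.5 * (np.arctan(bv_p) + np.arctan(bv_n))
    theta = 0.5 * (theta_h - theta_v)

    dc_h = float(np.mean(np.diff(np.sort(h[:, 2]))))
    dc_v = float(np.mean(np.diff(np.sort(v[:, 2]))))
    if scale is not None and (scale_x is None and scale_y is None):
        scale_x = scale_y = scale
    sx = scale_x / dc_v if scale_x is not None else 1.0
    sy = scale_y / dc_h if scale_y is not None else 1.0

    # perpendicular signed offsets of the averaged lines from the origin
    off_h_p = ch_p * np.cos(np.arctan(bh_p)) * sy
    off_h_n = ch_n * np.cos(np.arctan(bh_n)) * sy
    off_v_p = cv_p * np.cos(np.arctan(bv_p)) * sx
    off_v_n = cv_n * np.cos(np.arctan(bv_n)) * sx
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    und = np.array([(off_v_p, off_h_p), (off_v_n, off_h_p),
                    (off_v_p, off_h_n), (off_v_n, off_h_n)], dtype=float) @ rot.T
    return dist, und
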