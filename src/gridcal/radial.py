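"""Polynomial radial-distortion model and its calibration.

The model relates the radius of a point from the distortion center in the
undistorted space (r_u) and in the distorted space (r_d)::

    backward:  r_d = r_u * (k_0 + k_1 r_u + k_2 r_u^2 + ... + k_n r_u^n)
    forward:   r_u = r_d * (k'_0 + k'_1 r_d + ... + k'_n r_d^n)

"Backward" maps undistorted -> distorted (the direction used to resample
images), "forward" the reverse.  Coefficients are calibrated from
perspective-corrected line groups: each grid line is a parabola with
intercept c in the distorted space, and its undistorted counterpart is a
straight axis-parallel line whose intercept c^u is reconstructed by
arithmetic extrapolation from the lines nearest the center, where the
distortion vanishes.  Every reference point then yields one linear equation
in the polynomial coefficients via the per-point scale factor f = r_d/r_u.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RadialModel",
    "InterceptTable",
    "compute_undistorted_intercepts",
    "refine_spacing",
    "calc_coeffs",
    "convert_model",
    "unwarp_points",
]


@dataclass
class RadialModel:
    """Distortion center plus radial polynomial coefficients.

    coeffs[0] is k_0 (the magnification at the center, ~1 for mild
    distortion); direction declares which way the polynomial maps.
    """

    center: tuple[float, float]
    coeffs: np.ndarray
    direction: str = "backward"

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        self.center = (float(self.center[0]), float(self.center[1]))
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        if self.coeffs[0] <= 0:
            raise ValueError("k_0 must be positive")

    @property
    def order(self) -> int:
        return len(self.coeffs) - 1

    def factor(self, r: np.ndarray) -> np.ndarray:
        """Radial scale factor k_0 + k_1 r + ... evaluated at radius r."""
        return np.polyval(self.coeffs[::-1], np.asarray(r, dtype=float))

    def map_radius(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return r * self.factor(r)

    def to_dict(self) -> dict:
        return {"center": [self.center[0], self.center[1]],
                "direction": self.direction,
                "coeffs": [float(c) for c in self.coeffs]}

    @classmethod
    def from_dict(cls, d: dict) -> "RadialModel":
        return cls((d["center"][0], d["center"][1]), np.array(d["coeffs"]),
                   d["direction"])

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    @classmethod
    def from_json(cls, path) -> "RadialModel":
        with open(path) as f:
            return cls.from_dict(json.load(f))

    def to_metadata_txt(self, path) -> None:
        """Flat labelled text file for tomography-pipeline interchange."""
        lines = [f"xcenter {self.center[0]:.6f}", f"ycenter {self.center[1]:.6f}",
                 f"direction {self.direction}"]
        lines += [f"factor{i} {c:.14e}" for i, c in enumerate(self.coeffs)]
        with open(path, "w") as f:
            f.write("\n".join(lines) + "\n")


@dataclass
class InterceptTable:
    """Distorted and reconstructed undistorted intercepts of one orientation.

    Lines are indexed in c-sorted order; ``i0`` is the anchor line nearest
    the distortion center and ``delta_c`` the reconstructed undistorted
    spacing between adjacent lines.
    """

    indices: np.ndarray
    c_dist: np.ndarray
    c_und: np.ndarray
    i0: int
    delta_c: float


def compute_undistorted_intercepts(coeffs: np.ndarray, n_near: int = 6) -> InterceptTable:
    """Reconstruct undistorted line intercepts near-center extrapolation.

    With the origin at the distortion center, the undistorted grid lines are
    equidistant; their common spacing is estimated as the mean absolute
    difference of the distorted intercepts over the ``n_near`` lines nearest
    the center (where distortion is negligible), and the undistorted
    intercept of line i is the sign-preserving arithmetic extrapolation
    c_i^u = c_{i0} + (i - i0) * dc from the anchor line i0 = argmin |c|.
    """
    c = np.asarray(coeffs, dtype=float)
    if c.ndim == 2:
        c = c[:, 2]
    order = np.argsort(c)
    c_sorted = c[order]
    n = len(c_sorted)
    if n < 3:
        raise ValueError("need at least 3 lines")
    i0 = int(np.argmin(np.abs(c_sorted)))
    lo = max(0, min(i0 - n_near // 2, n - n_near - 1))
    hi = min(n - 1, lo + n_near)
    delta_c = float(np.mean(np.abs(np.diff(c_sorted[lo:hi + 1]))))
    c_und = c_sorted[i0] + (np.arange(n) - i0) * delta_c
    return InterceptTable(indices=np.arange(n), c_dist=c_sorted, c_und=c_und,
                          i0=i0, delta_c=delta_c)


def _stack_equations(groups: list[np.ndarray], c_und: np.ndarray, axis: int,
                     order: int, direction: str, r_norm: float,
                     min_intercept: float = 1.0):
    """Linear-system rows for one orientation.

    axis=1 for horizontal lines (f = y_d / c^u), axis=0 for vertical
    (f = x_d / c^u).  Lines passing too close to the center are excluded
    because the scale factor f degenerates there.
    """
    rows, rhs = [], []
    for g, cu in zip(groups, c_und):
        if abs(cu) < min_intercept:
            continue
        pts = np.asarray(g, dtype=float)
        f = pts[:, axis] / cu
        ok = f > 0.2
        pts, f = pts[ok], f[ok]
        r_d = np.hypot(pts[:, 0], pts[:, 1])
        if direction == "backward":
            r_u = r_d / f
            vand = np.vander(r_u / r_norm, order + 1, increasing=True)
            rows.append(vand)
            rhs.append(f)
        else:
            vand = np.vander(r_d / r_norm, order + 1, increasing=True)
            rows.append(vand)
            rhs.append(1.0 / f)
    if not rows:
        return np.zeros((0, order + 1)), np.zeros(0)
    return np.vstack(rows), np.concatenate(rhs)


def calc_coeffs(groups_h: list[np.ndarray], groups_v: list[np.ndarray],
                table_h: InterceptTable, table_v: InterceptTable,
                order: int = 4, direction: str = "backward",
                center: tuple[float, float] = (0.0, 0.0)) -> RadialModel:
    """Least-squares radial polynomial from both line orientations.

    Inputs must be perspective-corrected groups in center-origin coordinates
    (matching the intercept tables, whose groups are in c-sorted order).
    Both orientations are stacked into a single system so the image has one
    radial model.

    Raises
    ------
    ValueError
        If the stacked system is ill-conditioned (reported with the
        condition estimate) or empty.
    """
    r_norm = 1.0
    all_pts = np.vstack([np.vstack(groups_h), np.vstack(groups_v)])
    r_norm = max(float(np.hypot(all_pts[:, 0], all_pts[:, 1]).max()), 1.0)
    a_h, b_h = _stack_equations(groups_h, table_h.c_und, 1, order, direction, r_norm)
    a_v, b_v = _stack_equations(groups_v, table_v.c_und, 0, order, direction, r_norm)
    a = np.vstack([a_h, a_v])
    b = np.concatenate([b_h, b_v])
    if a.shape[0] < order + 1:
        raise ValueError("not enough usable reference points for the requested order")
    sol, _, rank, sv = np.linalg.lstsq(a, b, rcond=None)
    cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
    if rank < order + 1 or cond > 1e10:
        raise ValueError(f"ill-conditioned radial system (cond~{cond:.3g})")
    coeffs = sol / r_norm ** np.arange(order + 1)
    return RadialModel(center=center, coeffs=coeffs, direction=direction)


def refine_spacing(groups_h: list[np.ndarray], groups_v: list[np.ndarray],
                   table_h: InterceptTable, table_v: InterceptTable,
                   which: str = "h", search_fraction: float = 0.05,
                   n_steps: int = 21, order: int = 4) -> InterceptTable:
    """Grid-search refinement of one orientation's line spacing dc.

    The candidate spacing is varied by +/- ``search_fraction`` around the
    initial estimate; for each candidate a forward radial model is fitted
    and the cost is the sum of squared straightness residuals of the
    corrected points.  The minimizing table is returned.  Only one
    orientation is searched at a time because a common rescale of both
    orientations' spacings is absorbed exactly by the polynomial
    coefficients and leaves the cost unchanged.
    """
    from .postproc import evaluate_straightness

    base = table_h if which == "h" else table_v
    candidates = base.delta_c * np.linspace(1 - search_fraction, 1 + search_fraction, n_steps)
    best_cost, best_table = np.inf, base
    for dc in candidates:
        c_und = base.c_dist[base.i0] + (base.indices - base.i0) * dc
        trial = InterceptTable(base.indices, base.c_dist, c_und, base.i0, float(dc))
        th = trial if which == "h" else table_h
        tv = trial if which == "v" else table_v
        try:
            model = calc_coeffs(groups_h, groups_v, th, tv, order=order,
                                direction="forward")
        except (ValueError, np.linalg.LinAlgError):
            continue
        corr_h = [unwarp_points(g, model) for g in groups_h]
        corr_v = [unwarp_points(g, model) for g in groups_v]
        rep = evaluate_straightness(corr_h + corr_v)
        cost = float(np.sum(rep.distance_to_line ** 2))
        if cost < best_cost:
            best_cost, best_table = cost, trial
    return best_table


def convert_model(model: RadialModel, order: int | None = None,
                  domain: tuple[float, float] = (0.0, 2000.0),
                  n_samples: int = 512) -> RadialModel:
    """Fit the opposite-direction polynomial by sampling the known model.

    Radii are sampled over ``domain`` in the model's own input space, mapped
    through the model, and the reverse ratio is fitted by least squares.
    """
    if order is None:
        order = model.order
    r_in = np.linspace(domain[0], domain[1], n_samples)
    r_out = model.map_radius(r_in)
    if np.any(np.diff(r_out) <= 0):
        raise ValueError("model is not invertible over the requested domain")
    # ratio r_in/r_out at r=0 tends to 1/k_0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(r_out > 0, r_in / np.maximum(r_out, 1e-30), 1.0 / model.coeffs[0])
    r_norm = max(float(r_out.max()), 1.0)
    vand = np.vander(r_out / r_norm, order + 1, increasing=True)
    sol, *_ = np.linalg.lstsq(vand, ratio, rcond=None)
    coeffs = sol / r_norm ** np.arange(order + 1)
    direction = "forward" if model.direction == "backward" else "backward"
    return RadialModel(center=model.center, coeffs=coeffs, direction=direction)


def unwarp_points(points: np.ndarray, model: RadialModel) -> np.ndarray:
    """Apply the radial map of ``model`` to points in its input space.

    A backward model treats the input as undistorted coordinates and returns
    distorted ones; a forward model the reverse.  The distortion center is
    the fixed point (r = 0 handled exactly).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if model.order == 0 and model.coeffs[0] == 1.0:
        return pts.copy()   # identity map, bit-exact
    xc, yc = model.center
    dx, dy = pts[:, 0] - xc, pts[:, 1] - yc
    r = np.hypot(dx, dy)
    fac = model.factor(r)
    return np.column_stack([xc + dx * fac, yc + dy * fac])
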