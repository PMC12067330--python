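"""Grouping reference points into horizontal / vertical grid lines.

Each grid line in the distorted image is represented by a parabola:
horizontal lines ``y = a x^2 + b x + c`` (independent variable x), vertical
lines ``x = a y^2 + b y + c`` (independent variable y).  The coefficient
trends across lines carry all the calibration information used downstream:
a encodes radial curvature, b and c the line slope and position.

Two grouping strategies are provided.  The slope-guided search projects
points along the known grid slope and clusters them by ordinate; it is fast
and robust for small-to-medium curvature.  The middle-out search starts
from a slab around the image center, where distortion is minimal, and grows
each line outward guided by a running polynomial fit — this is the method
of choice for strongly curved (fisheye) grids where the slope-guided
projection mixes neighbouring lines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LineGroups",
    "fit_parabola",
    "group_points_slope_guided",
    "group_points_middle_out",
    "remove_residual_outliers",
    "shift_origin",
]

MIN_POINTS = 4


@dataclass
class LineGroups:
    """Points partitioned into ordered line groups of one orientation.

    groups[i] is an (n_i, 2) array of (x, y) points sorted along the line;
    coeffs[i] = (a, b, c) is its parabola.  Groups are ordered by intercept
    c.  ``ungrouped`` collects outliers that joined no line.
    """

    orientation: str
    groups: list = field(default_factory=list)
    coeffs: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    ungrouped: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def __post_init__(self) -> None:
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError("orientation must be 'horizontal' or 'vertical'")

    def __len__(self) -> int:
        return len(self.groups)

    def refit(self) -> "LineGroups":
        self.coeffs = np.array([fit_parabola(g, self.orientation) for g in self.groups])
        return self

    def sort_by_intercept(self) -> "LineGroups":
        if len(self.groups) == 0:
            return self
        order = np.argsort(self.coeffs[:, 2])
        self.groups = [self.groups[i] for i in order]
        self.coeffs = self.coeffs[order]
        return self

    def all_points(self) -> np.ndarray:
        if not self.groups:
            return np.zeros((0, 2))
        return np.vstack(self.groups)

    def to_dict(self) -> dict:
        return {"orientation": self.orientation,
                "groups": [g.tolist() for g in self.groups],
                "coeffs": self.coeffs.tolist(),
                "ungrouped": self.ungrouped.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "LineGroups":
        return cls(d["orientation"], [np.array(g, dtype=float) for g in d["groups"]],
                   np.array(d["coeffs"], dtype=float),
                   np.array(d["ungrouped"], dtype=float).reshape(-1, 2))

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f)

    @classmethod
    def from_json(cls, path) -> "LineGroups":
        with open(path) as f:
            return cls.from_dict(json.load(f))


def fit_parabola(group: np.ndarray, orientation: str) -> np.ndarray:
    """Least-squares parabola (a, b, c) for one line group.

    Horizontal lines regress y on x; vertical lines regress x on y.  With
    exactly three points this is the interpolating parabola.
    """
    pts = np.asarray(group, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a parabola fit")
    if orientation == "horizontal":
        return np.polyfit(pts[:, 0], pts[:, 1], 2)
    return np.polyfit(pts[:, 1], pts[:, 0], 2)


def _axes(orientation: str) -> tuple[int, int]:
    """(independent, dependent) column indices for an orientation."""
    return (0, 1) if orientation == "horizontal" else (1, 0)


def group_points_slope_guided(points: np.ndarray, orientation: str,
                              slope: float = 0.0,
                              nominal_distance: float | None = None,
                              tolerance_ratio: float = 0.3,
                              max_missing: int = 4,
                              min_points: int = MIN_POINTS) -> LineGroups:
    """Chain points into lines guided by the grid slope.

    Points are scanned in order of the independent coordinate and joined
    to the chain whose running prediction (last point extrapolated along
    the chain's local slope, initialized from the grid ``slope``) lies
    within ``tolerance_ratio * nominal_distance``; a point matching no
    chain starts a new one.  The per-chain slope adapts as the chain
    grows, which tolerates the line-to-line slope variation perspective
    introduces and mild curvature.  A chain is not extended across a gap
    longer than ``max_missing + 1`` in-line spacings.  Chains with fewer
    than ``min_points`` points are reported as ungrouped outliers.
    """
    pts = np.asarray(points, dtype=float)
    ind, dep = _axes(orientation)
    if pts.shape[0] < 3 * min_points:
        raise ValueError("insufficient points for grouping")
    if nominal_distance is None:
        from scipy.spatial import cKDTree
        dists, _ = cKDTree(pts).query(pts, k=2)
        nominal_distance = float(np.median(dists[:, 1]))
    tol = tolerance_ratio * nominal_distance
    max_gap = (max_missing + 1) * nominal_distance
    order = np.lexsort((pts[:, dep], pts[:, ind]))
    slope0 = np.tan(slope)

    # chains: [u_last, v_last, local slope, list of row indices]
    chains: list[list] = []
    for idx in order:
        u, v = pts[idx, ind], pts[idx, dep]
        best, best_resid = None, tol
        for ch in chains:
            du = u - ch[0]
            if du > max_gap:
                continue
            resid = abs(v - (ch[1] + ch[2] * du))
            if resid < best_resid:
                best, best_resid = ch, resid
        if best is None:
            chains.append([u, v, slope0, [idx]])
        else:
            du = u - best[0]
            if du > 0.25 * nominal_distance:
                local = (v - best[1]) / du
                best[2] = 0.6 * best[2] + 0.4 * local
            best[0], best[1] = u, v
            best[3].append(idx)

    groups, outliers = [], []
    for ch in chains:
        sub = pts[ch[3]]
        sub = sub[np.argsort(sub[:, ind])]
        if len(sub) >= min_points:
            groups.append(sub)
        else:
            outliers.append(sub)
    if len(groups) < 3:
        raise ValueError("insufficient lines: fewer than 3 groups found")
    ungrouped = np.vstack(outliers) if outliers else np.zeros((0, 2))
    lg = LineGroups(orientation, groups, ungrouped=ungrouped)
    return lg.refit().sort_by_intercept()


def group_points_middle_out(points: np.ndarray, orientation: str,
                            nominal_distance: float,
                            slab_width: float | None = None,
                            residual_tolerance: float | None = None,
                            min_points: int = MIN_POINTS) -> LineGroups:
    """Middle-out grouping for strongly curved (fisheye) grids.

    A central slab perpendicular to the line direction — where distortion is
    weakest — is grouped with the slope-guided method; each group gets a
    running polynomial fit (a straight line while the group is short, a
    parabola from five points on).  The slab then advances symmetrically
    outward, each new point being claimed by the group whose running fit
    predicts it within ``residual_tolerance`` (ties go to the smallest
    absolute residual); fits are updated after every slab.  Points no group
    claims are reported ungrouped.
    """
    pts = np.asarray(points, dtype=float)
    ind, dep = _axes(orientation)
    if slab_width is None:
        slab_width = 2.0 * nominal_distance
    if residual_tolerance is None:
        residual_tolerance = 0.4 * nominal_distance
    lo, hi = pts[:, ind].min(), pts[:, ind].max()
    mid = 0.5 * (lo + hi)

    # widen the seed band until the line count stabilizes: each line needs
    # >= 3 points inside the band for its seed fit
    half0 = 1.5 * slab_width / 2.0
    seed, n_prev = None, -1
    for grow in range(4):
        half_seed = half0 + grow * slab_width
        central = np.abs(pts[:, ind] - mid) <= half_seed
        try:
            cand = group_points_slope_guided(pts[central], orientation, slope=0.0,
                                             nominal_distance=nominal_distance,
                                             tolerance_ratio=0.5, min_points=3)
        except ValueError:
            continue
        if len(cand) <= n_prev:
            break
        seed, n_prev = cand, len(cand)
        half0_used = half_seed
    if seed is None:
        raise ValueError("insufficient lines: no seed groups in the central band")
    members: list[np.ndarray] = [g for g in seed.groups]
    claimed = {tuple(p) for g in members for p in g}

    def predict(group: np.ndarray, u: np.ndarray) -> np.ndarray:
        deg = 2 if len(group) >= 5 else 1
        coef = np.polyfit(group[:, ind], group[:, dep], deg)
        return np.polyval(coef, u)

    half = half0_used
    while half < (hi - lo) / 2.0 + slab_width:
        nxt = half + slab_width
        in_slab = (np.abs(pts[:, ind] - mid) > half) & (np.abs(pts[:, ind] - mid) <= nxt)
        cand = [p for p in pts[in_slab] if tuple(p) not in claimed]
        if cand:
            cand = np.array(cand)
            preds = np.column_stack([predict(g, cand[:, ind]) for g in members])
            resid = np.abs(preds - cand[:, [dep]])
            best = np.argmin(resid, axis=1)
            for k, p in enumerate(cand):
                if resid[k, best[k]] <= residual_tolerance:
                    members[best[k]] = np.vstack([members[best[k]], p])
                    claimed.add(tuple(p))
        half = nxt

    groups, outliers = [], []
    for g in members:
        g = g[np.argsort(g[:, ind])]
        (groups if len(g) >= min_points else outliers).append(g)
    unc = [p for p in pts if tuple(p) not in claimed]
    if outliers:
        unc.extend([p for g in outliers for p in g])
    if len(groups) < 3:
        raise ValueError("insufficient lines: fewer than 3 groups found")
    ungrouped = np.array(unc).reshape(-1, 2) if unc else np.zeros((0, 2))
    lg = LineGroups(orientation, groups, ungrouped=ungrouped)
    lg.refit()
    # drop groups whose parabola fit is degenerate for this orientation
    keep = np.isfinite(lg.coeffs).all(axis=1)
    if not keep.all():
        import warnings
        warnings.warn("dropping group(s) with degenerate parabola fit")
        lg.groups = [g for g, k in zip(lg.groups, keep) if k]
        lg.coeffs = lg.coeffs[keep]
    return lg.sort_by_intercept()


def remove_residual_outliers(groups: LineGroups, threshold_px: float = 2.0) -> LineGroups:
    """Drop points farther than ``threshold_px`` from their fitted parabola.

    The parabola is refitted once after removal.  This is the
    distortion-strength-agnostic replacement for nearest-neighbour
    misplaced-dot removal, usable even under strong distortion.
    """
    ind, dep = _axes(groups.orientation)
    new_groups, dropped = [], []
    for g, coef in zip(groups.groups, groups.coeffs):
        resid = np.abs(np.polyval(coef, g[:, ind]) - g[:, dep])
        keep = resid <= threshold_px
        if keep.sum() >= 3:
            new_groups.append(g[keep])
        dropped.append(g[~keep])
    ungrouped = np.vstack([groups.ungrouped] + dropped) if dropped else groups.ungrouped
    out = LineGroups(groups.orientation, new_groups, ungrouped=ungrouped)
    return out.refit().sort_by_intercept()


def shift_origin(groups: LineGroups, center: tuple[float, float]) -> LineGroups:
    """Return a copy with point coordinates relative to ``center``, refitted."""
    shifted = [g - np.asarray(center, dtype=float) for g in groups.groups]
    ung = groups.ungrouped - np.asarray(center, dtype=float) if len(groups.ungrouped) else groups.ungrouped
    out = LineGroups(groups.orientation, shifted, ungrouped=ung)
    return out.refit().sort_by_intercept()
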