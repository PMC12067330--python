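"""Synthetic calibration targets with known ground-truth distortion.

Generates the three standard calibration patterns — dot grids, line grids
and chessboards — as point lattices and as rendered intensity images, warped
by a known radial polynomial and an optional perspective homography.  Every
downstream stage of the calibration pipeline is tested against these known
truths.

Composition order of the ground-truth warp: the radial map (about the
distortion center) is applied first, the perspective map last, i.e.
``distorted = P(R(undistorted))``.  This mirrors the calibration workflow,
which undoes perspective first and then calibrates the remaining, purely
radial distortion.

The generator emulates the geometry and the dominant image defects of real
targets (uneven illumination, noise, merged / missing / misplaced dots); it
does not attempt photorealistic optics or X-ray physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .perspective import PerspectiveModel, apply_perspective
from .radial import RadialModel, convert_model, unwarp_points

__all__ = [
    "GridSpec",
    "GroundTruth",
    "DefectLedger",
    "make_undistorted_grid",
    "distort_points",
    "render_dot_pattern",
    "render_line_pattern",
    "render_chessboard",
    "save_ground_truth",
    "load_ground_truth",
]


@dataclass
class GridSpec:
    """Geometry and rendering parameters of a synthetic grid target."""

    n_hlines: int = 15
    n_vlines: int = 15
    spacing: float = 40.0
    image_height: int = 640
    image_width: int = 640
    dot_radius: float = 5.0
    line_width: float = 3.0
    square_size: float | None = None
    background_level: float = 0.9
    feature_level: float = 0.2
    noise_sigma: float = 0.0
    defect_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.n_hlines * self.n_vlines < 9:
            raise ValueError("grid must contain at least a 3x3 lattice")
        if not 0 <= self.defect_rate < 1:
            raise ValueError("defect_rate must lie in [0, 1)")
        if self.square_size is None:
            self.square_size = self.spacing


@dataclass
class GroundTruth:
    """Known distortion parameters of a synthetic grid.

    ``forward_coeffs`` are the distorted->undistorted polynomial
    coefficients; ``backward_coeffs`` (undistorted->distorted) drive the
    generation and are derived from the forward ones if absent.  The
    perspective model, when present, maps the radially distorted
    (perspective-free) space to the observed image.
    """

    center: tuple[float, float]
    forward_coeffs: np.ndarray | None = None
    backward_coeffs: np.ndarray | None = None
    perspective: PerspectiveModel | None = None
    grid_slope: float = 0.0
    _domain: float = 2000.0

    def __post_init__(self) -> None:
        if self.forward_coeffs is None and self.backward_coeffs is None:
            self.backward_coeffs = np.array([1.0])
        if self.backward_coeffs is not None:
            self.backward_coeffs = np.atleast_1d(np.asarray(self.backward_coeffs, float))
        if self.forward_coeffs is not None:
            self.forward_coeffs = np.atleast_1d(np.asarray(self.forward_coeffs, float))

    def backward_model(self) -> RadialModel:
        if self.backward_coeffs is None:
            fwd = RadialModel(self.center, self.forward_coeffs, "forward")
            return convert_model(fwd, domain=(0.0, self._domain))
        return RadialModel(self.center, self.backward_coeffs, "backward")

    def forward_model(self) -> RadialModel:
        if self.forward_coeffs is None:
            bwd = RadialModel(self.center, self.backward_coeffs, "backward")
            return convert_model(bwd, domain=(0.0, self._domain))
        return RadialModel(self.center, self.forward_coeffs, "forward")


@dataclass
class DefectLedger:
    """Indices of lattice dots perturbed by the defect simulator."""

    removed: list = field(default_factory=list)
    displaced: list = field(default_factory=list)
    enlarged: list = field(default_factory=list)

    @property
    def all_defective(self) -> list:
        return sorted(self.removed + self.displaced + self.enlarged)

    @property
    def n_defects(self) -> int:
        return len(self.removed) + len(self.displaced) + len(self.enlarged)


def make_undistorted_grid(spec: GridSpec, origin: tuple[float, float] | None = None,
                          slope: float = 0.0):
    """Exact intersection lattice of the grid with row/column labels.

    Point (column j, row i) sits at (x0 + j*spacing, y0 + i*spacing),
    rotated by ``slope`` radians about the image center.  Returns
    (points (N, 2), rows (N,), cols (N,)).

    Raises ``ValueError`` naming the offending dimension when the grid does
    not fit in the image.
    """
    if origin is None:
        x0 = 0.5 * (spec.image_width - (spec.n_vlines - 1) * spec.spacing)
        y0 = 0.5 * (spec.image_height - (spec.n_hlines - 1) * spec.spacing)
    else:
        x0, y0 = origin
    w_span = x0 + (spec.n_vlines - 1) * spec.spacing
    h_span = y0 + (spec.n_hlines - 1) * spec.spacing
    if slope == 0.0:
        if w_span > spec.image_width:
            raise ValueError(f"grid exceeds image width ({w_span:.1f} > {spec.image_width})")
        if h_span > spec.image_height:
            raise ValueError(f"grid exceeds image height ({h_span:.1f} > {spec.image_height})")
    jj, ii = np.meshgrid(np.arange(spec.n_vlines), np.arange(spec.n_hlines))
    x = x0 + jj.ravel() * spec.spacing
    y = y0 + ii.ravel() * spec.spacing
    pts = np.column_stack([x, y])
    if slope != 0.0:
        cx, cy = spec.image_width / 2.0, spec.image_height / 2.0
        c, s = np.cos(slope), np.sin(slope)
        rot = np.array([[c, -s], [s, c]])
        pts = (pts - [cx, cy]) @ rot.T + [cx, cy]
    return pts, ii.ravel(), jj.ravel()


def distort_points(points: np.ndarray, truth: GroundTruth) -> np.ndarray:
    """Map undistorted points into the observed (distorted) image space.

    The radial (backward) map about the distortion center is applied first,
    the perspective map last.  A point at the center maps to the center
    exactly (zero-radius fixed point) when no perspective is present.
    """
    out = unwarp_points(points, truth.backward_model())
    if truth.perspective is not None:
        out = apply_perspective(out, truth.perspective)
    return out


def _paint_discs(img: np.ndarray, centers: np.ndarray, radii: np.ndarray,
                 level: float, supersample: int = 4) -> None:
    """Alpha-composite anti-aliased discs into ``img`` (in place).

    Coverage per pixel is computed on a ``supersample`` x finer local grid,
    which keeps sub-pixel centroid fidelity without rendering the whole
    frame at high resolution.
    """
    h, w = img.shape
    ss = supersample
    for (cx, cy), r in zip(centers, radii):
        x0, x1 = int(np.floor(cx - r - 1)), int(np.ceil(cx + r + 1))
        y0, y1 = int(np.floor(cy - r - 1)), int(np.ceil(cy + r + 1))
        x0c, x1c = max(x0, 0), min(x1, w - 1)
        y0c, y1c = max(y0, 0), min(y1, h - 1)
        if x0c > x1c or y0c > y1c:
            continue
        xs = np.arange(x0c, x1c + 1)
        ys = np.arange(y0c, y1c + 1)
        sub = (np.arange(ss) + 0.5) / ss - 0.5
        gx = xs[None, :, None, None] + sub[None, None, :, None]
        gy = ys[:, None, None, None] + sub[None, None, None, :]
        inside = (gx - cx) ** 2 + (gy - cy) ** 2 <= r * r
        cov = inside.mean(axis=(2, 3))
        region = img[y0c:y1c + 1, x0c:x1c + 1]
        img[y0c:y1c + 1, x0c:x1c + 1] = region + (level - region) * cov


def render_dot_pattern(points: np.ndarray, spec: GridSpec,
                       truth: GroundTruth | None = None,
                       rng: np.random.Generator | int | None = None,
                       background_gradient: float = 0.0):
    """Render an anti-aliased dot-pattern image with optional defects.

    ``points`` are the (already distorted) dot centers.  Out-of-bounds dots
    are silently clipped.  When ``spec.defect_rate`` > 0 a seeded fraction
    of dots is removed, displaced or enlarged; the returned
    :class:`DefectLedger` records which.  ``background_gradient`` adds a
    smooth linear ramp (peak relative amplitude) to exercise background
    normalization.

    Returns (image, ledger).
    """
    if spec.dot_radius >= spec.spacing / 2.0:
        raise ValueError("dot_radius must be smaller than spacing/2 (dots would merge)")
    rng = np.random.default_rng(rng)
    pts = np.asarray(points, dtype=float).copy()
    n = len(pts)
    radii = np.full(n, float(spec.dot_radius))
    ledger = DefectLedger()
    if spec.defect_rate > 0 and n:
        n_def = int(round(spec.defect_rate * n))
        idx = rng.choice(n, size=n_def, replace=False)
        kinds = rng.integers(0, 3, size=n_def)
        keep = np.ones(n, bool)
        for i, kind in zip(idx, kinds):
            if kind == 0:
                keep[i] = False
                ledger.removed.append(int(i))
            elif kind == 1:
                ang = rng.uniform(0, 2 * np.pi)
                shift = spec.spacing * rng.uniform(0.35, 0.5)
                pts[i] += shift * np.array([np.cos(ang), np.sin(ang)])
                ledger.displaced.append(int(i))
            else:
                radii[i] *= rng.uniform(2.0, 2.5)
                ledger.enlarged.append(int(i))
        pts, radii = pts[keep], radii[keep]
    img = np.full((spec.image_height, spec.image_width), spec.background_level)
    if background_gradient:
        yy, xx = np.mgrid[0:spec.image_height, 0:spec.image_width]
        ramp = (xx / max(spec.image_width - 1, 1) + yy / max(spec.image_height - 1, 1)) / 2.0
        img *= 1.0 + background_gradient * (ramp - 0.5)
    _paint_discs(img, pts, radii, spec.feature_level)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return img, ledger


def _polyline_y(curve_pts: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Dense ordinate of a line's distorted curve by monotone interpolation."""
    order = np.argsort(curve_pts[:, 0])
    return np.interp(x, curve_pts[order, 0], curve_pts[order, 1])


def render_line_pattern(points: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                        spec: GridSpec,
                        rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Render a line-pattern image through the (distorted) lattice points.

    Each grid row / column is drawn as an anti-aliased band of
    ``spec.line_width`` through a dense interpolation of its lattice
    points.
    """
    rng = np.random.default_rng(rng)
    img = np.full((spec.image_height, spec.image_width), spec.background_level)
    half = spec.line_width / 2.0
    xs = np.arange(spec.image_width, dtype=float)
    ys = np.arange(spec.image_height, dtype=float)

    def draw_band(center_of_col, along_x: bool) -> None:
        # coverage = clipped overlap of pixel with the band
        if along_x:
            yy = ys[:, None]
            cov = np.clip(half + 0.5 - np.abs(yy - center_of_col[None, :]), 0.0, 1.0)
        else:
            xx = xs[None, :]
            cov = np.clip(half + 0.5 - np.abs(xx - center_of_col[:, None]), 0.0, 1.0)
        np.copyto(img, img + (spec.feature_level - img) * cov)

    for i in np.unique(rows):
        sel = points[rows == i]
        if len(sel) >= 2:
            lo, hi = sel[:, 0].min(), sel[:, 0].max()
            yc = np.where((xs >= lo - 1) & (xs <= hi + 1), _polyline_y(sel, xs), np.inf)
            draw_band(yc, along_x=True)
    for j in np.unique(cols):
        sel = points[cols == j]
        if len(sel) >= 2:
            lo, hi = sel[:, 1].min(), sel[:, 1].max()
            xc = np.where((ys >= lo - 1) & (ys <= hi + 1),
                          _polyline_y(sel[:, ::-1], ys), np.inf)
            draw_band(xc, along_x=False)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return img


def render_chessboard(spec: GridSpec, truth: GroundTruth | None = None,
                      rng: np.random.Generator | int | None = None,
                      supersample: int = 8) -> np.ndarray:
    """Render a (possibly distorted) chessboard image.

    Square corners coincide with the grid lattice.  Distortion is applied
    analytically: each rendered pixel is pulled back to the undistorted
    space through the forward radial model (and inverse perspective) and
    coloured by the parity of its undistorted cell, anti-aliased by
    supersampling.
    """
    rng = np.random.default_rng(rng)
    ss = supersample
    h, w = spec.image_height, spec.image_width
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    acc = np.zeros((h, w))
    x0 = 0.5 * (w - (spec.n_vlines - 1) * spec.spacing)
    y0 = 0.5 * (h - (spec.n_hlines - 1) * spec.spacing)
    for dy in sub:
        for dx in sub:
            px = xx + dx
            py = yy + dy
            pts = np.column_stack([px.ravel(), py.ravel()])
            if truth is not None:
                if truth.perspective is not None:
                    pts = apply_perspective(pts, truth.perspective.invert())
                pts = unwarp_points(pts, truth.forward_model())
            ci = np.floor((pts[:, 0] - x0) / spec.square_size).astype(int)
            cj = np.floor((pts[:, 1] - y0) / spec.square_size).astype(int)
            inside = ((ci >= 0) & (ci < spec.n_vlines - 1)
                      & (cj >= 0) & (cj < spec.n_hlines - 1))
            acc += np.where(inside, (ci + cj) % 2, 0).reshape(h, w)
    frac = acc / ss ** 2
    img = spec.background_level + (spec.feature_level - spec.background_level) * frac
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return img


def save_ground_truth(path, truth: GroundTruth, points: np.ndarray | None = None,
                      rows: np.ndarray | None = None, cols: np.ndarray | None = None) -> None:
    """JSON sidecar with center, coefficients, homography and lattice."""
    d: dict = {"center": list(truth.center), "grid_slope": truth.grid_slope}
    if truth.forward_coeffs is not None:
        d["forward_coeffs"] = [float(c) for c in truth.forward_coeffs]
    if truth.backward_coeffs is not None:
        d["backward_coeffs"] = [float(c) for c in truth.backward_coeffs]
    if truth.perspective is not None:
        d["perspective"] = truth.perspective.to_dict()
    if points is not None:
        d["lattice"] = np.asarray(points).tolist()
    if rows is not None:
        d["rows"] = np.asarray(rows).astype(int).tolist()
    if cols is not None:
        d["cols"] = np.asarray(cols).astype(int).tolist()
    with open(path, "w") as f:
        json.dump(d, f)


def load_ground_truth(path):
    """Load the sidecar; returns (GroundTruth, lattice or None, rows, cols)."""
    with open(path) as f:
        d = json.load(f)
    persp = PerspectiveModel.from_dict(d["perspective"]) if "perspective" in d else None
    truth = GroundTruth(center=tuple(d["center"]),
                        forward_coeffs=np.array(d["forward_coeffs"]) if "forward_coeffs" in d else None,
                        backward_coeffs=np.array(d["backward_coeffs"]) if "backward_coeffs" in d else None,
                        perspective=persp, grid_slope=d.get("grid_slope", 0.0))
    lat = np.array(d["lattice"]) if "lattice" in d else None
    rows = np.array(d["rows"]) if "rows" in d else None
    cols = np.array(d["cols"]) if "cols" in d else None
    return truth, lat, rows, cols
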