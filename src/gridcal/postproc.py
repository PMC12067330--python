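"""Image / stack unwarping and residual-distortion evaluation.

Correction resamples the output (undistorted) pixel grid through the
backward model: for every undistorted pixel the backward map gives the
matching position in the distorted image, whose four neighbouring pixels
are interpolated.  Samples falling outside the image take the clipped-edge
value by default (a fill constant is available).  The same backward-mapping
contract serves plain images, perspective correction, composed
perspective+radial correction in a single resampling pass, and sinogram
generation from a projection stack, where only the minimal band of source
rows touched by the map is read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .perspective import PerspectiveModel, apply_perspective
from .radial import RadialModel

__all__ = [
    "ResidualReport",
    "unwarp_image_radial",
    "unwarp_image_perspective",
    "unwarp_sinogram",
    "evaluate_straightness",
]


@dataclass
class ResidualReport:
    """Per-point straightness residuals of grouped reference points.

    distance_to_line is the perpendicular distance of each point to its
    group's least-squares straight line; distance_to_center the distance
    from the report origin.  Summaries are overall max and RMS.
    """

    distance_to_line: np.ndarray
    distance_to_center: np.ndarray
    group_index: np.ndarray
    signed_distance: np.ndarray

    @property
    def max(self) -> float:
        return float(np.max(self.distance_to_line)) if len(self.distance_to_line) else 0.0

    @property
    def rms(self) -> float:
        if not len(self.distance_to_line):
            return 0.0
        return float(np.sqrt(np.mean(self.distance_to_line ** 2)))

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "group_index": self.group_index,
            "distance_to_line": self.distance_to_line,
            "signed_distance": self.signed_distance,
            "distance_to_center": self.distance_to_center,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _backward_coords_radial(shape: tuple[int, int], model: RadialModel):
    """Distorted-space sampling coordinates (rows, cols) for every
    undistorted pixel, via the polynomial backward map."""
    h, w = shape
    xc, yc = model.center
    xu = np.arange(w, dtype=float)[None, :] - xc
    yu = np.arange(h, dtype=float)[:, None] - yc
    ru = np.hypot(xu, yu)
    fac = model.factor(ru)  # r_d / r_u, finite at r_u = 0 (limit k_0)
    xd = xu * fac + xc
    yd = yu * fac + yc
    return yd, xd


def _interpolate(image: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                 interpolation: str, fill: float | None) -> np.ndarray:
    order = {"nearest": 0, "bilinear": 1}.get(interpolation)
    if order is None:
        raise ValueError("interpolation must be 'nearest' or 'bilinear'")
    if fill is None:
        return ndimage.map_coordinates(np.asarray(image, float), [rows, cols],
                                       order=order, mode="nearest")
    return ndimage.map_coordinates(np.asarray(image, float), [rows, cols],
                                   order=order, mode="constant", cval=fill)


def unwarp_image_radial(image: np.ndarray, model: RadialModel,
                        interpolation: str = "bilinear",
                        fill: float | None = None) -> np.ndarray:
    """Correct radial distortion of an image with a backward model.

    For every undistorted pixel the backward polynomial gives the matching
    distorted-space position, and the four neighbouring source pixels are
    interpolated (bilinear default, nearest available).  Neighbour indices
    outside the image are clipped to the edge unless ``fill`` is given.
    """
    if model.direction != "backward":
        raise ValueError("image correction needs a backward model; "
                         "use convert_model() on a forward model first")
    img = np.asarray(image, dtype=float)
    rows, cols = _backward_coords_radial(img.shape, model)
    return _interpolate(img, rows, cols, interpolation, fill)


def unwarp_image_perspective(image: np.ndarray, model: PerspectiveModel,
                             interpolation: str = "bilinear",
                             fill: float | None = None,
                             radial: RadialModel | None = None) -> np.ndarray:
    """Correct perspective (optionally composed with radial) distortion.

    ``model`` must be a backward homography (undistorted -> distorted).
    When ``radial`` is given, the radial backward map is applied first and
    the homography second — one resampling pass with a single
    interpolation, matching the ground-truth composition
    distorted = P(R(undistorted)).
    """
    if model.direction != "backward":
        raise ValueError("image correction needs a backward model; use invert()")
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if radial is not None:
        if radial.direction != "backward":
            raise ValueError("composed radial model must be backward")
        rows, cols = _backward_coords_radial(img.shape, radial)
        pts = np.column_stack([cols.ravel(), rows.ravel()])
    else:
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
    mapped = apply_perspective(pts, model)
    rows = mapped[:, 1].reshape(h, w)
    cols = mapped[:, 0].reshape(h, w)
    return _interpolate(img, rows, cols, interpolation, fill)


def unwarp_sinogram(stack, row: int, model: RadialModel,
                    interpolation: str = "bilinear"):
    """Undistorted sinogram of one detector row from a projection stack.

    ``stack`` is indexed (angle, row, column) and may be any sliceable
    array-like (numpy array, HDF5 dataset, memory-mapped TIFF stack).  The
    backward map of the output row touches only a narrow band of source
    rows; only that band is read, so full-stack correction is never needed
    to reconstruct a single slice.

    Returns (sinogram (n_angles, width), (band_lo, band_hi)).
    """
    if model.direction != "backward":
        raise ValueError("sinogram correction needs a backward model")
    n_ang, n_row, n_col = stack.shape[0], stack.shape[1], stack.shape[2]
    xc, yc = model.center
    xu = np.arange(n_col, dtype=float) - xc
    yu = float(row) - yc
    ru = np.hypot(xu, yu)
    fac = model.factor(ru)
    xd = xu * fac + xc
    yd = yu * fac + yc
    lo = int(np.floor(yd.min()))
    hi = int(np.ceil(yd.max()))
    if lo < 0 or hi > n_row - 1:
        import warnings
        warnings.warn("backward-mapped row band exceeds the stack; clipping")
    lo_c, hi_c = max(lo, 0), min(hi, n_row - 1)
    band = np.asarray(stack[:, lo_c:hi_c + 1, :], dtype=float)
    rows_local = np.clip(yd - lo_c, 0.0, hi_c - lo_c)
    cols = xd
    sino = np.empty((n_ang, n_col))
    for a in range(n_ang):
        sino[a] = _interpolate(band[a], rows_local, cols, interpolation, None)
    return sino, (lo_c, hi_c)


def _line_residuals(points: np.ndarray):
    """Signed perpendicular distances to the total-least-squares line."""
    pts = np.asarray(points, dtype=float)
    mean = pts.mean(axis=0)
    centered = pts - mean
    if len(pts) < 2:
        return np.zeros(len(pts))
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    return centered @ normal


def evaluate_straightness(groups, center: tuple[float, float] = (0.0, 0.0)) -> ResidualReport:
    """Straightness of grouped points: distance to each group's fitted line.

    ``groups`` is a list of (n, 2) point arrays (or a LineGroups).  A
    straight line is fitted per group by total least squares and the
    perpendicular distance of every point reported, together with the
    point's distance from ``center``.
    """
    if hasattr(groups, "groups"):
        groups = groups.groups
    dists, radial, gidx, signed = [], [], [], []
    for k, g in enumerate(groups):
        g = np.asarray(g, dtype=float)
        s = _line_residuals(g)
        signed.append(s)
        dists.append(np.abs(s))
        radial.append(np.hypot(g[:, 0] - center[0], g[:, 1] - center[1]))
        gidx.append(np.full(len(g), k))
    cat = (lambda a: np.concatenate(a) if a else np.zeros(0))
    return ResidualReport(cat(dists), cat(radial), cat(gidx), cat(signed))
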