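"""Reference-point extraction from dot, line and chessboard images.

The calibration image is reduced to a clean set of sub-pixel reference
points: dot patterns via background normalization, binarization and
center-of-mass computation with defect filters; line patterns via intensity
profiles cast perpendicular to the lines, with Gaussian validation of every
candidate extremum; chessboards either through a gradient conversion to a
line image or through sliding-linear-fit edge localization.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu, sobel
from skimage.measure import regionprops

__all__ = [
    "normalize_background",
    "binarize",
    "get_dot_centroids",
    "filter_by_size",
    "filter_by_ellipticity",
    "remove_misplaced_dots",
    "detect_points_on_lines",
    "validate_extremum",
    "chessboard_to_line_image",
    "chessboard_edge_points",
    "calc_grid_slope",
    "mask_points_parabolic",
    "remove_subset",
]

_EIGHT = np.ones((3, 3), dtype=int)


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 32:
        raise ValueError("expect a 2-D image of at least 32x32 pixels")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains NaN/Inf")
    return img


def normalize_background(image: np.ndarray, method: str = "gaussian",
                         size: float = 51.0) -> np.ndarray:
    """Flatten uneven illumination by dividing by a smoothed background.

    ``size`` is the median window (must exceed the dot size) or, for the
    Gaussian method, is converted to an equivalent sigma (size/4).  The
    background estimate is floored at a small epsilon so the division is
    always finite.
    """
    img = _check_image(image)
    if size >= min(img.shape):
        raise ValueError("background window must be smaller than the image")
    if method == "gaussian":
        bg = ndimage.gaussian_filter(img, sigma=size / 4.0)
        # second pass: re-estimate with the grid features masked out
        # (normalized convolution), otherwise the background dips around
        # every dot/line and biases the sub-pixel centroids
        resid = img / np.maximum(bg, 1e-12 * max(float(np.abs(img).max()), 1.0))
        try:
            thr = threshold_otsu(resid)
        except ValueError:
            thr = None
        if thr is not None and 0.02 < (resid < thr).mean() < 0.98:
            fg = resid < thr if (resid < thr).mean() < 0.5 else resid >= thr
            fg = ndimage.binary_dilation(fg, iterations=2)
            keep = (~fg).astype(float)
            num = ndimage.gaussian_filter(img * keep, sigma=size / 4.0)
            den = ndimage.gaussian_filter(keep, sigma=size / 4.0)
            good = den > 1e-6
            bg = np.where(good, num / np.maximum(den, 1e-12), bg)
    elif method == "median":
        bg = ndimage.median_filter(img, size=int(size))
    else:
        raise ValueError("method must be 'gaussian' or 'median'")
    eps = 1e-6 * max(float(np.abs(img).max()), 1.0)
    return img / np.maximum(bg, eps)


def binarize(image: np.ndarray, method: str = "otsu", ratio: float = 0.95,
             invert: bool | None = None):
    """Threshold a normalized image into a dot mask.

    method 'otsu' uses Otsu's criterion; 'sorting' thresholds at the pixel
    value of rank ``ratio * N`` in the sorted intensity list.  The dot phase
    (darker or brighter) is auto-detected as the minority phase unless
    ``invert`` forces it.  Returns (mask, median dot size in pixels).
    """
    img = _check_image(image)
    if float(np.ptp(img)) < 1e-8:
        raise ValueError("no bimodal structure: image is uniform")
    if method == "otsu":
        thr = threshold_otsu(img)
    elif method == "sorting":
        flat = np.sort(img, axis=None)
        idx = int(np.clip(round(ratio * (flat.size - 1)), 0, flat.size - 1))
        thr = flat[idx]
    else:
        raise ValueError("method must be 'otsu' or 'sorting'")
    dark = img < thr
    if invert is None:
        # dots are the minority phase of a grid target
        mask = dark if dark.mean() <= 0.5 else ~dark
    else:
        mask = ~dark if invert else dark
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        raise ValueError("no foreground objects after thresholding")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return mask, float(np.median(sizes))


def get_dot_centroids(binary: np.ndarray, weights: np.ndarray | None = None):
    """Centroid of every 8-connected component.

    By default the centroid is unweighted (binary center of mass);
    ``weights`` switches to an intensity-weighted centroid.  Returns
    (points (N, 2) in (x, y), sizes (N,) in pixels).
    """
    mask = np.asarray(binary).astype(bool)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        raise ValueError("empty mask: no connected components")
    idx = np.arange(1, n + 1)
    if weights is None:
        com = ndimage.center_of_mass(mask, labels, index=idx)
    else:
        com = ndimage.center_of_mass(np.asarray(weights, float) * mask, labels, index=idx)
    com = np.asarray(com, dtype=float)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=idx)
    return com[:, ::-1].copy(), sizes  # (row, col) -> (x, y)


def filter_by_size(points: np.ndarray, sizes: np.ndarray,
                   tolerance_ratio: float = 0.3):
    """Keep components whose pixel count is close to the median size."""
    sizes = np.asarray(sizes, dtype=float)
    med = np.median(sizes)
    keep = np.abs(sizes - med) <= tolerance_ratio * med
    return np.asarray(points)[keep], sizes[keep]


def filter_by_ellipticity(binary: np.ndarray, points: np.ndarray,
                          max_ratio: float = 2.0) -> np.ndarray:
    """Drop components whose best-fit ellipse is too elongated.

    The ellipse axes come from the second-order central moments of each
    component; the component containing each point is tested and removed
    when major/minor exceeds ``max_ratio``.
    """
    mask = np.asarray(binary).astype(bool)
    labels, _ = ndimage.label(mask, structure=_EIGHT)
    ratio_of_label = {}
    for prop in regionprops(labels):
        minor = max(prop.axis_minor_length, 1e-3)
        ratio_of_label[prop.label] = prop.axis_major_length / minor
    pts = np.asarray(points, dtype=float)
    keep = []
    for p in pts:
        lab = labels[int(round(p[1])), int(round(p[0]))]
        keep.append(lab != 0 and ratio_of_label.get(lab, np.inf) <= max_ratio)
    return pts[np.asarray(keep, bool)]


def remove_misplaced_dots(points: np.ndarray, tolerance_ratio: float = 0.3) -> np.ndarray:
    """Drop dots whose local spacing disagrees with the grid.

    For every dot the distances to its four nearest neighbours are compared
    with the global median nearest-neighbour distance d_m; the dot is
    removed iff none of the four lies within ``tolerance_ratio * d_m`` of
    d_m.  Not suitable for strongly distorted grids, where the local
    spacing itself varies with radius — use residual-based removal after
    grouping instead.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 6:
        return pts
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=5)
    nn = dists[:, 1:]
    d_m = float(np.median(nn[:, 0]))
    band = tolerance_ratio * d_m
    keep = np.any(np.abs(nn - d_m) <= band, axis=1)
    return pts[keep]


def _gaussian(x, amp, mu, sigma, offset):
    return offset + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def validate_extremum(profile: np.ndarray, index: int, window: int = 7,
                      quality_threshold: float = 0.2,
                      min_sigma: float = 0.4,
                      min_amplitude: float = 0.0) -> float | None:
    """Gaussian-validate one candidate extremum of an intensity profile.

    A Gaussian plus constant offset is fitted over ``window`` samples
    centered on the candidate.  The candidate is accepted iff the relative
    fit residual (RMS residual / fitted amplitude) stays below
    ``quality_threshold`` and the fitted width is sane (between
    ``min_sigma`` and the window size); the fitted mean is then the
    sub-pixel coordinate.  Returns None on rejection.
    """
    prof = np.asarray(profile, dtype=float)
    half = window // 2
    lo, hi = index - half, index + half + 1
    if lo < 0 or hi > len(prof):
        return None
    x = np.arange(lo, hi, dtype=float)
    y = prof[lo:hi]
    amp0 = y[half] - 0.5 * (y[0] + y[-1])
    if abs(amp0) < 1e-12:
        return None
    p0 = [amp0, float(index), max(window / 5.0, 0.8), 0.5 * (y[0] + y[-1])]
    try:
        popt, _ = optimize.curve_fit(_gaussian, x, y, p0=p0, maxfev=400)
    except (RuntimeError, optimize.OptimizeWarning):
        return None
    amp, mu, sigma, _ = popt
    sigma = abs(sigma)
    if abs(amp) < max(min_amplitude, 1e-12) or sigma < min_sigma or sigma > window:
        return None
    resid = y - _gaussian(x, *popt)
    if np.sqrt(np.mean(resid ** 2)) / abs(amp) > quality_threshold:
        return None
    if not (lo - 1 <= mu <= hi):
        return None
    return float(mu)


def _local_extrema(profile: np.ndarray, polarity: str) -> np.ndarray:
    from scipy.signal import find_peaks
    prof = np.asarray(profile, dtype=float)
    prom = 0.1 * float(np.ptp(prof))
    if prom <= 0:
        return np.array([], dtype=int)
    if polarity == "min":
        peaks, _ = find_peaks(-prof, prominence=prom)
    else:
        peaks, _ = find_peaks(prof, prominence=prom)
    return peaks


def detect_points_on_lines(image: np.ndarray, orientation: str = "horizontal",
                           profile_spacing: int = 10, search_radius: int = 7,
                           polarity: str = "auto",
                           quality_threshold: float = 0.2) -> np.ndarray:
    """Detect points on (possibly curved) grid lines via crossing profiles.

    For horizontal lines, vertical intensity profiles are cast every
    ``profile_spacing`` columns; each validated local extremum yields one
    sub-pixel point.  ``polarity`` selects dark lines ('min'), bright lines
    ('max') or the dominant contrast ('auto').

    Raises ``ValueError`` when no extremum passes validation.
    """
    img = _check_image(image)
    if polarity == "auto":
        med = np.median(img)
        polarity = "min" if (med - img.min()) > (img.max() - med) else "max"
    h, w = img.shape
    # amplitude floor against the global contrast: rejects the shallow ghost
    # extrema a profile picks up where it runs along a perpendicular line
    contrast = float(np.percentile(img, 95) - np.percentile(img, 5))
    min_amp = 0.3 * contrast
    pts = []
    positions = np.arange(profile_spacing // 2, (w if orientation == "horizontal" else h),
                          profile_spacing)
    for pos in positions:
        prof = img[:, pos] if orientation == "horizontal" else img[pos, :]
        for cand in _local_extrema(prof, polarity):
            loc = validate_extremum(prof, int(cand), window=2 * search_radius + 1,
                                    quality_threshold=quality_threshold,
                                    min_amplitude=min_amp)
            if loc is not None:
                if orientation == "horizontal":
                    pts.append((float(pos), loc))
                else:
                    pts.append((loc, float(pos)))
    if not pts:
        raise ValueError("no line structure detected")
    return np.array(pts)


def chessboard_to_line_image(image: np.ndarray,
                             orientation: str | None = None) -> np.ndarray:
    """Gradient image whose ridges lie on square boundaries.

    With no orientation the Sobel gradient magnitude is returned (ridges on
    all boundaries).  With 'horizontal'/'vertical' only the derivative
    across that line orientation is used, so ridges of the perpendicular
    boundaries vanish — this keeps profile casting from tripping over
    boundaries parallel to the profile.
    """
    from skimage.filters import sobel_h, sobel_v
    img = _check_image(image)
    if orientation is None:
        return sobel(img)
    if orientation == "horizontal":
        return np.abs(sobel_h(img))
    if orientation == "vertical":
        return np.abs(sobel_v(img))
    raise ValueError("orientation must be None, 'horizontal' or 'vertical'")


def _sliding_slope(profile: np.ndarray, fit_window: int) -> np.ndarray:
    """Slope of a sliding linear fit at every profile position.

    Equivalent to correlation with a normalized ramp kernel; turns step
    edges into peaks.
    """
    prof = np.asarray(profile, dtype=float)
    w = fit_window if fit_window % 2 == 1 else fit_window + 1
    x = np.arange(w) - w // 2
    kernel = x / float(np.sum(x * x))
    return np.correlate(prof, kernel[::-1], mode="same")


def chessboard_edge_points(image: np.ndarray, orientation: str = "horizontal",
                           profile_spacing: int = 10, fit_window: int = 7,
                           quality_threshold: float = 0.3) -> np.ndarray:
    """Locate square-boundary edges as peaks of a sliding linear-fit slope.

    Along each cast profile the local linear-fit slope is computed per
    position; extrema of |slope| are validated and sub-pixel localized with
    the same Gaussian criterion used for line patterns.
    """
    img = _check_image(image)
    h, w = img.shape
    pts = []
    positions = np.arange(profile_spacing // 2,
                          (w if orientation == "horizontal" else h), profile_spacing)
    for pos in positions:
        prof = img[:, pos] if orientation == "horizontal" else img[pos, :]
        slope_sig = np.abs(_sliding_slope(prof, fit_window))
        if float(np.ptp(slope_sig)) < 1e-10:
            continue
        cands = _local_extrema(slope_sig, "max")
        if len(cands) == 0:
            continue
        # full-height steps share one peak amplitude; peaks halved by a
        # nearby corner (profile grazing a perpendicular boundary) are
        # biased and get rejected by the amplitude floor
        amp_floor = 0.55 * float(np.median(slope_sig[cands]))
        for cand in cands:
            loc = validate_extremum(slope_sig, int(cand), window=fit_window + 4,
                                    quality_threshold=quality_threshold,
                                    min_amplitude=amp_floor)
            if loc is not None:
                if orientation == "horizontal":
                    pts.append((float(pos), loc))
                else:
                    pts.append((loc, float(pos)))
    return np.array(pts).reshape(-1, 2)


def calc_grid_slope(points: np.ndarray, k: int = 5) -> tuple[float, float]:
    """Dominant grid rotation from nearest-neighbour displacement angles.

    Displacement angles are folded to [-pi/4, pi/4); the estimate is the
    median of the near-horizontal (resp. near-vertical) displacements,
    returned as (horizontal, vertical) slopes in radians.
    """
    pts = np.asarray(points, dtype=float)
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=min(k, len(pts)))
    disp = pts[idx[:, 1:]] - pts[:, None, :]
    ang = np.arctan2(disp[..., 1], disp[..., 0]).ravel()
    folded = ((ang + np.pi / 4) % (np.pi / 2)) - np.pi / 4
    ang_mod = ang % np.pi
    near_h = (ang_mod < np.pi / 4) | (ang_mod > 3 * np.pi / 4)
    sl_h = float(np.median(folded[near_h])) if near_h.any() else 0.0
    sl_v = float(np.median(folded[~near_h])) if (~near_h).any() else sl_h
    return sl_h, sl_v


def mask_points_parabolic(points: np.ndarray, coeffs, margin: float = np.inf,
                          orientation: str = "horizontal",
                          side: str = "band") -> np.ndarray:
    """Keep points relative to the parabola (a, b, c).

    side 'band' keeps points within ``margin`` of the curve; 'below' /
    'above' keep the half-plane on one side (a half-plane mask when a = b =
    0).
    """
    pts = np.asarray(points, dtype=float)
    a, b, c = coeffs
    if orientation == "horizontal":
        resid = pts[:, 1] - (a * pts[:, 0] ** 2 + b * pts[:, 0] + c)
    else:
        resid = pts[:, 0] - (a * pts[:, 1] ** 2 + b * pts[:, 1] + c)
    if side == "band":
        keep = np.abs(resid) <= margin
    elif side == "below":
        keep = resid >= 0
    elif side == "above":
        keep = resid <= 0
    else:
        raise ValueError("side must be 'band', 'below' or 'above'")
    return pts[keep]


def remove_subset(points: np.ndarray, region) -> np.ndarray:
    """Remove points inside the rectangular region (xmin, xmax, ymin, ymax)."""
    pts = np.asarray(points, dtype=float)
    xmin, xmax, ymin, ymax = region
    inside = ((pts[:, 0] >= xmin) & (pts[:, 0] <= xmax)
              & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax))
    return pts[~inside]
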