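"""Shared synthetic fixtures: grids with known ground-truth distortion."""

import numpy as np
import pytest

from gridcal.config import CalibConfig
from gridcal.perspective import make_tilt_homography
from gridcal.synthetic import (GridSpec, GroundTruth, distort_points,
                               make_undistorted_grid, render_dot_pattern)


@pytest.fixture(scope="session")
def barrel_grid():
    """Moderate-barrel point grid (no perspective), 1400 px frame."""
    spec = GridSpec(n_hlines=21, n_vlines=21, spacing=60,
                    image_height=1400, image_width=1400)
    pts, rows, cols = make_undistorted_grid(spec)
    truth = GroundTruth(center=(750.0, 660.0),
                        backward_coeffs=[1.0, -4e-5, 4e-9], _domain=1400)
    return {"spec": spec, "points": pts, "rows": rows, "cols": cols,
            "truth": truth, "distorted": distort_points(pts, truth)}


@pytest.fixture(scope="session")
def pincushion_grid():
    spec = GridSpec(n_hlines=21, n_vlines=21, spacing=60,
                    image_height=1400, image_width=1400)
    pts, rows, cols = make_undistorted_grid(spec)
    truth = GroundTruth(center=(680.0, 720.0),
                        backward_coeffs=[1.0, 3e-5], _domain=1400)
    return {"spec": spec, "points": pts, "rows": rows, "cols": cols,
            "truth": truth, "distorted": distort_points(pts, truth)}


@pytest.fixture(scope="session")
def fisheye_grid():
    """Strong-barrel (fisheye-like) grid: sagitta ~15% of the frame."""
    spec = GridSpec(n_hlines=25, n_vlines=25, spacing=70,
                    image_height=2000, image_width=2000)
    pts, rows, cols = make_undistorted_grid(spec)
    truth = GroundTruth(center=(1050.0, 960.0),
                        backward_coeffs=[1.0, -2e-4], _domain=2400)
    return {"spec": spec, "points": pts, "rows": rows, "cols": cols,
            "truth": truth, "distorted": distort_points(pts, truth)}


@pytest.fixture(scope="session")
def dot_image():
    """Rendered noisy dot-pattern image with barrel + mild tilt."""
    spec = GridSpec(n_hlines=15, n_vlines=15, spacing=50,
                    image_height=800, image_width=800,
                    dot_radius=6, noise_sigma=0.01)
    pts, rows, cols = make_undistorted_grid(spec)
    center = (430.0, 380.0)
    truth = GroundTruth(center=center, backward_coeffs=[1.0, -5e-5],
                        perspective=make_tilt_homography(center, 2.0, -1.0),
                        _domain=900)
    distorted = distort_points(pts, truth)
    image, ledger = render_dot_pattern(distorted, spec, rng=7)
    return {"spec": spec, "points": pts, "rows": rows, "cols": cols,
            "truth": truth, "distorted": distorted, "image": image,
            "ledger": ledger,
            "config": CalibConfig(nominal_distance=50.0,
                                  normalization_size=35)}
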