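"""Calibration configuration: one mapping for every tunable threshold."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass


@dataclass
class CalibConfig:
    """Parameters of the full calibration pipeline.

    Grouping modes: 'slope_guided' for small-to-medium curvature,
    'middle_out' for strongly curved (fisheye) grids.  All tolerances are
    in the units stated; see docs/methods.md for the reasoning behind the
    defaults.
    """

    pattern_type: str = "dot"            # dot | line | chessboard
    # preprocessing
    normalization_method: str = "gaussian"   # gaussian | median
    normalization_size: float = 51.0         # px, > dot size
    binarization_method: str = "otsu"        # otsu | sorting
    binarization_ratio: float = 0.95         # sorting rank fraction
    centroid_method: str = "weighted"        # weighted | binary
    size_tolerance: float = 0.3              # fraction of median dot size
    ellipticity_max_ratio: float = 2.0
    misplaced_tolerance: float | None = None  # None disables (strong distortion)
    profile_spacing: int = 10                # px between cast profiles
    search_radius: int = 7                   # half window of extremum fits
    quality_threshold: float = 0.2           # Gaussian-fit residual bound
    # grouping
    grouping_mode: str = "slope_guided"      # slope_guided | middle_out
    nominal_distance: float | None = None    # px between lines; None = auto
    grouping_tolerance: float = 0.3          # fraction of nominal distance
    max_missing: int = 4                     # allowed run of missing dots
    residual_threshold: float = 2.0          # px, post-grouping outlier cut
    # model
    poly_order: int = 4
    n_near: int = 6                          # lines used for the dc estimate
    refine_steps: int = 15                   # dc grid-search steps (0 = off)
    refine_fraction: float = 0.02
    center_iterations: int = 3
    perspective_correction: str = "auto"     # auto | homography | coeffs | off
    scale: float | None = None               # undistorted px per line
    # misc
    seed: int = 0

    def validate(self) -> "CalibConfig":
        if self.pattern_type not in ("dot", "line", "chessboard"):
            raise ValueError("pattern_type must be dot, line or chessboard")
        if self.grouping_mode not in ("slope_guided", "middle_out"):
            raise ValueError("grouping_mode must be slope_guided or middle_out")
        for name in ("normalization_size", "size_tolerance", "ellipticity_max_ratio",
                     "grouping_tolerance", "residual_threshold", "quality_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.poly_order < 1:
            raise ValueError("poly_order must be >= 1")
        return self

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibConfig":
        with open(path) as f:
            return cls(**json.load(f)).validate()
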