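"""Core record types shared across the detection pipeline.

These dataclasses carry the calibrated input image, the per-protrusion
detection records, and the tunable parameters of the morphological
pipeline.  All coordinates are 0-based ``(row, col)`` pixel indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "GrayImage",
    "DetectionParams",
    "PixelRegion",
    "EllipseFit",
    "FilopodiumRecord",
    "DetectionResult",
]


@dataclass(frozen=True)
class GrayImage:
    """A calibrated 2-D grayscale intensity raster.

    Parameters
    ----------
    pixels : ndarray
        2-D array of non-negative integer intensities (uint8 or uint16).
    bit_depth : int
        8 or 16.
    pixel_size_um : float
        Physical size of one pixel in microns; must be positive.  All
        micron-valued thresholds of the pipeline (opening radius, minimum
        filopodium length) are converted to pixels through this value.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {px.shape}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("image must be at least 2x2 pixels")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"pixel intensities must be integer, got dtype {px.dtype}")
        vmax = (1 << self.bit_depth) - 1
        if px.min() < 0 or px.max() > vmax:
            raise ValueError(f"intensities out of range [0, {vmax}]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the filopodia detection pipeline.

    Defaults follow the published operating point: a first opening at
    0.5 um (filopodia are <= ~0.4 um wide, so the opening removes them
    from the cell body), an elongation filter at a 1.5 major/minor axis
    ratio, a 0.4 um minimum reported length, and a 10-gray-level window
    for the background-valley search to the right of the triangle
    threshold.
    """

    opening_radius_um: float = 0.5
    min_length_um: float = 0.4
    axis_ratio_min: float = 1.5
    local_min_window: int = 10
    threshold_method: str = "modified_triangle"

    def __post_init__(self) -> None:
        if not self.opening_radius_um > 0:
            raise ValueError("opening_radius_um must be positive")
        if not self.min_length_um > 0:
            raise ValueError("min_length_um must be positive")
        if self.axis_ratio_min < 1:
            raise ValueError("axis_ratio_min must be >= 1")
        if self.local_min_window < 0:
            raise ValueError("local_min_window must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PixelRegion:
    """An 8-connected set of pixels, a candidate protrusion fragment."""

    pixels: frozenset
    bounding_box: tuple[int, int, int, int]  # row0, col0, row1, col1 (inclusive)

    @classmethod
    def from_pixels(cls, pixels) -> "PixelRegion":
        pix = frozenset((int(r), int(c)) for r, c in pixels)
        if not pix:
            raise ValueError("a PixelRegion must contain at least one pixel")
        rows = [p[0] for p in pix]
        cols = [p[1] for p in pix]
        return cls(pixels=pix, bounding_box=(min(rows), min(cols), max(rows), max(cols)))

    @property
    def area(self) -> int:
        return len(self.pixels)

    def centroid(self) -> tuple[float, float]:
        rows = [p[0] for p in self.pixels]
        cols = [p[1] for p in self.pixels]
        return (float(np.mean(rows)), float(np.mean(cols)))


@dataclass(frozen=True)
class EllipseFit:
    """Axis lengths of the moment-equivalent ellipse of a pixel region."""

    major_axis_px: float
    minor_axis_px: float

    def __post_init__(self) -> None:
        if not (self.major_axis_px >= self.minor_axis_px > 0):
            raise ValueError("require major >= minor > 0")

    @property
    def axis_ratio(self) -> float:
        return self.major_axis_px / self.minor_axis_px


@dataclass(frozen=True)
class FilopodiumRecord:
    """One detected filopodium (a combined group is a single record).

    ``length_um`` is the skeleton pixel count times the pixel size: the
    length of a thinned protrusion equals its area once it is one pixel
    wide, and for a combined group it is the total length of all members.
    """

    region: PixelRegion
    skeleton: frozenset
    length_um: float
    n_endpoints: int
    n_branchpoints: int
    is_combined: bool

    def __post_init__(self) -> None:
        if not self.skeleton:
            raise ValueError("skeleton must be nonempty")


@dataclass(frozen=True)
class DetectionResult:
    """Per-cell detection output: records plus summary counts."""

    n_single: int
    n_combined: int
    n_total: int
    filopodia: tuple
    params_used: DetectionParams
    threshold_level: int

    def __post_init__(self) -> None:
        if self.n_total != self.n_single + self.n_combined:
            raise ValueError("n_total must equal n_single + n_combined")
        if self.n_total != len(self.filopodia):
            raise ValueError("n_total must equal the number of records")

    @property
    def mean_length_um(self) -> float:
        if not self.filopodia:
            return float("nan")
        return float(np.mean([f.length_um for f in self.filopodia]))

    @property
    def lengths_um(self) -> list[float]:
        return [f.length_um for f in self.filopodia]
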