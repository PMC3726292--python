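"""Filopodia extraction, classification and length measurement.

The detection strategy is purely morphological.  A first opening of the
segmented cell body with a disk whose radius (default 0.5 um) exceeds
the typical filopodium half-width strips the thin protrusions from the
periphery; the stripped fragments are candidate filopodia.  Fragments
that are not filament-like (moment-ellipse major axis < 1.5x minor
axis) are discarded and the mean minor-axis length ``L`` of the
survivors gives a cell-specific estimate of filopodium width.  A second
opening with a disk of radius ``L`` pixels produces the final candidate
set, which is filtered to drop protrusions shorter than 0.4 um.

Each surviving fragment is thinned to a one-pixel-wide skeleton; its
length is the skeleton pixel count times the pixel size, and a fragment
whose skeleton has more than one branch point and at least four
endpoints is classified as a *combined* group (filopodia fused at the
base or crossing in projection), counted as one object.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .records import (
    DetectionParams,
    DetectionResult,
    EllipseFit,
    FilopodiumRecord,
    GrayImage,
    PixelRegion,
)
from .segmentation import EIGHT_CONN, CellMask, segment_cell

__all__ = [
    "disk_structuring_element",
    "disk_footprint",
    "morphological_opening",
    "extract_candidates",
    "fit_region_ellipse",
    "estimate_filopodium_width",
    "skeletonize_region",
    "count_skeleton_features",
    "classify_combined",
    "measure_length",
    "detect_filopodia",
]


def disk_structuring_element(radius_um: float, pixel_size_um: float) -> frozenset:
    """Disk neighbourhood of a pixel ``P`` as a set of (dr, dc) offsets.

    Contains every offset whose centre-to-centre distance from ``P`` is
    at most ``radius_um``; always contains (0, 0).  A radius smaller
    than one pixel spacing degenerates to the single-pixel element, with
    a warning, since no neighbouring centre is in range.
    """
    if not radius_um > 0:
        raise ValueError("radius_um must be positive")
    r_px = radius_um / pixel_size_um
    n = int(np.floor(r_px))
    offsets = {
        (dr, dc)
        for dr in range(-n, n + 1)
        for dc in range(-n, n + 1)
        if np.hypot(dr, dc) <= r_px
    }
    if offsets == {(0, 0)}:
        warnings.warn(
            f"opening radius {radius_um} um is below one pixel spacing "
            f"({pixel_size_um} um): structuring element degenerates to a single pixel",
            stacklevel=2,
        )
    return frozenset(offsets)


def disk_footprint(radius_px: float) -> np.ndarray:
    """Boolean disk footprint of the given pixel radius (odd square array)."""
    if not radius_px > 0:
        raise ValueError("radius_px must be positive")
    n = int(np.floor(radius_px))
    dr, dc = np.mgrid[-n : n + 1, -n : n + 1]
    return np.hypot(dr, dc) <= radius_px


def _offsets_to_footprint(se) -> np.ndarray:
    if isinstance(se, np.ndarray):
        return se.astype(bool)
    offs = list(se)
    n = max(max(abs(dr), abs(dc)) for dr, dc in offs)
    fp = np.zeros((2 * n + 1, 2 * n + 1), dtype=bool)
    for dr, dc in offs:
        fp[dr + n, dc + n] = True
    return fp


def morphological_opening(mask: np.ndarray, se) -> np.ndarray:
    """Binary opening: erosion then dilation with the same element.

    Pixels outside the image count as OFF during erosion, so structures
    hugging the border erode like any other.  ``se`` may be an offset
    set from :func:`disk_structuring_element` or a boolean footprint.
    """
    mask = np.asarray(mask, dtype=bool)
    fp = _offsets_to_footprint(se)
    eroded = ndimage.binary_erosion(mask, structure=fp, border_value=0)
    return ndimage.binary_dilation(eroded, structure=fp, border_value=0)


def extract_candidates(cell: CellMask | np.ndarray, opened: np.ndarray) -> list[PixelRegion]:
    """Fragments stripped by the opening: components of cell AND NOT opened.

    Returned in raster order of each component's first pixel.
    """
    cell_mask = cell.mask if isinstance(cell, CellMask) else np.asarray(cell, dtype=bool)
    opened = np.asarray(opened, dtype=bool)
    if (opened & ~cell_mask).any():
        raise ValueError("opened mask must be a subset of the cell mask")
    residue = cell_mask & ~opened
    labels, n = ndimage.label(residue, structure=EIGHT_CONN)
    regions = []
    for i in range(1, n + 1):  # scipy labels components in raster order
        rows, cols = np.nonzero(labels == i)
        regions.append(PixelRegion.from_pixels(zip(rows.tolist(), cols.tolist())))
    return regions


def fit_region_ellipse(region: PixelRegion) -> EllipseFit:
    """Moment-equivalent ellipse axis lengths of a pixel region.

    Axes come from the eigenvalues of the second central moments of the
    pixel coordinates, with each pixel treated as a unit square (a 1/12
    variance term per axis), so a one-pixel-wide line has a finite minor
    axis close to 1 px.  A single pixel fits a unit circle (both axes 1).
    """
    if region.area == 1:
        return EllipseFit(major_axis_px=1.0, minor_axis_px=1.0)
    coords = np.array(sorted(region.pixels), dtype=np.float64)
    cov = np.cov(coords, rowvar=False, bias=True) + np.eye(2) / 12.0
    eigvals = np.linalg.eigvalsh(cov)
    minor, major = 4.0 * np.sqrt(eigvals)
    return EllipseFit(major_axis_px=float(major), minor_axis_px=float(minor))


def estimate_filopodium_width(candidates: list[PixelRegion],
                              params: DetectionParams,
                              pixel_size_um: float) -> float:
    """Cell-specific filopodium width ``L`` in pixels.

    Candidates whose moment ellipse is elongated (major axis at least
    ``axis_ratio_min`` times the minor axis) are treated as filaments;
    ``L`` is the mean of their minor-axis lengths.  If nothing survives
    the elongation filter, ``L`` falls back to the first-pass opening
    radius (in pixels), with a warning.
    """
    minors = [
        fit.minor_axis_px
        for fit in map(fit_region_ellipse, candidates)
        if fit.major_axis_px >= params.axis_ratio_min * fit.minor_axis_px
    ]
    if not minors:
        fallback = params.opening_radius_um / pixel_size_um
        warnings.warn(
            "no elongated candidate fragments: falling back to the first-pass "
            f"opening radius ({fallback:.2f} px) as the width estimate",
            stacklevel=2,
        )
        return float(fallback)
    return float(np.mean(minors))


def skeletonize_region(region: PixelRegion) -> frozenset:
    """Thin a region to a one-pixel-wide 8-connected curve.

    Thinning runs on the region's bounding-box crop and the skeleton is
    returned in absolute image coordinates; deterministic for a fixed
    input.
    """
    r0, c0, r1, c1 = region.bounding_box
    crop = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    for r, c in region.pixels:
        crop[r - r0, c - c0] = True
    skel = skeletonize(crop)
    if not skel.any():
        # thinning annihilates nothing topologically, but guard tiny regions
        rows, cols = np.nonzero(crop)
        skel[rows[0], cols[0]] = True
    rows, cols = np.nonzero(skel)
    return frozenset((int(r) + r0, int(c) + c0) for r, c in zip(rows, cols))


def count_skeleton_features(skeleton: frozenset) -> tuple[int, int]:
    """(n_endpoints, n_branchpoints) of a skeleton pixel set.

    An endpoint has exactly one 8-neighbour on the skeleton; a branch
    point has three or more.  An isolated pixel counts as one endpoint
    and no branch point.
    """
    pts = set(skeleton)
    n_end = n_branch = 0
    for r, c in pts:
        nn = sum(
            (r + dr, c + dc) in pts
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        )
        if nn <= 1:
            n_end += 1
        elif nn >= 3:
            n_branch += 1
    return n_end, n_branch


def classify_combined(n_endpoints: int, n_branchpoints: int) -> bool:
    """A protrusion is a combined group iff its skeleton has more than
    one branch point and at least four endpoints."""
    return n_branchpoints > 1 and n_endpoints >= 4


def measure_length(skeleton: frozenset, pixel_size_um: float) -> float:
    """Length in microns: skeleton pixel count times pixel size.

    The length of a one-pixel-wide curve equals its area, so a combined
    group's length is the total length of all its members.
    """
    if not skeleton:
        raise ValueError("skeleton must be nonempty")
    return len(skeleton) * pixel_size_um


def _make_record(region: PixelRegion, pixel_size_um: float) -> FilopodiumRecord:
    skel = skeletonize_region(region)
    n_end, n_branch = count_skeleton_features(skel)
    return FilopodiumRecord(
        region=region,
        skeleton=skel,
        length_um=measure_length(skel, pixel_size_um),
        n_endpoints=n_end,
        n_branchpoints=n_branch,
        is_combined=classify_combined(n_end, n_branch),
    )


def detect_filopodia(image: GrayImage,
                     params: DetectionParams = DetectionParams(),
                     cell: CellMask | None = None) -> DetectionResult:
    """Run the full detection pipeline on a calibrated image.

    Segmentation -> first opening at ``opening_radius_um`` -> elongation
    filter -> width estimate ``L`` -> second opening of the cell body at
    radius ``L`` px -> minimum-length filter -> combined classification.
    An empty detection is a valid result.  ``cell`` may be supplied to
    reuse an existing segmentation.
    """
    if cell is None:
        cell = segment_cell(image, method=params.threshold_method,
                            window=params.local_min_window)
    px_um = image.pixel_size_um

    se1 = disk_structuring_element(params.opening_radius_um, px_um)
    opened1 = morphological_opening(cell.mask, se1)
    first_pass = extract_candidates(cell, opened1)

    width_px = estimate_filopodium_width(first_pass, params, px_um)
    width_px = max(width_px, 1.0)

    opened2 = morphological_opening(cell.mask, disk_footprint(width_px))
    records = [
        rec
        for region in extract_candidates(cell, opened2)
        for rec in (_make_record(region, px_um),)
        if rec.length_um >= params.min_length_um
    ]
    n_combined = sum(r.is_combined for r in records)
    return DetectionResult(
        n_single=len(records) - n_combined,
        n_combined=n_combined,
        n_total=len(records),
        filopodia=tuple(records),
        params_used=params,
        threshold_level=cell.threshold_level,
    )
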