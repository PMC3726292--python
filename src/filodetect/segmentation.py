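"""Cell-body segmentation: binarize, keep the main cell, fill holes.

A thresholded confocal image typically contains the cell plus debris and
noise specks; of these only the largest 8-connected object is kept as
the cell body.  Dim interior structures (the nucleus, thin cytoplasm)
often fall below the global threshold and leave holes, which are filled
so that downstream morphology sees one solid cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .records import GrayImage
from .thresholding import level_to_native, threshold_image

__all__ = [
    "CellMask",
    "binarize",
    "select_largest_component",
    "fill_holes",
    "segment_cell",
]

# 8-connectivity for foreground objects; the complementary background
# connectivity (hole filling) is 4-connected, avoiding the topological
# paradox of both phases being 8-connected.
EIGHT_CONN = np.ones((3, 3), dtype=bool)
FOUR_CONN = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class CellMask:
    """The segmented cell body: one 8-connected, hole-free component."""

    mask: np.ndarray
    area_px: int
    pixel_size_um: float
    threshold_level: int = 0

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        n_on = int(mask.sum())
        if n_on == 0:
            raise ValueError("cell mask is empty")
        if n_on != self.area_px:
            raise ValueError("area_px must equal the number of ON pixels")
        _, n_comp = ndimage.label(mask, structure=EIGHT_CONN)
        if n_comp != 1:
            raise ValueError(f"cell mask must be one 8-connected component, found {n_comp}")
        if int(fill_holes(mask).sum()) != n_on:
            raise ValueError("cell mask must be hole-free")
        object.__setattr__(self, "mask", mask)


def binarize(image: GrayImage, level: int) -> np.ndarray:
    """Boolean foreground mask: pixel ON iff intensity strictly above ``level``.

    ``level`` is on the 256-level histogram scale; for 16-bit images it
    is mapped to native depth at the bin midpoint before comparison.
    """
    native = level_to_native(int(level), image.bit_depth)
    return image.pixels > native


def select_largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground object.

    Area ties are broken toward the component encountered first in
    raster order (labels are assigned in raster order of first pixel).
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=EIGHT_CONN)
    if n == 0:
        raise ValueError("no foreground found")
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1  # argmax keeps the lowest label on ties
    return labels == best


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Set ON every background pixel unreachable from the image border.

    Background reachability is 4-connected (the complement of the
    8-connected foreground).
    """
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool), structure=FOUR_CONN)


def segment_cell(image: GrayImage, method: str = "modified_triangle",
                 window: int = 10) -> CellMask:
    """Segment the single main cell body from ``image``.

    Pipeline: global threshold (modified triangle by default) ->
    binarize (strict ``>``) -> keep largest 8-connected object -> fill
    holes.  Deterministic: identical input bytes give identical masks.
    """
    level = threshold_image(image, method=method, window=window)
    fg = binarize(image, level)
    if not fg.any():
        raise ValueError("no foreground found at the computed threshold")
    body = fill_holes(select_largest_component(fg))
    return CellMask(
        mask=body,
        area_px=int(body.sum()),
        pixel_size_um=image.pixel_size_um,
        threshold_level=int(level),
    )
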