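"""Image and result I/O: calibrated reads, result tables, overlays.

Pixel-size calibration is supplied by the caller (flag or config); a
TIFF resolution tag that disagrees produces a warning, never an
override, since acquisition metadata is frequently stale.  Results are
written as a per-filopodium CSV plus a JSON sidecar with the per-cell
summary, and detections can be rendered on the image as an RGB overlay
(single filopodia red, combined groups yellow).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .records import DetectionResult, GrayImage

__all__ = [
    "read_image",
    "write_mask",
    "read_mask",
    "write_results",
    "read_results",
    "render_overlay",
]

# ITU-R 601 luminance weights for RGB -> gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path, pixel_size_um: float) -> GrayImage:
    """Read a single-channel TIFF/PNG as a calibrated grayscale image.

    RGB inputs are converted by luminance weighting with a warning (the
    expected inputs are single-channel fluorescence images).  16-bit
    data is kept at native depth.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if not pixel_size_um > 0:
        raise ValueError(f"pixel_size_um must be positive, got {pixel_size_um}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValueError(f"unsupported channel count: {arr.shape[2]}")
        warnings.warn(
            f"{path.name}: RGB input converted to grayscale by luminance weighting; "
            "expected a single-channel fluorescence image",
            stacklevel=2,
        )
        arr = np.rint(arr.astype(np.float64) @ _LUMA).astype(arr.dtype)
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{path.name}: empty image")
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"unsupported dtype {arr.dtype}; expected uint8 or uint16")
    _check_tiff_resolution(path, pixel_size_um)
    return GrayImage(pixels=arr, bit_depth=bit_depth, pixel_size_um=pixel_size_um)


def _check_tiff_resolution(path: Path, pixel_size_um: float) -> None:
    """Warn when embedded TIFF resolution disagrees with the stated calibration."""
    if path.suffix.lower() not in (".tif", ".tiff"):
        return
    try:
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is None or unit is None:
                return
            num, den = xres.value
            if num == 0 or den == 0:
                return
            per_unit = num / den  # pixels per unit
            unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit.value))  # inch, cm
            if unit_um is None:
                return
            meta_px_um = unit_um / per_unit
            if abs(meta_px_um - pixel_size_um) / pixel_size_um > 0.05:
                warnings.warn(
                    f"{path.name}: TIFF resolution tag implies {meta_px_um:.4g} um/px "
                    f"but calibration is {pixel_size_um:.4g} um/px; using the stated "
                    "calibration",
                    stacklevel=3,
                )
    except Exception:
        return


def write_mask(mask: np.ndarray, path) -> None:
    """Serialize a binary mask as an 8-bit PNG with values {0, 255}."""
    out = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), out)


def read_mask(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    return np.asarray(arr) > 0


def _json_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_results(result: DetectionResult, path) -> None:
    """Write a per-filopodium CSV plus a JSON sidecar with the summary.

    The CSV has one row per detected filopodium (a combined group is one
    row); the sidecar (same stem, ``.json``) carries counts, mean
    length, the threshold used, and the detection parameters.
    """
    path = Path(path)
    rows = []
    for i, rec in enumerate(result.filopodia):
        cr, cc = rec.region.centroid()
        rows.append({
            "id": i,
            "length_um": rec.length_um,
            "is_combined": rec.is_combined,
            "n_endpoints": rec.n_endpoints,
            "n_branchpoints": rec.n_branchpoints,
            "centroid_row": cr,
            "centroid_col": cc,
        })
    columns = ["id", "length_um", "is_combined", "n_endpoints",
               "n_branchpoints", "centroid_row", "centroid_col"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, float_format="%.6f")
    summary = {
        "n_single": result.n_single,
        "n_combined": result.n_combined,
        "n_total": result.n_total,
        "mean_length_um": None if result.n_total == 0 else round(result.mean_length_um, 6),
        "threshold_level": result.threshold_level,
        "params": result.params_used.to_dict(),
    }
    _json_path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def read_results(path) -> tuple[pd.DataFrame, dict]:
    """Read back a results CSV and its JSON sidecar."""
    path = Path(path)
    table = pd.read_csv(path)
    summary = json.loads(_json_path(path).read_text())
    return table, summary


def render_overlay(image: GrayImage, result: DetectionResult, path) -> None:
    """RGB PNG of the image with detections painted over it.

    Single filopodia are pure red, combined groups pure yellow; all
    other pixels show the grayscale base (16-bit scaled to 8).
    """
    px = image.pixels
    if image.bit_depth == 16:
        base = (px >> 8).astype(np.uint8)
    else:
        base = px.astype(np.uint8)
    rgb = np.stack([base] * 3, axis=-1)
    rows, cols = image.shape
    for rec in result.filopodia:
        color = (255, 255, 0) if rec.is_combined else (255, 0, 0)
        for r, c in rec.region.pixels:
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"detection pixel ({r}, {c}) outside image bounds")
            rgb[r, c] = color
    iio.imwrite(Path(path), rgb)
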