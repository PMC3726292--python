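"""Global intensity thresholding from the image histogram.

The segmentation of a fluorescently labelled cell from its dark
background hinges on one global gray-level threshold.  The method of
choice here is a modified triangle threshold: the classical triangle
construction (maximum perpendicular distance between the histogram and
the chord joining the histogram peak to the far end of its longer tail)
followed by a search for the lowest histogram count within a small
window of gray levels to the right of the triangle point.  The valley
step discards background pixels whose intensities crowd up against the
dim end of the foreground, the typical failure mode of plain triangle
or Otsu thresholding on confocal images of thin actin protrusions.

All thresholds are computed on a 256-bin histogram; 16-bit images are
rebinned by integer division and the resulting level is mapped back to
native depth at the bin midpoint.  The threshold semantics downstream
are strict: a pixel is foreground iff its intensity is *above* the
returned level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import GrayImage

__all__ = [
    "IntensityHistogram",
    "compute_histogram",
    "triangle_threshold",
    "modified_triangle_threshold",
    "baseline_threshold",
    "level_to_native",
    "BASELINE_METHODS",
]

N_BINS = 256


@dataclass(frozen=True)
class IntensityHistogram:
    """Per-gray-level pixel counts over a 256-level scale."""

    counts: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size != N_BINS:
            raise ValueError(f"counts must be a length-{N_BINS} vector")
        if (counts < 0).any():
            raise ValueError("histogram counts must be non-negative")
        total = int(counts.sum())
        if total == 0:
            raise ValueError("histogram must contain at least one pixel")
        if total != self.n_pixels:
            raise ValueError("n_pixels must equal sum(counts)")
        object.__setattr__(self, "counts", counts)

    def nonzero_support(self) -> tuple[int, int]:
        """(first, last) gray level with a nonzero count."""
        nz = np.flatnonzero(self.counts)
        return int(nz[0]), int(nz[-1])


def compute_histogram(image: GrayImage) -> IntensityHistogram:
    """256-bin intensity histogram of ``image``.

    16-bit intensities are rebinned by integer division so that each of
    the 256 bins covers 256 consecutive native levels.
    """
    px = image.pixels
    if image.bit_depth == 16:
        px = px >> 8  # value // 256 -> bin index
    counts = np.bincount(px.ravel().astype(np.int64), minlength=N_BINS)
    return IntensityHistogram(counts=counts, n_pixels=int(px.size))


def level_to_native(level: int, bit_depth: int) -> float:
    """Map a 256-scale threshold level back to native depth (bin midpoint)."""
    if bit_depth == 16:
        return level * 256 + 127.5
    return float(level)


def _histogram_peak(counts: np.ndarray) -> int:
    # ties broken toward the lower gray level
    return int(np.argmax(counts))


def triangle_threshold(hist: IntensityHistogram) -> int:
    """Triangle threshold: level of maximum perpendicular chord distance.

    A chord is drawn from the histogram peak ``b`` to the last nonzero
    level ``a`` on the longer tail (the side of the peak whose nonzero
    support spans more gray levels).  Counts are normalised by the peak
    count and levels by the chord's gray-level span so that the two axes
    are commensurable; the threshold is the level between ``b`` and
    ``a`` whose (level, count) point lies farthest from the chord, ties
    broken toward the lower level.

    Raises
    ------
    ValueError
        If the histogram has a single nonzero bin (degenerate: no chord
        can be drawn).
    """
    counts = hist.counts
    first, last = hist.nonzero_support()
    if first == last:
        raise ValueError("degenerate histogram: a single nonzero gray level")
    b = _histogram_peak(counts)
    # longer tail: greater span of nonzero support; tie -> bright side
    span_left = b - first
    span_right = last - b
    a = last if span_right >= span_left else first

    lo, hi = (b, a) if b <= a else (a, b)
    levels = np.arange(lo, hi + 1)
    span = float(hi - lo)
    cmax = float(counts.max())
    x = (levels - lo) / span
    y = counts[levels] / cmax
    # chord endpoints in normalised coordinates
    xb, yb = (b - lo) / span, counts[b] / cmax
    xa, ya = (a - lo) / span, counts[a] / cmax
    # perpendicular distance from (x, y) to the line through (xb,yb)-(xa,ya)
    dx, dy = xa - xb, ya - yb
    norm = float(np.hypot(dx, dy))
    dist = np.abs(dy * (x - xb) - dx * (y - yb)) / norm
    # lowest level whose distance ties the maximum; the absolute epsilon
    # absorbs rounding residue when the histogram lies exactly on the chord
    best = float(dist.max())
    return int(levels[int(np.argmax(dist >= best - 1e-12))])


def modified_triangle_threshold(hist: IntensityHistogram, window: int = 10) -> int:
    """Triangle threshold followed by a rightward valley search.

    Let ``t`` be the triangle threshold.  The returned level is the
    argmin of the histogram counts over the closed window
    ``[t, t + window]`` (clipped to the gray-level range), ties broken
    toward the lower level, so the result is always ``>= t``.  When the
    counts increase monotonically to the right of ``t`` the search
    degrades gracefully to ``t`` itself.
    """
    t = triangle_threshold(hist)
    hi = min(t + window, N_BINS - 1)
    window_counts = hist.counts[t : hi + 1]
    return t + int(np.argmin(window_counts))


def _class_stats(counts: np.ndarray):
    """Cumulative weights and means for every split level t (class0 <= t)."""
    levels = np.arange(N_BINS, dtype=np.float64)
    w = counts.astype(np.float64)
    cw = np.cumsum(w)
    cm = np.cumsum(w * levels)
    total_w, total_m = cw[-1], cm[-1]
    return cw, cm, total_w, total_m


def _otsu(counts: np.ndarray) -> int:
    cw, cm, total_w, total_m = _class_stats(counts)
    w0 = cw[:-1]
    w1 = total_w - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(w0 > 0, cm[:-1] / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (total_m - cm[:-1]) / np.maximum(w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    best = between.max()
    # centre of the maximal plateau: with widely separated modes the
    # between-class variance is flat across the gap and any level in it
    # splits identically, so report the middle of the plateau
    plateau = np.flatnonzero(between == best)
    return int(plateau[(len(plateau) - 1) // 2])


def _mean_level(counts: np.ndarray) -> int:
    levels = np.arange(N_BINS)
    return int(round(float((counts * levels).sum() / counts.sum())))


def _isodata(counts: np.ndarray) -> int:
    levels = np.arange(N_BINS, dtype=np.float64)
    w = counts.astype(np.float64)
    t = _mean_level(counts)
    for _ in range(N_BINS):
        lo_w = w[: t + 1].sum()
        hi_w = w[t + 1 :].sum()
        if lo_w == 0 or hi_w == 0:
            # one-sided split: nudge toward the populated side
            first, last = np.flatnonzero(w)[[0, -1]]
            t = int((first + last) // 2) if lo_w == 0 else t
            lo_w = w[: t + 1].sum()
            hi_w = w[t + 1 :].sum()
            if lo_w == 0 or hi_w == 0:
                return t
        mu0 = (w[: t + 1] * levels[: t + 1]).sum() / lo_w
        mu1 = (w[t + 1 :] * levels[t + 1 :]).sum() / hi_w
        t_new = int(round((mu0 + mu1) / 2.0))
        if t_new == t:
            return t
        t = t_new
    return t


def _max_entropy(counts: np.ndarray) -> int:
    """Kapur's threshold: maximise the summed entropies of both classes."""
    p = counts.astype(np.float64) / counts.sum()
    cp = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cplogp = np.cumsum(plogp)
    best_t, best_h = 0, -np.inf
    for t in range(N_BINS - 1):
        w0, w1 = cp[t], 1.0 - cp[t]
        if w0 <= 0 or w1 <= 0:
            continue
        h0 = np.log(w0) - cplogp[t] / w0
        h1 = np.log(w1) - (cplogp[-1] - cplogp[t]) / w1
        h = h0 + h1
        if h > best_h + 1e-12:
            best_h, best_t = h, t
    return best_t


BASELINE_METHODS = ("otsu", "mean", "isodata", "max_entropy")


def baseline_threshold(hist: IntensityHistogram, method: str) -> int:
    """Classical global thresholds used as comparison baselines.

    ``otsu`` maximises the between-class variance, ``mean`` is the
    rounded mean intensity, ``isodata`` iterates the midpoint of the two
    class means to a fixpoint, and ``max_entropy`` (Kapur) maximises the
    summed class entropies.
    """
    counts = hist.counts
    if method == "otsu":
        return _otsu(counts)
    if method == "mean":
        return _mean_level(counts)
    if method == "isodata":
        return _isodata(counts)
    if method == "max_entropy":
        return _max_entropy(counts)
    raise ValueError(
        f"unknown threshold method {method!r}; expected one of {BASELINE_METHODS}"
    )


def threshold_image(image: GrayImage, method: str = "modified_triangle",
                    window: int = 10) -> int:
    """Dispatch: compute the requested global threshold for ``image``."""
    hist = compute_histogram(image)
    if method == "modified_triangle":
        return modified_triangle_threshold(hist, window=window)
    if method == "triangle":
        return triangle_threshold(hist)
    return baseline_threshold(hist, method)
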