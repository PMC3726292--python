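"""Evaluation of automated counts and lengths against annotations.

The headline figure of merit is the mean absolute count error

    MAE = (1/N) * sum_i |M_i - F_i| / M_i   (as a percent)

i.e. the per-cell relative error between the manual count ``M_i`` and
the automated count ``F_i``, averaged over the ``N`` cells.  Count and
length series are further compared by Pearson correlation and the
ordinary-least-squares slope of automated on manual.  For synthetic
data, detections are matched to the generator's ground truth by base
position so per-filopodium length errors can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .records import DetectionResult
from .synthetic import SyntheticGroundTruth

__all__ = [
    "CountComparison",
    "mean_absolute_error",
    "compare_series",
    "MatchResult",
    "score_against_truth",
]


@dataclass(frozen=True)
class CountComparison:
    """Paired per-cell counts: manual M_i and automated F_i."""

    manual: tuple
    auto: tuple

    def __post_init__(self) -> None:
        m = tuple(float(v) for v in self.manual)
        f = tuple(float(v) for v in self.auto)
        if len(m) != len(f):
            raise ValueError("manual and automated series must have equal length")
        if len(m) == 0:
            raise ValueError("need at least one cell")
        if any(v <= 0 for v in m):
            raise ValueError("all manual counts must be positive (MAE divides by M_i)")
        object.__setattr__(self, "manual", m)
        object.__setattr__(self, "auto", f)

    @property
    def n_cells(self) -> int:
        return len(self.manual)


def mean_absolute_error(cmp: CountComparison) -> float:
    """Mean per-cell relative count error, as a percent."""
    m = np.asarray(cmp.manual)
    f = np.asarray(cmp.auto)
    return float(np.mean(np.abs(m - f) / m) * 100.0)


def compare_series(x, y) -> tuple[float, float]:
    """(Pearson r, OLS slope of y on x) for two paired series."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length series of at least 2 points")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    if np.var(y) == 0:
        # flat y: slope 0; correlation undefined, reported as 0
        return 0.0, 0.0
    fit = stats.linregress(x, y)
    return float(fit.rvalue), float(fit.slope)


@dataclass(frozen=True)
class MatchResult:
    n_matched: int
    n_missed: int
    n_spurious: int
    length_errors_um: tuple  # detected - true, one per matched pair
    matched_true_lengths_um: tuple
    matched_detected_lengths_um: tuple


def _detection_bases(result: DetectionResult, body_mask: np.ndarray):
    """Base point of each detection: its region pixel nearest the cell body."""
    dist_to_body = ndimage.distance_transform_edt(~np.asarray(body_mask, dtype=bool))
    bases = []
    for rec in result.filopodia:
        pix = sorted(rec.region.pixels)  # deterministic tie-break
        d = [dist_to_body[r, c] for r, c in pix]
        bases.append(pix[int(np.argmin(d))])
    return bases


def score_against_truth(truth: SyntheticGroundTruth,
                        result: DetectionResult,
                        match_radius_um: float,
                        pixel_size_um: float) -> MatchResult:
    """Greedy one-to-one matching of detections to ground-truth filopodia.

    Pairs within ``match_radius_um`` of base-to-base distance are
    matched greedily by ascending distance (ties by smaller length
    difference); each truth entry and each detection is used at most
    once.  Length error is detected minus true, in microns.
    """
    det_bases = _detection_bases(result, truth.body_mask)
    pairs = []
    for di, (dr, dc) in enumerate(det_bases):
        det_len = result.filopodia[di].length_um
        for ti, tf in enumerate(truth.filopodia):
            dist_um = float(np.hypot(dr - tf.base[0], dc - tf.base[1])) * pixel_size_um
            if dist_um <= match_radius_um:
                pairs.append((dist_um, abs(det_len - tf.length_um), di, ti))
    pairs.sort()
    used_d, used_t = set(), set()
    errors, true_lens, det_lens = [], [], []
    for _, _, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        det_len = result.filopodia[di].length_um
        true_len = truth.filopodia[ti].length_um
        errors.append(det_len - true_len)
        true_lens.append(true_len)
        det_lens.append(det_len)
    n_matched = len(used_d)
    return MatchResult(
        n_matched=n_matched,
        n_missed=truth.n_filopodia - n_matched,
        n_spurious=result.n_total - n_matched,
        length_errors_um=tuple(errors),
        matched_true_lengths_um=tuple(true_lens),
        matched_detected_lengths_um=tuple(det_lens),
    )
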