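"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (plain loops, breadth-first
search, closed-form statistics) and shares no code with the package
implementation it checks.
"""

from collections import deque

import numpy as np


def triangle_bruteforce(counts):
    """Exhaustive perpendicular-distance scan for the triangle threshold.

    Same geometric convention as the implementation contract: chord from
    the histogram peak to the last nonzero level of the longer-support
    tail, counts normalised by the maximum count, levels by the chord
    span, ties toward the lower level — but evaluated level by level
    with scalar arithmetic.
    """
    counts = np.asarray(counts)
    nz = np.flatnonzero(counts)
    first, last = int(nz[0]), int(nz[-1])
    b = int(np.argmax(counts))
    a = last if (last - b) >= (b - first) else first
    lo, hi = min(a, b), max(a, b)
    span = float(hi - lo)
    cmax = float(counts.max())
    xb, yb = (b - lo) / span, counts[b] / cmax
    xa, ya = (a - lo) / span, counts[a] / cmax
    dx, dy = xa - xb, ya - yb
    norm = (dx * dx + dy * dy) ** 0.5
    dists = []
    for level in range(lo, hi + 1):
        x = (level - lo) / span
        y = counts[level] / cmax
        dists.append(abs(dy * (x - xb) - dx * (y - yb)) / norm)
    best = max(dists)
    for level, dist in zip(range(lo, hi + 1), dists):
        # lowest level tying the maximum, with the same rounding epsilon
        # as the implementation contract
        if dist >= best - 1e-12:
            return level
    raise AssertionError("unreachable")


def random_histogram(rng, n_bins=256):
    """Random histogram with at least two distinct nonzero levels."""
    counts = np.zeros(n_bins, dtype=np.int64)
    k = int(rng.integers(2, 40))
    levels = rng.choice(n_bins, size=k, replace=False)
    counts[levels] = rng.integers(1, 10_000, size=k)
    return counts


def bfs_label(mask, connectivity=8):
    """Flood-fill connected-component labelling by breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                queue = deque([(r, c)])
                labels[r, c] = current
                while queue:
                    rr, cc = queue.popleft()
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < rows and 0 <= nc < cols
                                and mask[nr, nc] and labels[nr, nc] == 0):
                            labels[nr, nc] = current
                            queue.append((nr, nc))
    return labels, current


def fill_holes_bruteforce(mask):
    """Hole filling as border flood fill of the 4-connected background."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    outside = np.zeros_like(mask)
    queue = deque()
    for r in range(rows):
        for c in (0, cols - 1):
            if not mask[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    for c in range(cols):
        for r in (0, rows - 1):
            if not mask[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    while queue:
        rr, cc = queue.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = rr + dr, cc + dc
            if (0 <= nr < rows and 0 <= nc < cols
                    and not mask[nr, nc] and not outside[nr, nc]):
                outside[nr, nc] = True
                queue.append((nr, nc))
    return mask | ~outside


def pearson_slope_closed_form(x, y):
    """Textbook Pearson r and OLS slope from raw sums."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5, sxy / sxx
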