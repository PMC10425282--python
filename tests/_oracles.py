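"""Independent brute-force oracles used to validate the image operators.

These stay deliberately naive (per-pixel loops, BFS flood fill, exhaustive
overlap counting) and share no code with the implementations they check.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def bernsen_oracle(
    px: np.ndarray, radius: int, contrast_threshold: int, low_contrast_cut: int
) -> np.ndarray:
    """Per-pixel sliding-window Bernsen threshold with exact rational midgray."""
    nrows, ncols = px.shape
    out = np.zeros((nrows, ncols), dtype=bool)
    r2 = radius * radius
    for i in range(nrows):
        for j in range(ncols):
            vals = []
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    if di * di + dj * dj > r2:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nrows and 0 <= jj < ncols:
                        vals.append(int(px[ii, jj]))
            hi, lo = max(vals), min(vals)
            contrast = hi - lo
            midgray = Fraction(hi + lo, 2)
            if contrast < contrast_threshold:
                out[i, j] = midgray >= low_contrast_cut
            else:
                out[i, j] = int(px[i, j]) > midgray
    return out


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components via BFS, in raster order of their first pixel."""
    nrows, ncols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps: list[set[tuple[int, int]]] = []
    for i in range(nrows):
        for j in range(ncols):
            if not mask[i, j] or seen[i, j]:
                continue
            comp = set()
            stack = [(i, j)]
            seen[i, j] = True
            while stack:
                a, b = stack.pop()
                comp.add((a, b))
                for da in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        if da == 0 and db == 0:
                            continue
                        aa, bb = a + da, b + db
                        if 0 <= aa < nrows and 0 <= bb < ncols and mask[aa, bb] and not seen[aa, bb]:
                            seen[aa, bb] = True
                            stack.append((aa, bb))
            comps.append(comp)
    return comps


def overlap_oracle(child_labels: np.ndarray, parent_labels: np.ndarray) -> dict[int, int | None]:
    """Exhaustive pixel-overlap maximization, ties to the lowest parent label."""
    out: dict[int, int | None] = {}
    for child in sorted(int(c) for c in np.unique(child_labels) if c != 0):
        counts: dict[int, int] = {}
        for i, j in zip(*np.nonzero(child_labels == child)):
            p = int(parent_labels[i, j])
            if p != 0:
                counts[p] = counts.get(p, 0) + 1
        if not counts:
            out[child] = None
        else:
            best = max(counts.values())
            out[child] = min(p for p, c in counts.items() if c == best)
    return out
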