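"""Boundary tracing of binary regions (Moore-neighbor tracing).

Contours are ordered lists of boundary *pixel centers* of an 8-connected
region, traced clockwise (in image coordinates, row increasing downwards)
starting at the topmost-then-leftmost boundary pixel. Sub-pixel contouring is
deliberately out of scope: deviation distances downstream are reported in
whole-pixel geometry.
"""

from __future__ import annotations

import numpy as np

__all__ = ["trace_boundary", "mask_contours"]

# Clockwise Moore neighborhood: N, NE, E, SE, S, SW, W, NW.
_CW = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of the (single) region in ``mask``.

    Returns an ``(K, 2)`` array of (row, col) pixel coordinates ordered
    clockwise, starting at the topmost-then-leftmost region pixel. A
    single-pixel region yields that one pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask)
    if len(pts) == 0:
        raise ValueError("cannot trace the boundary of an empty mask")
    h, w = mask.shape

    def at(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    order = np.lexsort((pts[:, 1], pts[:, 0]))
    start = (int(pts[order[0]][0]), int(pts[order[0]][1]))

    contour = [start]
    cur = start
    # The start pixel is topmost-then-leftmost, so its west neighbor is
    # outside the region: begin the clockwise scan just after west (i.e. NW).
    scan_from = 7
    first_move = None
    max_steps = 8 * len(pts) + 8
    for _ in range(max_steps):
        found = None
        for i in range(8):
            d = (scan_from + i) % 8
            if at(cur[0] + _CW[d][0], cur[1] + _CW[d][1]):
                found = d
                break
        if found is None:  # isolated pixel
            break
        if first_move is None:
            first_move = (cur, found)
        elif (cur, found) == first_move:
            break  # re-entering the start in the initial direction: closed
        cur = (cur[0] + _CW[found][0], cur[1] + _CW[found][1])
        contour.append(cur)
        # restart the scan from the cell just after the backtrack direction
        scan_from = (found + 6) % 8
    if len(contour) > 1 and contour[-1] == start:
        contour.pop()
    return np.array(contour, dtype=np.intp)


def mask_contours(mask: np.ndarray) -> list[np.ndarray]:
    """Trace one outer contour per 8-connected component of ``mask``."""
    from scipy import ndimage

    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    return [trace_boundary(labels == k) for k in range(1, n + 1)]
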