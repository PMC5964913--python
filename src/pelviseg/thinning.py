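"""Two-subiteration thinning (parallel skeletonization).

A binary shape is reduced to a one-pixel-wide skeleton by repeatedly deleting
boundary pixels that cannot split a region. The 8-neighborhood of a pixel p1
is indexed

    p9 p2 p3
    p8 p1 p4
    p7 p6 p5

and, with n(p1) the number of non-zero neighbors and s(p1) the number of
0->1 transitions in the circular sequence p2,p3,...,p9,p2, a pixel is
deletable when

* subiteration 1:  2 <= n <= 6,  s = 1,  p2*p4*p6 = 0,  p4*p6*p8 = 0
  (east/south/north-west boundary pixels),
* subiteration 2:  2 <= n <= 6,  s = 1,  p2*p4*p8 = 0,  p2*p6*p8 = 0
  (north/west/south-east boundary pixels).

Deletions within a subiteration are applied simultaneously after the whole
image has been scanned; the two subiterations alternate until a full cycle
deletes nothing. Pixels outside the image count as background.

Known quirk of the scheme, kept deliberately: an isolated 2x2 block satisfies
the first subiteration at all four pixels and vanishes entirely. Marker
generation (``markerseg.skeleton_markers``) guards against the resulting
empty skeleton by re-seeding such components with their centroid pixel.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["NEIGHBOR_OFFSETS", "transitions", "neighbor_count", "deletable", "thin"]

#: Offsets of p2..p9 relative to p1, in circular order N, NE, E, SE, S, SW, W, NW.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)


def transitions(neighbors: Sequence[int]) -> int:
    """Number of 0->1 transitions in the circular sequence p2,p3,...,p9,p2."""
    p = [1 if v else 0 for v in neighbors]
    if len(p) != 8:
        raise ValueError("neighborhood must list the 8 values p2..p9")
    return sum((not p[i]) and p[(i + 1) % 8] for i in range(8))


def neighbor_count(neighbors: Sequence[int]) -> int:
    """n(p1): number of non-zero pixels among p2..p9."""
    return sum(1 for v in neighbors if v)


def deletable(neighbors: Sequence[int], subiteration: int, center: int = 1) -> bool:
    """Whether a foreground pixel with the given p2..p9 neighborhood may be
    deleted in the given subiteration (1 or 2)."""
    if not center:
        raise ValueError("deletability is defined for foreground pixels only")
    if subiteration not in (1, 2):
        raise ValueError("subiteration must be 1 or 2")
    p = [1 if v else 0 for v in neighbors]
    n = neighbor_count(p)
    if not (2 <= n <= 6 and transitions(p) == 1):
        return False
    p2, p3, p4, p5, p6, p7, p8, p9 = p
    if subiteration == 1:
        return p2 * p4 * p6 == 0 and p4 * p6 * p8 == 0
    return p2 * p4 * p8 == 0 and p2 * p6 * p8 == 0


def _neighbor_planes(img: np.ndarray) -> list[np.ndarray]:
    padded = np.pad(img, 1, mode="constant", constant_values=False)
    h, w = img.shape
    return [padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w] for dr, dc in NEIGHBOR_OFFSETS]


def _deletion_mask(img: np.ndarray, subiteration: int) -> np.ndarray:
    p = _neighbor_planes(img)
    n = np.sum(p, axis=0)
    s = np.zeros(img.shape, dtype=np.int8)
    for i in range(8):
        s += (~p[i]) & p[(i + 1) % 8]
    p2, _, p4, _, p6, _, p8, _ = p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7]
    cond = img & (n >= 2) & (n <= 6) & (s == 1)
    if subiteration == 1:
        return cond & ~(p2 & p4 & p6) & ~(p4 & p6 & p8)
    return cond & ~(p2 & p4 & p8) & ~(p2 & p6 & p8)


def thin(mask: np.ndarray) -> np.ndarray:
    """Thin a binary image to its skeleton; the result is a subset of the
    input foreground and is a fixed point of further thinning."""
    img = np.asarray(mask).astype(bool).copy()
    if img.ndim != 2:
        raise ValueError("thin expects a 2-D binary image")
    while True:
        changed = False
        for sub in (1, 2):
            dele = _deletion_mask(img, sub)
            if dele.any():
                img[dele] = False
                changed = True
        if not changed:
            return img
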