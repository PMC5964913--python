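"""Single-slice segmentation by the skeleton-marker watershed.

Given a reference foreground (bone) mask for a slice, segmentation proceeds:

1. Sobel gradient of the slice; the watershed surface is the L2 magnitude.
2. Markers: the thinning skeleton of the foreground mask (one label per
   8-connected skeleton component) plus the skeleton of its complement as a
   single background label.
3. Minima imposition: marker pixels are forced strictly below the global
   minimum of the surface and all other regional minima are removed by
   morphological reconstruction-by-erosion, so each marker grows exactly one
   catchment basin.
4. Priority flooding of the imposed surface from the markers.

Flooding conventions (the surface says nothing about ties, so they are fixed
here and mirrored bit-for-bit by the reference oracle used in the tests):
8-connectivity; claims are processed in increasing surface value with FIFO
order among equal values; a pixel that has been claimed by two different
labels by the time it is first popped becomes a ridge pixel (label 0); ridge
pixels still propagate the earliest claiming label so that enclosed plateaus
remain reachable; marker pixels always keep their own label.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import reconstruction

from .contour import trace_boundary
from .thinning import thin

__all__ = [
    "GradientImage",
    "MarkerImage",
    "SegmentationResult",
    "sobel_gradient",
    "skeleton_markers",
    "impose_minima",
    "watershed_transform",
    "edit_markers",
]

_S8 = np.ones((3, 3), dtype=bool)

# Sobel templates. With the neighborhood layout p9,p2,p3 / p8,p1,p4 / p7,p6,p5
# (p2 = north), Gx = p9+2*p2+p3 - (p7+2*p6+p5) differentiates along rows and
# Gy = p9+2*p8+p7 - (p3+2*p4+p5) along columns.
_SOBEL_X = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=np.float64)
_SOBEL_Y = np.array([[1, 0, -1], [2, 0, -2], [1, 0, -1]], dtype=np.float64)


@dataclass
class GradientImage:
    """Sobel gradient field: per-axis components and the L2 magnitude."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray


@dataclass
class MarkerImage:
    """Integer-labeled watershed seeds.

    Labels ``1..n_foreground`` are foreground (bone) skeleton components;
    label ``n_foreground + 1`` is the single background label; 0 = unmarked.
    """

    labels: np.ndarray
    n_foreground: int

    @property
    def background_label(self) -> int:
        return self.n_foreground + 1

    def validate(self) -> None:
        lab = self.labels
        present = np.unique(lab[lab > 0])
        if self.n_foreground < 1 or not (lab == self.background_label).any():
            raise ValueError("markers need >= 1 foreground and a background label")
        if present.max(initial=0) > self.background_label:
            raise ValueError("marker label out of range")


@dataclass
class SegmentationResult:
    """Watershed output for one slice.

    ``labels`` carries the marker label space with 0 for watershed ridge
    pixels; ``bone_mask`` is the union of the foreground-labeled regions;
    ``contours`` maps each foreground label to its clockwise boundary trace.
    """

    labels: np.ndarray
    bone_mask: np.ndarray
    n_foreground: int
    contours: dict[int, np.ndarray] = field(default_factory=dict)


def sobel_gradient(gray: np.ndarray) -> GradientImage:
    """Sobel gradient with replicate padding at the borders."""
    img = np.asarray(gray, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("sobel_gradient needs a 2-D image of at least 3x3")
    gx = ndimage.correlate(img, _SOBEL_X, mode="nearest")
    gy = ndimage.correlate(img, _SOBEL_Y, mode="nearest")
    return GradientImage(gx=gx, gy=gy, magnitude=np.hypot(gx, gy))


def skeleton_markers(foreground_mask: np.ndarray) -> MarkerImage:
    """Markers from a reference bone mask: thinned foreground components get
    labels 1..K, the thinned complement gets the single background label K+1.

    A foreground component whose skeleton vanished entirely (the isolated
    2x2 thinning quirk) is re-seeded with the component pixel closest to its
    centroid, under a fresh label.
    """
    mask = np.asarray(foreground_mask, dtype=bool)
    if not mask.any() or mask.all():
        raise ValueError("foreground mask must be non-empty and not full-frame")

    fg_skel = thin(mask)
    comp, k = ndimage.label(fg_skel, structure=_S8)
    labels = comp.astype(np.int32)

    in_comp, n_in = ndimage.label(mask, structure=_S8)
    for i in range(1, n_in + 1):
        sel = in_comp == i
        if not fg_skel[sel].any():
            pts = np.argwhere(sel)
            centroid = pts.mean(axis=0)
            nearest = pts[np.argmin(((pts - centroid) ** 2).sum(axis=1))]
            k += 1
            labels[nearest[0], nearest[1]] = k

    bg_skel = thin(~mask)
    if not bg_skel.any():  # complement collapsed (tiny images): re-seed it too
        pts = np.argwhere(~mask)
        centroid = pts.mean(axis=0)
        nearest = pts[np.argmin(((pts - centroid) ** 2).sum(axis=1))]
        bg_skel[nearest[0], nearest[1]] = True
    labels[bg_skel] = k + 1
    return MarkerImage(labels=labels, n_foreground=k)


def impose_minima(magnitude: np.ndarray, markers: MarkerImage) -> np.ndarray:
    """Force the regional minima of a surface to be exactly the markers.

    Marker pixels are set strictly below the global minimum; every other
    regional minimum is then removed by grayscale reconstruction-by-erosion
    (8-connectivity) of the modified surface.
    """
    surface = np.asarray(magnitude, dtype=np.float64)
    marked = markers.labels > 0
    if surface.shape != marked.shape:
        raise ValueError("surface and markers must share a shape")
    if not marked.any():
        raise ValueError("no marker pixels to impose")
    lo = float(surface.min()) - 1.0
    hi = float(surface.max()) + 1.0
    seed = np.where(marked, lo, hi)
    mask = np.where(marked, lo, surface)
    return reconstruction(seed, mask, method="erosion", footprint=_S8)


def watershed_transform(surface: np.ndarray, markers: MarkerImage) -> SegmentationResult:
    """Priority-flood the surface from the markers (conventions in the module
    docstring). The surface is expected to have its minima imposed already."""
    surface = np.asarray(surface, dtype=np.float64)
    h, w = surface.shape
    lab = markers.labels.astype(np.int64)
    if lab.shape != (h, w):
        raise ValueError("surface and markers must share a shape")
    if len(np.unique(lab[lab > 0])) < 2:
        raise ValueError("watershed needs at least two marker labels")

    flat_surf = surface.ravel()
    assigned = lab.ravel().copy()  # >0 label, 0 unknown, -1 ridge
    claims: dict[int, list[int]] = {}
    heap: list[tuple[float, int, int, int]] = []
    seq = 0

    def push(p: int, label: int) -> None:
        nonlocal seq
        seq += 1
        heapq.heappush(heap, (flat_surf[p], seq, p, label))
        claims.setdefault(p, []).append(label)

    marker_flat = np.flatnonzero(assigned > 0)
    for p in marker_flat:
        r, c = divmod(int(p), w)
        label = int(assigned[p])
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    q = rr * w + cc
                    if assigned[q] == 0:
                        push(q, label)

    while heap:
        _, _, p, label = heapq.heappop(heap)
        if assigned[p] != 0:
            continue
        claimed = claims[p]
        first = claimed[0]
        if any(c != first for c in claimed):
            assigned[p] = -1  # ridge between basins
        else:
            assigned[p] = label
        r, c = divmod(p, w)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    q = rr * w + cc
                    if assigned[q] == 0:
                        push(q, first)

    out = assigned.reshape(h, w)
    out = np.where(out == -1, 0, out).astype(np.int32)
    bone = (out >= 1) & (out <= markers.n_foreground)
    contours = {}
    for k in range(1, markers.n_foreground + 1):
        region = out == k
        if region.any():
            contours[k] = trace_boundary(region)
    return SegmentationResult(
        labels=out, bone_mask=bone, n_foreground=markers.n_foreground, contours=contours
    )


def edit_markers(
    markers: MarkerImage,
    add: tuple[tuple[int, int, int], ...] = (),
    remove: tuple[tuple[int, int], ...] = (),
) -> MarkerImage:
    """Apply expert point edits: removals first, then additions; the result is
    relabeled so foreground components are 1..K' and background is K'+1.

    Additions are ``(row, col, label)`` where ``label`` may be an existing
    label, a fresh one, or the current background label to extend the
    background marker. Removing a non-marker pixel, or adding on top of a
    pixel that already carries a different label, is an error.
    """
    lab = markers.labels.copy()
    bg = markers.background_label
    for r, c in remove:
        if lab[r, c] == 0:
            raise ValueError(f"({r}, {c}) is not a marker pixel")
        lab[r, c] = 0
    for r, c, label in add:
        if label <= 0:
            raise ValueError("added labels must be positive")
        if lab[r, c] not in (0, label):
            raise ValueError(f"({r}, {c}) already carries label {lab[r, c]}")
        lab[r, c] = label

    is_bg = lab == bg
    fg = (lab > 0) & ~is_bg
    comp, k = ndimage.label(fg, structure=_S8)
    new = comp.astype(np.int32)
    new[is_bg] = k + 1
    result = MarkerImage(labels=new, n_foreground=k)
    result.validate()
    return result
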