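"""End-to-end orchestration: key frames -> marking -> sequence segmentation.

The full flow mirrors clinical use: pre-process the series, extract the
target key-frame set, generate (or accept from an expert) a bone mask for
each key frame, then segment every slice by matching it to the most similar
key frame and running the skeleton-marker watershed with that key frame's
mask as the reference foreground.

Key frames themselves are re-segmented through the watershed rather than
returned as raw masks, so their contours are gradient-aligned like every
other slice's. Key-frame matching searches the whole target set by
normalized correlation; anatomical continuity makes the nearest key frame
win in practice, but the search is not restricted to neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .keyframes import (
    KeyFrameResult,
    extract_keyframes,
    interesting_image,
    ncc,
    roi_mask,
    wavelet_approximation,
)
from .markerseg import (
    MarkerImage,
    SegmentationResult,
    edit_markers,
    impose_minima,
    skeleton_markers,
    sobel_gradient,
    watershed_transform,
)
from .preprocess import SliceStack

__all__ = [
    "PipelineResult",
    "initial_keyframe_mask",
    "match_keyframe",
    "segment_slice",
    "segment_sequence",
    "run_pipeline",
]


@dataclass
class PipelineResult:
    keyframes: KeyFrameResult
    keyframe_masks: dict[int, np.ndarray]
    matches: dict[int, int]                  # slice index -> matched key frame
    results: list[SegmentationResult]        # one per slice, in stack order

    @property
    def bone_masks(self) -> np.ndarray:
        return np.stack([r.bone_mask for r in self.results])


def initial_keyframe_mask(
    img: np.ndarray, sigma: float = 1.0, wavelet: str = "haar", level: int = 1
) -> np.ndarray:
    """Automatic first-guess bone mask for a key frame.

    The binary version of the slice used for marking reuses the candidate
    stage's region-of-interest machinery: threshold the wavelet approximation
    of the smoothed slice at the mean of its non-zero pixels. This isolates
    the bright (bone-dense) area, which an expert then corrects by editing
    markers.
    """
    img = np.asarray(img, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(img, sigma, truncate=4.0)
    recon = wavelet_approximation(smoothed, wavelet=wavelet, level=level)
    return roi_mask(recon)


def match_keyframe(
    stack: SliceStack, slice_index: int, keyframe_masks: dict[int, np.ndarray]
) -> int:
    """Key frame most similar to a slice, by normalized correlation over the
    whole target set. Ties break to the anatomically nearest key frame, then
    to the smaller index. Key frames with undefined correlation (constant
    images) are skipped; all-undefined is an error."""
    if not keyframe_masks:
        raise ValueError("no key frames to match against")
    img = stack.image(slice_index)
    best: tuple[float, int, int] | None = None
    for k in sorted(keyframe_masks):
        try:
            score = ncc(img, stack.image(k))
        except ValueError:
            continue
        key = (-score, abs(k - slice_index), k)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("correlation undefined against every key frame")
    return best[2]


def segment_slice(img: np.ndarray, reference_mask: np.ndarray) -> SegmentationResult:
    """Skeleton-marker watershed of one slice against a reference bone mask."""
    markers = skeleton_markers(reference_mask)
    grad = sobel_gradient(img)
    imposed = impose_minima(grad.magnitude, markers)
    return watershed_transform(imposed, markers)


def segment_sequence(
    stack: SliceStack, keyframe_masks: dict[int, np.ndarray]
) -> tuple[list[SegmentationResult], dict[int, int]]:
    """Segment every slice of a stack, propagating key-frame masks.

    Returns the per-slice results (stack order) and the slice -> key frame
    match map. A key-frame slice is matched to itself.
    """
    if not keyframe_masks:
        raise ValueError("keyframe_masks must not be empty")
    results = []
    matches: dict[int, int] = {}
    for idx in stack.slice_indices:
        k = idx if idx in keyframe_masks else match_keyframe(stack, idx, keyframe_masks)
        matches[idx] = k
        results.append(segment_slice(stack.image(idx), keyframe_masks[k]))
    return results, matches


def run_pipeline(
    stack: SliceStack,
    marker_edits: dict[int, dict] | None = None,
    keyframe_masks: dict[int, np.ndarray] | None = None,
    sigma: float = 1.0,
    wavelet: str = "haar",
    level: int = 1,
) -> PipelineResult:
    """Whole method on a pre-processed stack.

    ``marker_edits`` optionally maps a key-frame slice index to
    ``{"add": [(r, c, label), ...], "remove": [(r, c), ...]}`` point edits
    applied to that key frame's automatic markers before flooding (the
    programmatic stand-in for interactive expert marking). Alternatively,
    ``keyframe_masks`` supplies expert bone masks for (a subset of) the key
    frames directly, bypassing the automatic first guess.
    """
    kf = extract_keyframes(stack, sigma=sigma, wavelet=wavelet, level=level)
    marker_edits = marker_edits or {}
    keyframe_masks = dict(keyframe_masks or {})

    final_masks: dict[int, np.ndarray] = {}
    for k in kf.sets.target:
        img = stack.image(k)
        if k in keyframe_masks:
            mask = np.asarray(keyframe_masks[k], dtype=bool)
        else:
            mask = initial_keyframe_mask(img, sigma=sigma, wavelet=wavelet, level=level)
        markers = skeleton_markers(mask)
        if k in marker_edits:
            edits = marker_edits[k]
            markers = edit_markers(
                markers,
                add=tuple(tuple(p) for p in edits.get("add", ())),
                remove=tuple(tuple(p) for p in edits.get("remove", ())),
            )
        grad = sobel_gradient(img)
        seg = watershed_transform(impose_minima(grad.magnitude, markers), markers)
        final_masks[k] = seg.bone_mask

    results, matches = segment_sequence(stack, final_masks)
    return PipelineResult(
        keyframes=kf, keyframe_masks=final_masks, matches=matches, results=results
    )
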