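"""Key-frame extraction from a pre-processed CT slice sequence.

A *key frame* is a slice at which the bone topology visibly changes; only key
frames are marked by an expert, and their segmentations are propagated to the
rest of the sequence. Extraction runs in two stages:

Candidate stage.  Each slice is reduced to its "interesting image": Gaussian
smoothing, a 2-D wavelet decomposition reconstructed from the approximation
band only, thresholding that reconstruction at the mean of its non-zero
pixels (T1) to get an approximate bone region, and masking the smoothed slice
with it. The pixel difference Dif_i (sum of absolute differences) between
adjacent interesting images feeds a threshold T2 = 0.7 * mean(Dif): slice
i+1 is a candidate whenever Dif_i > T2. The deliberately low factor 0.7
over-selects rather than risk missing a key frame.

Target stage.  On the *pre-processed* slices (not the interesting images),
mutual information between adjacent candidates is compared with its mean T3
(pairs with I <= T3, i.e. dissimilar pairs, keep their second frame), then
the normalized correlation coefficient between adjacent survivors is
compared with its mean T4 the same way to drop redundant frames.

Slice 1 is always retained at every stage: the selection rules only ever add
the *second* frame of a pair, and without slice 1 the head of the sequence
would have no plausible key frame to match. Thresholds are fixed from the
initial pass over each series (single sweep, no recomputation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

from .preprocess import SliceStack

__all__ = [
    "DiffSeries",
    "KeyFrameSets",
    "KeyFrameResult",
    "roi_threshold",
    "roi_mask",
    "interesting_image",
    "interesting_stack",
    "pixel_diff",
    "candidates_from_diffs",
    "candidate_set",
    "mutual_information",
    "ncc",
    "select_target",
    "extract_keyframes",
]


@dataclass
class DiffSeries:
    """Adjacent-slice pixel differences and the candidate threshold.

    ``dif[i]`` is the difference between slices ``i+1`` and ``i+2`` (1-based);
    ``t2 = 0.7 * mean(dif)``.
    """

    dif: np.ndarray
    t2: float


@dataclass
class KeyFrameSets:
    """Candidate / intermediate / target key-frame index lists (1-based) with
    the thresholds that produced them. ``target <= intermediate <= candidate``
    as sets; slice 1 is in all three."""

    candidate: list[int]
    intermediate: list[int]
    target: list[int]
    t3: float | None = None
    t4: float | None = None
    mi_values: list[float] = field(default_factory=list)   # adjacent candidates
    ncc_values: list[float] = field(default_factory=list)  # adjacent intermediates


@dataclass
class KeyFrameResult:
    diffs: DiffSeries
    sets: KeyFrameSets


def roi_threshold(reconstruction: np.ndarray) -> float:
    """T1: mean of the reconstruction over its non-zero pixels.

    With N*M pixels in total and Zeros(S) of them zero, this is
    sum(f) / (N*M - Zeros(S)). Undefined (error) for an all-zero image.
    """
    f = np.asarray(reconstruction, dtype=np.float64)
    nonzero = np.count_nonzero(f)
    if nonzero == 0:
        raise ValueError("T1 is undefined for an all-zero reconstruction")
    return float(f.sum() / nonzero)


def roi_mask(reconstruction: np.ndarray, t1: float | None = None) -> np.ndarray:
    """Binary approximate-bone mask: 1 where the reconstruction exceeds T1
    (strict inequality), 0 elsewhere."""
    f = np.asarray(reconstruction, dtype=np.float64)
    if t1 is None:
        t1 = roi_threshold(f)
    return f > t1


def wavelet_approximation(img: np.ndarray, wavelet: str = "haar", level: int = 1) -> np.ndarray:
    """Reconstruction of ``img`` from the approximation band of its 2-D
    discrete wavelet transform, with all detail bands zeroed."""
    if level < 1:
        raise ValueError("wavelet level must be >= 1")
    img = np.asarray(img, dtype=np.float64)
    coeffs = pywt.wavedec2(img, wavelet, level=level)
    coeffs = [coeffs[0]] + [
        tuple(np.zeros_like(d) for d in detail) for detail in coeffs[1:]
    ]
    recon = pywt.waverec2(coeffs, wavelet)
    return recon[: img.shape[0], : img.shape[1]]  # odd sizes reconstruct 1 larger


def interesting_image(
    img: np.ndarray, sigma: float = 1.0, wavelet: str = "haar", level: int = 1
) -> np.ndarray:
    """Reduce a slice to its approximate bone region ("interesting image").

    The slice is Gaussian-smoothed (kernel truncated at 4 sigma), the wavelet
    approximation of the smoothed slice is thresholded at T1, and the
    resulting binary mask multiplies the smoothed slice.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = np.asarray(img, dtype=np.float64)
    if not np.any(img):
        raise ValueError("interesting_image is undefined for an all-zero slice")
    smoothed = ndimage.gaussian_filter(img, sigma, truncate=4.0)
    recon = wavelet_approximation(smoothed, wavelet=wavelet, level=level)
    mask = roi_mask(recon)
    return smoothed * mask


def interesting_stack(
    stack: SliceStack, sigma: float = 1.0, wavelet: str = "haar", level: int = 1
) -> np.ndarray:
    """Interesting image of every slice, stacked (L, H, W)."""
    return np.stack(
        [interesting_image(im, sigma=sigma, wavelet=wavelet, level=level) for im in stack.images]
    )


def pixel_diff(a: np.ndarray, b: np.ndarray) -> float:
    """Pixel difference of two images: the sum of absolute differences.

    Magnitude-based and sign-free, so larger values mean lower similarity
    regardless of which slice is brighter; symmetric, and zero iff equal.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(b - a).sum())


def candidates_from_diffs(dif: np.ndarray) -> tuple[DiffSeries, list[int]]:
    """Apply the candidate rule to a difference series.

    T2 = 0.7 * mean(dif); slice ``i+2`` (1-based) is a candidate whenever
    ``dif[i] > T2`` (strict); slice 1 is always prepended.
    """
    dif = np.asarray(dif, dtype=np.float64)
    if dif.ndim != 1 or len(dif) == 0:
        raise ValueError("need a 1-D series of at least one difference")
    t2 = 0.7 * float(dif.mean())
    cands = [1] + [i + 2 for i in range(len(dif)) if dif[i] > t2]
    return DiffSeries(dif=dif, t2=t2), cands


def candidate_set(interesting: np.ndarray) -> tuple[DiffSeries, list[int]]:
    """Candidate key frames of a sequence of interesting images (L >= 2)."""
    interesting = np.asarray(interesting)
    if len(interesting) < 2:
        raise ValueError("candidate extraction needs at least two slices")
    dif = np.array(
        [pixel_diff(interesting[i], interesting[i + 1]) for i in range(len(interesting) - 1)]
    )
    return candidates_from_diffs(dif)


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (bits) of two 8-bit images via their 256x256 joint
    gray-level histogram. Symmetric and non-negative; the log base only
    rescales the mean-thresholding rule downstream, so base 2 is cosmetic."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("mutual information of empty images is undefined")
    joint, _, _ = np.histogram2d(
        a.ravel(), b.ravel(), bins=256, range=[[0, 256], [0, 256]]
    )
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    denom = np.outer(px, py)
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / denom[nz])))


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized correlation coefficient (Pearson) of two images' pixels."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da * da).sum() * (db * db).sum())
    if denom == 0:
        raise ValueError("normalized correlation is undefined for a constant image")
    return float((da * db).sum() / denom)


def _mean_filter(
    indices: list[int], values: list[float]
) -> tuple[list[int], float]:
    """Keep the first index plus every index whose pair value is <= the mean."""
    mean = float(np.mean(values))
    kept = [indices[0]] + [indices[j + 1] for j, v in enumerate(values) if v <= mean]
    return kept, mean


def select_target(stack: SliceStack, candidates: list[int]) -> KeyFrameSets:
    """Filter candidates to the target key-frame set.

    Stage 1 keeps candidate pairs whose mutual information is at most its
    mean T3; stage 2 keeps surviving pairs whose correlation is at most its
    mean T4. Both similarities are computed on the pre-processed slices.
    Fewer than two candidates pass through unchanged.
    """
    candidates = [int(i) for i in candidates]
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    if len(candidates) < 2:
        return KeyFrameSets(
            candidate=candidates, intermediate=list(candidates), target=list(candidates)
        )

    mi_vals = [
        mutual_information(stack.image(i), stack.image(j))
        for i, j in zip(candidates, candidates[1:])
    ]
    intermediate, t3 = _mean_filter(candidates, mi_vals)

    if len(intermediate) < 2:
        return KeyFrameSets(
            candidate=candidates,
            intermediate=intermediate,
            target=list(intermediate),
            t3=t3,
            mi_values=mi_vals,
        )
    ncc_vals = [
        ncc(stack.image(i), stack.image(j))
        for i, j in zip(intermediate, intermediate[1:])
    ]
    target, t4 = _mean_filter(intermediate, ncc_vals)
    return KeyFrameSets(
        candidate=candidates,
        intermediate=intermediate,
        target=target,
        t3=t3,
        t4=t4,
        mi_values=mi_vals,
        ncc_values=ncc_vals,
    )


def extract_keyframes(
    stack: SliceStack, sigma: float = 1.0, wavelet: str = "haar", level: int = 1
) -> KeyFrameResult:
    """Full two-stage key-frame extraction on a pre-processed stack."""
    roi = interesting_stack(stack, sigma=sigma, wavelet=wavelet, level=level)
    diffs, cands = candidate_set(roi)
    sets = select_target(stack, cands)
    return KeyFrameResult(diffs=diffs, sets=sets)
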