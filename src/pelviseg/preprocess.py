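"""CT pre-processing: intensity windowing, body masking and sequence cropping.

A raw CT series (Hounsfield units after the DICOM rescale transform) is turned
into the 8-bit "input image" stack that the rest of the pipeline consumes:

1. window each slice to 256 gray levels (bone window by default),
2. binarize, clean up with 3x3 closing/opening, keep the largest connected
   component as the body ("pelvis") mask,
3. zero everything outside the body mask (CT table, cables, artifacts),
4. crop every slice to one sequence-global bounding box around the body.

The crop box is global, not per-slice, because downstream inter-slice
similarity measures (pixel difference, mutual information, correlation)
require all slices to share a single shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "WindowSettings",
    "BONE_WINDOW",
    "SliceStack",
    "PreprocessResult",
    "window_transform",
    "body_mask",
    "apply_mask",
    "union_bounding_box",
    "crop_masks",
    "crop_stack",
    "preprocess_stack",
]

#: 3x3 square structuring element; 8-connectivity everywhere in this package.
_S8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class WindowSettings:
    """CT display window: width ``w`` and level (center) ``c``, both in the
    units of the raw data (Hounsfield units for calibrated CT)."""

    w: float
    c: float

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError(f"window width must be positive, got {self.w}")


#: Bone window used throughout: width 600 Hu, level 900 Hu.
BONE_WINDOW = WindowSettings(w=600.0, c=900.0)


@dataclass
class SliceStack:
    """An ordered stack of same-shaped 2-D gray slices with spacing metadata.

    ``images`` is a ``(L, H, W)`` array. ``slice_indices`` are the 1-based
    anatomical positions of the slices (defaults to ``1..L``); all public
    slice indices in this package are 1-based to match how CT sequences are
    numbered.
    """

    images: np.ndarray
    slice_indices: tuple[int, ...] | None = None
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 1.0

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 3:
            raise ValueError("images must be a (L, H, W) array")
        if self.slice_indices is None:
            self.slice_indices = tuple(range(1, len(self.images) + 1))
        else:
            self.slice_indices = tuple(int(i) for i in self.slice_indices)
            if len(self.slice_indices) != len(self.images):
                raise ValueError("one slice index per image required")
            if any(b <= a for a, b in zip(self.slice_indices, self.slice_indices[1:])):
                raise ValueError("slice_indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]

    def image(self, slice_index: int) -> np.ndarray:
        """Return the slice with 1-based anatomical index ``slice_index``."""
        try:
            pos = self.slice_indices.index(int(slice_index))
        except ValueError:
            raise KeyError(f"no slice with index {slice_index}") from None
        return self.images[pos]

    def with_images(self, images: np.ndarray) -> "SliceStack":
        return SliceStack(
            images=images,
            slice_indices=self.slice_indices,
            pixel_spacing=self.pixel_spacing,
            slice_thickness=self.slice_thickness,
        )


def window_transform(raw: np.ndarray, settings: WindowSettings = BONE_WINDOW) -> np.ndarray:
    """Compress raw CT intensities to 8 bits through a display window.

    Values at or below ``c - w/2`` map to 0, values at or above ``c + w/2``
    map to 255, and the interior maps linearly with half-up rounding::

        f(x) = [x - (c - w/2)] * 255 / w

    Parameters
    ----------
    raw:
        2-D array of raw intensities (Hounsfield units for DICOM input).
    settings:
        Window width/level; defaults to the bone window (600/900 Hu).
    """
    x = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("raw image contains non-finite values")
    lo = settings.c - settings.w / 2.0
    hi = settings.c + settings.w / 2.0
    linear = np.floor((x - lo) * 255.0 / settings.w + 0.5)
    out = np.where(x <= lo, 0.0, np.where(x >= hi, 255.0, np.clip(linear, 0.0, 255.0)))
    return out.astype(np.uint8)


def body_mask(gray: np.ndarray) -> np.ndarray:
    """Largest-component body mask of an 8-bit slice.

    Non-zero pixels are binarized, a 3x3 morphological closing then opening
    separates the body from thin cables and the table, and only the largest
    8-connected component (the body/pelvis) is kept.

    Raises ``ValueError`` on an all-zero image, or when the morphology leaves
    no foreground at all.
    """
    gray = np.asarray(gray)
    if not np.any(gray):
        raise ValueError("cannot compute a body mask of an all-zero image")
    binary = gray != 0
    binary = ndimage.binary_closing(binary, structure=_S8)
    binary = ndimage.binary_opening(binary, structure=_S8)
    labels, n = ndimage.label(binary, structure=_S8)
    if n == 0:
        raise ValueError("morphological clean-up removed all foreground")
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1  # ties: first label in scan order
    return labels == largest


def apply_mask(gray: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pixel-wise product of an image with a binary mask (off-mask -> 0)."""
    gray = np.asarray(gray)
    mask = np.asarray(mask)
    if gray.shape != mask.shape:
        raise ValueError(f"shape mismatch: {gray.shape} vs {mask.shape}")
    return gray * mask.astype(gray.dtype)


def union_bounding_box(
    masks: np.ndarray, margin: int = 2, shape: tuple[int, int] | None = None
) -> tuple[int, int, int, int]:
    """Bounding box ``(r0, r1, c0, c1)`` (half-open) of the union of per-slice
    masks, padded by ``margin`` pixels and clipped to the image frame."""
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim == 2:
        masks = masks[None]
    if not masks.any():
        raise ValueError("all masks are empty; no bounding box")
    if shape is None:
        shape = masks.shape[1:]
    union = masks.any(axis=0)
    rows = np.flatnonzero(union.any(axis=1))
    cols = np.flatnonzero(union.any(axis=0))
    r0 = max(int(rows[0]) - margin, 0)
    r1 = min(int(rows[-1]) + 1 + margin, shape[0])
    c0 = max(int(cols[0]) - margin, 0)
    c1 = min(int(cols[-1]) + 1 + margin, shape[1])
    return r0, r1, c0, c1


def crop_masks(masks: np.ndarray, box: tuple[int, int, int, int]) -> np.ndarray:
    r0, r1, c0, c1 = box
    return np.asarray(masks)[..., r0:r1, c0:c1]


def crop_stack(stack: SliceStack, masks: np.ndarray, margin: int = 2) -> SliceStack:
    """Crop every slice to the sequence-global bounding box of ``masks``.

    All slices keep one identical shape; pixel values inside the box are
    preserved bit-exactly.
    """
    masks = np.asarray(masks, dtype=bool)
    if len(masks) != len(stack):
        raise ValueError("one mask per slice required")
    box = union_bounding_box(masks, margin=margin, shape=stack.shape)
    return stack.with_images(crop_masks(stack.images, box))


@dataclass
class PreprocessResult:
    """Windowed, body-masked and cropped stack plus the artifacts of the way."""

    stack: SliceStack                 # cropped 8-bit input images
    body_masks: np.ndarray            # cropped per-slice body masks (L, H', W')
    box: tuple[int, int, int, int]    # crop box in original coordinates
    full_masks: np.ndarray = field(repr=False, default=None)  # uncropped masks


def preprocess_stack(
    raw: SliceStack,
    window: WindowSettings = BONE_WINDOW,
    margin: int = 2,
    windowed: bool = False,
) -> PreprocessResult:
    """Run the full pre-processing chain on a raw (or already 8-bit) stack.

    Set ``windowed=True`` when ``raw`` already holds 8-bit windowed slices
    (e.g. phantom output); the window transform is then skipped.
    """
    if windowed:
        imgs8 = np.asarray(raw.images, dtype=np.uint8)
    else:
        imgs8 = np.stack([window_transform(im, window) for im in raw.images])
    masks = np.stack([body_mask(im) for im in imgs8])
    masked = np.stack([apply_mask(im, m) for im, m in zip(imgs8, masks)])
    box = union_bounding_box(masks, margin=margin, shape=raw.shape)
    stack8 = raw.with_images(crop_masks(masked, box))
    return PreprocessResult(
        stack=stack8, body_masks=crop_masks(masks, box), box=box, full_masks=masks
    )
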