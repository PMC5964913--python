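"""Reading and writing stacks, key-frame sets, markers and reports.

Supported inputs: a DICOM series (one file per slice; rescale slope and
intercept honored, slices ordered by z-position with instance number as the
fallback), a directory of grayscale PNGs, or a multi-page TIFF. Outputs are
plain formats: PNG masks/labels, JSON sidecars, CSV series.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .keyframes import KeyFrameResult
from .preprocess import SliceStack

__all__ = [
    "read_dicom_series",
    "read_image_dir",
    "read_tiff_stack",
    "read_stack",
    "write_stack_png",
    "write_masks_png",
    "write_label_png",
    "keyframes_to_json",
    "keyframes_series_csv",
    "load_marker_edits",
    "write_contours_csv",
]


def read_dicom_series(directory: str | Path) -> SliceStack:
    """Read a one-file-per-slice DICOM series as a raw Hounsfield stack."""
    import pydicom

    paths = sorted(p for p in Path(directory).iterdir() if p.suffix.lower() in {".dcm", ""})
    datasets = [pydicom.dcmread(str(p)) for p in paths if p.is_file()]
    if not datasets:
        raise ValueError(f"no DICOM files found in {directory}")

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return (0, float(ipp[2]))
        return (1, int(getattr(ds, "InstanceNumber", 0)))

    datasets.sort(key=sort_key)
    images = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        images.append(arr * slope + intercept)
    first = datasets[0]
    spacing = getattr(first, "PixelSpacing", [1.0, 1.0])
    thickness = float(getattr(first, "SliceThickness", 1.0))
    return SliceStack(
        images=np.stack(images),
        pixel_spacing=(float(spacing[0]), float(spacing[1])),
        slice_thickness=thickness,
    )


def read_image_dir(directory: str | Path) -> SliceStack:
    """Read a directory of same-shaped grayscale images, sorted by filename."""
    import imageio.v3 as iio

    exts = {".png", ".tif", ".tiff", ".bmp"}
    paths = sorted(p for p in Path(directory).iterdir() if p.suffix.lower() in exts)
    if not paths:
        raise ValueError(f"no image files found in {directory}")
    images = np.stack([np.asarray(iio.imread(p)) for p in paths])
    return SliceStack(images=images)


def read_tiff_stack(path: str | Path) -> SliceStack:
    import tifffile

    return SliceStack(images=np.asarray(tifffile.imread(str(path))))


def read_stack(path: str | Path) -> SliceStack:
    """Dispatch on the input kind: DICOM dir, image dir, or multi-page TIFF."""
    path = Path(path)
    if path.is_file():
        return read_tiff_stack(path)
    if any(p.suffix.lower() == ".dcm" for p in path.iterdir()):
        return read_dicom_series(path)
    return read_image_dir(path)


def write_stack_png(stack: SliceStack, directory: str | Path, prefix: str = "slice") -> None:
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for idx, img in zip(stack.slice_indices, stack.images):
        iio.imwrite(directory / f"{prefix}_{idx:04d}.png", np.asarray(img, dtype=np.uint8))


def write_masks_png(masks: np.ndarray, directory: str | Path, prefix: str = "mask") -> None:
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, mask in enumerate(np.asarray(masks, dtype=bool), start=1):
        iio.imwrite(directory / f"{prefix}_{i:04d}.png", mask.astype(np.uint8) * 255)


def write_label_png(labels: np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.asarray(labels, dtype=np.uint16))


def keyframes_to_json(result: KeyFrameResult, path: str | Path) -> None:
    """Key-frame index lists and thresholds as a JSON document."""
    payload = {
        "candidate": result.sets.candidate,
        "intermediate": result.sets.intermediate,
        "target": result.sets.target,
        "T2": result.diffs.t2,
        "T3": result.sets.t3,
        "T4": result.sets.t4,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def keyframes_series_csv(result: KeyFrameResult, path: str | Path) -> None:
    """The Dif/MI/NCC series behind the thresholds, as tidy CSV."""
    rows = []
    for i, v in enumerate(result.diffs.dif, start=1):
        rows.append({"series": "dif", "first": i, "second": i + 1, "value": float(v)})
    sets = result.sets
    for (i, j), v in zip(zip(sets.candidate, sets.candidate[1:]), sets.mi_values):
        rows.append({"series": "mi", "first": i, "second": j, "value": float(v)})
    for (i, j), v in zip(zip(sets.intermediate, sets.intermediate[1:]), sets.ncc_values):
        rows.append({"series": "ncc", "first": i, "second": j, "value": float(v)})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_marker_edits(path: str | Path) -> dict[int, dict]:
    """Expert point edits: ``{"12": {"add": [[r, c, label]], "remove": [[r, c]]}}``."""
    raw = json.loads(Path(path).read_text())
    return {int(k): v for k, v in raw.items()}


def write_contours_csv(results, path: str | Path) -> None:
    """Per-slice, per-region contour coordinates as tidy CSV."""
    rows = []
    for slice_pos, res in enumerate(results, start=1):
        for label, contour in res.contours.items():
            for order, (r, c) in enumerate(contour):
                rows.append(
                    {"slice": slice_pos, "region": label, "order": order,
                     "row": int(r), "col": int(c)}
                )
    pd.DataFrame(rows).to_csv(path, index=False)
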