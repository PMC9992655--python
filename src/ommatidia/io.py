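"""Shared file I/O: images, TIFF stacks, CSV and JSON summaries.

All CSV output uses a fixed dialect (comma separator, '.' decimal, UTF-8,
header row) so that two runs with identical inputs produce byte-identical
files.
"""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np
import tifffile

from .errors import FormatError
from .oda2d import CalibratedImage

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Color images collapse to the channel average (luminance)."""
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise FormatError(f"expected a 2D grayscale image, got shape {arr.shape}")
    return arr.astype(float)


def read_image(path, pixel_size: float = 1.0, mask_path=None) -> CalibratedImage:
    """Read a TIFF/PNG/JPEG image (and optional mask) into a
    :class:`~ommatidia.oda2d.CalibratedImage`.

    The mask is a white silhouette on black: pixels brighter than 50% of the
    mask maximum count as foreground.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    pixels = _to_grayscale(np.asarray(arr))
    mask = None
    if mask_path is not None:
        mask_path = Path(mask_path)
        if not mask_path.exists():
            raise FormatError(f"mask file not found: {mask_path}")
        if mask_path.suffix.lower() in _TIFF_SUFFIXES:
            mask = _to_grayscale(np.asarray(tifffile.imread(mask_path)))
        else:
            from PIL import Image

            mask = _to_grayscale(np.asarray(Image.open(mask_path)))
        if mask.shape != pixels.shape:
            raise FormatError(
                f"mask shape {mask.shape} does not match image {pixels.shape}"
            )
    return CalibratedImage(pixels=pixels, pixel_size=pixel_size, mask=mask)


def write_image(path, image: np.ndarray) -> None:
    """Write a 2D array as TIFF (lossless for 8/16-bit grayscale)."""
    tifffile.imwrite(Path(path), np.asarray(image))


def read_stack(directory, pattern: str = "*.tif*") -> np.ndarray:
    """Read a directory of same-shape TIFF slices into a (slice, row, col)
    array. Slices are ordered by filename."""
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise FormatError(f"no slices matching {pattern!r} in {directory}")
    slices = []
    shape = None
    for p in paths:
        arr = np.asarray(tifffile.imread(p))
        if arr.ndim != 2:
            raise FormatError(f"slice {p.name} is not 2D (shape {arr.shape})")
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise FormatError(
                f"slice {p.name} has shape {arr.shape}, expected {shape}"
            )
        slices.append(arr)
    return np.stack(slices)


def write_stack(directory, stack: np.ndarray, prefix: str = "slice") -> list:
    """Write a 3D array as numbered TIFF slices; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(stack))))
    paths = []
    for i, sl in enumerate(stack):
        p = directory / f"{prefix}_{i:0{width}d}.tif"
        tifffile.imwrite(p, sl)
        paths.append(p)
    return paths


def to_uint8(image: np.ndarray) -> np.ndarray:
    """Rescale any finite image to the full 8-bit range."""
    img = np.asarray(image, float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round(255 * (img - lo) / (hi - lo)).astype(np.uint8)


def write_csv(df, path) -> None:
    """Write a DataFrame with the fixed CSV dialect."""
    df.to_csv(Path(path), index=False, encoding="utf-8", lineterminator="\n")


# Minimal schema for the run summary: required keys and their types.
SUMMARY_SCHEMA = {
    "count": int,
    "diameter_mean_um": float,
    "diameter_sd_um": float,
    "skewness_median_deg": float,
    "skewness_iqr_deg": float,
    "io_angle_median_deg": float,
    "io_angle_iqr_deg": float,
    "fov_horizontal_deg": float,
    "fov_vertical_deg": float,
}


def validate_summary(summary: dict) -> None:
    """Check a summary dict against :data:`SUMMARY_SCHEMA`."""
    for key, typ in SUMMARY_SCHEMA.items():
        if key not in summary:
            raise FormatError(f"summary missing required key {key!r}")
        value = summary[key]
        if typ is float and not isinstance(value, (int, float)):
            raise FormatError(f"summary key {key!r} must be numeric")
        if typ is int and not isinstance(value, (int, np.integer)):
            raise FormatError(f"summary key {key!r} must be an integer")


def write_summary_json(summary: dict, path) -> None:
    """Validate and write the run summary as JSON."""
    validate_summary(summary)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(summary, indent=2, default=_default) + "\n")
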