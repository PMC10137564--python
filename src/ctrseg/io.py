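"""Image, mask, and manifest I/O plus contour-overlay rendering.

Conventions
-----------
Rasters are 2-D ``numpy`` arrays in row-major order with the origin at the
top-left corner; ``x`` is the column index and increases rightward.  All
transverse (CTR) spans are measured along columns.

Label masks are ``uint8`` arrays restricted to the class codes
``{0 = background, 1 = lung, 2 = heart}``.  Masks are stored as indexed
(palette) PNG and never as JPEG: lossy compression corrupts labels.
Images are stored as 8-bit grayscale PNG and read back scaled to [0, 1];
16-bit grayscale and RGB inputs (converted by luminance) are accepted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError, MaskValidationError

BACKGROUND = 0
LUNG = 1
HEART = 2
CLASS_NAMES = {BACKGROUND: "background", LUNG: "lung", HEART: "heart"}
N_CLASSES = 3

# display palette for indexed mask PNGs (class code -> RGB)
_MASK_PALETTE = [0, 0, 0, 80, 160, 255, 220, 60, 60]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class SampleRecord:
    """One manifest row: an image, its optional reference mask and CTR."""

    image_path: Path
    mask_path: Path | None = None
    reference_ctr: float | None = None
    split_tag: str = "test"

    def __post_init__(self):
        if self.reference_ctr is not None and not (0.0 < self.reference_ctr < 1.0):
            raise FormatError(
                f"reference_ctr must lie in (0, 1), got {self.reference_ctr}"
            )
        if self.split_tag not in ("train", "val", "test"):
            raise FormatError(f"unknown split_tag {self.split_tag!r}")


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check a label mask's dtype/shape/values; return it as uint8."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise MaskValidationError(f"mask must be 2-D, got shape {mask.shape}")
    bad = np.setdiff1d(np.unique(mask), [BACKGROUND, LUNG, HEART])
    if bad.size:
        raise MaskValidationError(
            f"mask contains invalid class value(s) {bad.tolist()}; allowed: 0, 1, 2"
        )
    return mask.astype(np.uint8, copy=False)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG image as a single-channel float raster in [0, 1].

    8-bit values are divided by 255, 16-bit by 65535, RGB is converted to
    luminance before scaling.
    """
    path = Path(path)
    if path.suffix.lower() not in _IMAGE_SUFFIXES:
        raise FormatError(f"unsupported image format: {path.name}")
    try:
        with Image.open(path) as im:
            if im.mode in ("I;16", "I;16B", "I"):
                arr = np.asarray(im, dtype=np.float64) / 65535.0
            elif im.mode in ("RGB", "RGBA", "P"):
                arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
            elif im.mode == "L":
                arr = np.asarray(im, dtype=np.float64) / 255.0
            else:
                raise FormatError(f"unsupported image mode {im.mode!r} in {path.name}")
    except (OSError, SyntaxError) as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    return np.clip(arr, 0.0, 1.0)


def write_image(image: np.ndarray, path: str | os.PathLike) -> Path:
    """Write a [0, 1] float raster as an 8-bit grayscale PNG."""
    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="L").save(path)
    return path


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a label mask from an indexed or grayscale PNG.

    JPEG is rejected outright (lossy), and any pixel value outside
    {0, 1, 2} raises :class:`MaskValidationError`.
    """
    path = Path(path)
    if path.suffix.lower() in (".jpg", ".jpeg"):
        raise FormatError(
            f"refusing to read mask from lossy JPEG: {path.name}; masks must be PNG"
        )
    if path.suffix.lower() != ".png":
        raise FormatError(f"unsupported mask format: {path.name}")
    try:
        with Image.open(path) as im:
            if im.format == "JPEG":
                raise FormatError(f"refusing lossy JPEG content as mask: {path.name}")
            arr = np.asarray(im if im.mode in ("P", "L") else im.convert("L"))
    except (OSError, SyntaxError) as exc:
        raise FormatError(f"cannot read mask {path}: {exc}") from exc
    return validate_mask(arr)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> Path:
    """Write a label mask as an indexed PNG (lossless round trip)."""
    path = Path(path)
    mask = validate_mask(mask)
    im = Image.fromarray(mask, mode="P")
    im.putpalette(_MASK_PALETTE + [0] * (768 - len(_MASK_PALETTE)))
    im.save(path)
    return path


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a CSV manifest (image_path, mask_path, true_ctr, seed)."""
    df = pd.read_csv(path)
    if "image_path" not in df.columns:
        raise FormatError(f"manifest {path} lacks an image_path column")
    return df


def write_manifest(df: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def _boundary(binary: np.ndarray) -> np.ndarray:
    """4-connected inner boundary of a binary region."""
    from scipy import ndimage

    eroded = ndimage.binary_erosion(
        binary, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
        border_value=0,
    )
    return binary & ~eroded


def render_overlay(
    image: np.ndarray,
    predicted: np.ndarray | None,
    reference: np.ndarray | None,
    out: str | os.PathLike,
) -> Path:
    """Render contour outlines over a grayscale image and save as PNG.

    The predicted mask's heart+lung contours are drawn in blue; the
    reference heart contour in red and the reference lung contour in
    orange.  Either mask may be omitted.
    """
    image = np.asarray(image, dtype=np.float64)
    rgb = np.stack([np.clip(image, 0, 1) * 255] * 3, axis=-1).astype(np.uint8)
    for mask, spec in (
        (reference, ((LUNG, (255, 165, 0)), (HEART, (220, 40, 40)))),
        (predicted, ((LUNG, (60, 120, 255)), (HEART, (60, 120, 255)))),
    ):
        if mask is None:
            continue
        mask = validate_mask(mask)
        if mask.shape != image.shape:
            raise MaskValidationError(
                f"mask shape {mask.shape} does not match image shape {image.shape}"
            )
        for cls, color in spec:
            edge = _boundary(mask == cls)
            rgb[edge] = color
    out = Path(out)
    Image.fromarray(rgb, mode="RGB").save(out)
    return out
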