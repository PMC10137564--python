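"""Cardiothoracic-ratio geometry from label masks.

The CTR is the ratio of the maximum transverse cardiac dimension to the
maximum transverse internal thoracic dimension.  Both spans are measured
as global column extents of the corresponding mask classes: the cardiac
span over all heart-class pixels, the thoracic span over all lung-class
pixels (left edge of the left lung field to the right edge of the right
lung field).  Widths are inclusive pixel counts (right − left + 1); the
+1 convention cancels to O(1/width) in the ratio.

Connected-component cleanup guards against stray mis-segmented blobs
before the spans are taken; cardiomegaly is called at CTR strictly
greater than 50%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import io
from .errors import MissingStructureError

# 4-connectivity for component labelling
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class CTRResult:
    cardiac_width_px: int
    thoracic_width_px: int
    ctr: float
    heart_cols: tuple[int, int]
    thorax_cols: tuple[int, int]
    cleanup_applied: bool


def _keep_largest(binary: np.ndarray, k: int) -> np.ndarray:
    """Keep the k largest 4-connected components of a binary mask."""
    labels, n = ndimage.label(binary, structure=_STRUCT4)
    if n <= k:
        return binary
    areas = np.bincount(labels.ravel())[1:]  # skip background label 0
    keep = np.argsort(areas)[::-1][:k] + 1
    return np.isin(labels, keep)


def clean_mask(mask: np.ndarray) -> np.ndarray:
    """Keep the 2 largest lung components and the largest heart component.

    All other foreground pixels become background.  A single surviving lung
    component is kept alone.  Raises :class:`MissingStructureError` if a
    class is empty afterwards (i.e. was empty before, since the largest
    components are preserved).
    """
    mask = io.validate_mask(mask)
    lungs = _keep_largest(mask == io.LUNG, 2)
    heart = _keep_largest(mask == io.HEART, 1)
    if not heart.any():
        raise MissingStructureError("heart")
    if not lungs.any():
        raise MissingStructureError("lung")
    out = np.zeros_like(mask)
    out[lungs] = io.LUNG
    out[heart] = io.HEART
    return out


def horizontal_extent(mask: np.ndarray, class_set) -> tuple[int, int, int]:
    """(leftmost column, rightmost column, inclusive width) of a class set."""
    mask = np.asarray(mask)
    if np.isscalar(class_set) or isinstance(class_set, (int, np.integer)):
        class_set = {int(class_set)}
    member = np.isin(mask, list(class_set))
    cols = np.flatnonzero(member.any(axis=0))
    if cols.size == 0:
        names = "/".join(io.CLASS_NAMES.get(c, str(c)) for c in sorted(class_set))
        raise MissingStructureError(names)
    left, right = int(cols[0]), int(cols[-1])
    return left, right, right - left + 1


def compute_ctr(mask: np.ndarray, do_cleanup: bool = True) -> CTRResult:
    """Measure the CTR from a label mask.

    Raises :class:`MissingStructureError` when heart or lung pixels are
    absent — the signal that the image needs human review instead of an
    automated number.
    """
    mask = io.validate_mask(mask)
    if do_cleanup:
        mask = clean_mask(mask)
    h_left, h_right, cardiac = horizontal_extent(mask, {io.HEART})
    t_left, t_right, thoracic = horizontal_extent(mask, {io.LUNG})
    return CTRResult(
        cardiac_width_px=cardiac,
        thoracic_width_px=thoracic,
        ctr=cardiac / thoracic,
        heart_cols=(h_left, h_right),
        thorax_cols=(t_left, t_right),
        cleanup_applied=bool(do_cleanup),
    )


def classify_cardiomegaly(ctr: float, threshold: float = 0.50) -> bool:
    """Cardiomegaly call: strictly CTR > threshold; ties are negative."""
    if ctr <= 0:
        raise ValueError(f"ctr must be positive, got {ctr}")
    return bool(ctr > threshold)
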