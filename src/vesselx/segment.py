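"""Mean-C adaptive thresholding and morphological cleanup.

A local mean image (box filter of side W) estimates the slowly varying
background; a pixel is marked as vessel when it exceeds its local mean by
more than the constant C.  Because the decision is relative to the local
neighborhood, the rule is robust to the uneven illumination typical of
fundus photographs.  C = 0.039 on the [0, 1] intensity scale is the fixed
empirical constant of the method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError
from .preprocess import BinaryMask, _disk_footprint

__all__ = ["ThresholdParams", "mean_c_threshold", "cleanup"]


@dataclass
class ThresholdParams:
    """Mean-C thresholding and cleanup parameters.

    window
        Odd box-filter side length W in pixels.  Default 13, appropriate
        for ~565-px-wide images; scale proportionally for other widths.
    c
        Threshold constant on the [0, 1] scale.  Default 0.039.
    opening_radius
        Disk radius of the morphological opening that removes small
        speckle after thresholding.  0 disables the opening.
    min_object_px
        Connected components (8-connectivity) smaller than this are
        dropped.  0 disables the size filter.
    """

    window: int = 13
    c: float = 0.039
    opening_radius: int = 1
    min_object_px: int = 30

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if not (0.0 <= self.c < 1.0):
            raise ValueError("c must lie in [0, 1)")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be >= 0")


def mean_c_threshold(
    img: np.ndarray,
    p: Optional[ThresholdParams] = None,
    fov: Optional[BinaryMask] = None,
) -> BinaryMask:
    """Binarize: vessel where img − local_mean > C (strict; ties are
    background).  Pixels outside the FOV are forced to background.
    """
    if p is None:
        p = ThresholdParams()
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("mean_c_threshold expects a 2D image")
    if p.window >= min(img.shape):
        raise DegenerateInputError(
            f"window {p.window} >= smallest image dimension {min(img.shape)}"
        )
    mean = ndimage.uniform_filter(img, size=p.window, mode="reflect")
    diff = img - mean
    mask = diff > p.c
    if fov is not None:
        mask &= fov.astype_bool()
    return BinaryMask(mask.astype(np.uint8))


def cleanup(mask: BinaryMask, p: Optional[ThresholdParams] = None) -> BinaryMask:
    """Morphological opening (disk) then small-object removal.

    Anti-extensive (output ⊆ input) and idempotent at fixed parameters.
    """
    if p is None:
        p = ThresholdParams()
    out = mask.astype_bool()
    if p.opening_radius > 0:
        out = ndimage.binary_opening(
            out, structure=_disk_footprint(p.opening_radius)
        )
    if p.min_object_px > 0:
        labels, nlab = ndimage.label(out, structure=np.ones((3, 3), dtype=int))
        if nlab:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            out = sizes[labels] >= p.min_object_px
    return BinaryMask(out.astype(np.uint8))
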