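"""Fundus image loading and preprocessing.

Fundus photographs show dark vessels on a brighter retinal field inside a
roughly circular camera aperture (the field of view, FOV).  Everything
downstream operates on the green channel, which carries the best
vessel/background contrast, as a float image on [0, 1].  The bright rim of
the aperture is a step edge that would otherwise dominate any second-order
derivative filter, so it is flattened before vesselness filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import ConsistencyError, DegenerateInputError, InputFormatError

__all__ = [
    "FundusImage",
    "BinaryMask",
    "load_image",
    "load_mask",
    "save_mask",
    "extract_green",
    "compute_fov_mask",
    "suppress_border",
]


@dataclass
class BinaryMask:
    """A 0/1 pixel mask, row-major, origin top-left."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ConsistencyError(f"mask must be 2D, got shape {px.shape}")
        uniq = np.unique(px)
        if not np.isin(uniq, [0, 1]).all():
            raise ConsistencyError("mask values must be exactly 0 or 1")
        self.pixels = px.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def astype_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)


@dataclass
class FundusImage:
    """An intensity image on [0, 1], 2D or 3-channel, with optional FOV."""

    pixels: np.ndarray
    fov: Optional[BinaryMask] = field(default=None)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim not in (2, 3):
            raise InputFormatError(f"image must be 2D or 3D, got shape {px.shape}")
        if px.ndim == 3 and px.shape[2] not in (1, 3):
            raise InputFormatError(
                f"3D image must have 1 or 3 channels, got {px.shape[2]}"
            )
        if not np.isfinite(px).all():
            raise InputFormatError("image contains non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise InputFormatError("image intensities must lie in [0, 1]")
        self.pixels = px
        if self.fov is not None and self.fov.shape != px.shape[:2]:
            raise ConsistencyError(
                f"fov shape {self.fov.shape} != image shape {px.shape[:2]}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_multichannel(self) -> bool:
        return self.pixels.ndim == 3


def _rescale_to_unit(arr: np.ndarray, path: str) -> np.ndarray:
    """Rescale a raster to float64 on [0, 1] by its dtype maximum."""
    if arr.dtype == bool:
        return arr.astype(np.float64)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        if info.min < 0:
            raise InputFormatError(f"signed integer raster not supported: {path}")
        return arr.astype(np.float64) / float(info.max)
    if np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(np.float64)
        if not np.isfinite(out).all():
            raise InputFormatError(f"non-finite pixels in {path}")
        if out.min() < 0.0 or out.max() > 1.0:
            # float rasters are expected pre-normalized
            raise InputFormatError(f"float raster outside [0, 1]: {path}")
        return out
    raise InputFormatError(f"unsupported pixel dtype {arr.dtype} in {path}")


def load_image(path) -> FundusImage:
    """Load a PNG/TIFF/PPM/JPEG/GIF raster as a FundusImage on [0, 1].

    Integer rasters are divided by their type maximum (255 for 8-bit,
    65535 for 16-bit).  An alpha channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise InputFormatError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 2:  # gray + alpha
        arr = arr[:, :, 0]
    return FundusImage(_rescale_to_unit(arr, str(path)))


def load_mask(path) -> BinaryMask:
    """Load a raster as a binary mask: any pixel > 0 becomes 1.

    Palette GIF masks (as shipped with the public fundus databases) and
    plain 0/255 PNGs both binarize correctly under this rule.
    """
    img = load_image(path)
    px = img.pixels
    if px.ndim == 3:
        px = px.max(axis=2)
    return BinaryMask((px > 0).astype(np.uint8))


def save_mask(mask: BinaryMask, path) -> None:
    """Write a mask as an 8-bit PNG with values {0, 255}."""
    iio.imwrite(Path(path), (mask.pixels * 255).astype(np.uint8))


def extract_green(img: FundusImage) -> FundusImage:
    """Return the green channel as a 2D image; 2D input passes through.

    The FOV mask, if present, is carried over.  Idempotent.
    """
    if not img.is_multichannel:
        return img
    nchan = img.pixels.shape[2]
    if nchan == 1:
        return FundusImage(img.pixels[:, :, 0], fov=img.fov)
    if nchan != 3:
        raise InputFormatError(f"expected 1 or 3 channels, got {nchan}")
    return FundusImage(img.pixels[:, :, 1], fov=img.fov)


def compute_fov_mask(img: FundusImage, luminance_threshold: float = 0.1) -> BinaryMask:
    """Estimate the circular field-of-view mask of a fundus photograph.

    Pixels brighter than ``luminance_threshold`` are kept; the largest
    connected component is retained and its holes filled.  Fundus apertures
    are near-black outside the field, so a low threshold on the (green)
    intensity isolates the disk reliably.
    """
    if img.is_multichannel:
        raise InputFormatError("compute_fov_mask expects a 2D image")
    if not (0.0 < luminance_threshold < 1.0):
        raise ValueError("luminance_threshold must lie in (0, 1)")
    raw = img.pixels > luminance_threshold
    if not raw.any():
        raise DegenerateInputError("empty FOV: no pixel above threshold")
    labels, nlab = ndimage.label(raw)
    if nlab > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        raw = labels == sizes.argmax()
    filled = ndimage.binary_fill_holes(raw)
    return BinaryMask(filled.astype(np.uint8))


def suppress_border(
    img: FundusImage,
    fov: BinaryMask,
    erosion_radius: int = 5,
    fill: str = "nearest",
) -> FundusImage:
    """Flatten everything at and outside the aperture rim.

    The FOV is eroded by ``erosion_radius`` pixels and every pixel outside
    the eroded FOV is replaced: with ``fill="nearest"`` (default) by the
    value of the nearest pixel inside the eroded FOV, which continues the
    image smoothly across the rim; with ``fill="mean"`` by the mean
    intensity inside the original FOV (a flat fill, which leaves a small
    residual step wherever the local intensity differs from the global
    mean).  Either way the aperture step edge carries no second-derivative
    signal, so Hessian-based filters see no rim.  Pixels strictly inside
    the eroded FOV are never altered.
    """
    if img.is_multichannel:
        raise InputFormatError("suppress_border expects a 2D image")
    if erosion_radius < 0:
        raise ValueError("erosion_radius must be >= 0")
    if fill not in ("nearest", "mean"):
        raise ValueError(f"unknown fill mode {fill!r}")
    if fov.shape != img.pixels.shape:
        raise ConsistencyError("fov dimensions do not match image")
    inside = fov.astype_bool()
    if erosion_radius > 0:
        selem = _disk_footprint(erosion_radius)
        eroded = ndimage.binary_erosion(inside, structure=selem)
    else:
        eroded = inside
    if not eroded.any():
        raise DegenerateInputError("erosion removed the entire field of view")
    if fill == "nearest":
        idx = ndimage.distance_transform_edt(
            ~eroded, return_distances=False, return_indices=True
        )
        out = np.where(eroded, img.pixels, img.pixels[tuple(idx)])
    else:
        fill_val = float(img.pixels[inside].mean())
        out = np.where(eroded, img.pixels, fill_val)
    return FundusImage(out, fov=img.fov)


def _disk_footprint(radius: int) -> np.ndarray:
    """Boolean disk footprint of the given integer radius."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy * yy + xx * xx) <= radius * radius
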