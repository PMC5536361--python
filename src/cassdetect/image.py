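"""Intensity rasters and grayscale image I/O.

Images are handled internally as 2-D float64 arrays in arbitrary intensity
units; files read from disk are rescaled to the [0, 255] range regardless of
bit depth.  Arrays are row-major with ``(x, y) = (column, row)`` and *y*
increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import InvalidInputError

__all__ = ["ImageField", "as_pixels", "load_image", "save_image"]


@dataclass(frozen=True)
class ImageField:
    """A 2-D floating-point intensity raster.

    Attributes
    ----------
    pixels : ndarray
        2-D float array of intensities, finite everywhere.
    """

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise InvalidInputError(f"expected a 2-D raster, got ndim={px.ndim}")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise InvalidInputError(
                f"image must be at least 3x3 for filtering, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise InvalidInputError("image contains non-finite pixels")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_pixels(image) -> np.ndarray:
    """Coerce an :class:`ImageField` or array-like to a validated float array."""
    if isinstance(image, ImageField):
        return image.pixels
    return ImageField(np.asarray(image)).pixels


def load_image(path) -> ImageField:
    """Read a grayscale PNG/PGM/TIFF image, rescaling intensities to [0, 255].

    Multi-channel files are converted to luminance by averaging channels.
    8-bit data is used as-is; 16-bit data is divided by 257 so that full
    scale maps to 255; float data is used unscaled.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise InvalidInputError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise InvalidInputError(f"unsupported image layout {arr.shape} in {path}")
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 257.0
    else:
        arr = arr.astype(np.float64)
    return ImageField(arr)


def save_image(path, pixels: np.ndarray) -> None:
    """Write a float or boolean raster as an 8-bit grayscale image.

    Boolean maps are written as {0, 255}; float maps are clipped to [0, 255].
    """
    path = Path(path)
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        out = arr.astype(np.uint8) * 255
    else:
        out = np.clip(arr, 0, 255).astype(np.uint8)
    iio.imwrite(path, out)
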