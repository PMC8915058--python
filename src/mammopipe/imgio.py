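"""Raster I/O and intensity normalization.

All pipeline stages operate on single-plane float arrays ("Image2D") kept
on the 0-255 scale; quantization to integers happens only when an image is
written to disk.  RGB inputs are split into three aligned planes; grayscale
inputs are replicated into three identical planes so the color-handling
stages run unchanged.
"""

from __future__ import annotations

import os
from typing import NamedTuple

import imageio.v3 as iio
import numpy as np

__all__ = ["ImageRGB", "read_image", "write_image", "rescale_to_8bit"]


class ImageRGB(NamedTuple):
    """Three aligned intensity planes on the 0-255 scale."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    def validate(self) -> "ImageRGB":
        shapes = {self.red.shape, self.green.shape, self.blue.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for plane in self:
            validate_image(plane)
        return self


def validate_image(img: np.ndarray) -> np.ndarray:
    """Check a single-plane image: 2-D, non-empty, finite."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"zero-sized raster: shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def read_image(path: str | os.PathLike) -> ImageRGB:
    """Read a raster image and split it into three planes on the 0-255 scale.

    Grayscale inputs are replicated into three identical planes; 16-bit
    inputs are linearly rescaled by 255/65535.  Alpha channels are dropped.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - plugin errors vary by format
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-sized raster in {path!r}")
    arr = np.asarray(arr)
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) * (255.0 / 65535.0)
    elif arr.dtype == bool:
        arr = arr.astype(np.float64) * 255.0
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 2:
        plane = validate_image(arr)
        return ImageRGB(plane.copy(), plane.copy(), plane.copy())
    if arr.ndim == 3 and arr.shape[2] >= 3:
        return ImageRGB(arr[:, :, 0].copy(), arr[:, :, 1].copy(), arr[:, :, 2].copy()).validate()
    raise ValueError(f"unsupported raster layout {arr.shape} in {path!r}")


def write_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write an 8-bit single-channel raster (values rounded half-to-even)."""
    img = validate_image(img)
    if img.min() < 0 or img.max() > 255:
        raise ValueError(
            f"values outside [0, 255] (min={img.min()}, max={img.max()}); rescale first"
        )
    iio.imwrite(path, np.rint(img).astype(np.uint8))


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean mask as an 8-bit {0, 255} raster."""
    write_image(np.asarray(mask, dtype=bool).astype(np.float64) * 255.0, path)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a {0, 255} mask raster back to boolean (threshold at 128)."""
    return read_image(path).red >= 128


def rescale_to_8bit(img: np.ndarray) -> np.ndarray:
    """Affinely map (min, max) -> (0, 255); a constant image maps to zeros."""
    img = validate_image(img).astype(np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    # clip guards the <= 255 invariant against float round-off
    return np.clip((img - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
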