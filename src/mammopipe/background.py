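"""Background uniformity via morphological bottom-hat / top-hat transforms.

bottom_hat(f) = closing(f) - f extracts dark structures smaller than the
structuring element; top_hat(f) = f - opening(f) extracts bright ones.
``uniformize`` recombines them as the classic contrast-enhancement composite
f + top_hat - bottom_hat, then rescales to [0, 255].  Borders are handled by
edge replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imgio import ImageRGB, rescale_to_8bit, validate_image

__all__ = [
    "StructuringElement",
    "bottom_hat",
    "top_hat",
    "uniformize",
    "uniformize_rgb",
    "default_structuring_element",
]


@dataclass(frozen=True)
class StructuringElement:
    """Flat structuring element: odd-sized boolean footprint, true anchor."""

    footprint: np.ndarray

    def __post_init__(self) -> None:
        fp = np.asarray(self.footprint, dtype=bool)
        object.__setattr__(self, "footprint", fp)
        if fp.ndim != 2:
            raise ValueError("footprint must be 2-D")
        if fp.shape[0] % 2 == 0 or fp.shape[1] % 2 == 0:
            raise ValueError(f"footprint dimensions must be odd, got {fp.shape}")
        if not fp.any():
            raise ValueError("footprint must contain at least one true pixel")
        if not fp[fp.shape[0] // 2, fp.shape[1] // 2]:
            raise ValueError("footprint anchor (center pixel) must be true")

    @classmethod
    def disk(cls, radius: int) -> "StructuringElement":
        if radius < 1:
            raise ValueError("radius must be >= 1")
        yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        return cls(yy**2 + xx**2 <= radius**2)

    @classmethod
    def square(cls, size: int) -> "StructuringElement":
        if size < 1 or size % 2 == 0:
            raise ValueError("size must be a positive odd integer")
        return cls(np.ones((size, size), dtype=bool))


def default_structuring_element(shape: tuple[int, int], kind: str = "disk") -> StructuringElement:
    """Disk of radius 15 px for 1024-px images, scaled with the short side."""
    radius = max(1, round(15 * min(shape) / 1024))
    if kind == "disk":
        return StructuringElement.disk(radius)
    if kind == "square":
        return StructuringElement.square(2 * radius + 1)
    raise ValueError(f"unknown structuring element kind {kind!r}")


def _closing(f: np.ndarray, b: StructuringElement) -> np.ndarray:
    return ndimage.grey_closing(f, footprint=b.footprint, mode="nearest")


def _opening(f: np.ndarray, b: StructuringElement) -> np.ndarray:
    return ndimage.grey_opening(f, footprint=b.footprint, mode="nearest")


def bottom_hat(f: np.ndarray, b: StructuringElement) -> np.ndarray:
    """closing(f, b) - f; non-negative by extensivity of closing."""
    f = validate_image(f).astype(np.float64)
    return _closing(f, b) - f


def top_hat(f: np.ndarray, b: StructuringElement) -> np.ndarray:
    """f - opening(f, b); non-negative by anti-extensivity of opening."""
    f = validate_image(f).astype(np.float64)
    return f - _opening(f, b)


def uniformize(f: np.ndarray, b: StructuringElement | None = None) -> np.ndarray:
    """Composite enhancement f + top_hat - bottom_hat, rescaled to [0, 255]."""
    f = validate_image(f).astype(np.float64)
    if b is None:
        b = default_structuring_element(f.shape)
    return rescale_to_8bit(f + top_hat(f, b) - bottom_hat(f, b))


def uniformize_rgb(
    img: ImageRGB, b: StructuringElement | None = None, per_channel: bool = True
) -> ImageRGB:
    """Apply ``uniformize`` to each plane (or only the green plane)."""
    img = img.validate()
    if per_channel:
        return ImageRGB(*(uniformize(plane, b) for plane in img))
    return ImageRGB(img.red.copy(), uniformize(img.green, b), img.blue.copy())
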