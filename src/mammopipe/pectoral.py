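"""Pectoral-muscle removal by orientation-aware seeded region growing.

The chest-wall side is detected from the brighter image half, the seed is
placed just inside the top corner on that side, and the region grows over
connected neighbors whose intensity stays within a tolerance of the running
region mean.  Growth stops when no candidate qualifies or the region hits a
fraction-of-image cap.  Masked pixels are zeroed rather than cropped so the
raster geometry survives for downstream metrics.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np

from .imgio import validate_image

__all__ = ["RegionGrowParams", "detect_orientation", "grow_pectoral", "remove_pectoral"]

_NEIGHBORS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_NEIGHBORS8 = _NEIGHBORS4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass(frozen=True)
class RegionGrowParams:
    intensity_tolerance: float = 25.0   # absolute difference from the running region mean
    connectivity: int = 8               # 4 or 8
    max_region_fraction: float = 0.35
    seed_offset: int = 10               # pixels inward from the detected corner
    min_seed_intensity: float = 1.0     # seed must sit on at least this intensity

    def __post_init__(self) -> None:
        if self.intensity_tolerance <= 0:
            raise ValueError("intensity_tolerance must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not 0.0 < self.max_region_fraction <= 1.0:
            raise ValueError("max_region_fraction must be in (0, 1]")
        if self.seed_offset < 0:
            raise ValueError("seed_offset must be >= 0")


def detect_orientation(img: np.ndarray) -> str:
    """Chest-wall side: the column half with the greater mean intensity."""
    img = validate_image(img)
    w = img.shape[1]
    left = img[:, : w // 2].mean() if w > 1 else img.mean()
    right = img[:, w - w // 2 :].mean() if w > 1 else img.mean()
    if left == right:
        warnings.warn("left/right intensity tie; defaulting to left orientation")
        return "left"
    return "left" if left > right else "right"


def _seed_pixel(shape: tuple[int, int], side: str, offset: int) -> tuple[int, int]:
    h, w = shape
    row = min(offset, h - 1)
    col = min(offset, w - 1) if side == "left" else max(0, w - 1 - offset)
    return row, col


def grow_pectoral(
    img: np.ndarray,
    params: RegionGrowParams = RegionGrowParams(),
    side: str | None = None,
) -> np.ndarray:
    """Grow the pectoral mask from the top chest-wall corner seed."""
    img = validate_image(img).astype(np.float64)
    h, w = img.shape
    if side is None:
        side = detect_orientation(img)
    seed = _seed_pixel((h, w), side, params.seed_offset)
    if img[seed] < params.min_seed_intensity:
        raise ValueError(
            f"seed pixel {seed} has background-level intensity {img[seed]:.3f}; "
            "try a different seed_offset"
        )
    neighbors = _NEIGHBORS8 if params.connectivity == 8 else _NEIGHBORS4
    cap = int(params.max_region_fraction * h * w)
    cap = max(cap, 1)

    mask = np.zeros((h, w), dtype=bool)
    queued = np.zeros((h, w), dtype=bool)
    mask[seed] = True
    queued[seed] = True
    total = img[seed]
    count = 1
    frontier = deque()
    for dr, dc in neighbors:
        r, c = seed[0] + dr, seed[1] + dc
        if 0 <= r < h and 0 <= c < w and not queued[r, c]:
            queued[r, c] = True
            frontier.append((r, c))

    while frontier and count < cap:
        r, c = frontier.popleft()
        if abs(img[r, c] - total / count) > params.intensity_tolerance:
            queued[r, c] = False  # may requalify later as the mean drifts
            continue
        mask[r, c] = True
        total += img[r, c]
        count += 1
        for dr, dc in neighbors:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not queued[rr, cc] and not mask[rr, cc]:
                queued[rr, cc] = True
                frontier.append((rr, cc))
    return mask


def remove_pectoral(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero the pixels under the mask; everything else is untouched."""
    img = validate_image(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    out = img.astype(np.float64).copy()
    out[mask] = 0.0
    return out
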