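"""Enhancement-quality metrics: MSE/PSNR, log-contrast, and EME.

PSNR has two variants.  ``as_printed`` follows the source convention
10*log10((L-1)/MSE) with L = 2^8 - 1 = 255 for 8-bit images; ``standard``
is the conventional 10*log10(L^2/MSE).  The printed form is the default;
the standard form is provided because the printed one is nonstandard.

Contrast is the intensity variance in decibels, 10*log10(var).  EME is the
block-average of 20*log10(Imax/Imin) over a K1 x K2 grid, with Imin floored
at a small epsilon so dark blocks stay finite.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass

import numpy as np

from .imgio import validate_image

__all__ = [
    "MetricsConfig",
    "MetricsReport",
    "dynamic_range",
    "mse",
    "psnr",
    "contrast_db",
    "eme",
    "report",
    "reports_to_csv",
]

CSV_COLUMNS = ["image_id", "stage", "psnr_db", "contrast_db", "eme", "psnr_variant", "k1", "k2"]


def dynamic_range(bit_depth: int = 8) -> int:
    """Maximum pixel value L = 2^n - 1 (255 for 8-bit images)."""
    if bit_depth < 1:
        raise ValueError("bit_depth must be >= 1")
    return 2**bit_depth - 1


@dataclass(frozen=True)
class MetricsConfig:
    k1: int = 8                        # horizontal (column) blocks
    k2: int = 8                        # vertical (row) blocks
    psnr_variant: str = "as_printed"   # or "standard"
    bit_depth: int = 8
    eme_eps: float = 1.0               # Imin floor keeping EME finite

    def __post_init__(self) -> None:
        if self.k1 < 1 or self.k2 < 1:
            raise ValueError("block counts must be >= 1")
        if self.psnr_variant not in ("as_printed", "standard"):
            raise ValueError(f"unknown psnr variant {self.psnr_variant!r}")


@dataclass
class MetricsReport:
    """PSNR/contrast/EME for one (original, enhanced) image pair."""

    image_id: str
    psnr_db: float
    contrast_db: float          # of the enhanced image
    eme: float                  # of the enhanced image
    contrast_db_original: float
    eme_original: float
    block_grid: tuple[int, int]
    psnr_variant: str

    def rows(self) -> list[dict]:
        k1, k2 = self.block_grid
        return [
            {
                "image_id": self.image_id,
                "stage": "original",
                "psnr_db": "",
                "contrast_db": self.contrast_db_original,
                "eme": self.eme_original,
                "psnr_variant": self.psnr_variant,
                "k1": k1,
                "k2": k2,
            },
            {
                "image_id": self.image_id,
                "stage": "enhanced",
                "psnr_db": self.psnr_db,
                "contrast_db": self.contrast_db,
                "eme": self.eme,
                "psnr_variant": self.psnr_variant,
                "k1": k1,
                "k2": k2,
            },
        ]


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = validate_image(x).astype(np.float64)
    y = validate_image(y).astype(np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean of squared per-pixel differences."""
    x, y = _check_pair(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(
    x: np.ndarray, y: np.ndarray, variant: str = "as_printed", bit_depth: int = 8
) -> float:
    """Peak signal-to-noise ratio in dB; NaN (with a warning) when MSE = 0."""
    err = mse(x, y)
    if err == 0.0:
        warnings.warn("identical images: PSNR is unbounded, returning NaN")
        return float("nan")
    level = dynamic_range(bit_depth)
    if variant == "as_printed":
        return float(10.0 * np.log10((level - 1) / err))
    if variant == "standard":
        return float(10.0 * np.log10(level**2 / err))
    raise ValueError(f"unknown psnr variant {variant!r}")


def contrast_db(y: np.ndarray) -> float:
    """10*log10 of the intensity variance; NaN (with warning) when constant."""
    y = validate_image(y).astype(np.float64)
    c = float(np.mean(y**2) - np.mean(y) ** 2)
    if c <= 0.0:
        warnings.warn("zero-variance image: contrast undefined, returning NaN")
        return float("nan")
    return float(10.0 * np.log10(c))


def _block_edges(n: int, k: int) -> list[tuple[int, int]]:
    size = n // k
    edges = [(i * size, (i + 1) * size) for i in range(k)]
    edges[-1] = (edges[-1][0], n)  # last block absorbs the remainder
    return edges


def eme(y: np.ndarray, k1: int = 8, k2: int = 8, eps: float = 1.0) -> float:
    """Block-average 20*log10(Imax / max(Imin, eps)) over a k1 x k2 grid."""
    y = validate_image(y).astype(np.float64)
    h, w = y.shape
    if not 1 <= k2 <= h or not 1 <= k1 <= w:
        raise ValueError(f"grid ({k1}, {k2}) incompatible with image {y.shape}")
    total = 0.0
    for r0, r1 in _block_edges(h, k2):
        for c0, c1 in _block_edges(w, k1):
            block = y[r0:r1, c0:c1]
            imin = max(float(block.min()), eps)
            imax = max(float(block.max()), eps)
            total += 20.0 * np.log10(imax / imin)
    return total / (k1 * k2)


def report(
    original: np.ndarray,
    enhanced: np.ndarray,
    cfg: MetricsConfig = MetricsConfig(),
    image_id: str = "image",
) -> MetricsReport:
    """Assemble all three metrics for one (original, enhanced) pair."""
    original, enhanced = _check_pair(original, enhanced)
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        return MetricsReport(
            image_id=image_id,
            psnr_db=psnr(original, enhanced, cfg.psnr_variant, cfg.bit_depth),
            contrast_db=contrast_db(enhanced),
            eme=eme(enhanced, cfg.k1, cfg.k2, cfg.eme_eps),
            contrast_db_original=contrast_db(original),
            eme_original=eme(original, cfg.k1, cfg.k2, cfg.eme_eps),
            block_grid=(cfg.k1, cfg.k2),
            psnr_variant=cfg.psnr_variant,
        )


def reports_to_csv(reports: list[MetricsReport]) -> str:
    """Serialize reports, two rows per image (original/enhanced stages)."""
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=CSV_COLUMNS, lineterminator="\n")
    writer.writeheader()
    for rep in reports:
        for row in rep.rows():
            writer.writerow(row)
    return buf.getvalue()
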