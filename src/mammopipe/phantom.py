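"""Synthetic CC/MLO mammogram phantoms with ground-truth masks.

The phantom emulates the geometry of screening mammograms: a half-elliptical
breast anchored to the chest-wall side of the frame, a right-triangular
pectoral wedge in the top chest-wall corner (MLO view only), bright Gaussian
lesions, a linear illumination ramp, and additive Gaussian noise.  It exists
so every pipeline stage and metric can be exercised without clinical data;
its parameters are free knobs, not claims about any particular scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imgio import ImageRGB

__all__ = ["PhantomSpec", "PhantomBundle", "make_phantom", "degrade"]

#: red/blue channels carry slightly more noise than green
CHANNEL_NOISE_FACTORS = {"red": 1.25, "green": 1.0, "blue": 1.25}


@dataclass(frozen=True)
class PhantomSpec:
    view: str = "MLO"                       # "CC" or "MLO"
    side: str = "left"                      # chest-wall side: "left" or "right"
    height: int = 256
    width: int = 256
    breast_intensity: float = 120.0
    background_intensity: float = 20.0
    pectoral_intensity: float = 200.0       # MLO only
    lesions: tuple[tuple[float, float, float, float], ...] = ()
    # each lesion: (center_row, center_col, radius_pixels, peak_amplitude)
    illumination_slope: float = 0.0         # intensity units per column
    noise_sigma: float = 0.0                # green-channel noise std
    seed: int = 0
    pectoral_frac: tuple[float, float] = (0.45, 0.35)  # triangle legs as (row, col) fractions

    def __post_init__(self) -> None:
        if self.view not in ("CC", "MLO"):
            raise ValueError(f"view must be CC or MLO, got {self.view!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left or right, got {self.side!r}")
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be >= 1")
        for name in ("breast_intensity", "background_intensity", "pectoral_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for les in self.lesions:
            if len(les) != 4:
                raise ValueError(f"lesion must be (row, col, radius, amplitude): {les}")
            if les[2] < 1:
                raise ValueError(f"lesion radius must be >= 1, got {les[2]}")


@dataclass
class PhantomBundle:
    spec: PhantomSpec
    clean: np.ndarray
    degraded: ImageRGB
    breast_mask: np.ndarray
    pectoral_mask: np.ndarray
    lesion_mask: np.ndarray


def _breast_mask(spec: PhantomSpec) -> np.ndarray:
    """Half-ellipse anchored to the chest-wall edge."""
    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    if spec.side == "right":
        cc = (spec.width - 1) - cc
    a = 0.48 * spec.height            # vertical semi-axis
    b = 0.80 * spec.width             # horizontal semi-axis (from the chest wall)
    return ((rr - spec.height / 2.0) / a) ** 2 + (cc / b) ** 2 <= 1.0


def _pectoral_mask(spec: PhantomSpec) -> np.ndarray:
    """Filled right triangle in the top chest-wall corner (MLO view)."""
    if spec.view != "MLO":
        return np.zeros((spec.height, spec.width), dtype=bool)
    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    if spec.side == "right":
        cc = (spec.width - 1) - cc
    leg_r = spec.pectoral_frac[0] * spec.height
    leg_c = spec.pectoral_frac[1] * spec.width
    return (rr / leg_r + cc / leg_c) <= 1.0


def _lesion_fields(spec: PhantomSpec, breast: np.ndarray, pectoral: np.ndarray):
    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    bumps = np.zeros((spec.height, spec.width))
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for row, col, radius, amp in spec.lesions:
        d2 = (rr - row) ** 2 + (cc - col) ** 2
        disk = d2 <= radius**2
        if np.any(disk & ~breast):
            raise ValueError(f"lesion at ({row}, {col}) r={radius} extends outside the breast")
        if np.any(disk & pectoral):
            raise ValueError(f"lesion at ({row}, {col}) overlaps the pectoral triangle")
        sigma = radius / 2.0
        bumps += amp * np.exp(-d2 / (2.0 * sigma**2)) * disk  # clipped Gaussian bump
        mask |= disk
    return bumps, mask


def degrade(img: np.ndarray, slope: float, sigma: float, seed) -> np.ndarray:
    """Add a column-wise illumination ramp and Gaussian noise, clip to [0, 255]."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    img = np.asarray(img, dtype=np.float64)
    out = img + slope * np.arange(img.shape[1], dtype=np.float64)[None, :]
    if sigma > 0:
        out = out + np.random.default_rng(seed).normal(0.0, sigma, size=img.shape)
    elif slope == 0:
        return img.copy()
    return np.clip(out, 0.0, 255.0)


def make_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render the phantom deterministically for a fixed spec/seed."""
    breast = _breast_mask(spec)
    pectoral = _pectoral_mask(spec)
    bumps, lesion_mask = _lesion_fields(spec, breast, pectoral)

    clean = np.full((spec.height, spec.width), spec.background_intensity)
    clean[breast] = spec.breast_intensity
    if spec.view == "MLO":
        clean[pectoral] = spec.pectoral_intensity
    clean = np.clip(clean + bumps, 0.0, 255.0)

    ss = np.random.SeedSequence(spec.seed)
    planes = {}
    for name, child in zip(("red", "green", "blue"), ss.spawn(3)):
        planes[name] = degrade(
            clean, spec.illumination_slope, spec.noise_sigma * CHANNEL_NOISE_FACTORS[name], child
        )
    return PhantomBundle(
        spec=spec,
        clean=clean,
        degraded=ImageRGB(planes["red"], planes["green"], planes["blue"]),
        breast_mask=breast,
        pectoral_mask=pectoral,
        lesion_mask=lesion_mask,
    )
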