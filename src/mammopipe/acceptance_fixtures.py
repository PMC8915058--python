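"""Canonical phantom fleets and pipeline configurations for benchmarking.

These builders are shared by the benchmark CLI subcommand, the test suite,
and the acceptance report so that all three exercise the same inputs.
"""

from __future__ import annotations

import numpy as np

from .coherence import DiffusionConfig
from .metrics import MetricsConfig
from .pectoral import RegionGrowParams
from .phantom import PhantomBundle, PhantomSpec, make_phantom
from .pipeline import PipelineConfig

__all__ = [
    "mlo_phantoms",
    "directionality_bundles",
    "directionality_config",
    "lesion_phantom",
]


def lesion_phantom(seed: int = 3) -> PhantomBundle:
    """Low-tissue-contrast phantom with one bright clipped lesion.

    Tissue and background share one intensity so two-cluster intensity
    k-means isolates the lesion rather than the breast outline.
    """
    spec = PhantomSpec(
        view="CC",
        height=128,
        width=128,
        breast_intensity=70.0,
        background_intensity=70.0,
        lesions=((64.0, 40.0, 12.0, 320.0),),
        noise_sigma=1.0,
        seed=seed,
    )
    return make_phantom(spec)


def mlo_phantoms(n: int = 20, size: int = 128, seed: int = 0) -> list[PhantomBundle]:
    """Randomized MLO geometries for pectoral-recovery evaluation."""
    rng = np.random.default_rng(seed)
    bundles = []
    for i in range(n):
        spec = PhantomSpec(
            view="MLO",
            side=("left", "right")[int(rng.integers(2))],
            height=size,
            width=size,
            breast_intensity=float(rng.uniform(100, 140)),
            background_intensity=float(rng.uniform(10, 30)),
            pectoral_intensity=float(rng.uniform(180, 220)),
            pectoral_frac=(float(rng.uniform(0.35, 0.55)), float(rng.uniform(0.25, 0.45))),
            noise_sigma=float(rng.uniform(1.0, 4.0)),
            illumination_slope=0.0,
            seed=int(rng.integers(2**31)),
        )
        bundles.append(make_phantom(spec))
    return bundles


def directionality_bundles(n: int = 20, size: int = 128, seed: int = 0) -> list[PhantomBundle]:
    """Degraded CC phantoms for the before/after and baseline comparisons.

    The degradation is dominated by the illumination ramp with noise near
    the quantization level: the enhancement directionality claims concern
    contrast restoration, and a ramp-dominated degradation keeps the EME of
    the degraded input from being inflated by amplified background noise.
    Lesions are plateau-scale bright masses inside the breast.
    """
    rng = np.random.default_rng(seed)
    h = w = size
    a, b = 0.48 * size, 0.80 * size

    def fits(row: float, col: float, radius: float) -> bool:
        for dr, dc in ((radius, 0), (-radius, 0), (0, radius), (0, -radius)):
            if ((row + dr - size / 2) / a) ** 2 + ((col + dc) / b) ** 2 > 0.88:
                return False
        return True

    bundles = []
    for i in range(n):
        lesions = []
        for _ in range(400):
            if len(lesions) >= 7:
                break
            radius = float(rng.uniform(7, 14))
            row = float(rng.uniform(0.15 * h, 0.85 * h))
            col = float(rng.uniform(0.05 * w, 0.60 * w))
            if fits(row, col, radius):
                lesions.append((row, col, radius, float(rng.uniform(40, 65))))
        spec = PhantomSpec(
            view="CC",
            side="left",
            height=h,
            width=w,
            breast_intensity=float(rng.uniform(182, 198)),
            background_intensity=60.0,
            lesions=tuple(lesions),
            noise_sigma=float(rng.uniform(0.15, 0.3)),
            illumination_slope=float(rng.uniform(0.03, 0.07)),
            seed=int(rng.integers(2**31)),
        )
        bundles.append(make_phantom(spec))
    return bundles


def directionality_config() -> PipelineConfig:
    """Pipeline configuration for the directionality benchmark.

    The LoG stage produces a structural (edge-like) rendering that is not
    comparable to the clean image in an L2 sense, so the benchmark runs the
    diffusion-only coherence path; the structuring element is kept at the
    minimum radius so the hat composite amplifies structure edges rather
    than noise.
    """
    return PipelineConfig(
        view="CC",
        skip_log=True,
        se_radius=1,
        diffusion=DiffusionConfig(max_iters=10),
        metric=MetricsConfig(),
    )
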