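"""Pipeline orchestration: channels -> uniformity -> PCA gray -> pectoral
removal -> LoG -> oriented diffusion, with per-stage artifacts, a metrics
CSV, and a manifest sufficient to re-run any image bit-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import background, baselines, coherence, gray_pca, metrics, pectoral, segment
from .imgio import ImageRGB, read_image, read_mask, rescale_to_8bit, write_image, write_mask

__all__ = ["PipelineConfig", "enhance_rgb", "run_pipeline", "run_segment", "run_bench"]

logger = logging.getLogger("mammopipe")

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".pgm"}


@dataclass(frozen=True)
class PipelineConfig:
    view: str = "MLO"                  # CC phantoms skip pectoral removal
    skip_pectoral: bool = False
    skip_log: bool = False
    skip_diffusion: bool = False
    se_shape: str = "disk"             # disk | square
    se_radius: int = 0                 # 0 = auto-scale with image size
    per_channel: bool = True           # hats on all channels vs green only
    gray_method: str = "pca"           # pca | green-channel
    region: pectoral.RegionGrowParams = field(default_factory=pectoral.RegionGrowParams)
    diffusion: coherence.DiffusionConfig = field(default_factory=coherence.DiffusionConfig)
    metric: metrics.MetricsConfig = field(default_factory=metrics.MetricsConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.view not in ("CC", "MLO"):
            raise ValueError(f"view must be CC or MLO, got {self.view!r}")
        if self.gray_method not in ("pca", "green-channel"):
            raise ValueError(f"unknown gray method {self.gray_method!r}")

    # -- plain-text key=value round trip -------------------------------------
    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            value = getattr(self, f.name)
            if dataclasses.is_dataclass(value):
                for sub in fields(value):
                    lines.append(f"{f.name}.{sub.name}={getattr(value, sub.name)!r}")
            else:
                lines.append(f"{f.name}={value!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        import ast

        flat: dict[str, dict] = {}
        top: dict[str, object] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            value = ast.literal_eval(raw)
            if "." in key:
                group, sub = key.split(".", 1)
                flat.setdefault(group, {})[sub] = value
            else:
                top[key] = value
        if "region" in flat:
            top["region"] = pectoral.RegionGrowParams(**flat["region"])
        if "diffusion" in flat:
            top["diffusion"] = coherence.DiffusionConfig(**flat["diffusion"])
        if "metric" in flat:
            top["metric"] = metrics.MetricsConfig(**flat["metric"])
        return cls(**top)


def _structuring_element(cfg: PipelineConfig, shape: tuple[int, int]):
    if cfg.se_radius > 0:
        if cfg.se_shape == "disk":
            return background.StructuringElement.disk(cfg.se_radius)
        return background.StructuringElement.square(2 * cfg.se_radius + 1)
    return background.default_structuring_element(shape, cfg.se_shape)


def enhance_rgb(img: ImageRGB, cfg: PipelineConfig = PipelineConfig()) -> dict[str, object]:
    """Run all enabled stages in memory; returns every intermediate by name."""
    img = img.validate()
    stages: dict[str, object] = {}
    se = _structuring_element(cfg, img.shape)
    uniform = background.uniformize_rgb(img, se, per_channel=cfg.per_channel)
    stages["uniform"] = uniform

    if cfg.gray_method == "pca":
        gray = gray_pca.pca_gray(uniform)
    else:
        gray = rescale_to_8bit(uniform.green)
    stages["gray"] = gray

    current = gray
    if cfg.view == "MLO" and not cfg.skip_pectoral:
        mask = pectoral.grow_pectoral(current, cfg.region)
        stages["pectoral_mask"] = mask
        current = pectoral.remove_pectoral(current, mask)
        stages["muscle_free"] = current

    if not cfg.skip_log:
        current = coherence.log_filter(current, sigma=2.0)
        stages["log"] = current

    if not cfg.skip_diffusion:
        current, iters, trace = coherence.diffuse(current, cfg.diffusion)
        stages["diffused"] = current
        stages["diffusion_iterations"] = iters
        stages["entropy_trace"] = trace

    stages["final"] = current
    return stages


_STAGE_IMAGES = ("gray", "muscle_free", "log", "diffused")


def _process_one(path: Path, cfg: PipelineConfig, out_dir: Path) -> metrics.MetricsReport:
    stem = path.stem
    timings: list[tuple[str, float]] = []
    t0 = time.perf_counter()
    rgb = read_image(path)
    timings.append(("read", time.perf_counter() - t0))

    t0 = time.perf_counter()
    stages = enhance_rgb(rgb, cfg)
    timings.append(("enhance", time.perf_counter() - t0))

    uniform: ImageRGB = stages["uniform"]  # type: ignore[assignment]
    for name, plane in zip(("red", "green", "blue"), uniform):
        write_image(plane, out_dir / f"{stem}__uniform_{name}.png")
    for stage_name in _STAGE_IMAGES:
        if stage_name in stages:
            write_image(np.clip(stages[stage_name], 0, 255), out_dir / f"{stem}__{stage_name}.png")
    if "pectoral_mask" in stages:
        write_mask(stages["pectoral_mask"], out_dir / f"{stem}__pectoral_mask.png")
    write_image(np.clip(stages["final"], 0, 255), out_dir / f"{stem}__final.png")

    reference = gray_pca.luminance(rgb)
    rep = metrics.report(reference, stages["final"], cfg.metric, image_id=stem)

    with open(out_dir / "manifest.txt", "a") as fh:
        fh.write(f"[image {stem}]\n")
        fh.write(f"source={str(path)!r}\nseed={cfg.seed}\n")
        for stage_name, dt in timings:
            fh.write(f"time.{stage_name}={dt:.4f}\n")
    return rep


def run_pipeline(input_path: str | Path, cfg: PipelineConfig, out_dir: str | Path) -> list:
    """Process one image or every image in a directory.

    Batch mode logs and skips per-image failures; single-image mode
    re-raises.  Returns the metric reports that were produced.
    """
    input_path = Path(input_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.txt", "w") as fh:
        fh.write("[config]\n")
        fh.write(cfg.to_text())

    if input_path.is_dir():
        paths = sorted(
            p for p in input_path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        batch = True
    else:
        paths = [input_path]
        batch = False

    reports = []
    for path in paths:
        try:
            reports.append(_process_one(path, cfg, out_dir))
        except Exception:
            if not batch:
                raise
            logger.exception("skipping %s after failure", path)
    (out_dir / "metrics.csv").write_text(metrics.reports_to_csv(reports))
    return reports


def run_segment(
    enhanced_path: str | Path,
    out_dir: str | Path,
    ks: tuple[int, ...] = (2, 4, 6, 8),
    truth_mask_path: str | Path | None = None,
    select_cluster: int | None = None,
) -> dict[int, segment.ClusterResult]:
    """Emit k-means label maps for each k, plus an evaluation CSV if a
    ground-truth mask is supplied."""
    enhanced_path = Path(enhanced_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img = gray_pca.luminance(read_image(enhanced_path))
    stem = enhanced_path.stem

    results: dict[int, segment.ClusterResult] = {}
    for k in ks:
        res = segment.kmeans_intensity(img, k)
        results[k] = res
        viewable = res.labels.astype(np.float64) * (255.0 / (k - 1))
        write_image(viewable, out_dir / f"{stem}__kmeans_k{k}.png")

    if truth_mask_path is None:
        logger.warning("no truth mask supplied: skipping evaluation CSV")
        return results

    truth = read_mask(truth_mask_path)
    rows = ["k,specificity,sensitivity,accuracy"]
    for k, res in results.items():
        which = {select_cluster} if select_cluster is not None else None
        pred = segment.mask_from_clusters(res, which)
        scores = segment.evaluate_mask(pred, truth)
        rows.append(f"{k},{scores.specificity},{scores.sensitivity},{scores.accuracy}")
    (out_dir / f"{stem}__segment_eval.csv").write_text("\n".join(rows) + "\n")
    return results


def run_bench(
    bundles,
    cfg: PipelineConfig = PipelineConfig(),
) -> dict[str, dict[str, float]]:
    """Compare the pipeline against HE/CLAHE/BBHE on degraded phantoms.

    Returns mean contrast_db / eme per method (plus PSNR against the clean
    ground truth for methods applied to the degraded luminance).
    """
    methods = {
        "pipeline": None,
        "HE": baselines.hist_equalize,
        "CLAHE": baselines.clahe,
        "BBHE": baselines.bbhe,
        "degraded": lambda x: x,
    }
    acc = {name: {"psnr_db": [], "contrast_db": [], "eme": []} for name in methods}
    for bundle in bundles:
        degraded_y = gray_pca.luminance(bundle.degraded)
        for name, fn in methods.items():
            if fn is None:
                out = enhance_rgb(bundle.degraded, cfg)["final"]
            else:
                out = fn(degraded_y)
            acc[name]["psnr_db"].append(
                metrics.psnr(bundle.clean, out, cfg.metric.psnr_variant)
            )
            acc[name]["contrast_db"].append(metrics.contrast_db(out))
            acc[name]["eme"].append(metrics.eme(out, cfg.metric.k1, cfg.metric.k2))
    return {
        name: {key: float(np.mean(vals)) for key, vals in series.items()}
        for name, series in acc.items()
    }
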