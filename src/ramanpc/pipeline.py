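"""End-to-end orchestration: spectra in, super-resolved pseudo-color out.

Stage order: average repeats -> peak image -> normalize -> Retinex ->
minimum-size interpolation -> median filter -> super-resolution to the
target size -> adaptive guided filter -> Jet colorization -> metrics.
The guided filter runs on the grayscale image before colorization by
default; ``filter_rgb`` instead filters the R, G, B channels of the
colorized image separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import srcnn as _srcnn
from .adaptive_guided import (
    PUBLISHED_COEFFICIENTS,
    AdaptiveCoefficients,
    GuidedFilterParams,
    adaptive_params,
    guided_filter,
    summarize_sigma2,
)
from .colorize import colorize
from .enhance import median_filter, resize_to_min, retinex_enhance
from .metrics import MetricReport, channel_entropies, entropy_color, entropy_gray
from .peak_image import band_variance_map, extract_peak_image, full_band, normalize_gray
from .spectra_io import BandWindow, SpectralScan, average_repeats

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "PipelineStageError",
    "run_pipeline",
    "save_png",
    "warm_mask",
    "dice",
    "upsample_mask",
]


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    band: BandWindow | None = None
    nsym: int = 0
    median_window: int = 3
    min_size: int = 20
    resize_any_side: bool = False  # upscale when either side is short
    target_size: int = 320
    sr_scale: int = 2
    use_srcnn: bool = True
    weights: object | None = None  # SRCNNWeights | path | None (packaged default)
    coefficients: AdaptiveCoefficients = field(default_factory=lambda: PUBLISHED_COEFFICIENTS)
    var_threshold: float = 1000.0
    sigma2_mode: str = "mean"
    skip_retinex: bool = False
    filter_rgb: bool = False
    colormap: str = "jet"


@dataclass
class PipelineResult:
    rgb: np.ndarray
    gray_final: np.ndarray
    params: GuidedFilterParams
    report: MetricReport
    stages: dict[str, np.ndarray]


def _resolve_weights(cfg: PipelineConfig):
    if not cfg.use_srcnn:
        return None
    if cfg.weights is None:
        return _srcnn.default_weights()
    if isinstance(cfg.weights, _srcnn.SRCNNWeights):
        return cfg.weights
    return _srcnn.load_weights(cfg.weights)


def run_pipeline(scan: SpectralScan, cfg: PipelineConfig | None = None) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    stages: dict[str, np.ndarray] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise PipelineStageError(name, exc) from exc
        if isinstance(out, np.ndarray):
            stages[name] = out
        return out

    averaged = stage("average_repeats", average_repeats, scan)
    band = cfg.band or full_band(averaged)
    raw = stage("extract_peak_image", extract_peak_image, averaged, band, cfg.nsym)
    gray = stage("normalize", normalize_gray, raw)
    if not cfg.skip_retinex:
        gray = stage("retinex", retinex_enhance, gray)
    gray = stage("resize_to_min", resize_to_min, gray, cfg.min_size,
                 force=cfg.resize_any_side)
    gray = stage("median_filter", median_filter, gray, cfg.median_window)
    weights = _resolve_weights(cfg)
    gray = stage("superresolve", _srcnn.superresolve, gray, weights,
                 target_min=cfg.target_size, scale=cfg.sr_scale,
                 use_network=cfg.use_srcnn)
    gray = np.clip(gray, 0.0, 255.0)

    vm = stage("band_variance_map", band_variance_map, averaged, band,
               cfg.var_threshold)
    sigma2 = summarize_sigma2(vm, cfg.sigma2_mode)
    params = adaptive_params(averaged.n_points, vm.n_above, sigma2,
                             cfg.coefficients)

    if cfg.filter_rgb:
        rgb = stage("colorize", colorize, gray, cfg.colormap)
        filtered = stage("guided_filter", guided_filter,
                         rgb.astype(float), params)
        rgb = np.clip(np.round(filtered), 0, 255).astype(np.uint8)
        gray_final = gray
    else:
        gray_final = stage("guided_filter", guided_filter, gray, params)
        gray_final = np.clip(gray_final, 0.0, 255.0)
        rgb = stage("colorize", colorize, gray_final, cfg.colormap)

    report = MetricReport(
        entropy_bits=entropy_color(rgb),
        channel_entropies=channel_entropies(rgb),
        extras={
            "gray_entropy_bits": entropy_gray(gray_final),
            "guided_omega": params.omega,
            "guided_eps": params.eps,
            "guided_r": params.r,
            "n1": averaged.n_points,
            "n2": vm.n_above,
            "sigma2": sigma2,
        },
    )
    return PipelineResult(rgb=rgb, gray_final=gray_final, params=params,
                          report=report, stages=stages)


def save_png(img: np.ndarray, path) -> None:
    """Write an 8-bit grayscale or RGB PNG (deterministic bytes)."""
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr.astype(float)), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(Path(path), format="PNG")


# --- ground-truth comparison helpers (phantom evaluation) -------------------


def warm_mask(gray: np.ndarray, threshold: float = 0.6) -> np.ndarray:
    """Pixels whose normalized gray value exceeds ``threshold``."""
    return np.asarray(gray, dtype=float) / 255.0 > threshold


def upsample_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor upsample of a boolean grid to ``shape``."""
    mask = np.asarray(mask, dtype=bool)
    ri = np.minimum((np.arange(shape[0]) * mask.shape[0]) // shape[0],
                    mask.shape[0] - 1)
    ci = np.minimum((np.arange(shape[1]) * mask.shape[1]) // shape[1],
                    mask.shape[1] - 1)
    return mask[np.ix_(ri, ci)]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|); 1.0 when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
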