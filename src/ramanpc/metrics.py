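"""Image quality metrics: PSNR, histogram entropies, CIELAB KL sharpness."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2lab

__all__ = [
    "MetricReport",
    "psnr",
    "entropy_gray",
    "entropy_color",
    "kl_sharpness",
    "PSNR_INF",
]

#: Sentinel reported when MSE == 0 (identical images).
PSNR_INF = math.inf


@dataclass
class MetricReport:
    mse: float | None = None
    psnr_db: float | None = None
    entropy_bits: float | None = None
    channel_entropies: tuple[float, float, float] | None = None
    kl_divergence: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "mse": self.mse,
            "psnr_db": None if self.psnr_db == PSNR_INF else self.psnr_db,
            "psnr_infinite": self.psnr_db == PSNR_INF,
            "entropy_bits": self.entropy_bits,
            "channel_entropies": self.channel_entropies,
            "kl_divergence": self.kl_divergence,
        }
        out.update(self.extras)
        return out


def psnr(img_i: np.ndarray, img_k: np.ndarray) -> tuple[float, float]:
    """(MSE, PSNR in dB) between two equally shaped rasters on 0..255.

    RGB inputs average the squared error over the three channels. Identical
    images give MSE 0 and the +inf PSNR sentinel.
    """
    a = np.asarray(img_i, dtype=float)
    b = np.asarray(img_k, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return 0.0, PSNR_INF
    return mse, 20.0 * math.log10(255.0 / math.sqrt(mse))


def _hist_entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log2(p)).sum())


def entropy_gray(img: np.ndarray) -> float:
    """Shannon entropy (bits) of the 0..255 gray-level histogram."""
    levels = np.clip(np.round(np.asarray(img, dtype=float)), 0, 255).astype(int)
    return _hist_entropy(np.bincount(levels.ravel(), minlength=256))


def entropy_color(img: np.ndarray) -> float:
    """Joint Shannon entropy (bits) over observed (R, G, B) triples.

    The joint histogram is normalized by the pixel count so it is a proper
    distribution.
    """
    rgb = np.asarray(img)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    flat = rgb.reshape(-1, 3).astype(np.int64)
    codes = (flat[:, 0] << 16) | (flat[:, 1] << 8) | flat[:, 2]
    _, counts = np.unique(codes, return_counts=True)
    return _hist_entropy(counts)


def channel_entropies(img: np.ndarray) -> tuple[float, float, float]:
    rgb = np.asarray(img)
    return tuple(entropy_gray(rgb[..., c]) for c in range(3))


def _lab_histogram(
    rgb: np.ndarray,
    bins: tuple[int, int, int],
    alpha: float,
) -> np.ndarray:
    """Smoothed (L*, C*, h) histogram of an 8-bit RGB image, D65/2 degrees."""
    lab = rgb2lab(np.asarray(rgb, dtype=np.uint8))
    l_star = lab[..., 0].ravel()
    a_star = lab[..., 1].ravel()
    b_star = lab[..., 2].ravel()
    chroma = np.hypot(a_star, b_star)
    hue = np.degrees(np.arctan2(b_star, a_star)) % 360.0
    coords = [
        np.clip(l_star, 0.0, 100.0 - 1e-9),
        np.clip(chroma, 0.0, 150.0 - 1e-9),
        np.clip(hue, 0.0, 360.0 - 1e-9),
    ]
    ranges = [(0.0, 100.0), (0.0, 150.0), (0.0, 360.0)]
    idx = [
        np.floor(c / (hi - lo) * nb).astype(int)
        for c, (lo, hi), nb in zip(coords, ranges, bins)
    ]
    hist = np.zeros(bins)
    np.add.at(hist, tuple(idx), 1.0)
    hist += alpha
    return hist / hist.sum()


def kl_sharpness(
    img_p: np.ndarray,
    img_q: np.ndarray,
    bins: tuple[int, int, int] = (10, 10, 36),
    alpha: float = 1e-6,
) -> float:
    """|KL divergence| between CIELAB (L*, C*, h) histograms of two images.

    Images may differ in size (distributions are compared, not pixels).
    Laplace smoothing ``alpha`` keeps the divergence finite; log base 10.
    """
    p = _lab_histogram(img_p, bins, alpha)
    q = _lab_histogram(img_q, bins, alpha)
    return float(abs(np.sum(p * np.log10(p / q))))
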