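"""Deterministic desk-scale training data for the super-resolution network.

Builds grayscale training imagery from randomized synthetic phantoms pushed
through the early pipeline stages (peak image, Retinex, median filter) and a
bicubic upscale, so the network sees the kind of content it will restore.
"""

from __future__ import annotations

import numpy as np

from .enhance import median_filter, retinex_enhance
from .peak_image import extract_peak_image, normalize_gray
from .phantom import Ellipse, PhantomSpec, generate_phantom
from .spectra_io import BandWindow, average_repeats
from .srcnn import superresolve

__all__ = ["phantom_training_images"]

_BAND = BandWindow(2750.0, 3050.0)


def _random_spec(rng: np.random.Generator, seed: int) -> PhantomSpec:
    rows = cols = 20
    semi_row = rng.uniform(3.0, 6.5)
    semi_col = rng.uniform(3.0, 6.5)
    center_row = rng.uniform(semi_row, rows - 1 - semi_row)
    center_col = rng.uniform(semi_col, cols - 1 - semi_col)
    return PhantomSpec(
        grid_rows=rows,
        grid_cols=cols,
        cells=[Ellipse(center_row, center_col, semi_row, semi_col)],
        peak_amp_inside=rng.uniform(800.0, 1600.0),
        peak_amp_outside=rng.uniform(50.0, 250.0),
        gauss_sigma=rng.uniform(5.0, 30.0),
        shot_scale=rng.uniform(0.1, 0.8),
        salt_prob=rng.uniform(0.0, 0.05),
        repeats=2,
        seed=seed,
    )


def phantom_training_images(seed: int = 0, n_phantoms: int = 3,
                            size: int = 80) -> list[np.ndarray]:
    """Grayscale [0,255] images of ``size`` pixels for patch cutting."""
    rng = np.random.default_rng(seed)
    images = []
    for k in range(n_phantoms):
        spec = _random_spec(rng, seed=seed * 1009 + k)
        scan, _ = generate_phantom(spec)
        gray = normalize_gray(extract_peak_image(average_repeats(scan), _BAND))
        gray = median_filter(retinex_enhance(gray), 3)
        # nearest-neighbor upscale keeps edges sharp, so the bicubic input the
        # network sees is genuinely blurred relative to its target
        factor = -(-size // max(gray.shape))
        big = np.kron(gray, np.ones((factor, factor)))
        images.append(np.clip(big, 0.0, 255.0))
    return images
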