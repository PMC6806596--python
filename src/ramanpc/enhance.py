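"""Contrast enhancement: ratio-reset Retinex, median filter, minimum-size resize.

The Retinex variant compares log-intensity ratios between pixel pairs at a
step that starts at half the image extent and halves each round down to one
pixel, resetting any luminance that exceeds the global log-maximum after each
directional pass, and finishes with a uniform affine stretch to [0, 255].
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .peak_image import normalize_gray

__all__ = ["retinex_enhance", "median_filter", "resize_to_min"]


def _ratio_reset_pass(lum, logd, constant, step, axis):
    """One propagation pass at the given step along one axis.

    Each pixel with a partner ``step`` pixels ahead (and, symmetrically,
    behind) receives the partner's luminance plus the log brightness ratio,
    reset at ``constant``, averaged with its current estimate. Pairs falling
    outside the image are skipped — no wraparound.
    """
    for sign in (+1, -1):
        shift = sign * step
        cand = np.roll(lum, -shift, axis=axis) + logd - np.roll(logd, -shift, axis=axis)
        np.minimum(cand, constant, out=cand)
        valid = np.zeros(lum.shape, dtype=bool)
        if axis == 0:
            if shift > 0:
                valid[: lum.shape[0] - shift, :] = True
            else:
                valid[-shift:, :] = True
        else:
            if shift > 0:
                valid[:, : lum.shape[1] - shift] = True
            else:
                valid[:, -shift:] = True
        lum[valid] = 0.5 * (lum[valid] + cand[valid])
    return lum


def retinex_enhance(img: np.ndarray) -> np.ndarray:
    """Iterative ratio-reset Retinex enhancement.

    Luminance is initialized everywhere to ``log10(P)`` with ``P`` the
    maximum of the working image (zero pixels are offset to 1 so ratios are
    defined). At row-step ``h = m//2`` each pixel compares against its
    partners ``h`` rows away: the partner's luminance plus the log ratio of
    own to partner brightness, reset at ``log10(P)``, is averaged into the
    pixel's estimate. The same happens at column-step ``theta = n//2``; both
    steps halve (integer floor, min 1) each round until both have been
    applied at step 1. The result is stretched affinely so min -> 0 and
    max -> 255; a constant input returns all zeros.

    Invariant to multiplicative rescaling of a strictly positive input.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError("retinex requires a 2-D image of at least 2x2")
    d = np.where(img == 0, 1.0, img)
    m, n = d.shape
    logd = np.log10(d)
    constant = math.log10(d.max())
    lum = np.full((m, n), constant)
    h, theta = m // 2, n // 2
    while True:
        if h < m:
            lum = _ratio_reset_pass(lum, logd, constant, h, axis=0)
        if theta < n:
            lum = _ratio_reset_pass(lum, logd, constant, theta, axis=1)
        if h == 1 and theta == 1:
            break
        h = max(h // 2, 1)
        theta = max(theta // 2, 1)
    return normalize_gray(lum)


def median_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Median over a window x window neighborhood with reflect borders."""
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    return ndimage.median_filter(np.asarray(img, dtype=float), size=window,
                                 mode="reflect")


def resize_to_min(img: np.ndarray, min_side: int = 20, force: bool = False) -> np.ndarray:
    """Bilinear upscale so the smaller side reaches ``min_side``.

    Applied only when *both* sides are below ``min_side`` (set ``force`` to
    upscale whenever the smaller side is short). Aspect ratio is preserved;
    the longer side rounds half up. Larger images pass through unchanged.
    """
    img = np.asarray(img, dtype=float)
    if min_side < 1:
        raise ValueError("min_side must be >= 1")
    a, b = img.shape
    below = (a < min_side and b < min_side) or (force and min(a, b) < min_side)
    if not below:
        return img
    scale = min_side / min(a, b)
    new_a = min_side if a <= b else int(math.floor(a * scale + 0.5))
    new_b = min_side if b <= a else int(math.floor(b * scale + 0.5))
    out = _sk_resize(img, (new_a, new_b), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.asarray(out, dtype=float)
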