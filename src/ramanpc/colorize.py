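"""Pseudo-color mapping of grayscale images (Jet lookup)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["jet_colorize", "jet_lut", "COLORMAPS", "colorize"]

_LUT_PATH = Path(__file__).parent / "data" / "jet_lut.csv"


def _jet_channels(v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # piecewise-linear jet ramp: blue -> cyan -> green -> yellow -> red
    r = np.clip(np.minimum(4 * v - 1.5, -4 * v + 4.5), 0.0, 1.0)
    g = np.clip(np.minimum(4 * v - 0.5, -4 * v + 3.5), 0.0, 1.0)
    b = np.clip(np.minimum(4 * v + 0.5, -4 * v + 2.5), 0.0, 1.0)
    return r, g, b


def jet_colorize(img: np.ndarray) -> np.ndarray:
    """Map gray [0, 255] to uint8 RGB. gray 0 -> (0,0,128), 255 -> (128,0,0)."""
    v = np.asarray(img, dtype=float) / 255.0
    rgb = np.stack(_jet_channels(v), axis=-1)
    return np.round(255.0 * rgb).astype(np.uint8)


def jet_lut() -> np.ndarray:
    """The full 256 x 3 uint8 lookup table generated from the jet formula."""
    return jet_colorize(np.arange(256, dtype=float))


def load_lut_fixture() -> np.ndarray:
    """The committed 256-entry LUT (bit-exactness reference)."""
    return np.loadtxt(_LUT_PATH, delimiter=",", dtype=np.uint8, skiprows=1)


COLORMAPS = {"jet": jet_colorize}


def colorize(img: np.ndarray, colormap: str = "jet") -> np.ndarray:
    try:
        fn = COLORMAPS[colormap]
    except KeyError:
        raise ValueError(f"unknown colormap {colormap!r}; "
                         f"available: {sorted(COLORMAPS)}") from None
    return fn(img)
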