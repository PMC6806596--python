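"""Band-limited peak-intensity images and per-point band-variance maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import BandWindow, SpectralScan

__all__ = [
    "VarianceMap",
    "extract_peak_image",
    "normalize_gray",
    "band_variance_map",
    "full_band",
]


@dataclass
class VarianceMap:
    """Per-scan-point population variance of in-band intensities.

    ``n_above`` counts points whose variance strictly exceeds ``threshold``.
    """

    values: np.ndarray
    threshold: float = 1000.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("variances must be non-negative")

    @property
    def n_above(self) -> int:
        return int(np.count_nonzero(self.values > self.threshold))


def full_band(scan: SpectralScan) -> BandWindow:
    """Window covering the entire wavenumber axis."""
    return BandWindow(float(scan.wavenumbers[0]), float(scan.wavenumbers[-1]))


def _band_columns(scan: SpectralScan, band: BandWindow) -> np.ndarray:
    cols = np.nonzero(band.mask(scan.wavenumbers))[0]
    if cols.size == 0:
        raise ValueError(
            f"band [{band.lo}, {band.hi}] does not intersect the wavenumber axis "
            f"[{scan.wavenumbers[0]}, {scan.wavenumbers[-1]}]"
        )
    return cols


def extract_peak_image(scan: SpectralScan, band: BandWindow, n_sym: int = 0) -> np.ndarray:
    """Per-point band-restricted peak intensity, arranged on the scan grid.

    With ``n_sym == 0`` the pixel is the in-band maximum. With
    ``n_sym in {4, 8, 12}`` it is the mean of the peak sample and its
    ``n_sym`` symmetric neighbors (``n_sym/2`` per side, clipped to the band
    edges). Peak ties resolve to the lowest-wavenumber maximal channel.
    Returns raw (un-normalized) intensities as a float (rows, cols) array.
    """
    if scan.repeats != 1:
        raise ValueError("average repeats before peak extraction")
    if n_sym not in (0, 4, 8, 12):
        raise ValueError(f"n_sym must be one of 0, 4, 8, 12; got {n_sym}")
    cols = _band_columns(scan, band)
    sub = scan.intensities[:, cols]  # (points, band channels)
    peak_idx = np.argmax(sub, axis=1)  # first maximum on ties
    if n_sym == 0:
        values = sub[np.arange(sub.shape[0]), peak_idx]
    else:
        half = n_sym // 2
        values = np.empty(sub.shape[0])
        for p, k in enumerate(peak_idx):
            lo = max(0, k - half)
            hi = min(sub.shape[1], k + half + 1)
            values[p] = sub[p, lo:hi].mean()
    return values.reshape(scan.grid_rows, scan.grid_cols)


def normalize_gray(img: np.ndarray) -> np.ndarray:
    """Affine stretch to [0, 255]; a constant image maps to all zeros."""
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("non-finite pixel values")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    # divide-then-scale so the extremes land on exactly 0 and 255
    return (img - lo) / (hi - lo) * 255.0


def band_variance_map(
    scan: SpectralScan, band: BandWindow, threshold: float = 1000.0
) -> VarianceMap:
    """Population variance of in-band intensities at each scan point."""
    if scan.repeats != 1:
        raise ValueError("average repeats before computing variances")
    cols = _band_columns(scan, band)
    if cols.size < 2:
        raise ValueError("need at least 2 channels in band for a variance")
    sub = scan.intensities[:, cols]
    var = sub.var(axis=1)  # population variance (ddof=0)
    return VarianceMap(values=var.reshape(scan.grid_rows, scan.grid_cols),
                       threshold=threshold)
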