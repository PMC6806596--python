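"""Synthetic point-scan Raman scenes with ground truth.

Emulates the relevant features of instrument exports: a small rectangular
scan grid, ~1024 wavenumber channels over 155-3926 cm^-1, cell-shaped
regions with an elevated band-localized peak (CH-stretch region by default),
a broad fluorescence-like baseline, Gaussian read noise, signal-dependent
shot noise (Gaussian approximation), occasional positive salt spikes, and
two repeated scans per point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_io import SpectralScan

__all__ = ["Ellipse", "PhantomSpec", "generate_phantom", "default_spec"]


@dataclass(frozen=True)
class Ellipse:
    """Cell footprint on the scan grid, in grid units."""

    center_row: float
    center_col: float
    semi_row: float
    semi_col: float

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return (
            ((rows - self.center_row) / self.semi_row) ** 2
            + ((cols - self.center_col) / self.semi_col) ** 2
        ) <= 1.0


@dataclass
class PhantomSpec:
    grid_rows: int = 20
    grid_cols: int = 20
    n_channels: int = 1024
    wavenumber_lo: float = 155.0
    wavenumber_hi: float = 3926.0
    cells: list[Ellipse] = field(default_factory=list)
    peak_center: float = 2930.0
    peak_width: float = 25.0
    peak_amp_inside: float = 1200.0
    peak_amp_outside: float = 150.0
    baseline_scale: float = 300.0
    gauss_sigma: float = 20.0
    shot_scale: float = 0.5
    salt_prob: float = 0.02
    salt_amp: float = 6000.0
    repeats: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1 or self.repeats < 1:
            raise ValueError("grid dims and repeats must be positive")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if not self.wavenumber_lo < self.wavenumber_hi:
            raise ValueError("wavenumber_lo must be < wavenumber_hi")
        if not 0.0 <= self.salt_prob <= 1.0:
            raise ValueError("salt_prob must be a probability")
        for name in ("peak_amp_inside", "peak_amp_outside", "baseline_scale",
                     "gauss_sigma", "shot_scale", "salt_amp", "peak_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for e in self.cells:
            if min(e.semi_row, e.semi_col) <= 0:
                raise ValueError("ellipse semi-axes must be positive")
            if (e.center_row - e.semi_row < 0
                    or e.center_row + e.semi_row > self.grid_rows - 1
                    or e.center_col - e.semi_col < 0
                    or e.center_col + e.semi_col > self.grid_cols - 1):
                raise ValueError("ellipse extends outside the scan grid")


def default_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """The stock 20x20, two-repeat phantom with a single elliptical cell.

    The cell scales with any grid-size override unless cells are given
    explicitly.
    """
    rows = overrides.get("grid_rows", 20)
    cols = overrides.get("grid_cols", 20)
    params = dict(
        cells=[Ellipse(center_row=(rows - 1) / 2.0, center_col=(cols - 1) / 2.0,
                       semi_row=0.275 * rows, semi_col=0.35 * cols)],
        seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def cell_mask(spec: PhantomSpec) -> np.ndarray:
    rows, cols = np.meshgrid(
        np.arange(spec.grid_rows), np.arange(spec.grid_cols), indexing="ij"
    )
    mask = np.zeros((spec.grid_rows, spec.grid_cols), dtype=bool)
    for ellipse in spec.cells:
        mask |= ellipse.contains(rows, cols)
    return mask


def generate_phantom(spec: PhantomSpec) -> tuple[SpectralScan, np.ndarray]:
    """Render the scene. Returns the scan and the binary cell mask.

    Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    wn = np.linspace(spec.wavenumber_lo, spec.wavenumber_hi, spec.n_channels)
    t = (wn - spec.wavenumber_lo) / (spec.wavenumber_hi - spec.wavenumber_lo)
    baseline = spec.baseline_scale * (1.1 - 0.9 * t + 0.45 * t * t)
    peak_shape = np.exp(-0.5 * ((wn - spec.peak_center) / max(spec.peak_width, 1e-9)) ** 2)
    mask = cell_mask(spec)

    n_points = spec.grid_rows * spec.grid_cols
    spectra = np.empty((n_points * spec.repeats, spec.n_channels))
    flat_mask = mask.ravel()
    row = 0
    for point in range(n_points):
        amp = spec.peak_amp_inside if flat_mask[point] else spec.peak_amp_outside
        clean = baseline + amp * peak_shape
        for _ in range(spec.repeats):
            noisy = clean.copy()
            if spec.gauss_sigma > 0:
                noisy = noisy + rng.normal(0.0, spec.gauss_sigma, spec.n_channels)
            if spec.shot_scale > 0:
                shot_sd = spec.shot_scale * np.sqrt(np.maximum(clean, 0.0))
                noisy = noisy + rng.normal(0.0, 1.0, spec.n_channels) * shot_sd
            if spec.salt_prob > 0 and rng.random() < spec.salt_prob:
                noisy[rng.integers(spec.n_channels)] += spec.salt_amp
            spectra[row] = np.maximum(noisy, 0.0)
            row += 1

    scan = SpectralScan(
        wavenumbers=wn,
        intensities=spectra,
        grid_rows=spec.grid_rows,
        grid_cols=spec.grid_cols,
        repeats=spec.repeats,
    )
    return scan, mask
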