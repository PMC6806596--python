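"""Point-scan spectral I/O.

File dialect: delimited UTF-8 text (tab or comma). Row 1 is the wavenumber
axis (cm^-1, strictly increasing); every following row is one spectrum.
Spectra are stored row-major over the scan grid, with all repeats of a point
on consecutive rows. Grid geometry and the repeat count are *not* embedded in
the file; they are supplied by the caller (CLI: ``--grid RxC --repeats K``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpectralScan",
    "BandWindow",
    "ScanFormatError",
    "ScanGeometryError",
    "read_scan",
    "write_scan",
    "average_repeats",
]


class ScanFormatError(ValueError):
    """Malformed spectral file (ragged rows, non-numeric cells, ...)."""


class ScanGeometryError(ValueError):
    """Row count inconsistent with the declared grid geometry."""


@dataclass(frozen=True)
class BandWindow:
    """Closed wavenumber interval [lo, hi] in cm^-1."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band requires lo < hi, got [{self.lo}, {self.hi}]")

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Boolean mask of axis channels falling inside the window."""
        return (wavenumbers >= self.lo) & (wavenumbers <= self.hi)


@dataclass
class SpectralScan:
    """Grid-organized point-scan Raman spectra.

    ``intensities`` has one row per (point, repeat) in row-major scan order
    with repeats consecutive, and one column per wavenumber channel.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    grid_rows: int
    grid_cols: int
    repeats: int = 1
    scan_order: str = field(default="row_major")

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.scan_order != "row_major":
            raise ValueError(f"unsupported scan order: {self.scan_order!r}")
        if self.grid_rows < 1 or self.grid_cols < 1 or self.repeats < 1:
            raise ValueError("grid dims and repeat count must be positive")
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 2:
            raise ScanFormatError("wavenumbers must be 1-D, intensities 2-D")
        n_expected = self.grid_rows * self.grid_cols * self.repeats
        if self.intensities.shape[0] != n_expected:
            raise ScanGeometryError(
                f"{self.intensities.shape[0]} spectra for a "
                f"{self.grid_rows}x{self.grid_cols} grid with "
                f"{self.repeats} repeat(s); expected {n_expected}"
            )
        if self.intensities.shape[1] != self.wavenumbers.size:
            raise ScanFormatError(
                f"{self.intensities.shape[1]} channels per spectrum but "
                f"{self.wavenumbers.size} wavenumbers"
            )
        if self.wavenumbers.size == 0:
            raise ScanFormatError("empty wavenumber axis")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ScanFormatError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ScanFormatError("non-finite intensity values")

    @property
    def n_points(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def n_channels(self) -> int:
        return int(self.wavenumbers.size)

    def point_spectra(self) -> np.ndarray:
        """Intensities reshaped to (points, repeats, channels)."""
        return self.intensities.reshape(self.n_points, self.repeats, -1)


def _parse_rows(path: Path) -> list[np.ndarray]:
    rows: list[np.ndarray] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            sep = "\t" if "\t" in line else ","
            cells = [c for c in line.split(sep) if c != ""]
            try:
                rows.append(np.array([float(c) for c in cells]))
            except ValueError as exc:
                raise ScanFormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    return rows


def read_scan(path, grid_rows: int, grid_cols: int, repeats: int = 1) -> SpectralScan:
    """Read the TSV/CSV dialect and validate against the declared geometry."""
    path = Path(path)
    rows = _parse_rows(path)
    if not rows:
        raise ScanFormatError(f"{path}: empty file")
    wavenumbers = rows[0]
    n_chan = wavenumbers.size
    for i, row in enumerate(rows[1:], start=2):
        if row.size != n_chan:
            raise ScanFormatError(
                f"{path}:{i}: row has {row.size} values, header has {n_chan}"
            )
    intensities = np.vstack(rows[1:]) if len(rows) > 1 else np.empty((0, n_chan))
    return SpectralScan(
        wavenumbers=wavenumbers,
        intensities=intensities,
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        repeats=repeats,
    )


def write_scan(scan: SpectralScan, path) -> None:
    """Write a scan in the TSV dialect. Round-trips through read_scan."""
    if scan.intensities.shape[0] == 0:
        raise ValueError("refusing to write a scan with zero spectra")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(repr(float(w)) for w in scan.wavenumbers) + "\n")
        for row in scan.intensities:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def average_repeats(scan: SpectralScan) -> SpectralScan:
    """Arithmetic mean over each point's repeated spectra (repeats -> 1)."""
    if scan.repeats == 1:
        return scan
    averaged = scan.point_spectra().mean(axis=1)
    return SpectralScan(
        wavenumbers=scan.wavenumbers.copy(),
        intensities=averaged,
        grid_rows=scan.grid_rows,
        grid_cols=scan.grid_cols,
        repeats=1,
    )
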