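"""Self-guided edge-preserving filtering with adaptively chosen parameters.

The filter assumes the output is locally an affine function of the guide
(here the input itself): per window k, ``a_k = var/(var + eps)`` and
``b_k = (1 - a_k) * mean``, and each pixel averages the coefficients of every
window that covers it. Window size ``|w|`` and the penalty ``eps`` come from
a linear model in (N1, N2, sigma2): total scan points, points whose band
variance exceeds a threshold, and a scalar band-variance summary. The model
is fitted by ordinary least squares; a published coefficient matrix is
shipped as the default.

Scale convention: the fitted model produces eps in squared gray levels on
the 0..255 range; the filter itself works on pixels normalized to [0, 1], so
the model output is divided by 255**2 (and floored at 1e-4) before use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .peak_image import VarianceMap

__all__ = [
    "GuidedFilterParams",
    "AdaptiveCoefficients",
    "FitDataset",
    "PUBLISHED_COEFFICIENTS",
    "EPS_FLOOR",
    "guided_filter",
    "adaptive_params",
    "fit_coefficients",
    "summarize_sigma2",
]

#: Minimum regularization on the [0,1] gray scale.
EPS_FLOOR = 1e-4

#: Conversion between eps in (0..255)^2 units and the [0,1]^2 scale.
_GRAY_SCALE_SQ = 255.0**2


def _window_width(omega: float) -> int:
    """Odd window width nearest to round(omega), floored at 3."""
    w = int(np.floor(omega + 0.5))
    if w % 2 == 0:
        w = w + 1 if (omega - (w - 1)) >= ((w + 1) - omega) else w - 1
    return max(w, 3)


@dataclass(frozen=True)
class GuidedFilterParams:
    """Window-size / regularization pair for the guided filter.

    ``omega`` is the (real-valued) model output for the window size;
    ``eps`` the regularization on the [0,1] gray scale; ``eps_raw`` the
    un-rescaled model output when the pair came from the adaptive model.
    """

    omega: float
    eps: float
    eps_raw: float | None = None

    def __post_init__(self) -> None:
        if not self.eps > 0:
            raise ValueError("eps must be positive")

    @property
    def width(self) -> int:
        return _window_width(self.omega)

    @property
    def r(self) -> int:
        return self.width // 2

    @classmethod
    def from_radius(cls, r: int, eps: float) -> "GuidedFilterParams":
        if r < 1:
            raise ValueError("radius must be >= 1")
        return cls(omega=float(2 * r + 1), eps=eps)


@dataclass(frozen=True)
class AdaptiveCoefficients:
    """The 8 linear-model coefficients: (a,b,c,d) for |w| and for eps."""

    a1: float
    b1: float
    c1: float
    d1: float
    a2: float
    b2: float
    c2: float
    d2: float

    def predict(self, n1: float, n2: float, sigma2: float) -> tuple[float, float]:
        """Raw (omega, eps) pair; eps in squared 0..255 gray units."""
        omega = self.a1 * n1 + self.b1 * n2 + self.c1 * sigma2 + self.d1
        eps = self.a2 * n1 + self.b2 * n2 + self.c2 * sigma2 + self.d2
        return omega, eps


#: Published coefficient matrix of the adaptive model (default).
PUBLISHED_COEFFICIENTS = AdaptiveCoefficients(
    a1=0.0113, b1=-0.0056, c1=0.0001, d1=3.1181,
    a2=-0.0797, b2=0.1210, c2=-0.0001, d2=44.2304,
)


@dataclass
class FitDataset:
    """Observations for fitting the adaptive model.

    Columns: N1 (total scan points), N2 (variance-above-threshold count),
    sigma2 (band-variance summary), and the parameter pair actually used.
    """

    n1: np.ndarray
    n2: np.ndarray
    sigma2: np.ndarray
    omega: np.ndarray
    eps: np.ndarray

    def __post_init__(self) -> None:
        cols = [np.asarray(getattr(self, f), dtype=float).ravel()
                for f in ("n1", "n2", "sigma2", "omega", "eps")]
        n = cols[0].size
        if any(c.size != n for c in cols):
            raise ValueError("all columns must have equal length")
        if np.any(cols[1] > cols[0]):
            raise ValueError("N2 cannot exceed N1")
        self.n1, self.n2, self.sigma2, self.omega, self.eps = cols

    def __len__(self) -> int:
        return self.n1.size

    @classmethod
    def from_rows(cls, rows) -> "FitDataset":
        arr = np.asarray(rows, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 5:
            raise ValueError("expected rows of (N1, N2, sigma2, omega, eps)")
        return cls(*(arr[:, i] for i in range(5)))


def _box_sum(x: np.ndarray, r: int) -> np.ndarray:
    """Sum over (2r+1)^2 windows, shrunk at the borders, via running sums."""
    m, n = x.shape
    c = np.zeros((m + 1, n))
    np.cumsum(x, axis=0, out=c[1:])
    rows = np.arange(m)
    part = c[np.minimum(rows + r, m - 1) + 1] - c[np.maximum(rows - r, 0)]
    c2 = np.zeros((m, n + 1))
    np.cumsum(part, axis=1, out=c2[:, 1:])
    cols = np.arange(n)
    return c2[:, np.minimum(cols + r, n - 1) + 1] - c2[:, np.maximum(cols - r, 0)]


def _window_counts(m: int, n: int, r: int) -> np.ndarray:
    rows = np.minimum(np.arange(m) + r, m - 1) - np.maximum(np.arange(m) - r, 0) + 1
    cols = np.minimum(np.arange(n) + r, n - 1) - np.maximum(np.arange(n) - r, 0) + 1
    return rows[:, None] * cols[None, :].astype(float)


def guided_filter(p: np.ndarray, params: GuidedFilterParams) -> np.ndarray:
    """Self-guided filter of a grayscale image in [0, 255].

    Border windows shrink to the valid pixels. Output stays within
    [min(p), max(p)] (each window estimate is a convex combination).
    For RGB inputs apply per channel.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim == 3:
        return np.dstack([guided_filter(p[..., c], params) for c in range(p.shape[2])])
    r, eps = params.r, params.eps
    if min(p.shape) < 2 * r + 1:
        raise ValueError(f"image {p.shape} smaller than the {2*r+1}x{2*r+1} window")
    x = p / 255.0
    cnt = _window_counts(*x.shape, r)
    mean = _box_sum(x, r) / cnt
    var = _box_sum(x * x, r) / cnt - mean * mean
    np.clip(var, 0.0, None, out=var)
    a = var / (var + eps)
    b = (1.0 - a) * mean
    q = (_box_sum(a, r) / cnt) * x + _box_sum(b, r) / cnt
    return q * 255.0


def adaptive_params(
    n1: int,
    n2: int,
    sigma2: float,
    coef: AdaptiveCoefficients = PUBLISHED_COEFFICIENTS,
) -> GuidedFilterParams:
    """Evaluate the linear model and package the filter parameters."""
    if n1 < 1:
        raise ValueError("N1 must be >= 1")
    if not 0 <= n2 <= n1:
        raise ValueError("need 0 <= N2 <= N1")
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    omega, eps_raw = coef.predict(n1, n2, sigma2)
    eps = max(eps_raw / _GRAY_SCALE_SQ, EPS_FLOOR)
    return GuidedFilterParams(omega=omega, eps=eps, eps_raw=eps_raw)


def fit_coefficients(data: FitDataset) -> AdaptiveCoefficients:
    """Least-squares fit of the 8 model coefficients.

    Solves the two independent linear systems with design [N1, N2, sigma2, 1].
    Rank-deficient designs fall back to the minimum-norm solution with a
    warning. Noise-free consistent data is recovered exactly.
    """
    if len(data) < 4:
        raise ValueError(f"need >= 4 rows to fit 4 coefficients, got {len(data)}")
    design = np.column_stack([data.n1, data.n2, data.sigma2,
                              np.ones(len(data))])
    targets = np.column_stack([data.omega, data.eps])
    sol, _, rank, _ = np.linalg.lstsq(design, targets, rcond=None)
    if rank < 4:
        warnings.warn(
            f"design matrix has rank {rank} < 4; returning the minimum-norm fit",
            stacklevel=2,
        )
    (a1, a2), (b1, b2), (c1, c2), (d1, d2) = sol
    return AdaptiveCoefficients(a1=a1, b1=b1, c1=c1, d1=d1,
                                a2=a2, b2=b2, c2=c2, d2=d2)


def summarize_sigma2(vm: VarianceMap, mode: str = "mean") -> float:
    """Collapse a variance map to the model's scalar sigma2."""
    v = np.asarray(vm.values, dtype=float)
    if v.size == 0:
        raise ValueError("empty variance map")
    if mode == "mean":
        return float(v.mean())
    if mode == "median":
        return float(np.median(v))
    if mode == "max":
        return float(v.max())
    raise ValueError(f"unknown sigma2 summary mode: {mode!r}")
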