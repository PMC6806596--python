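"""Independent brute-force reference implementations used by the tests.

These are deliberately literal per-pixel/per-window loops, kept separate
from the package's vectorized code paths.
"""

import math

import numpy as np


def retinex_oracle(img):
    """Literal loop version of the iterative ratio-reset enhancement.

    Per pass, each pixel looks at the partner ``step`` ahead and then the
    partner ``step`` behind along the axis; the partner's luminance plus the
    own/partner log brightness ratio, capped at the global log maximum, is
    averaged into the pixel's estimate (simultaneous update per direction).
    """
    img = np.asarray(img, dtype=float)
    m, n = img.shape
    d = [[1.0 if img[i][j] == 0 else float(img[i][j]) for j in range(n)]
         for i in range(m)]
    p = max(max(row) for row in d)
    const = math.log10(p)
    lum = [[const for _ in range(n)] for _ in range(m)]

    def one_direction(step, axis, sign):
        old = [row[:] for row in lum]
        for i in range(m):
            for j in range(n):
                pi = i + sign * step if axis == 0 else i
                pj = j + sign * step if axis == 1 else j
                if not (0 <= pi < m and 0 <= pj < n):
                    continue
                cand = old[pi][pj] + math.log10(d[i][j] / d[pi][pj])
                if cand > const:
                    cand = const
                lum[i][j] = 0.5 * (old[i][j] + cand)

    h, theta = m // 2, n // 2
    while True:
        if h < m:
            one_direction(h, 0, +1)
            one_direction(h, 0, -1)
        if theta < n:
            one_direction(theta, 1, +1)
            one_direction(theta, 1, -1)
        if h == 1 and theta == 1:
            break
        h = max(h // 2, 1)
        theta = max(theta // 2, 1)
    flat = [v for row in lum for v in row]
    lo, hi = min(flat), max(flat)
    if hi == lo:
        return np.zeros((m, n))
    return (np.array(lum) - lo) / (hi - lo) * 255.0


def guided_filter_oracle(p, r, eps):
    """Literal double-loop self-guided filter with shrinking border windows.

    Operates on [0,255] input normalized internally to [0,1], like the
    implementation under test.
    """
    x = np.asarray(p, dtype=float) / 255.0
    m, n = x.shape
    a = np.zeros((m, n))
    b = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            win = x[max(0, i - r):i + r + 1, max(0, j - r):j + r + 1]
            mu = win.mean()
            var = (win * win).mean() - mu * mu
            a[i, j] = var / (var + eps)
            b[i, j] = (1.0 - a[i, j]) * mu
    q = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            abar = a[max(0, i - r):i + r + 1, max(0, j - r):j + r + 1].mean()
            bbar = b[max(0, i - r):i + r + 1, max(0, j - r):j + r + 1].mean()
            q[i, j] = abar * x[i, j] + bbar
    return q * 255.0
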