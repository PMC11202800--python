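"""Independent, deliberately simple sifting routine used as a
cross-check oracle for the package's EMD.

Coded separately from ecpdh.emd with different policies on purpose:
extrema are found by a plain three-point comparison (no plateau
handling), envelopes are cubic splines anchored at the signal endpoints
instead of mirror-extended, and each mode is sifted a fixed number of
times with no convergence criterion. Agreement with the package is
therefore expected to be loose (EMD variants differ mostly at the
boundaries), which is exactly what the comparison tests assert.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


def _naive_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    maxima = [i for i in range(1, x.size - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]]
    minima = [i for i in range(1, x.size - 1) if x[i] < x[i - 1] and x[i] < x[i + 1]]
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def _anchored_envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    knots_x = np.concatenate([[0], idx, [x.size - 1]])
    knots_x, keep = np.unique(knots_x, return_index=True)
    knots_y = np.concatenate([[x[0]], x[idx], [x[-1]]])[keep]
    t = np.arange(x.size, dtype=float)
    if knots_x.size < 2:
        return np.full(x.size, x[0], dtype=float)
    if knots_x.size < 4:
        return np.interp(t, knots_x, knots_y)
    return CubicSpline(knots_x, knots_y)(t)


def naive_emd(signal: np.ndarray, max_imfs: int = 3, n_sift: int = 8):
    """Fixed-iteration sifting with endpoint-anchored spline envelopes."""
    residual = np.asarray(signal, dtype=float).copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        maxima, minima = _naive_extrema(residual)
        if maxima.size < 1 or minima.size < 1:
            break
        h = residual.copy()
        for _ in range(n_sift):
            ma, mi = _naive_extrema(h)
            if ma.size < 1 or mi.size < 1:
                break
            mean = 0.5 * (_anchored_envelope(h, ma) + _anchored_envelope(h, mi))
            h = h - mean
        imfs.append(h)
        residual = residual - h
    return imfs, residual
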