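"""Empirical mode decomposition (EMD) of short per-residue signals.

Each residue contributes four short "digital signals" (the bound,
unbound and delta solvent-accessibility blocks and the
secondary-structure block). Sifting splits a signal into intrinsic mode
functions (IMFs) — components whose extrema and zero-crossing counts
differ by at most one and whose local envelope mean is near zero — plus
a monotone-ish residual trend. Four statistics of each retained IMF
(mean, unbiased variance, energy, lag-m autocorrelation) form the EMD
feature block.

Signals here are very short (6-8 samples), so boundary policy dominates:
envelopes are cubic splines through the interior extrema after
mirror-extending up to two extrema at each end. Sifting of one mode
stops on a Cauchy-style relative-change criterion (threshold 0.2) with a
hard iteration cap; decomposition stops when the residual has too few
interior extrema or is monotone, or after ``max_imfs`` modes.

All of this is deterministic: no randomness enters the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .datamodel import ResidueRecord
from .errors import InvalidInputError, SchemaError
from .schema import EMD_STATS, emd_names

#: relative envelope-mean tolerance used by :func:`is_imf`
IMF_ENVELOPE_TOL = 0.25


@dataclass(frozen=True)
class EMDConfig:
    """Sifting parameters.

    max_imfs: number of modes retained (the feature block uses the first
    three). sd_threshold: Cauchy stopping threshold on the normalised
    squared change between sifting iterations. max_sift_iterations: hard
    cap per mode. min_extrema: minimum interior extrema for the residual
    to be decomposed further. boundary: only mirror extension is
    implemented.
    """

    max_imfs: int = 3
    sd_threshold: float = 0.2
    max_sift_iterations: int = 10
    boundary: str = "mirror"
    min_extrema: int = 2
    autocorr_lag: int = 1

    def __post_init__(self) -> None:
        if self.max_imfs < 1:
            raise InvalidInputError("max_imfs must be >= 1")
        if self.sd_threshold <= 0:
            raise InvalidInputError("sd_threshold must be > 0")
        if self.boundary != "mirror":
            raise InvalidInputError("only 'mirror' boundary handling is implemented")


@dataclass
class IMFSet:
    """Ordered IMFs plus the residual from sifting one signal."""

    imfs: list[np.ndarray]
    residual: np.ndarray

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out = out + imf
        return out


@dataclass(frozen=True)
class IMFStats:
    """Mean, unbiased variance, energy and lag-m autocorrelation of one IMF."""

    mean: float
    variance: float
    energy: float
    autocorr: float

    def as_dict(self) -> dict:
        return {
            "meanValue": self.mean,
            "variance": self.variance,
            "energy": self.energy,
            "autocorr": self.autocorr,
        }


def find_extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior maxima and minima.

    A plateau bounded by strictly lower (higher) samples counts once, at
    the midpoint index rounded down. Endpoints are never extrema.
    Signals shorter than 3 samples have no interior and yield empty sets.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    maxima: list[int] = []
    minima: list[int] = []
    i = 1
    while i < n - 1:
        if x[i] == x[i - 1]:
            i += 1
            continue
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1  # plateau [i, j]
        if j == n - 1:
            break  # plateau runs into the right endpoint
        mid = (i + j) // 2
        if x[i] > x[i - 1] and x[i] > x[j + 1]:
            maxima.append(mid)
        elif x[i] < x[i - 1] and x[i] < x[j + 1]:
            minima.append(mid)
        i = j + 1
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def count_zero_crossings(signal: np.ndarray) -> int:
    """Sign changes along the signal; exact zeros are transparent."""
    s = np.sign(np.asarray(signal, dtype=float))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[:-1] != s[1:]))


class NotEnoughExtrema(Exception):
    """Raised when a signal has too few extrema to build envelopes."""


def _mirror_knots(idx: np.ndarray, vals: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to two extrema of one kind across each endpoint."""
    left_x = [-int(i) for i in idx[:2]][::-1]
    left_y = list(vals[:2])[::-1]
    right_x = [2 * (n - 1) - int(i) for i in idx[-2:]][::-1]
    right_y = list(vals[-2:])[::-1]
    xs = np.array(left_x + list(idx) + right_x, dtype=float)
    ys = np.array(left_y + list(vals) + right_y, dtype=float)
    keep = np.concatenate([[True], np.diff(xs) > 0])
    return xs[keep], ys[keep]


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema ``idx`` after mirror extension."""
    n = x.size
    if idx.size < 1:
        raise NotEnoughExtrema("no extrema for envelope")
    xs, ys = _mirror_knots(idx, x[idx], n)
    if xs.size < 2:
        raise NotEnoughExtrema("fewer than 2 envelope knots after extension")
    t = np.arange(n, dtype=float)
    if xs.size == 2:
        return np.interp(t, xs, ys)
    bc = "not-a-knot" if xs.size >= 4 else "natural"
    return CubicSpline(xs, ys, bc_type=bc)(t)


def envelope_mean(
    signal: np.ndarray,
    maxima: np.ndarray | None = None,
    minima: np.ndarray | None = None,
) -> np.ndarray:
    """Pointwise mean of the upper and lower cubic-spline envelopes.

    Raises :class:`NotEnoughExtrema` when either envelope cannot be
    built (fewer than 2 knots after mirror extension), which the sifting
    loop treats as "stop decomposing".
    """
    x = np.asarray(signal, dtype=float)
    if maxima is None or minima is None:
        maxima, minima = find_extrema(x)
    upper = _envelope(x, np.asarray(maxima, dtype=int))
    lower = _envelope(x, np.asarray(minima, dtype=int))
    return 0.5 * (upper + lower)


def is_imf(seq: np.ndarray, tol: float = IMF_ENVELOPE_TOL) -> bool:
    """True iff the sequence satisfies the two IMF conditions: extrema
    and zero-crossing counts differ by at most one, and the envelope
    mean is small relative to the signal's half-range."""
    x = np.asarray(seq, dtype=float)
    maxima, minima = find_extrema(x)
    n_ext = maxima.size + minima.size
    if n_ext == 0:
        return False
    if abs(n_ext - count_zero_crossings(x)) > 1:
        return False
    amplitude = 0.5 * (x.max() - x.min())
    if amplitude == 0:
        return False
    try:
        m = envelope_mean(x, maxima, minima)
    except NotEnoughExtrema:
        return False
    return bool(np.max(np.abs(m)) <= tol * amplitude)


def _sift_one_mode(signal: np.ndarray, config: EMDConfig) -> np.ndarray | None:
    """Extract one certified IMF from ``signal``.

    Returns None when no candidate satisfying the IMF conditions emerges
    within the iteration cap; only certified modes are ever emitted, so
    the validity invariant holds by construction.
    """
    h = np.asarray(signal, dtype=float).copy()
    for _ in range(config.max_sift_iterations):
        maxima, minima = find_extrema(h)
        if maxima.size < 1 or minima.size < 1:
            return None
        try:
            m = envelope_mean(h, maxima, minima)
        except NotEnoughExtrema:
            return None
        prev = h
        h = h - m
        denom = float(np.sum(prev**2))
        sd = float(np.sum((prev - h) ** 2)) / denom if denom > 0 else 0.0
        if sd < config.sd_threshold and is_imf(h):
            return h
    return h if is_imf(h) else None


def sift(signal: np.ndarray, config: EMDConfig | None = None) -> IMFSet:
    """Full empirical mode decomposition of one signal.

    Decomposition is conservative by construction: the residual is the
    input minus the extracted IMFs, so IMFs + residual always reproduce
    the input exactly. Stops when ``max_imfs`` modes were extracted or
    the residual is monotone / has fewer than ``min_extrema`` interior
    extrema.
    """
    config = config or EMDConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError("signal must be one-dimensional")
    if x.size < 4:
        return IMFSet(imfs=[], residual=x.copy())
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(config.max_imfs):
        maxima, minima = find_extrema(residual)
        if maxima.size + minima.size < config.min_extrema:
            break
        imf = _sift_one_mode(residual, config)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
    return IMFSet(imfs=imfs, residual=residual)


def imf_stats(seq: np.ndarray, lag: int = 1) -> IMFStats:
    """The four per-IMF statistics.

    mean = (1/N) sum x_i; variance uses the N-1 denominator;
    energy = sum x_i^2; autocorrelation = sum_{i=0}^{N-1-lag} x_i x_{i+lag}
    (real signals, no wraparound).
    """
    x = np.asarray(seq, dtype=float)
    n = x.size
    if n < 2:
        raise InvalidInputError("variance needs at least 2 samples")
    if not 0 <= lag < n:
        raise InvalidInputError(f"lag must satisfy 0 <= lag < {n}, got {lag}")
    mean = float(np.mean(x))
    variance = float(np.sum((x - mean) ** 2) / (n - 1))
    energy = float(np.sum(x**2))
    autocorr = float(np.sum(x[: n - lag] * x[lag:])) if lag else energy
    return IMFStats(mean=mean, variance=variance, energy=energy, autocorr=autocorr)


# Per-group IMF/stat layout of the 43-entry EMD block: the three ASA
# groups carry 3 IMFs x 4 stats; the 6-sample secondary-structure block
# carries IMF1 (4 stats) and IMF2 (mean/variance/energy).
EMD_BLOCK_LAYOUT: dict[str, list[tuple[int, str]]] = {
    "ASA": [(k, s) for k in (1, 2, 3) for s in EMD_STATS],
    "u_ASA": [(k, s) for k in (1, 2, 3) for s in EMD_STATS],
    "d_ASA": [(k, s) for k in (1, 2, 3) for s in EMD_STATS],
    "dssp": [(1, s) for s in EMD_STATS]
    + [(2, s) for s in ("meanValue", "variance", "energy")],
}


def extract_emd_block(
    record: ResidueRecord, config: EMDConfig | None = None
) -> np.ndarray:
    """EMD feature block for one residue (default layout: 43 entries).

    Slots whose IMF was not produced (signal exhausted early) are filled
    with 0 so rows keep a fixed width.
    """
    config = config or EMDConfig()
    values: list[float] = []
    for group, layout in EMD_BLOCK_LAYOUT.items():
        decomposition = sift(record.signal(group), config)
        stats_by_imf: dict[int, dict] = {}
        for k, imf in enumerate(decomposition.imfs, start=1):
            stats_by_imf[k] = imf_stats(imf, lag=config.autocorr_lag).as_dict()
        for k, stat in layout:
            values.append(stats_by_imf.get(k, {}).get(stat, 0.0))
    out = np.asarray(values, dtype=float)
    expected = len(emd_names())
    if out.size != expected:
        raise SchemaError(f"EMD block has {out.size} entries, expected {expected}")
    return out
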