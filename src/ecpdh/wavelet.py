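"""Haar (db1) wavelet features of the four per-residue signal groups.

Two decompositions feed the feature block:

* a plain DWT cascade — repeated Haar analysis of the approximation
  branch down to level 3, giving approximation-band energies Ea(1..3)
  and the level-3 detail energy Ed;
* a level-3 wavelet-packet transform (WPT) — the full binary tree, both
  branches recursed, giving 8 leaf bands in natural order.

Per group the block holds 33 entries: Ea levels 1-3, their std and mean,
Ed, five entropies of the concatenated DWT coefficients, the total leaf
energy, 8 absolute leaf energies, five entropies of the concatenated WPT
leaves, and 8 relative leaf energies. Four groups give 132 features.

Haar is orthonormal, so energy is conserved at every split (Parseval);
relative leaf energies form a probability vector whenever the total
energy is positive, and are defined as 0 for an all-zero signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel import ResidueRecord
from .errors import InvalidInputError, SchemaError
from .schema import ENTROPY_KINDS, SIGNAL_GROUPS, wavelet_names

_SQRT2 = math.sqrt(2.0)

#: exponent of the "norm" entropy, sum |s_i|^p
NORM_ENTROPY_P = 1.5


@dataclass(frozen=True)
class WaveletConfig:
    wavelet: str = "db1"
    level: int = 3
    entropy_param: float = 0.2

    def __post_init__(self) -> None:
        if self.wavelet not in ("db1", "haar"):
            raise InvalidInputError("only the Haar/db1 wavelet is supported")
        if self.level < 1:
            raise InvalidInputError("level must be >= 1")
        if self.entropy_param <= 0:
            raise InvalidInputError("entropy_param must be > 0")


@dataclass
class WPTree:
    """Level-``level`` wavelet-packet leaves in natural (filter-bank) order."""

    leaves: list[np.ndarray]
    level: int

    @property
    def leaf_energies(self) -> np.ndarray:
        return np.array([float(np.sum(leaf**2)) for leaf in self.leaves])


def _pad_even(x: np.ndarray) -> np.ndarray:
    if x.size % 2:
        return np.concatenate([x, [0.0]])
    return x


def haar_step(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One orthonormal Haar analysis step.

    a_k = (x_{2k} + x_{2k+1})/sqrt(2), d_k = (x_{2k} - x_{2k+1})/sqrt(2).
    Odd-length inputs are zero-padded.
    """
    x = np.asarray(seq, dtype=float)
    if x.size == 0:
        raise InvalidInputError("empty input to haar_step")
    x = _pad_even(x)
    return (x[0::2] + x[1::2]) / _SQRT2, (x[0::2] - x[1::2]) / _SQRT2


def dwt_cascade(seq: np.ndarray, level: int = 3) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Haar DWT cascade: returns per-level approximations a_1..a_L and
    details d_1..d_L."""
    if level < 1:
        raise InvalidInputError("level must be >= 1")
    approxs: list[np.ndarray] = []
    details: list[np.ndarray] = []
    a = np.asarray(seq, dtype=float)
    for _ in range(level):
        a, d = haar_step(a)
        approxs.append(a)
        details.append(d)
    return approxs, details


def wpt_leaves(seq: np.ndarray, level: int = 3) -> WPTree:
    """Full wavelet-packet expansion: both branches of every node are
    split down to ``level``, yielding 2^level leaves in natural order.
    The input is zero-padded to the next multiple of 2^level."""
    if level < 1:
        raise InvalidInputError("level must be >= 1")
    x = np.asarray(seq, dtype=float)
    if x.size == 0:
        raise InvalidInputError("empty input to wpt_leaves")
    block = 2**level
    padded = block * math.ceil(x.size / block)
    if padded != x.size:
        x = np.concatenate([x, np.zeros(padded - x.size)])
    nodes = [x]
    for _ in range(level):
        nxt: list[np.ndarray] = []
        for node in nodes:
            a, d = haar_step(node)
            nxt.extend((a, d))
        nodes = nxt
    return WPTree(leaves=nodes, level=level)


def wavelet_entropy(coeffs: np.ndarray, kind: str, param: float = 0.2) -> float:
    """Classical wavelet-entropy family on a coefficient vector.

    shannon: -sum s^2 ln s^2 over nonzero coefficients; sure:
    N - #{|s| <= p} + sum min(s^2, p^2); threshold: #{|s| > p};
    norm: sum |s|^1.5; log_energy: sum ln s^2 over nonzero coefficients.
    """
    s = np.asarray(coeffs, dtype=float)
    if s.size == 0:
        raise InvalidInputError("empty coefficient vector")
    if kind == "shannon":
        sq = s[s != 0.0] ** 2
        return float(-np.sum(sq * np.log(sq))) if sq.size else 0.0
    if kind == "sure":
        return float(s.size - np.sum(np.abs(s) <= param) + np.sum(np.minimum(s**2, param**2)))
    if kind == "threshold":
        return float(np.sum(np.abs(s) > param))
    if kind == "norm":
        return float(np.sum(np.abs(s) ** NORM_ENTROPY_P))
    if kind == "log_energy":
        sq = s[s != 0.0] ** 2
        return float(np.sum(np.log(sq))) if sq.size else 0.0
    raise InvalidInputError(f"unknown entropy kind {kind!r}")


def _group_features(signal: np.ndarray, config: WaveletConfig) -> list[float]:
    level = config.level
    approxs, details = dwt_cascade(signal, level)
    ea = [float(np.sum(a**2)) for a in approxs]
    ed = float(np.sum(details[-1] ** 2))
    # full DWT coefficient vector: final approximation then details, coarse to fine
    dwt_coeffs = np.concatenate([approxs[-1]] + details[::-1])
    tree = wpt_leaves(signal, level)
    leaf_e = tree.leaf_energies
    total = float(leaf_e.sum())
    rel = leaf_e / total if total > 0 else np.zeros_like(leaf_e)
    wpt_coeffs = np.concatenate(tree.leaves)
    out = list(ea)
    out += [float(np.std(ea)), float(np.mean(ea)), ed]
    out += [wavelet_entropy(dwt_coeffs, k, config.entropy_param) for k in ENTROPY_KINDS]
    out.append(total)
    out += [float(v) for v in leaf_e]
    out += [wavelet_entropy(wpt_coeffs, k, config.entropy_param) for k in ENTROPY_KINDS]
    out += [float(v) for v in rel]
    return out


def extract_wavelet_block(
    record: ResidueRecord, config: WaveletConfig | None = None
) -> np.ndarray:
    """Wavelet feature block for one residue: 33 entries per signal
    group, groups concatenated in fixed order (132 at default level 3)."""
    config = config or WaveletConfig()
    values: list[float] = []
    for group in SIGNAL_GROUPS:
        values.extend(_group_features(record.signal(group), config))
    out = np.asarray(values, dtype=float)
    if config.level == 3 and out.size != len(wavelet_names()):
        raise SchemaError(
            f"wavelet block has {out.size} entries, expected {len(wavelet_names())}"
        )
    return out
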