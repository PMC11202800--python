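"""Synthetic residue tables with the statistical structure the pipeline
assumes.

Real inputs are manually curated mutation tables from thermodynamics
databases; none are deposited, so this generator emulates their shape:
rows grouped by complex, an imbalanced hot-spot fraction near
131/339 ~ 0.386, a ddG mixture that straddles the 1.0 kcal/mol hot-spot
threshold, and a small set of genuinely informative conventional
descriptors whose values shift with the class.

Signal blocks are low-order sinusoids plus noise so the EMD and wavelet
stages see oscillatory structure: short signals then yield one to three
intrinsic mode functions, which exercises the zero-fill rules for
absent modes. Class information enters the signal blocks only through
the informative slots, so feature-selection recovery experiments have a
well-defined ground truth.

The ddG value is drawn conditional on the class from truncated normals
(hot: mean 2.0, sd 0.8, truncated to >= 1.0; non-hot: mean 0.2, sd 0.4,
truncated to < 1.0), so the stored label always agrees with the label
implied by the ddG threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ResidueRecord
from .errors import InvalidInputError
from .schema import conventional_names

#: default class fraction: 131 hot spots of 339 mutation sites
DEFAULT_HOT_FRACTION = 131 / 339

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SynthSpec:
    n_complexes: int = 117
    residues_min: int = 2
    residues_max: int = 5
    hot_fraction: float = DEFAULT_HOT_FRACTION
    informative_slots: tuple[int, ...] = (0, 9, 17, 26, 34)
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.hot_fraction < 1:
            raise InvalidInputError("hot_fraction must lie in (0, 1)")
        if self.effect_size < 0:
            raise InvalidInputError("effect_size must be >= 0")
        if self.n_complexes < 1 or self.residues_min < 1:
            raise InvalidInputError("need at least one complex and one residue")
        if self.residues_max < self.residues_min:
            raise InvalidInputError("residues_max must be >= residues_min")
        names = conventional_names()
        if any(not 0 <= i < len(names) for i in self.informative_slots):
            raise InvalidInputError("informative slot index out of range")


def _truncated_normal(rng, mean, sd, low=None, high=None) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if (low is None or v >= low) and (high is None or v < high):
            return float(v)
    raise InvalidInputError("truncated normal rejection sampling failed")


def _smooth_signal(rng: np.random.Generator, length: int, noise_sd: float) -> np.ndarray:
    """Sum of one slow and one fast sinusoid with random phase/amplitude
    plus Gaussian noise: short signals with genuine oscillatory content."""
    t = np.arange(length, dtype=float)
    slow = rng.uniform(0.5, 2.0) * np.sin(2 * np.pi * t / length + rng.uniform(0, 2 * np.pi))
    fast = rng.uniform(0.3, 1.0) * np.sin(
        2 * np.pi * rng.integers(2, max(3, length // 2)) * t / length
        + rng.uniform(0, 2 * np.pi)
    )
    base = rng.normal(0.0, 2.0)
    return base + slow + fast + rng.normal(0.0, noise_sd, size=length)


def generate(spec: SynthSpec) -> list[ResidueRecord]:
    """Draw a full synthetic residue table, reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    records: list[ResidueRecord] = []
    n_conv = len(conventional_names())
    for c in range(spec.n_complexes):
        complex_id = f"SYN{c:04d}"
        n_res = int(rng.integers(spec.residues_min, spec.residues_max + 1))
        for r in range(n_res):
            hot = int(rng.random() < spec.hot_fraction)
            if hot:
                ddg = _truncated_normal(rng, 2.0, 0.8, low=1.0)
            else:
                ddg = _truncated_normal(rng, 0.2, 0.4, high=1.0)
            conv = np.empty(n_conv)
            blocks = {
                "asa_complex": _smooth_signal(rng, 8, spec.noise_sd),
                "asa_unbound": _smooth_signal(rng, 8, spec.noise_sd),
                "asa_delta": _smooth_signal(rng, 8, spec.noise_sd),
                "dssp": _smooth_signal(rng, 6, spec.noise_sd),
            }
            dpx_cx = rng.normal(0.0, 1.0, size=12)
            hbond = int(rng.poisson(2.0))
            # lay out the conventional vector, then add the class effect
            conv[0:8] = blocks["asa_complex"]
            conv[8:16] = blocks["asa_unbound"]
            conv[16:24] = blocks["asa_delta"]
            conv[24:30] = blocks["dssp"]
            conv[30:42] = dpx_cx
            conv[42] = hbond
            for slot in spec.informative_slots:
                conv[slot] += spec.effect_size * hot
            records.append(
                ResidueRecord(
                    complex_id=complex_id,
                    chain="A",
                    position=r + 1,
                    wild_aa=_AA[int(rng.integers(0, len(_AA)))],
                    asa_complex=conv[0:8],
                    asa_unbound=conv[8:16],
                    asa_delta=conv[16:24],
                    dssp=conv[24:30],
                    dpx_cx=conv[30:42],
                    hbond_count=hbond,
                    ddg=ddg,
                    label=hot,
                )
            )
    return records


def ground_truth(spec: SynthSpec) -> list[str]:
    """Names of the planted informative conventional columns."""
    names = conventional_names()
    return [names[i] for i in spec.informative_slots]
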