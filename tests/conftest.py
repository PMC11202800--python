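import numpy as np
import pytest

from ecpdh.datamodel import FeatureTable, ResidueRecord
from ecpdh.schema import FeatureSchema, build_default_schema


@pytest.fixture(scope="session")
def default_schema():
    return build_default_schema()


def make_record(seed: int = 0, **overrides) -> ResidueRecord:
    """A deterministic residue record with oscillatory signal blocks."""
    rng = np.random.default_rng(seed)

    def signal(length):
        t = np.arange(length, dtype=float)
        return (
            rng.normal(0, 2)
            + rng.uniform(0.5, 2) * np.sin(2 * np.pi * t / length + rng.uniform(0, 6))
            + rng.uniform(0.3, 1) * np.sin(2 * np.pi * 3 * t / length + rng.uniform(0, 6))
            + rng.normal(0, 0.3, size=length)
        )

    fields = dict(
        complex_id="1ABC",
        chain="A",
        position=12,
        wild_aa="R",
        asa_complex=signal(8),
        asa_unbound=signal(8),
        asa_delta=signal(8),
        dssp=signal(6),
        dpx_cx=rng.normal(size=12),
        hbond_count=2,
        ddg=1.7,
    )
    fields.update(overrides)
    return ResidueRecord(**fields)


@pytest.fixture
def record():
    return make_record(0)


def lies_on_minority_segment(row, minority, atol=1e-8):
    """True if ``row`` is a convex combination of some pair of minority
    rows (all-pairs scan)."""
    m = minority.shape[0]
    for i in range(m):
        base = minority[i]
        r = row - base
        if np.max(np.abs(r)) < atol:
            return True
        for j in range(m):
            if j == i:
                continue
            seg = minority[j] - base
            denom = float(np.dot(seg, seg))
            if denom == 0:
                continue
            t = float(np.dot(r, seg)) / denom
            if -1e-9 <= t <= 1 + 1e-9 and np.max(np.abs(base + t * seg - row)) < atol:
                return True
    return False


def planted_table(seed, n=300, d=50, n_planted=5, effect=1.0):
    """Feature table with the first ``n_planted`` columns shifted by
    ``effect`` standard deviations in the positive class."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = rng.integers(0, 2, n)
    X[:, :n_planted] += effect * y[:, None]
    names = [f"f{j:02d}" for j in range(d)]
    table = FeatureTable(
        FeatureSchema.from_names(names), X, y, np.array(["c"] * n, dtype=object)
    )
    return table, names[:n_planted]
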