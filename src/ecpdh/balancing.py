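"""Class rebalancing for the imbalanced hot-spot/non-hot-spot problem.

Hot spots are the minority class (about 102 vs 179 in a typical training
split). The default strategy is SMOTE-Tomek: synthesise minority samples
by interpolating between a minority point and one of its k nearest
minority neighbours until the classes are 1:1, then remove the
majority-class member of every Tomek link (a pair of opposite-class
mutual nearest neighbours) to clean the class boundary.

The SMOTE interpolation rule as sometimes printed,
``x_new = x + (x - xn) * u``, extrapolates away from the neighbour; the
conventional rule ``x_new = x + (xn - x) * u`` interpolates between the
pair. The conventional sign is the default; ``sign="printed"`` switches
to the other form for comparison.

Nearest neighbours use Euclidean distance on per-feature standardised
(z-scored) copies of the data; synthesis happens in the original feature
space. Balancing is meant to be applied to training folds only — the
cross-validation driver in :mod:`ecpdh.model_eval` enforces that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateDataError, InvalidInputError

DEFAULT_BALANCE_SEED = 74


@dataclass
class BalancedDataset:
    """Feature matrix + labels after resampling, with per-row provenance."""

    rows: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray  # "original" | "synthetic"
    seed: int

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.provenance = np.asarray(self.provenance, dtype=object)
        n = self.rows.shape[0]
        if self.labels.shape != (n,) or self.provenance.shape != (n,):
            raise InvalidInputError("labels/provenance length must equal row count")

    def class_counts(self) -> dict[int, int]:
        return {int(c): int(n) for c, n in zip(*np.unique(self.labels, return_counts=True))}


def smote_synthesize(
    x: np.ndarray, xn: np.ndarray, u: float, sign: str = "conventional"
) -> np.ndarray:
    """One synthetic sample on the line through ``x`` and neighbour ``xn``.

    conventional: x + (xn - x) * u (a convex combination for 0 < u < 1);
    printed: x + (x - xn) * u (extrapolates away from the neighbour).
    """
    x = np.asarray(x, dtype=float)
    xn = np.asarray(xn, dtype=float)
    if x.shape != xn.shape:
        raise InvalidInputError(f"width mismatch: {x.shape} vs {xn.shape}")
    if not 0.0 < u < 1.0:
        raise InvalidInputError("u must lie strictly in (0, 1)")
    if sign == "conventional":
        return x + (xn - x) * u
    if sign == "printed":
        return x + (x - xn) * u
    raise InvalidInputError(f"unknown sign {sign!r}")


def _standardize(rows: np.ndarray) -> np.ndarray:
    mu = rows.mean(axis=0)
    sd = rows.std(axis=0)
    sd[sd == 0] = 1.0
    return (rows - mu) / sd


def _minority_majority(labels: np.ndarray) -> tuple[int, int]:
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise DegenerateDataError("both classes must be present")
    order = np.argsort(counts, kind="stable")
    return int(classes[order[0]]), int(classes[order[-1]])


def smote(
    rows: np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 5,
    target_ratio: float = 1.0,
    seed: int = DEFAULT_BALANCE_SEED,
    sign: str = "conventional",
) -> BalancedDataset:
    """SMOTE oversampling of the minority class to
    minority/majority = ``target_ratio``.

    Each synthetic row interpolates a randomly chosen minority sample
    with one of its k nearest minority neighbours.
    """
    rows = np.asarray(rows, dtype=float)
    labels = np.asarray(labels, dtype=int)
    minority, majority = _minority_majority(labels)
    min_idx = np.flatnonzero(labels == minority)
    maj_idx = np.flatnonzero(labels == majority)
    if min_idx.size <= 1:
        raise DegenerateDataError("need more than one minority sample to interpolate")
    n_new = int(round(maj_idx.size * target_ratio)) - min_idx.size
    prov = np.array(["original"] * rows.shape[0], dtype=object)
    if n_new <= 0:
        return BalancedDataset(rows.copy(), labels.copy(), prov, seed)
    z = _standardize(rows)
    zmin = z[min_idx]
    k = min(k_neighbors, min_idx.size - 1)
    d = cdist(zmin, zmin)
    np.fill_diagonal(d, np.inf)
    neighbor_idx = np.argsort(d, axis=1, kind="stable")[:, :k]
    rng = np.random.default_rng(seed)
    base = rng.integers(0, min_idx.size, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    gaps = rng.uniform(0.0, 1.0, size=n_new)
    gaps[gaps == 0.0] = 0.5  # u must be strictly inside (0,1)
    synth = np.empty((n_new, rows.shape[1]))
    for t in range(n_new):
        i = base[t]
        j = neighbor_idx[i, pick[t]]
        synth[t] = smote_synthesize(
            rows[min_idx[i]], rows[min_idx[j]], float(gaps[t]), sign=sign
        )
    out_rows = np.vstack([rows, synth])
    out_labels = np.concatenate([labels, np.full(n_new, minority, dtype=int)])
    out_prov = np.concatenate([prov, np.array(["synthetic"] * n_new, dtype=object)])
    return BalancedDataset(out_rows, out_labels, out_prov, seed)


def tomek_links(rows: np.ndarray, labels: np.ndarray) -> set[tuple[int, int]]:
    """All Tomek links: pairs (i, j), i < j, of opposite-class points
    that are each other's single nearest neighbour (Euclidean on
    standardised features; ties broken by index order)."""
    rows = np.asarray(rows, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = rows.shape[0]
    if n < 2:
        raise InvalidInputError("need at least 2 rows")
    z = _standardize(rows)
    d = cdist(z, z)
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=1)
    links: set[tuple[int, int]] = set()
    for i in range(n):
        j = int(nn[i])
        if nn[j] == i and labels[i] != labels[j]:
            links.add((min(i, j), max(i, j)))
    return links


def smote_tomek(
    rows: np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 5,
    seed: int = DEFAULT_BALANCE_SEED,
    sign: str = "conventional",
) -> BalancedDataset:
    """SMOTE to a 1:1 ratio, then drop the majority-class member of every
    Tomek link found in the expanded dataset."""
    over = smote(rows, labels, k_neighbors=k_neighbors, target_ratio=1.0,
                 seed=seed, sign=sign)
    _, majority = _minority_majority(np.asarray(labels, dtype=int))
    links = tomek_links(over.rows, over.labels)
    drop = {i for pair in links for i in pair if over.labels[i] == majority}
    keep = np.array([i for i in range(len(over.labels)) if i not in drop], dtype=int)
    return BalancedDataset(
        over.rows[keep], over.labels[keep], over.provenance[keep], seed
    )


def random_oversample(
    rows: np.ndarray, labels: np.ndarray, seed: int = DEFAULT_BALANCE_SEED
) -> BalancedDataset:
    """Duplicate minority rows uniformly at random until the classes are 1:1."""
    rows = np.asarray(rows, dtype=float)
    labels = np.asarray(labels, dtype=int)
    minority, majority = _minority_majority(labels)
    min_idx = np.flatnonzero(labels == minority)
    n_new = int(np.sum(labels == majority)) - min_idx.size
    prov = np.array(["original"] * rows.shape[0], dtype=object)
    if n_new <= 0:
        return BalancedDataset(rows.copy(), labels.copy(), prov, seed)
    rng = np.random.default_rng(seed)
    picks = min_idx[rng.integers(0, min_idx.size, size=n_new)]
    out_rows = np.vstack([rows, rows[picks]])
    out_labels = np.concatenate([labels, np.full(n_new, minority, dtype=int)])
    out_prov = np.concatenate([prov, np.array(["synthetic"] * n_new, dtype=object)])
    return BalancedDataset(out_rows, out_labels, out_prov, seed)


def adasyn(
    rows: np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 5,
    seed: int = DEFAULT_BALANCE_SEED,
) -> BalancedDataset:
    """Adaptive synthetic oversampling: synthesis effort per minority
    point is proportional to the fraction of majority points among its k
    nearest neighbours, so harder boundary regions receive more
    synthetic samples. Interpolation itself follows the conventional
    SMOTE rule between minority pairs."""
    rows = np.asarray(rows, dtype=float)
    labels = np.asarray(labels, dtype=int)
    minority, majority = _minority_majority(labels)
    min_idx = np.flatnonzero(labels == minority)
    if min_idx.size <= 1:
        raise DegenerateDataError("need more than one minority sample to interpolate")
    g_total = int(np.sum(labels == majority)) - min_idx.size
    prov = np.array(["original"] * rows.shape[0], dtype=object)
    if g_total <= 0:
        return BalancedDataset(rows.copy(), labels.copy(), prov, seed)
    z = _standardize(rows)
    d_all = cdist(z[min_idx], z)
    for r, i in enumerate(min_idx):
        d_all[r, i] = np.inf
    k = min(k_neighbors, rows.shape[0] - 1)
    neigh_all = np.argsort(d_all, axis=1, kind="stable")[:, :k]
    density = np.array(
        [np.sum(labels[neigh_all[r]] == majority) / k for r in range(min_idx.size)]
    )
    if density.sum() == 0:
        return BalancedDataset(rows.copy(), labels.copy(), prov, seed)
    weights = density / density.sum()
    alloc = np.floor(weights * g_total).astype(int)
    # distribute the rounding remainder to the densest points, deterministically
    remainder = g_total - int(alloc.sum())
    order = np.argsort(-weights, kind="stable")
    for t in range(remainder):
        alloc[order[t % order.size]] += 1
    # minority-only neighbours for interpolation
    d_min = cdist(z[min_idx], z[min_idx])
    np.fill_diagonal(d_min, np.inf)
    k_min = min(k_neighbors, min_idx.size - 1)
    neigh_min = np.argsort(d_min, axis=1, kind="stable")[:, :k_min]
    rng = np.random.default_rng(seed)
    synth: list[np.ndarray] = []
    for r in range(min_idx.size):
        for _ in range(int(alloc[r])):
            j = neigh_min[r, rng.integers(0, k_min)]
            u = float(rng.uniform(0.0, 1.0)) or 0.5
            synth.append(
                smote_synthesize(rows[min_idx[r]], rows[min_idx[j]], u)
            )
    if not synth:
        return BalancedDataset(rows.copy(), labels.copy(), prov, seed)
    synth_arr = np.vstack(synth)
    out_rows = np.vstack([rows, synth_arr])
    out_labels = np.concatenate([labels, np.full(len(synth), minority, dtype=int)])
    out_prov = np.concatenate([prov, np.array(["synthetic"] * len(synth), dtype=object)])
    return BalancedDataset(out_rows, out_labels, out_prov, seed)


_STRATEGIES = {
    "smote-tomek": lambda X, y, seed: smote_tomek(X, y, seed=seed),
    "smote": lambda X, y, seed: smote(X, y, seed=seed),
    "adasyn": lambda X, y, seed: adasyn(X, y, seed=seed),
    "random": lambda X, y, seed: random_oversample(X, y, seed=seed),
    "none": lambda X, y, seed: BalancedDataset(
        np.asarray(X, float).copy(),
        np.asarray(y, int).copy(),
        np.array(["original"] * len(y), dtype=object),
        seed,
    ),
}


def balance(
    rows: np.ndarray, labels: np.ndarray, strategy: str, seed: int = DEFAULT_BALANCE_SEED
) -> BalancedDataset:
    """Dispatch one of the named balancing strategies."""
    try:
        fn = _STRATEGIES[strategy]
    except KeyError:
        raise InvalidInputError(
            f"unknown balancing strategy {strategy!r}; choose from {sorted(_STRATEGIES)}"
        ) from None
    return fn(rows, labels, seed)
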