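"""Feature selection: mutual information, mRMR ranking, SFS wrapper
search, and the combined two-step mRMR-SFS used for the final model.

mRMR (minimum redundancy, maximum relevance) greedily ranks features by
the difference criterion: the first pick maximises I(f; y); every later
pick maximises I(f; y) minus the mean mutual information with the
already-chosen set. Mutual information uses the plug-in
contingency-table estimate on quantile-discretised columns (3 bins by
default), in nats.

SFS (sequential forward selection) then walks the ranked list, keeping
each candidate only if it improves a cross-validated objective (mean
AUC by default), and stops after a fixed number of consecutive
non-improvements. The evaluator is pluggable so the wrapper can run
with any classifier backend.

Ties everywhere break by column order, making every ranking
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .datamodel import FeatureTable
from .errors import InvalidInputError

Evaluator = Callable[[np.ndarray, np.ndarray], float]
"""Maps (feature matrix, labels) to a scalar objective (higher = better)."""


@dataclass
class SelectionResult:
    ranked_features: list[str]
    selected_subset: list[str]
    objective_trace: list[float]
    objective: str = "auc"
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if not set(self.selected_subset) <= set(self.ranked_features):
            raise InvalidInputError("selected subset must be within the ranked features")


def discretize(column: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Quantile (equal-frequency) binning via ranks; ties broken by
    value order so bin counts differ by at most one for distinct-valued
    input. Constant columns collapse to a single bin."""
    x = np.asarray(column, dtype=float)
    if x.size == 0:
        raise InvalidInputError("empty column")
    if n_bins < 2:
        raise InvalidInputError("n_bins must be >= 2")
    if np.all(x == x[0]):
        return np.zeros(x.size, dtype=int)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=int)
    ranks[order] = np.arange(x.size)
    return (ranks * n_bins) // x.size


def mutual_info(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) between two discrete vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise InvalidInputError("vectors must have equal length")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    mi = float(np.sum(joint[mask] * np.log(joint[mask] / (pa @ pb)[mask])))
    return max(mi, 0.0)


def mrmr_rank(table: FeatureTable, k: int | None = None, n_bins: int = 3) -> list[str]:
    """Greedy mRMR ranking (difference criterion) of the table's features
    against its labels. Returns the top ``k`` names (all when None)."""
    if len(table) == 0 or table.rows.shape[1] == 0:
        raise InvalidInputError("empty feature table")
    names = table.feature_names
    d = len(names)
    k = d if k is None else k
    if k > d:
        raise InvalidInputError(f"k={k} exceeds feature count {d}")
    disc = np.column_stack([discretize(table.rows[:, j], n_bins) for j in range(d)])
    y = table.labels
    relevance = np.array([mutual_info(disc[:, j], y) for j in range(d)])
    chosen: list[int] = []
    remaining = list(range(d))
    redundancy_sum = np.zeros(d)
    mi_cache: dict[tuple[int, int], float] = {}
    while remaining and len(chosen) < k:
        if not chosen:
            scores = relevance[remaining]
        else:
            scores = np.array(
                [relevance[j] - redundancy_sum[j] / len(chosen) for j in remaining]
            )
        best = remaining[int(np.argmax(scores))]  # argmax keeps first on ties
        chosen.append(best)
        remaining.remove(best)
        for j in remaining:
            key = (min(best, j), max(best, j))
            if key not in mi_cache:
                mi_cache[key] = mutual_info(disc[:, best], disc[:, j])
            redundancy_sum[j] += mi_cache[key]
    return [names[j] for j in chosen]


def sfs(
    table: FeatureTable,
    candidate_order: Sequence[str],
    evaluator: Evaluator,
    cv_folds: int = 10,
    patience: int = 5,
    objective: str = "auc",
) -> SelectionResult:
    """Order-restricted sequential forward selection.

    Walks ``candidate_order``, appending a candidate whenever it
    improves the evaluator's objective over the current best subset;
    stops after ``patience`` consecutive non-improvements or when the
    candidates are exhausted.
    """
    if not candidate_order:
        raise InvalidInputError("candidate_order must be nonempty")
    y = table.labels
    current: list[str] = []
    best_score = -np.inf
    trace: list[float] = []
    misses = 0
    for name in candidate_order:
        trial = current + [name]
        cols = [table.schema.index(n) for n in trial]
        try:
            score = evaluator(table.rows[:, cols], y)
        except Exception as exc:  # surface which feature broke the evaluator
            raise RuntimeError(f"evaluator failed on subset {trial}: {exc}") from exc
        if score > best_score:
            best_score = score
            current = trial
            misses = 0
        else:
            misses += 1
        trace.append(best_score)
        if misses >= patience:
            break
    return SelectionResult(
        ranked_features=list(candidate_order),
        selected_subset=current,
        objective_trace=trace,
        objective=objective,
        cv_folds=cv_folds,
    )


def mrmr_sfs(
    table: FeatureTable,
    evaluator: Evaluator,
    cv_folds: int = 10,
    patience: int = 5,
    n_bins: int = 3,
    objective: str = "auc",
) -> SelectionResult:
    """Two-step selection: mRMR ranking over all features, then SFS over
    that ranked order."""
    ranked = mrmr_rank(table, n_bins=n_bins)
    return sfs(table, ranked, evaluator, cv_folds=cv_folds, patience=patience,
               objective=objective)


def comparator_rank(
    table: FeatureTable, method: str, seed: int = 0
) -> list[str]:
    """Baseline full rankings: random-forest impurity importance or
    linear-SVM recursive feature elimination. Deterministic per seed;
    ties break by column order."""
    names = table.feature_names
    X, y = table.rows, table.labels
    if method == "rf_importance":
        from sklearn.ensemble import RandomForestClassifier

        rf = RandomForestClassifier(n_estimators=200, random_state=seed)
        rf.fit(X, y)
        imp = rf.feature_importances_
        order = np.argsort(-imp, kind="stable")
        return [names[j] for j in order]
    if method == "svm_rfe":
        from sklearn.feature_selection import RFE
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import LinearSVC

        Xz = StandardScaler().fit_transform(X)
        rfe = RFE(LinearSVC(dual=False, random_state=seed, max_iter=5000),
                  n_features_to_select=1)
        rfe.fit(Xz, y)
        order = np.argsort(rfe.ranking_, kind="stable")
        return [names[j] for j in order]
    raise InvalidInputError(f"unknown comparator method {method!r}")
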