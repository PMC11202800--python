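"""Classifier wrapper, confusion-based metrics and repeated
cross-validation.

The reference configuration is a gradient-boosted decision-tree
classifier with 150 boosting iterations, learning rate 0.03, tree depth
6 and seed 42. Several backends sit behind one contract so classifier
comparisons are a configuration sweep: scikit-learn gradient boosting
(default), logistic regression, an RBF SVM, random forest, and — when
installed — LightGBM and XGBoost.

Evaluation reports sensitivity, specificity, precision, F1, accuracy,
Matthews correlation and AUC. AUC is the normalised Mann-Whitney U
statistic computed from midranks, so tied scores count one half. Any
metric with a zero denominator is defined as 0. The decision threshold
on predicted probability is 0.5; hot spots are the positive class.

`repeated_cv` runs stratified k-fold cross-validation `repeats` times
with different shuffles. Balancing and feature selection — when enabled
— are fitted inside each training fold only, so no information from
held-out rows leaks into resampling or selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .balancing import balance
from .datamodel import FeatureTable
from .errors import DegenerateDataError, InvalidInputError

#: classification threshold on the positive-class probability
DECISION_THRESHOLD = 0.5


@dataclass(frozen=True)
class ModelConfig:
    iterations: int = 150
    learning_rate: float = 0.03
    depth: int = 6
    seed: int = 42
    backend: str = "gbdt"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise InvalidInputError("iterations must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise InvalidInputError("learning_rate must be in (0, 1]")
        if self.depth < 1:
            raise InvalidInputError("depth must be >= 1")


@dataclass
class EvalReport:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    sen: float = 0.0
    spe: float = 0.0
    pre: float = 0.0
    f1: float = 0.0
    acc: float = 0.0
    mcc: float = 0.0
    auc: float = 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sen": self.sen, "spe": self.spe, "pre": self.pre,
            "f1": self.f1, "acc": self.acc, "mcc": self.mcc, "auc": self.auc,
        }


class FittedModel:
    """Opaque handle over a fitted backend exposing probability scores."""

    def __init__(self, estimator, config: ModelConfig):
        self._estimator = estimator
        self.config = config

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability per row."""
        est = self._estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(np.asarray(X, dtype=float))[:, 1]
        from scipy.special import expit

        return expit(est.decision_function(np.asarray(X, dtype=float)))

    def predict(self, X: np.ndarray, threshold: float = DECISION_THRESHOLD) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def _build_estimator(config: ModelConfig):
    b = config.backend
    if b == "gbdt":
        from sklearn.ensemble import GradientBoostingClassifier

        return GradientBoostingClassifier(
            n_estimators=config.iterations,
            learning_rate=config.learning_rate,
            max_depth=config.depth,
            random_state=config.seed,
        )
    if b == "logistic":
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=2000, random_state=config.seed)
    if b == "svm":
        from sklearn.svm import SVC

        return SVC(kernel="rbf", random_state=config.seed)
    if b == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=config.iterations, max_depth=config.depth,
            random_state=config.seed,
        )
    if b == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=config.iterations, learning_rate=config.learning_rate,
            max_depth=config.depth, random_state=config.seed, verbose=-1,
        )
    if b == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=config.iterations, learning_rate=config.learning_rate,
            max_depth=config.depth, random_state=config.seed,
        )
    raise InvalidInputError(f"unknown backend {b!r}")


def train(X: np.ndarray, y: np.ndarray, config: ModelConfig | None = None) -> FittedModel:
    """Fit the configured classifier; deterministic per seed/backend."""
    config = config or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise DegenerateDataError("training data contain a single class")
    est = _build_estimator(config)
    est.fit(X, y)
    return FittedModel(est, config)


def train_table(table: FeatureTable, config: ModelConfig | None = None) -> FittedModel:
    return train(table.rows, table.labels, config)


def confusion(labels: np.ndarray, predictions: np.ndarray) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) at a fixed prediction vector; hot spots (1) are
    the positive class."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise InvalidInputError("labels and predictions must have equal length")
    for v in (y, p):
        if not np.isin(v, (0, 1)).all():
            raise InvalidInputError("labels and predictions must be binary 0/1")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return tp, fp, tn, fn


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def metrics(tp: int, fp: int, tn: int, fn: int, auc_value: float | None = None) -> EvalReport:
    """The seven evaluation metrics from confusion counts.

    SEN = TP/(TP+FN); SPE = TN/(TN+FP); PRE = TP/(TP+FP);
    F1 = 2*SEN*PRE/(SEN+PRE); ACC = (TP+TN)/total;
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Any zero denominator makes the metric 0.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise InvalidInputError("confusion counts must be non-negative")
    if sum(counts) == 0:
        raise InvalidInputError("confusion counts are all zero")
    sen = _safe_div(tp, tp + fn)
    spe = _safe_div(tn, tn + fp)
    pre = _safe_div(tp, tp + fp)
    f1 = _safe_div(2 * sen * pre, sen + pre)
    acc = _safe_div(tp + tn, sum(counts))
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, denom)
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, sen=sen, spe=spe, pre=pre,
                      f1=f1, acc=acc, mcc=mcc,
                      auc=0.0 if auc_value is None else float(auc_value))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: the normalised Mann-Whitney U statistic with
    midranks, so ties contribute one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise InvalidInputError("scores and labels must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("AUC undefined with a single class")
    ranks = rankdata(s)  # midranks
    u = float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def evaluate(model: FittedModel, X: np.ndarray, y: np.ndarray) -> EvalReport:
    """Score a fitted model on held-out rows: confusion at threshold 0.5
    plus rank-based AUC."""
    scores = model.predict_proba(X)
    preds = (scores >= DECISION_THRESHOLD).astype(int)
    tp, fp, tn, fn = confusion(y, preds)
    return metrics(tp, fp, tn, fn, auc_value=auc(scores, np.asarray(y, dtype=int)))


SelectorFn = Callable[[FeatureTable], Sequence[str]]
"""Maps a training-fold table to the selected feature names."""


@dataclass
class CVSummary:
    """Mean and standard deviation of each metric over folds x repeats."""

    mean: EvalReport
    std: dict
    n_folds: int
    n_repeats: int


def repeated_cv(
    table: FeatureTable,
    config: ModelConfig | None = None,
    folds: int = 10,
    repeats: int = 50,
    seed: int = 0,
    balance_strategy: str = "none",
    balance_seed: int = 74,
    selector: SelectorFn | None = None,
) -> CVSummary:
    """Repeated stratified k-fold cross-validation.

    Per fold: optional rebalancing of the training rows, optional
    feature selection fitted on the (balanced) training rows, model
    training, then evaluation on the untouched held-out rows. Metrics
    are averaged over all folds of all repeats; the standard deviation
    across folds is reported alongside.
    """
    config = config or ModelConfig()
    y = table.labels
    if np.unique(y).size < 2:
        raise DegenerateDataError("cross-validation needs both classes")
    if folds > min(np.bincount(y)):
        raise InvalidInputError("more folds than members of the rarest class")
    reports: list[EvalReport] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for train_idx, test_idx in skf.split(table.rows, y):
            fold_table = table.subset_rows(train_idx)
            bal = balance(fold_table.rows, fold_table.labels, balance_strategy,
                          seed=balance_seed)
            train_rows, train_labels = bal.rows, bal.labels
            feature_names = table.feature_names
            if selector is not None:
                bal_table = FeatureTable(
                    fold_table.schema, train_rows, train_labels,
                    np.array(["_"] * len(train_labels), dtype=object),
                )
                feature_names = list(selector(bal_table))
                cols = [table.schema.index(n) for n in feature_names]
                train_rows = train_rows[:, cols]
            model = train(train_rows, train_labels, config)
            test_rows = table.rows[test_idx]
            if selector is not None:
                test_rows = test_rows[:, cols]
            reports.append(evaluate(model, test_rows, y[test_idx]))
    keys = ("sen", "spe", "pre", "f1", "acc", "mcc", "auc")
    means = {k: float(np.mean([getattr(rep, k) for rep in reports])) for k in keys}
    stds = {k: float(np.std([getattr(rep, k) for rep in reports])) for k in keys}
    counts = {k: int(np.sum([getattr(rep, k) for rep in reports]))
              for k in ("tp", "fp", "tn", "fn")}
    mean_report = EvalReport(**counts, **means)
    return CVSummary(mean=mean_report, std=stds, n_folds=folds, n_repeats=repeats)


def make_cv_evaluator(
    config: ModelConfig | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    objective: str = "auc",
):
    """Evaluator for the SFS wrapper: mean stratified-CV objective of the
    configured classifier on a candidate feature matrix."""
    config = config or ModelConfig()

    def _eval(X: np.ndarray, y: np.ndarray) -> float:
        y = np.asarray(y, dtype=int)
        folds = min(cv_folds, int(min(np.bincount(y))))
        if folds < 2:
            raise DegenerateDataError("too few samples per class for CV")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        scores = []
        for tr, te in skf.split(X, y):
            model = train(X[tr], y[tr], config)
            rep = evaluate(model, X[te], y[te])
            scores.append(getattr(rep, objective))
        return float(np.mean(scores))

    return _eval
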