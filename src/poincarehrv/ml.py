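"""Classification stage: hold-out split, wrapper feature selection, evaluation.

The workflow classifies subjects into low/high cardiovascular risk from the
nine Poincare features: an 80/20 stratified hold-out split, then — per
algorithm — a wrapper that searches feature subsets by mean accuracy over a
fixed, seeded stratified 10-fold cross-validation of the training set
(exhaustive over all 511 non-empty subsets of nine features by default, or
greedy forward selection), and finally a single fit on the full training set
evaluated on the untouched test set with five metrics (accuracy,
sensitivity, specificity, precision, AUCROC; high risk is the positive
class).

Algorithms: ADA-B (adaptive boosting of depth-limited decision trees), KNN
(k-nearest neighbours on standardised features) and NB (Gaussian naive
Bayes).  Boosting uses a thin SAMME loop over scikit-learn decision trees
(:class:`_BoostedTrees`), which matches AdaBoost predictions while keeping
the per-subset cost of the exhaustive wrapper tractable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES

__all__ = [
    "ALGORITHMS",
    "SplitSpec",
    "MLConfig",
    "WrapperResult",
    "holdout_split",
    "wrapper_select",
    "train_eval",
    "full_run",
    "format_report",
]

ALGORITHMS = ("ADA-B", "KNN", "NB")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class MLConfig:
    """Hyperparameters and workflow knobs, all logged into the report."""

    split: SplitSpec = SplitSpec()
    k_folds: int = 10
    wrapper: str = "exhaustive"          # or "greedy"
    positive: str = "high"
    knn_k: int = 5
    ada_rounds: int = 50
    ada_depth: int = 3
    ada_learning_rate: float = 1.0
    seed: int = 0


class _BoostedTrees:
    """SAMME adaptive boosting over sklearn decision trees.

    Binary-class, minimal-overhead reimplementation of the discrete AdaBoost
    update (estimator weight ``log((1-err)/err)`` for two classes, weights
    multiplied by ``exp(alpha)`` on misclassified samples).  ``predict_proba``
    returns the softmax-free normalised vote margin, sufficient for ranking
    scores (AUCROC).
    """

    def __init__(self, n_estimators=50, max_depth=3, learning_rate=1.0,
                 random_state=0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def get_params(self, deep=True):
        return {
            "n_estimators": self.n_estimators, "max_depth": self.max_depth,
            "learning_rate": self.learning_rate, "random_state": self.random_state,
        }

    def set_params(self, **params):
        for key, val in params.items():
            setattr(self, key, val)
        return self

    def fit(self, X, y):
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("_BoostedTrees is a binary classifier")
        yi = (y == self.classes_[1]).astype(np.int8)
        n = yi.size
        w = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        for m in range(self.n_estimators):
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth, random_state=self.random_state + m
            )
            tree.fit(X, yi, sample_weight=w, check_input=False)
            pred = tree.predict(X)
            miss = pred != yi
            err = float(w @ miss)
            if err <= 0.0:
                # perfect weak learner: it decides alone
                self.estimators_, self.alphas_ = [tree], [1.0]
                break
            if err >= 0.5:
                break
            alpha = self.learning_rate * np.log((1.0 - err) / err)
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
            w *= np.exp(alpha * miss)
            w /= w.sum()
        if not self.estimators_:  # first stump no better than chance
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth, random_state=self.random_state
            )
            tree.fit(X, yi, sample_weight=w, check_input=False)
            self.estimators_, self.alphas_ = [tree], [1.0]
        return self

    def decision_function(self, X):
        X = np.ascontiguousarray(X, dtype=np.float64)
        margin = np.zeros(X.shape[0])
        for alpha, tree in zip(self.alphas_, self.estimators_):
            margin += alpha * (2.0 * tree.predict(X) - 1.0)
        return margin / sum(self.alphas_)

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def predict_proba(self, X):
        score = (self.decision_function(X) + 1.0) / 2.0
        return np.column_stack([1.0 - score, score])


def make_classifier(algorithm: str, config: MLConfig, seed: int):
    """Instantiate one of the three algorithms with the configured knobs.

    KNN is wrapped with a standardiser fitted on training data only, so no
    test statistics ever leak into the distance metric.
    """
    if algorithm == "ADA-B":
        return _BoostedTrees(
            n_estimators=config.ada_rounds, max_depth=config.ada_depth,
            learning_rate=config.ada_learning_rate, random_state=seed,
        )
    if algorithm == "KNN":
        return make_pipeline(StandardScaler(),
                             KNeighborsClassifier(n_neighbors=config.knn_k))
    if algorithm == "NB":
        return GaussianNB()
    raise ValueError(f"unknown algorithm {algorithm!r} (expected one of {ALGORITHMS})")


def holdout_split(table: pd.DataFrame, labels, spec: SplitSpec | None = None):
    """Disjoint, exhaustive train/test partition, stratified and seeded."""
    spec = spec or SplitSpec()
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 5:
        raise ValueError("every class needs >= 5 rows to split")
    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=labels if spec.stratified else None,
        random_state=spec.seed,
        shuffle=True,
    )
    train_idx.sort()
    test_idx.sort()
    return (
        table.iloc[train_idx], table.iloc[test_idx],
        labels[train_idx], labels[test_idx],
    )


@dataclass(frozen=True)
class WrapperResult:
    algorithm: str
    best_subset: tuple
    cv_accuracy: float
    n_subsets_evaluated: int


def _cv_accuracy(X: np.ndarray, y: np.ndarray, folds, clf_factory) -> float:
    accs = np.empty(len(folds))
    for f, (tr, te) in enumerate(folds):
        clf = clf_factory()
        clf.fit(X[tr], y[tr])
        accs[f] = np.mean(clf.predict(X[te]) == y[te])
    return float(accs.mean())


def _subset_order(features: tuple) -> list[tuple]:
    """All non-empty subsets, smallest first then lexicographic by position."""
    order = []
    for size in range(1, len(features) + 1):
        order.extend(itertools.combinations(range(len(features)), size))
    return order


def wrapper_select(
    train: pd.DataFrame,
    labels,
    algorithm: str,
    k_folds: int = 10,
    seed: int = 0,
    config: MLConfig | None = None,
    features: list[str] | None = None,
) -> WrapperResult:
    """Pick the feature subset maximising mean CV accuracy on the train set.

    The stratified k-fold partition is built once from the seed and reused
    for every subset, so subsets compete on identical folds.  Ties resolve
    to the smaller subset, then to lexicographic (canonical feature order) —
    guaranteed by evaluating subsets in that order and keeping only strict
    improvements.
    """
    config = config or MLConfig(k_folds=k_folds, seed=seed)
    features = tuple(features or [f for f in FEATURE_NAMES if f in train.columns])
    if not features:
        raise ValueError("no feature columns to select from")
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if k_folds > counts.min():
        raise ValueError(
            f"k_folds={k_folds} exceeds the smallest class size {counts.min()}"
        )
    X_all = train[list(features)].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X_all, y))

    def evaluate(subset_idx: tuple) -> float:
        cols = np.asarray(subset_idx, dtype=int)
        return _cv_accuracy(
            X_all[:, cols], y, folds,
            lambda: make_classifier(algorithm, config, seed),
        )

    n_evaluated = 0
    if config.wrapper == "exhaustive":
        best_idx, best_acc = None, -1.0
        for subset in _subset_order(features):
            acc = evaluate(subset)
            n_evaluated += 1
            if acc > best_acc:
                best_idx, best_acc = subset, acc
    elif config.wrapper == "greedy":
        current: tuple = ()
        best_acc = -1.0
        remaining = list(range(len(features)))
        while remaining:
            round_best, round_acc = None, best_acc
            for f in remaining:  # ascending order -> lexicographic tie-break
                acc = evaluate(tuple(sorted(current + (f,))))
                n_evaluated += 1
                if acc > round_acc:
                    round_best, round_acc = f, acc
            if round_best is None:
                break
            current = tuple(sorted(current + (round_best,)))
            best_acc = round_acc
            remaining.remove(round_best)
        best_idx = current if current else (0,)
        if not current:  # degenerate: nothing beat -1, keep first feature
            best_acc = evaluate(best_idx)
    else:
        raise ValueError(f"unknown wrapper strategy {config.wrapper!r}")

    return WrapperResult(
        algorithm=algorithm,
        best_subset=tuple(features[i] for i in best_idx),
        cv_accuracy=best_acc,
        n_subsets_evaluated=n_evaluated,
    )


def train_eval(
    train: pd.DataFrame,
    test: pd.DataFrame,
    train_labels,
    test_labels,
    algorithm: str,
    subset,
    seed: int = 0,
    config: MLConfig | None = None,
) -> dict:
    """Fit on train (restricted to ``subset``), report five metrics on test."""
    config = config or MLConfig(seed=seed)
    subset = list(subset)
    y_train = np.asarray(train_labels)
    y_test = np.asarray(test_labels)
    if len(np.unique(y_test)) < 2:
        raise ValueError("test set contains a single class; metrics undefined")
    clf = make_classifier(algorithm, config, seed)
    clf.fit(train[subset].to_numpy(dtype=float), y_train)
    X_test = test[subset].to_numpy(dtype=float)
    pred = clf.predict(X_test)

    pos = config.positive
    tp = int(np.sum((pred == pos) & (y_test == pos)))
    fp = int(np.sum((pred == pos) & (y_test != pos)))
    tn = int(np.sum((pred != pos) & (y_test != pos)))
    fn = int(np.sum((pred != pos) & (y_test == pos)))

    proba = clf.predict_proba(X_test)
    pos_col = int(np.flatnonzero(clf.classes_ == pos)[0]) if hasattr(clf, "classes_") \
        else int(np.flatnonzero(clf[-1].classes_ == pos)[0])
    scores = proba[:, pos_col]
    from sklearn.metrics import roc_auc_score

    auc = float(roc_auc_score((y_test == pos).astype(int), scores))

    total = tp + fp + tn + fn
    return {
        "algorithm": algorithm,
        "selected_features": tuple(subset),
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "accuracy_pct": 100.0 * (tp + tn) / total,
        "sensitivity_pct": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        "specificity_pct": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        "precision_pct": 100.0 * tp / (tp + fp) if tp + fp else float("nan"),
        "aucroc": auc,
    }


def full_run(table: pd.DataFrame, labels, config: MLConfig | None = None) -> dict:
    """split -> per-algorithm wrapper -> per-algorithm evaluation.

    Returns a report dict with one row per algorithm plus the selected
    subsets and the full configuration echo.
    """
    config = config or MLConfig()
    split = SplitSpec(config.split.train_fraction, config.split.stratified,
                      config.seed)
    train, test, y_train, y_test = holdout_split(table, labels, split)
    rows, wrappers = [], {}
    for algorithm in ALGORITHMS:
        wr = wrapper_select(train, y_train, algorithm,
                            k_folds=config.k_folds, seed=config.seed,
                            config=config)
        wrappers[algorithm] = wr
        rows.append(
            train_eval(train, test, y_train, y_test, algorithm,
                       wr.best_subset, seed=config.seed, config=config)
        )
    return {
        "rows": rows,
        "wrappers": wrappers,
        "config": config,
        "n_train": len(train),
        "n_test": len(test),
    }


def format_report(report: dict) -> pd.DataFrame:
    """Evaluation-table view: metrics in % to one decimal, AUCROC to three."""
    out = []
    for row in report["rows"]:
        out.append({
            "Algorithm": row["algorithm"],
            "Accuracy [%]": round(row["accuracy_pct"], 1),
            "Sensitivity [%]": round(row["sensitivity_pct"], 1),
            "Specificity [%]": round(row["specificity_pct"], 1),
            "Precision [%]": round(row["precision_pct"], 1),
            "AUCROC": round(row["aucroc"], 3),
            "Features Selected": ", ".join(row["selected_features"]),
        })
    return pd.DataFrame(out)
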