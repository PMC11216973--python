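"""Permutation test for the presence of batch effects.

A random forest tries to predict a per-patient categorical label (typically
acquisition site or scanner) from the QC metrics. If the forest's
cross-validated accuracy is no better than the same forest trained on
randomly permuted labels, the metrics carry no detectable batch signal. The
comparison is a standard permutation test: B permuted-label replicates form
the null distribution, and the p-value uses the add-one estimator
``(1 + #{null >= observed}) / (B + 1)``, which can never be exactly zero.

The test runs at patient level — one feature vector per patient — to avoid
pseudoreplication from patients contributing many images. The refit forest's
impurity importances rank the metrics driving the batch signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from ._rng import derive_seed
from .features import PatientFeatureMatrix

logger = logging.getLogger("cohortsplit")


class BETestError(ValueError):
    pass


class BaggedForest:
    """Random forest as explicit bagging over sklearn decision trees.

    Equivalent to the textbook random forest (bootstrap per tree, sqrt-sized
    random feature subsets at each split, majority vote, impurity-based
    importances averaged over trees) but with far less per-fit overhead than
    the ensemble wrapper, which matters when the permutation test fits tens of
    thousands of tiny forests. Input arrays are converted once per test run.
    """

    def __init__(self, n_trees: int = 100, seed: int = 0):
        self.n_trees = n_trees
        self.seed = seed
        self.trees_: list[DecisionTreeClassifier] = []
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedForest":
        X = np.asarray(X, dtype=np.float32)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        self.trees_ = []
        for t in range(self.n_trees):
            idx = rng.integers(0, n, n)  # bootstrap sample
            tree = DecisionTreeClassifier(
                max_features="sqrt",
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], y_enc[idx], check_input=False)
            self.trees_.append(tree)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        assert self.classes_ is not None, "fit first"
        votes = np.zeros((X.shape[0], self.classes_.size), dtype=np.int32)
        for tree in self.trees_:
            pred = tree.predict(X, check_input=False).astype(int)
            votes[np.arange(X.shape[0]), pred] += 1
        return self.classes_[votes.argmax(axis=1)]  # ties -> lowest class index

    @property
    def feature_importances_(self) -> np.ndarray:
        imp = np.mean([t.feature_importances_ for t in self.trees_], axis=0)
        return np.asarray(imp, dtype=float)


@dataclass
class BETestResult:
    """Outcome of the batch-effect permutation test."""

    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    importances: list[tuple[str, float]]  # (metric, weight), descending
    labels_tested: str
    n_classes: int
    B: int = field(init=False)

    def __post_init__(self) -> None:
        self.null_stats = np.asarray(self.null_stats, dtype=float)
        self.B = int(self.null_stats.size)

    def top_metrics(self, n: int = 3) -> list[str]:
        return [name for name, _ in self.importances[:n]]


def _cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int,
    n_trees: int,
    stat_seed: int,
) -> float:
    """Mean stratified k-fold accuracy of a random forest on (X, y)."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=derive_seed(stat_seed, "cv"))
    accs = []
    for i, (tr, te) in enumerate(skf.split(X, y)):
        rf = BaggedForest(n_trees=n_trees, seed=derive_seed(stat_seed, "rf", i))
        rf.fit(X[tr], y[tr])
        accs.append(float((rf.predict(X[te]) == y[te]).mean()))
    return float(np.mean(accs))


def run_be_test(
    matrix: PatientFeatureMatrix,
    labels: Sequence[str],
    B: int = 999,
    seed: int = 0,
    cv_folds: int = 5,
    n_trees: int = 100,
) -> BETestResult:
    """Test whether QC metrics predict a categorical label above chance.

    ``labels`` aligns with ``matrix.patient_ids``. The observed statistic is
    the mean stratified ``cv_folds``-fold cross-validated accuracy of a
    ``n_trees``-tree random forest; each of the ``B`` null replicates permutes
    the labels uniformly (fresh derived seed) and recomputes the identical
    statistic. Importances come from a forest refit on all patients with the
    true labels, normalized to sum to one and ranked descending.
    """
    if B < 19:
        raise BETestError("B must be at least 19 for a meaningful permutation test")
    labels = np.asarray([str(l) for l in labels])
    if labels.shape[0] != matrix.n_patients:
        raise BETestError("labels length does not match patient count")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise BETestError("need at least 2 label classes")
    small = classes[counts < cv_folds]
    if small.size:
        raise BETestError(
            f"class(es) smaller than cv_folds={cv_folds}: {small.tolist()}"
        )
    X = np.ascontiguousarray(matrix.values, dtype=np.float32)
    if np.all(X.std(axis=0) == 0):
        raise BETestError("constant features only: nothing to test")

    observed = _cv_accuracy(X, labels, cv_folds, n_trees, derive_seed(seed, "observed"))

    null_stats = np.empty(B)
    for b in range(B):
        rep_seed = derive_seed(seed, "perm", b)
        rng = np.random.default_rng(rep_seed)
        y_perm = labels[rng.permutation(labels.size)]
        null_stats[b] = _cv_accuracy(X, y_perm, cv_folds, n_trees, rep_seed)

    p_value = (1.0 + float(np.sum(null_stats >= observed))) / (B + 1.0)

    full = BaggedForest(n_trees=n_trees, seed=derive_seed(seed, "importance"))
    full.fit(X, labels)
    imp = np.asarray(full.feature_importances_, dtype=float)
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / imp.size)
    ranked = sorted(zip(matrix.feature_names, imp), key=lambda t: -t[1])

    result = BETestResult(
        observed_stat=observed,
        null_stats=null_stats,
        p_value=p_value,
        importances=[(n, float(w)) for n, w in ranked],
        labels_tested="site",
        n_classes=int(classes.size),
    )
    logger.info(
        "BE test: observed accuracy=%.4f, B=%d, p=%.4g, top metric=%s",
        observed, B, p_value, ranked[0][0],
    )
    return result


def interpret_result(result: BETestResult, alpha: float = 0.05) -> tuple[str, str]:
    """Turn a test result into a verdict and a human-readable sentence."""
    if not 0.0 < alpha < 1.0:
        raise BETestError("alpha must be in (0, 1)")
    if result.p_value <= alpha:
        top = ", ".join(result.top_metrics(3))
        sentence = (
            f"Batch effects detected (p={result.p_value:.4g} <= alpha={alpha:g}): "
            f"QC metrics predict '{result.labels_tested}' with accuracy "
            f"{result.observed_stat:.3f}; most informative metrics: {top}."
        )
        return "BE_detected", sentence
    sentence = (
        f"No evidence of batch effects (p={result.p_value:.4g} > alpha={alpha:g}): "
        f"prediction of '{result.labels_tested}' is not better than permuted labels."
    )
    return "no_BE_evidence", sentence
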