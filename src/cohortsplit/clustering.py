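"""Batch-effect group detection by replicated k-means in embedding space.

Each k-means cluster of the 2-D embedding is treated as a batch-effect (BE)
group: a set of patients whose QC-metric presentation is similar. k-means is
replicated with distinct seeds and the replicate with the lowest within-cluster
sum of squares is kept, which damps the algorithm's initialization randomness.
Three internal cluster-validity indices (silhouette, Calinski–Harabasz,
Davies–Bouldin) summarize how separated — i.e. how severe — the detected
batch structure is.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from ._rng import derive_seed
from .embedding import EmbeddingResult

logger = logging.getLogger("cohortsplit")


class ClusteringError(ValueError):
    pass


@dataclass
class BEGrouping:
    """Patient-to-BE-group assignment.

    ``group_index`` is canonicalized: groups are renumbered by the first
    patient index they contain, so two runs with the same seed agree label
    for label. ``severity_metrics`` holds the three validity indices once
    :func:`cluster_quality` has run (NaN sentinels for a single group).
    """

    patient_ids: list[str]
    group_index: np.ndarray
    k: int
    n_replicates: int = 1
    chosen_replicate_objective: float = float("nan")
    severity_metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group_index = np.asarray(self.group_index, dtype=int)
        if self.group_index.shape != (len(self.patient_ids),):
            raise ClusteringError("group_index length does not match patient count")
        if self.group_index.size and (
            self.group_index.min() < 0 or self.group_index.max() >= self.k
        ):
            raise ClusteringError("group indices must lie in [0, k)")

    @property
    def n_groups(self) -> int:
        return int(len(np.unique(self.group_index)))

    def members(self, g: int) -> list[str]:
        return [p for p, gi in zip(self.patient_ids, self.group_index) if gi == g]

    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.group_index, minlength=self.k)


def default_cluster_count(n_patients: int, fold_count: int) -> int:
    """Default k: patients divided by the fold count, rounded up.

    With 3-fold cross-validation this yields roughly 3-patient clusters so
    one member of each cluster can land in each fold (e.g. 91 patients,
    3 folds -> k = 31).
    """
    if fold_count < 2:
        raise ClusteringError("fold_count must be at least 2")
    if n_patients < fold_count:
        raise ClusteringError(
            f"cannot form folds: {n_patients} patients < {fold_count} folds"
        )
    return math.ceil(n_patients / fold_count)


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels by ascending first-occurrence index."""
    mapping: dict[int, int] = {}
    for lab in labels:
        if int(lab) not in mapping:
            mapping[int(lab)] = len(mapping)
    return np.array([mapping[int(lab)] for lab in labels], dtype=int)


def cluster_replicated(
    embedding: EmbeddingResult,
    k: int,
    n_replicates: int = 10,
    seed: int = 0,
) -> BEGrouping:
    """Run k-means ``n_replicates`` times; keep the lowest-inertia replicate.

    Replicate seeds are derived from ``seed`` in a nested sequence, so raising
    ``n_replicates`` can only improve (never worsen) the chosen objective.
    """
    n = embedding.n_patients
    if not 1 <= k <= n:
        raise ClusteringError(f"k={k} outside [1, {n}]")
    if n_replicates < 1:
        raise ClusteringError("n_replicates must be >= 1")

    best_labels: Optional[np.ndarray] = None
    best_obj = np.inf
    for rep in range(n_replicates):
        labels, obj = _single_kmeans(embedding.coords, k, derive_seed(seed, "kmeans", rep))
        if obj < best_obj:
            best_obj, best_labels = obj, labels

    assert best_labels is not None
    return BEGrouping(
        patient_ids=list(embedding.patient_ids),
        group_index=_canonicalize(best_labels),
        k=k,
        n_replicates=n_replicates,
        chosen_replicate_objective=float(best_obj),
    )


def _single_kmeans(coords: np.ndarray, k: int, rep_seed: int) -> tuple[np.ndarray, float]:
    """One k-means run; re-seed up to 10 times if a cluster comes back empty."""
    for attempt in range(10):
        km = KMeans(n_clusters=k, n_init=1, random_state=derive_seed(rep_seed, "attempt", attempt))
        labels = km.fit_predict(coords)
        if len(np.unique(labels)) == k:
            return labels, float(km.inertia_)
        logger.warning("k-means replicate produced an empty cluster; re-seeding")
    raise ClusteringError(f"k-means could not fill {k} clusters after 10 re-seeds")


def cluster_quality(embedding: EmbeddingResult, grouping: BEGrouping) -> dict[str, float]:
    """Compute the three severity metrics and store them on the grouping.

    Silhouette in [-1, 1] (higher = more separated batches),
    Calinski–Harabasz > 0 (higher = more separated), Davies–Bouldin >= 0
    (lower = more separated). A single-group clustering yields NaN sentinels
    with a warning instead of an exception.
    """
    labels = grouping.group_index
    if grouping.n_groups < 2 or grouping.n_groups >= len(labels):
        logger.warning(
            "severity metrics undefined for %d group(s) over %d patients",
            grouping.n_groups, len(labels),
        )
        metrics = {
            "silhouette": float("nan"),
            "calinski_harabasz": float("nan"),
            "davies_bouldin": float("nan"),
        }
    else:
        X = embedding.coords
        metrics = {
            "silhouette": float(silhouette_score(X, labels)),
            "calinski_harabasz": float(calinski_harabasz_score(X, labels)),
            "davies_bouldin": float(davies_bouldin_score(X, labels)),
        }
    grouping.severity_metrics = metrics
    logger.info(
        "cluster severity: silhouette=%.4f calinski_harabasz=%.4f davies_bouldin=%.4f",
        metrics["silhouette"], metrics["calinski_harabasz"], metrics["davies_bouldin"],
    )
    return metrics
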