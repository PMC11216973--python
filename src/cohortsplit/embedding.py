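"""Two-dimensional manifold embedding of patient QC profiles.

The standardized patient feature matrix is projected to 2-D with UMAP before
clustering. UMAP is used (rather than t-SNE or PCA) because a fitted manifold
can embed new patients without refitting, it preserves both local and global
structure, and it is fast at cohort scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from ._rng import derive_seed
from .features import PatientFeatureMatrix, ScalingParams, apply_scaling  # noqa: F401

logger = logging.getLogger("cohortsplit")


class EmbeddingError(ValueError):
    pass


@dataclass
class EmbeddingResult:
    """A fitted 2-D embedding of the cohort.

    ``coords`` has one row per patient, two columns. ``projector`` (when the
    result came from :func:`fit_embedding`) can transform new standardized
    feature vectors into the same plane; ``scaling`` carries the feature
    center/scale so raw aggregated vectors can be brought onto the fitted
    scale first.
    """

    patient_ids: list[str]
    coords: np.ndarray
    hyperparams: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    feature_names: list[str] = field(default_factory=list)
    scaling: Optional[ScalingParams] = None
    projector: Any = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise EmbeddingError(f"coords must be n x 2, got {self.coords.shape}")
        if self.coords.shape[0] != len(self.patient_ids):
            raise EmbeddingError("coords row count does not match patient count")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


def fit_embedding(
    matrix: PatientFeatureMatrix,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    metric: str = "euclidean",
    seed: int = 42,
) -> EmbeddingResult:
    """Fit UMAP on a standardized patient feature matrix.

    A fixed seed gives reproducible coordinates on the same platform. Rows
    are canonicalized (sorted by patient id) before the fit and mapped back
    afterwards, so a patient's coordinate does not depend on row order. If
    the cohort is smaller than ``n_neighbors + 1`` the neighbor count shrinks
    to ``n_patients - 1`` with a warning so small cohorts still embed.
    """
    import umap  # deferred: numba JIT makes this import expensive

    n = matrix.n_patients
    if n < 3:
        raise EmbeddingError(f"need at least 3 patients to embed, got {n}")
    if n_neighbors >= n:
        logger.warning(
            "n_neighbors=%d >= %d patients; lowered to %d", n_neighbors, n, n - 1
        )
        n_neighbors = n - 1

    order = np.argsort(np.asarray(matrix.patient_ids, dtype=object))
    inverse = np.argsort(order)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", category=UserWarning)
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric=metric,
            random_state=derive_seed(seed, "umap"),
        )
        coords = reducer.fit_transform(matrix.values[order])[inverse]

    return EmbeddingResult(
        patient_ids=list(matrix.patient_ids),
        coords=coords,
        hyperparams={"n_neighbors": n_neighbors, "min_dist": min_dist, "metric": metric},
        seed=seed,
        feature_names=list(matrix.feature_names),
        scaling=matrix.scaling,
        projector=reducer,
    )


def embed_new(result: EmbeddingResult, new_matrix: PatientFeatureMatrix) -> np.ndarray:
    """Project new patients into a fitted manifold without refitting.

    ``new_matrix`` may be raw (unscaled): the stored scaling params are then
    applied first. Its features must match the fitted features exactly.
    """
    if result.projector is None:
        raise EmbeddingError("this EmbeddingResult has no fitted projector")
    if new_matrix.n_patients == 0:
        return np.empty((0, 2), dtype=float)
    if set(result.feature_names) - set(new_matrix.feature_names):
        diff = set(new_matrix.feature_names) ^ set(result.feature_names)
        raise EmbeddingError(f"feature names differ from fitted embedding: {sorted(diff)}")
    if new_matrix.scaling is None and result.scaling is not None:
        new_matrix = apply_scaling(new_matrix, result.scaling)
    if list(new_matrix.feature_names) != list(result.feature_names):
        idx = [new_matrix.feature_names.index(n) for n in result.feature_names]
        new_matrix = PatientFeatureMatrix(
            list(new_matrix.patient_ids), list(result.feature_names),
            new_matrix.values[:, idx], scaling=new_matrix.scaling,
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", category=UserWarning)
        return np.asarray(result.projector.transform(new_matrix.values), dtype=float)
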