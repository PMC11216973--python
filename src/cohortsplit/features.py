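"""Patient-level feature construction.

Clustering for batch-effect groups happens at patient level, so image-level
metric rows are reduced to one vector per patient (mean by default) and then
z-scored per metric. Standardization matters because QC metrics live on
wildly different scales — a brightness in [0, 255] would otherwise dominate a
microns-per-pixel value in every distance computation downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ingest import QCMetricTable

logger = logging.getLogger("cohortsplit")


class FeatureError(ValueError):
    pass


@dataclass
class ScalingParams:
    """Per-feature center/scale so held-out patients transform identically."""

    feature_names: list[str]
    center: np.ndarray
    scale: np.ndarray

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "center": [float(c) for c in self.center],
            "scale": [float(s) for s in self.scale],
        }


@dataclass
class PatientFeatureMatrix:
    """One feature vector per patient (rows align with ``patient_ids``)."""

    patient_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    scaling: Optional[ScalingParams] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise FeatureError("patient ids must be unique")
        if self.values.shape != (len(self.patient_ids), len(self.feature_names)):
            raise FeatureError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.feature_names)} features"
            )

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


def aggregate_per_patient(table: QCMetricTable, statistic: str = "mean") -> PatientFeatureMatrix:
    """Reduce image-level metrics to one vector per patient.

    ``statistic`` is ``"mean"`` (default) or ``"median"`` over the patient's
    images. Patient order is first-appearance order in the table.
    """
    if table.n_images == 0:
        raise FeatureError("empty table: no images to aggregate")
    if statistic not in ("mean", "median"):
        raise FeatureError(f"unknown aggregation statistic {statistic!r}")
    reducer = np.mean if statistic == "mean" else np.median

    order: list[str] = []
    rows: dict[str, list[int]] = {}
    for i, pid in enumerate(table.patient_ids):
        if pid not in rows:
            rows[pid] = []
            order.append(pid)
        rows[pid].append(i)

    values = np.vstack([reducer(table.metrics[rows[pid], :], axis=0) for pid in order])
    return PatientFeatureMatrix(order, list(table.metric_names), values)


def standardize(matrix: PatientFeatureMatrix) -> PatientFeatureMatrix:
    """Z-score each feature (sample sd, ddof=1); drop zero-variance features.

    The fitted center/scale are recorded in ``scaling`` so new patients can be
    transformed onto the same scale with :func:`apply_scaling`.
    """
    if matrix.n_patients < 2:
        raise FeatureError("standardization needs at least 2 patients")
    center = matrix.values.mean(axis=0)
    scale = matrix.values.std(axis=0, ddof=1)
    keep = scale > 0
    if not keep.any():
        raise FeatureError("no informative metrics: all features have zero variance")
    for name, k in zip(matrix.feature_names, keep):
        if not k:
            logger.warning("feature %r has zero variance; dropped before embedding", name)
    names = [n for n, k in zip(matrix.feature_names, keep) if k]
    params = ScalingParams(names, center[keep], scale[keep])
    values = (matrix.values[:, keep] - params.center) / params.scale
    return PatientFeatureMatrix(list(matrix.patient_ids), names, values, scaling=params)


def apply_scaling(matrix: PatientFeatureMatrix, params: ScalingParams) -> PatientFeatureMatrix:
    """Transform an unscaled matrix with previously fitted scaling params."""
    missing = set(params.feature_names) - set(matrix.feature_names)
    if missing:
        raise FeatureError(f"matrix lacks fitted features: {sorted(missing)}")
    idx = [matrix.feature_names.index(n) for n in params.feature_names]
    values = (matrix.values[:, idx] - params.center) / params.scale
    return PatientFeatureMatrix(list(matrix.patient_ids), list(params.feature_names), values, scaling=params)
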