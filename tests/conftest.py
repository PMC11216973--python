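import numpy as np
import pytest

from cohortsplit import (
    EmbeddingResult,
    QCMetricTable,
    SyntheticCohortSpec,
    aggregate_per_patient,
    fit_embedding,
    generate_cohort,
    standardize,
)


def make_embedding(coords, patient_ids=None) -> EmbeddingResult:
    """EmbeddingResult from explicit 2-D coordinates (no UMAP fit)."""
    coords = np.asarray(coords, dtype=float)
    if patient_ids is None:
        patient_ids = [f"P{i:03d}" for i in range(coords.shape[0])]
    return EmbeddingResult(patient_ids=list(patient_ids), coords=coords)


def blob_coords(rng, sizes, centers, sd=0.5):
    """Planted 2-D blobs with given sizes and centers."""
    pts, labels = [], []
    for b, (n, c) in enumerate(zip(sizes, centers)):
        pts.append(np.asarray(c) + sd * rng.normal(size=(n, 2)))
        labels += [b] * n
    return np.vstack(pts), np.array(labels)


@pytest.fixture
def tiny_table() -> QCMetricTable:
    """Four images from three patients, two metrics."""
    return QCMetricTable(
        image_ids=["P01_a.png", "P01_b.png", "P02_a.png", "P03_a.png"],
        patient_ids=["P01", "P01", "P02", "P03"],
        metric_names=["brightness", "contrast"],
        metrics=np.array([[0.2, 1.0], [0.4, 3.0], [0.5, 2.0], [0.9, 4.0]]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-patient, 3-batch synthetic cohort with its ground truth."""
    spec = SyntheticCohortSpec(n_patients=30, n_batches=3, separation=10.0, seed=5)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def fitted_embedding(small_cohort):
    """One fitted UMAP embedding shared across tests (the fit is the slow part)."""
    table, truth = small_cohort
    matrix = standardize(aggregate_per_patient(table))
    return matrix, fit_embedding(matrix, seed=3), truth
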