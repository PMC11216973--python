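"""Synthetic QC-metric cohorts with planted batch structure.

Real imaging cohorts acquire batch effects from scanners, staining runs and
sites: patients processed together share a systematic shift in their QC
metrics. The generator emulates that structure directly — each batch is a
Gaussian cluster in metric space with unit within-batch standard deviation,
batch centers are placed so that every pair of centers is exactly
``separation`` apart (in within-batch sd units), and each patient's images
jitter slightly around the patient's latent vector. Site labels can track the
batch exactly (confounded cohort), partially, or not at all (null cohort for
calibration studies).

The generator makes no attempt to mimic heavy tails, metric correlations or
site-specific missingness seen in real QC tables; tests built on it exercise
the pipeline's logic, not its robustness to those artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from ._rng import derive_seed
from .ingest import QCMetricTable


class SimulationError(ValueError):
    pass


@dataclass
class SyntheticCohortSpec:
    """Parameters of a planted-batch cohort.

    separation
        Pairwise distance between batch means in units of the within-batch
        standard deviation. 0 plants no batch signal; 4 (default) is a
        clearly visible but not trivially separable batch effect.
    label_confounding
        Probability that a patient's site label equals its batch index;
        ``1/n_batches`` makes labels independent of batches (the null),
        1.0 makes site a perfect proxy for batch.
    images_per_patient
        Fixed count or inclusive ``(lo, hi)`` range per patient.
    """

    n_patients: int = 30
    images_per_patient: Union[int, tuple[int, int]] = 3
    n_metrics: int = 6
    n_batches: int = 3
    separation: float = 4.0
    label_confounding: float = 1.0
    image_jitter: float = 0.1
    seed: int = 0


def _batch_centers(n_batches: int, n_metrics: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """Centers with exact pairwise distance ``separation``.

    Random orthonormal directions scaled by ``separation / sqrt(2)``: for
    orthonormal u_i, u_j the distance between s*u_i and s*u_j is s*sqrt(2).
    """
    if n_batches == 1 or separation == 0.0:
        return np.zeros((n_batches, n_metrics))
    if n_metrics < n_batches:
        raise SimulationError(
            f"need n_metrics >= n_batches for equidistant centers ({n_metrics} < {n_batches})"
        )
    A = rng.normal(size=(n_metrics, n_batches))
    Q, _ = np.linalg.qr(A)
    return (separation / np.sqrt(2.0)) * Q[:, :n_batches].T


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[QCMetricTable, np.ndarray]:
    """Generate a cohort table plus ground-truth batch labels per patient.

    Patients are assigned to batches as evenly as possible (sizes differ by
    at most one); the returned label array aligns with patient order
    ``P001, P002, ...`` which is also first-appearance order in the table.
    """
    if spec.n_metrics < 1:
        raise SimulationError("n_metrics must be >= 1")
    if spec.n_batches < 1:
        raise SimulationError("n_batches must be >= 1")
    if spec.n_patients < spec.n_batches:
        raise SimulationError("need at least one patient per batch")
    if not 0.0 <= spec.label_confounding <= 1.0:
        raise SimulationError("label_confounding must be in [0, 1]")

    rng = np.random.default_rng(derive_seed(spec.seed, "cohort"))
    centers = _batch_centers(spec.n_batches, spec.n_metrics, spec.separation, rng)

    # even assignment: batch b gets floor(n/k) patients, first n%k batches one more
    batch_of = np.repeat(np.arange(spec.n_batches), np.diff(
        np.round(np.linspace(0, spec.n_patients, spec.n_batches + 1)).astype(int)
    ))

    width = max(3, len(str(spec.n_patients)))
    patient_ids = [f"P{i + 1:0{width}d}" for i in range(spec.n_patients)]

    image_ids: list[str] = []
    row_patient: list[str] = []
    rows: list[np.ndarray] = []
    sites: list[str] = []
    for i, pid in enumerate(patient_ids):
        b = int(batch_of[i])
        latent = centers[b] + rng.normal(size=spec.n_metrics)
        if isinstance(spec.images_per_patient, int):
            n_img = spec.images_per_patient
        else:
            lo, hi = spec.images_per_patient
            n_img = int(rng.integers(lo, hi + 1))
        if n_img < 1:
            raise SimulationError("images_per_patient must be >= 1")

        if rng.random() < spec.label_confounding:
            site = b
        else:
            others = [s for s in range(spec.n_batches) if s != b]
            site = int(rng.choice(others)) if others else b

        for j in range(n_img):
            image_ids.append(f"{pid}_img{j + 1}.png")
            row_patient.append(pid)
            rows.append(latent + spec.image_jitter * rng.normal(size=spec.n_metrics))
            sites.append(f"site{site}")

    table = QCMetricTable(
        image_ids=image_ids,
        patient_ids=row_patient,
        metric_names=[f"metric_{j + 1}" for j in range(spec.n_metrics)],
        metrics=np.vstack(rows),
        site_label=sites,
    )
    return table, batch_of.copy()


def write_histoqc_tsv(table: QCMetricTable, path: str | Path, n_preamble: int = 2) -> Path:
    """Write the cohort as a HistoQC-style results TSV with '#' preamble."""
    path = Path(path)
    cols = ["filename"] + table.metric_names
    lines = [f"#synthetic QC table, preamble line {i + 1}" for i in range(n_preamble)]
    header = cols[:]
    if table.site_label is not None:
        header.append("site")
    if table.image_path is not None:
        header.append("image_path")
    lines.append("\t".join(header))
    for i in range(table.n_images):
        row = [table.image_ids[i]] + [repr(float(v)) for v in table.metrics[i]]
        if table.site_label is not None:
            row.append(table.site_label[i])
        if table.image_path is not None:
            row.append(table.image_path[i])
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
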