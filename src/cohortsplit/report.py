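"""Run outputs: results CSV, embedding figure, contact sheet, run log.

A run produces four artifacts: (1) a per-patient results CSV carrying the
metric values used for BE-group detection, the 2-D embedding coordinates, the
BE-group index, the train/test (or fold) assignment and the three cohort-level
severity metrics; (2) an embedding scatter plot with BE groups in color and
assignment as marker shape ("v" train, "o" test); (3) a contact sheet with
representative thumbnails per BE group; (4) a plain-text log collecting every
warning the pipeline emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .clustering import BEGrouping
from .embedding import EmbeddingResult
from .features import PatientFeatureMatrix
from .ingest import QCMetricTable
from .partition import PartitionPlan

logger = logging.getLogger("cohortsplit")

RESULT_FIXED_COLUMNS = ("umap_x", "umap_y", "be_group", "assignment",
                        "silhouette", "calinski_harabasz", "davies_bouldin")


class ReportError(ValueError):
    pass


@dataclass
class RunReport:
    """Paths and objects produced by a full run."""

    results_csv: Path
    figure_path: Optional[Path]
    contact_sheet_path: Optional[Path]
    log_path: Optional[Path]
    plan: PartitionPlan
    grouping: BEGrouping
    be_test: object = None


def configure_run_log(path: str | Path) -> logging.Handler:
    """Attach a timestamped file handler for this run; returns the handler."""
    path = Path(path)
    try:
        handler = logging.FileHandler(path, mode="w", encoding="utf-8")
    except OSError as exc:  # unwritable path is fatal at startup
        raise ReportError(f"cannot open log file {path}: {exc}") from exc
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    handler.setLevel(logging.INFO)
    root = logging.getLogger("cohortsplit")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def _check_same_patients(*id_lists: list[str]) -> None:
    ref = set(id_lists[0])
    for ids in id_lists[1:]:
        if set(ids) != ref:
            raise ReportError("inputs refer to different patient sets")


def write_results_csv(
    plan: PartitionPlan,
    grouping: BEGrouping,
    embedding: EmbeddingResult,
    matrix: PatientFeatureMatrix,
    path: str | Path,
) -> Path:
    """Write the per-patient results table.

    Columns, in order: patient_id, each metric used for detection, umap_x,
    umap_y, be_group, assignment, silhouette, calinski_harabasz,
    davies_bouldin. Floats are written at full round-trip precision with '.'
    decimal point, UTF-8, comma separated.
    """
    _check_same_patients(plan.patient_ids, grouping.patient_ids,
                         embedding.patient_ids, matrix.patient_ids)
    path = Path(path)
    sev = grouping.severity_metrics or {}
    g_of = dict(zip(grouping.patient_ids, grouping.group_index))
    c_of = dict(zip(embedding.patient_ids, embedding.coords))
    m_of = dict(zip(matrix.patient_ids, matrix.values))

    rows = []
    for pid in plan.patient_ids:
        row: dict[str, object] = {"patient_id": pid}
        for name, val in zip(matrix.feature_names, m_of[pid]):
            row[name] = float(val)
        row["umap_x"] = float(c_of[pid][0])
        row["umap_y"] = float(c_of[pid][1])
        row["be_group"] = int(g_of[pid])
        row["assignment"] = plan.render(pid)
        row["silhouette"] = sev.get("silhouette", float("nan"))
        row["calinski_harabasz"] = sev.get("calinski_harabasz", float("nan"))
        row["davies_bouldin"] = sev.get("davies_bouldin", float("nan"))
        rows.append(row)

    columns = ["patient_id"] + list(matrix.feature_names) + list(RESULT_FIXED_COLUMNS)
    df = pd.DataFrame(rows, columns=columns)
    # repr-precision floats so re-reading reproduces values bit-equal
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)), encoding="utf-8")
    logger.info("results CSV written to %s (%d patients)", path, len(rows))
    return path


def read_results_csv(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV (used for round-trip checks and reloading)."""
    return pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")


def render_assignment_plot(
    embedding: EmbeddingResult,
    grouping: BEGrouping,
    plan: PartitionPlan,
    path: str | Path,
) -> Path:
    """Scatter the embedding: color = BE group, marker = assignment.

    Training patients draw as "v", test patients as "o"; in fold mode every
    fold gets its own marker from a fixed cycle. The legend lists each group
    with its patient count.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    _check_same_patients(plan.patient_ids, grouping.patient_ids, embedding.patient_ids)
    path = Path(path)
    g_of = dict(zip(grouping.patient_ids, grouping.group_index))
    c_of = dict(zip(embedding.patient_ids, embedding.coords))

    cmap = plt.get_cmap("tab20")
    fold_markers = ["v", "o", "s", "D", "^", "P", "X", "*"]

    def marker_for(pid: str) -> str:
        a = plan.assignment[pid]
        if a == "train":
            return "v"
        if a == "test":
            return "o"
        return fold_markers[int(a) % len(fold_markers)]

    if not plan.is_fold_mode and not plan.test_patients():
        logger.warning("empty test set: plot rendered without 'o' glyphs")

    fig, ax = plt.subplots(figsize=(6, 5))
    for pid in plan.patient_ids:
        g = int(g_of[pid])
        ax.scatter(*c_of[pid], color=cmap(g % 20), marker=marker_for(pid),
                   s=45, edgecolors="none")
    sizes = grouping.group_sizes()
    handles = [
        plt.Line2D([], [], linestyle="", marker="s", color=cmap(g % 20),
                   label=f"BE group {g} (n={sizes[g]})")
        for g in range(grouping.k) if sizes[g] > 0
    ]
    ax.legend(handles=handles, fontsize=7, loc="best")
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.set_title(f"BE groups and {plan.strategy} assignment (v=train, o=test)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    logger.info("assignment plot written to %s", path)
    return path


def build_contact_sheet(
    table: QCMetricTable,
    grouping: BEGrouping,
    embedding: EmbeddingResult,
    per_group: int,
    path: str | Path,
    tile: int = 96,
) -> Optional[Path]:
    """Grid of representative thumbnails, one row per BE group.

    Each group contributes the ``per_group`` patients whose embedding
    coordinates lie nearest the group centroid (one thumbnail per patient,
    its first image). Returns None with a logged notice when the table has
    no image paths; unreadable images get a gray placeholder tile.
    """
    if per_group < 1:
        raise ReportError("per_group must be >= 1")
    if table.image_path is None:
        logger.info("no image paths in table: contact sheet skipped")
        return None
    from PIL import Image

    path = Path(path)
    first_path: dict[str, str] = {}
    for pid, ip in zip(table.patient_ids, table.image_path):
        first_path.setdefault(pid, ip)

    coords = dict(zip(embedding.patient_ids, embedding.coords))
    rows: list[list[str]] = []
    for g in range(grouping.k):
        members = grouping.members(g)
        if not members:
            continue
        centroid = np.mean([coords[p] for p in members], axis=0)
        members = sorted(members, key=lambda p: float(np.linalg.norm(coords[p] - centroid)))
        rows.append(members[:per_group])

    n_cols = max(len(r) for r in rows)
    sheet = Image.new("RGB", (n_cols * tile, len(rows) * tile), (255, 255, 255))
    for r, members in enumerate(rows):
        for c, pid in enumerate(members):
            try:
                img = Image.open(first_path[pid]).convert("RGB").resize((tile, tile))
            except Exception as exc:
                logger.warning("unreadable image for patient %r (%s); placeholder used", pid, exc)
                img = Image.new("RGB", (tile, tile), (128, 128, 128))
            sheet.paste(img, (c * tile, r * tile))
    sheet.save(path)
    logger.info("contact sheet written to %s (%d groups)", path, len(rows))
    return path
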