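"""Reading image quality-control metric tables.

Quality-control tools for pathology slides and MRI volumes emit one
tab-separated row per image: an identifier column followed by numeric quality
metrics (brightness, contrast, artifact extents, acquisition metadata) and,
often, free-text columns. This module reads such tables into a validated
in-memory :class:`QCMetricTable` and derives patient identifiers from image
identifiers, because every downstream step (aggregation, clustering,
partitioning) operates at patient level.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cohortsplit")

#: comment/preamble marker per dialect; the first non-preamble line is the header
DIALECTS = {"histoqc": "#", "mrqy": "#", "generic": "#"}


class IngestError(ValueError):
    """Fatal problem with an input metric table."""


@dataclass
class PatientRule:
    """How to derive a patient identifier from an image identifier.

    Exactly one of ``regex`` (first capture group) or ``delimiter``
    (split and take field ``field``) may be set; with neither, the image id
    is its own patient id (one image per patient, as for MRI volumes).
    """

    regex: Optional[str] = None
    delimiter: Optional[str] = None
    field: int = 0

    def __post_init__(self) -> None:
        if self.regex is not None and self.delimiter is not None:
            raise IngestError("patient rule: set regex or delimiter, not both")

    def apply(self, image_ids: Sequence[str]) -> list[str]:
        if self.regex is not None:
            pat = re.compile(self.regex)
            out, unmatched = [], []
            for iid in image_ids:
                m = pat.search(iid)
                if m is None or not m.groups():
                    unmatched.append(iid)
                else:
                    out.append(m.group(1))
            if unmatched:
                raise IngestError(
                    f"patient rule matched nothing for {len(unmatched)} image id(s): "
                    + ", ".join(unmatched[:10])
                )
            return out
        if self.delimiter is not None:
            out = []
            for iid in image_ids:
                parts = iid.split(self.delimiter)
                if len(parts) <= self.field:
                    raise IngestError(f"patient rule: cannot split {iid!r} on {self.delimiter!r}")
                out.append(parts[self.field])
            return out
        return list(image_ids)


@dataclass
class QCMetricTable:
    """Per-image quality metrics plus identifiers and optional labels.

    ``metrics`` holds only finite numbers after ingestion; rows align with
    ``image_ids`` and columns with ``metric_names``. Every image belongs to
    exactly one patient.
    """

    image_ids: list[str]
    patient_ids: list[str]
    metric_names: list[str]
    metrics: np.ndarray
    site_label: Optional[list[str]] = None
    outcome_label: Optional[list[str]] = None
    image_path: Optional[list[str]] = None
    dropped_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.metrics = np.asarray(self.metrics, dtype=float)
        n = len(self.image_ids)
        if len(set(self.image_ids)) != n:
            seen: set[str] = set()
            dups = []
            for iid in self.image_ids:
                if iid in seen:
                    dups.append(iid)
                seen.add(iid)
            raise IngestError(f"duplicate image ids: {sorted(set(dups))}")
        if len(self.patient_ids) != n:
            raise IngestError("patient_ids length does not match image count")
        if self.metrics.shape != (n, len(self.metric_names)):
            raise IngestError(
                f"metric matrix shape {self.metrics.shape} does not match "
                f"{n} images x {len(self.metric_names)} metrics"
            )
        for lbl_name in ("site_label", "outcome_label", "image_path"):
            lbl = getattr(self, lbl_name)
            if lbl is not None and len(lbl) != n:
                raise IngestError(f"{lbl_name} length does not match image count")

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.metrics, columns=self.metric_names)
        df.insert(0, "image_id", self.image_ids)
        df.insert(1, "patient_id", self.patient_ids)
        if self.site_label is not None:
            df["site"] = self.site_label
        if self.outcome_label is not None:
            df["outcome"] = self.outcome_label
        if self.image_path is not None:
            df["image_path"] = self.image_path
        return df

    def write_tsv(self, path: str | Path) -> None:
        """Write a generic-dialect TSV (image id first, metrics after)."""
        df = pd.DataFrame(self.metrics, columns=self.metric_names)
        df.insert(0, "filename", self.image_ids)
        if self.site_label is not None:
            df["site"] = self.site_label
        if self.image_path is not None:
            df["image_path"] = self.image_path
        df.to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))


def read_qc_table(
    path: str | Path,
    dialect: str = "generic",
    patient_rule: Optional[PatientRule] = None,
    label_column: Optional[str] = None,
    outcome_column: Optional[str] = None,
    path_column: Optional[str] = None,
    max_missing_frac: float = 0.5,
) -> QCMetricTable:
    """Read a QC-metric TSV into a :class:`QCMetricTable`.

    Preamble lines starting with the dialect's comment marker are skipped;
    the first remaining line is the header and its first column the image
    identifier. Non-numeric columns not named via ``label_column`` /
    ``outcome_column`` / ``path_column`` are excluded from the metric matrix
    and logged. Missing or non-finite metric values are imputed with the
    column median over finite entries; columns more than ``max_missing_frac``
    missing are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"input file not found: {path}")
    if dialect not in DIALECTS:
        raise IngestError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    marker = DIALECTS[dialect]

    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    n_preamble = 0
    for line in lines:
        if line.startswith(marker):
            n_preamble += 1
        else:
            break
    body = lines[n_preamble:]
    if not body:
        raise IngestError(f"{path}: no header line after preamble")

    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise IngestError(f"{path}: need an identifier column plus at least one metric column")

    id_col = df.columns[0]
    image_ids = df[id_col].astype(str).tolist()
    dup = df[id_col][df[id_col].duplicated()].unique().tolist()
    if dup:
        raise IngestError(f"duplicate image ids in {path.name}: {dup[:10]}")

    special = {id_col}
    site = outcome = img_path = None
    for col, target in ((label_column, "site"), (outcome_column, "outcome"), (path_column, "path")):
        if col is None:
            continue
        if col not in df.columns:
            raise IngestError(f"declared {target} column {col!r} not present in {path.name}")
        special.add(col)
    if label_column:
        site = df[label_column].astype(str).tolist()
    if outcome_column:
        outcome = df[outcome_column].astype(str).tolist()
    if path_column:
        img_path = df[path_column].astype(str).tolist()

    metric_names: list[str] = []
    columns: list[np.ndarray] = []
    dropped: list[str] = []
    for col in df.columns:
        if col in special:
            continue
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if finite.any():
            # pandas' fast parser is not correctly rounded; float() is
            raw = df[col].to_numpy()
            vals[finite] = [float(s) for s in raw[finite]]
        if not finite.any():
            dropped.append(col)
            logger.info("column %r is non-numeric; excluded from metrics", col)
            continue
        missing_frac = 1.0 - finite.mean()
        if missing_frac > max_missing_frac:
            dropped.append(col)
            logger.warning(
                "column %r dropped: %.0f%% missing exceeds %.0f%% threshold",
                col, 100 * missing_frac, 100 * max_missing_frac,
            )
            continue
        if not finite.all():
            med = float(np.median(vals[finite]))
            vals = np.where(finite, vals, med)
            logger.warning(
                "column %r: imputed %d missing value(s) with median %.6g",
                col, int((~finite).sum()), med,
            )
        metric_names.append(col)
        columns.append(vals)

    if not metric_names:
        raise IngestError(f"{path.name}: no usable metrics (zero numeric columns)")

    patient_ids = (patient_rule or PatientRule()).apply(image_ids)
    table = QCMetricTable(
        image_ids=image_ids,
        patient_ids=patient_ids,
        metric_names=metric_names,
        metrics=np.column_stack(columns),
        site_label=site,
        outcome_label=outcome,
        image_path=img_path,
        dropped_columns=dropped,
    )
    logger.info(
        "read %d images / %d patients / %d metrics from %s (dialect=%s, %d preamble line(s))",
        table.n_images, len(set(patient_ids)), len(metric_names), path.name, dialect, n_preamble,
    )
    return table


@dataclass
class Finding:
    severity: str  # info | warning
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.severity}] {self.message}"


def validate_table(table: QCMetricTable) -> list[Finding]:
    """Report data-quality findings without mutating the table.

    Flags zero-variance metrics, single-image patients, missing site labels
    (which make the batch-effect test unavailable) and site class counts.
    """
    findings: list[Finding] = []
    for j, name in enumerate(table.metric_names):
        if np.ptp(table.metrics[:, j]) == 0.0:
            findings.append(Finding("warning", f"zero variance: {name}"))
    counts: dict[str, int] = {}
    for pid in table.patient_ids:
        counts[pid] = counts.get(pid, 0) + 1
    singles = [p for p, c in counts.items() if c == 1]
    if singles and len(singles) < len(counts):
        findings.append(
            Finding("info", f"{len(singles)} patient(s) contribute a single image")
        )
    if table.site_label is None:
        findings.append(Finding("info", "no site label: BE test unavailable"))
    else:
        site_counts = pd.Series(table.site_label).value_counts().to_dict()
        logger.info("site label classes: %s", site_counts)
    for f in findings:
        logger.log(logging.WARNING if f.severity == "warning" else logging.INFO, f.message)
    return findings
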