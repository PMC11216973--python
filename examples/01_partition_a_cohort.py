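"""Partition a cohort into batch-balanced training and testing sets.

Simulates a 30-patient imaging cohort whose QC metrics carry three planted
batch signatures (e.g. three staining runs), writes it as a HistoQC-style
results TSV, then runs the full pipeline: ingest -> patient-level features ->
UMAP -> replicated k-means BE groups -> best-case split at a 0.2 test ratio.
"""

import tempfile
from pathlib import Path

from cohortsplit import (
    RunConfig,
    SyntheticCohortSpec,
    generate_cohort,
    read_results_csv,
    run,
    write_histoqc_tsv,
)

workdir = Path(tempfile.mkdtemp(prefix="cohortsplit_example_"))

table, truth = generate_cohort(
    SyntheticCohortSpec(n_patients=30, n_batches=3, separation=6.0, seed=17)
)
tsv = write_histoqc_tsv(table, workdir / "cohort.tsv")
print(f"simulated {table.n_images} image rows for 30 patients -> {tsv}")

report = run(RunConfig(
    input_path=tsv,
    output_dir=workdir / "out",
    dialect="histoqc",
    patient_delimiter="_",   # P001_img2.png -> patient P001
    strategy="best_case",
    test_ratio=0.2,
    seed=42,
))

df = read_results_csv(report.results_csv)
print(f"\nresults CSV: {report.results_csv}")
print(df[["patient_id", "be_group", "assignment"]].head(8).to_string(index=False))

n_test = (df["assignment"] == "test").sum()
print(f"\n{n_test} of {len(df)} patients in the test set (ratio 0.2).")
print(f"BE groups found: {report.grouping.n_groups} "
      f"(k = ceil(30/3) = {report.grouping.k} requested)")
print("severity metrics:", {k: round(v, 3) for k, v in report.grouping.severity_metrics.items()})
print("\nEach BE group contributes test patients proportionally, so both")
print("sides of the split see every technical presentation in the cohort.")
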