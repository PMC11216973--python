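"""End-to-end orchestration: ingest -> aggregate -> embed -> cluster ->
partition -> optional batch-effect test -> report.

:class:`RunConfig` mirrors the CLI flags one-to-one; all randomness flows from
its single ``seed`` through named per-stage derivations, so each stage is
independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from ._rng import derive_seed
from .betest import interpret_result, run_be_test
from .clustering import cluster_quality, cluster_replicated, default_cluster_count
from .embedding import fit_embedding
from .features import aggregate_per_patient, standardize
from .ingest import PatientRule, read_qc_table, validate_table
from .partition import (
    make_folds_best_case,
    partition_average_case,
    partition_best_case,
    partition_worst_case,
    verify_patient_integrity,
)
from .report import (
    RunReport,
    build_contact_sheet,
    configure_run_log,
    render_assignment_plot,
    write_results_csv,
)

logger = logging.getLogger("cohortsplit")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything a run needs; exactly one of test_ratio / n_folds is set."""

    input_path: Union[str, Path]
    output_dir: Union[str, Path]
    dialect: str = "generic"
    patient_regex: Optional[str] = None
    patient_delimiter: Optional[str] = None
    label_column: Optional[str] = None
    outcome_column: Optional[str] = None
    path_column: Optional[str] = None
    strategy: str = "best_case"
    test_ratio: Optional[float] = None
    n_folds: Optional[int] = None
    cluster_count: Union[int, str] = "auto"
    aggregation: str = "mean"
    n_neighbors: int = 15
    min_dist: float = 0.1
    n_replicates: int = 10
    seed: int = 42
    permutations: int = 999
    alpha: float = 0.05
    cv_folds: int = 5
    contact_sheet_per_group: int = 2
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.test_ratio is None) == (self.n_folds is None):
            raise ConfigError("set exactly one of test_ratio / n_folds")
        if self.strategy not in ("best_case", "average_case", "worst_case"):
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "worst_case" and self.n_folds is None:
            raise ConfigError("worst_case partitioning is fold-based: set n_folds")
        if self.cluster_count != "auto" and int(self.cluster_count) < 1:
            raise ConfigError("cluster_count must be 'auto' or a positive integer")


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all artifacts to the output dir."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = configure_run_log(outdir / "run.log")
    try:
        return _run_stages(config, outdir)
    except Exception as exc:
        logger.error("run failed: %s", exc)
        raise
    finally:
        logging.getLogger("cohortsplit").removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig, outdir: Path) -> RunReport:
    logger.info("run starts: strategy=%s seed=%d input=%s",
                config.strategy, config.seed, config.input_path)

    rule = PatientRule(regex=config.patient_regex, delimiter=config.patient_delimiter)
    table = read_qc_table(
        config.input_path,
        dialect=config.dialect,
        patient_rule=rule,
        label_column=config.label_column,
        outcome_column=config.outcome_column,
        path_column=config.path_column,
    )
    validate_table(table)

    matrix = standardize(aggregate_per_patient(table, statistic=config.aggregation))
    embedding = fit_embedding(
        matrix,
        n_neighbors=config.n_neighbors,
        min_dist=config.min_dist,
        seed=derive_seed(config.seed, "embedding"),
    )

    n = matrix.n_patients
    if config.cluster_count == "auto":
        k = default_cluster_count(n, config.n_folds if config.n_folds else 3)
    else:
        k = int(config.cluster_count)

    if config.strategy == "worst_case":
        plan, grouping = partition_worst_case(
            embedding, config.n_folds, seed=derive_seed(config.seed, "partition"),
            n_replicates=config.n_replicates,
        )
    else:
        grouping = cluster_replicated(
            embedding, k, n_replicates=config.n_replicates,
            seed=derive_seed(config.seed, "clustering"),
        )
        pseed = derive_seed(config.seed, "partition")
        if config.strategy == "best_case":
            if config.n_folds is not None:
                plan = make_folds_best_case(grouping, config.n_folds, seed=pseed)
            else:
                plan = partition_best_case(grouping, config.test_ratio, seed=pseed)
        else:
            plan = partition_average_case(
                matrix.patient_ids, test_ratio=config.test_ratio,
                n_folds=config.n_folds, seed=pseed,
            )
    cluster_quality(embedding, grouping)

    ok, findings = verify_patient_integrity(plan, table)
    if not ok:  # pragma: no cover - module-produced plans are always intact
        for f in findings:
            logger.error("%s", f.message)
        raise ConfigError("patient-level integrity violated")

    be_result = None
    if config.label_column is not None and table.site_label is not None:
        site_of: dict[str, str] = {}
        for pid, site in zip(table.patient_ids, table.site_label):
            site_of.setdefault(pid, site)
        labels = [site_of[p] for p in matrix.patient_ids]
        be_result = run_be_test(
            matrix, labels, B=config.permutations,
            seed=derive_seed(config.seed, "betest"), cv_folds=config.cv_folds,
        )
        verdict, sentence = interpret_result(be_result, config.alpha)
        logger.info("%s: %s", verdict, sentence)
        _write_betest_tsv(be_result, outdir / "be_test.tsv")

    results_csv = write_results_csv(plan, grouping, embedding, matrix, outdir / "results.csv")
    figure = render_assignment_plot(embedding, grouping, plan, outdir / "assignment.png")
    sheet = build_contact_sheet(
        table, grouping, embedding, config.contact_sheet_per_group,
        outdir / "contact_sheet.png",
    )
    logger.info("run complete")
    return RunReport(
        results_csv=results_csv,
        figure_path=figure,
        contact_sheet_path=sheet,
        log_path=outdir / "run.log",
        plan=plan,
        grouping=grouping,
        be_test=be_result,
    )


def _write_betest_tsv(result, path: Path) -> None:
    lines = [
        f"# observed_stat\t{result.observed_stat!r}",
        f"# B\t{result.B}",
        f"# p_value\t{result.p_value!r}",
        "metric\trank\timportance",
    ]
    for rank, (name, weight) in enumerate(result.importances, start=1):
        lines.append(f"{name}\t{rank}\t{weight!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    logger.info("BE test report written to %s", path)
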