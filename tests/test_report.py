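import numpy as np
import pytest
from PIL import Image

from cohortsplit import (
    BEGrouping,
    QCMetricTable,
    aggregate_per_patient,
    build_contact_sheet,
    cluster_quality,
    cluster_replicated,
    make_folds_best_case,
    partition_best_case,
    read_results_csv,
    render_assignment_plot,
    standardize,
    write_results_csv,
)
from cohortsplit.report import RESULT_FIXED_COLUMNS, ReportError

from conftest import make_embedding


@pytest.fixture
def toy_run(small_cohort):
    table, _ = small_cohort
    matrix = standardize(aggregate_per_patient(table))
    emb = make_embedding(matrix.values[:, :2], matrix.patient_ids)
    grouping = cluster_replicated(emb, k=3, seed=0)
    cluster_quality(emb, grouping)
    plan = partition_best_case(grouping, test_ratio=0.2, seed=0)
    return table, matrix, emb, grouping, plan


def test_results_csv_shape_and_columns(toy_run, tmp_path):
    table, matrix, emb, grouping, plan = toy_run
    path = write_results_csv(plan, grouping, emb, matrix, tmp_path / "r.csv")
    df = read_results_csv(path)
    assert len(df) == matrix.n_patients
    assert list(df.columns) == ["patient_id"] + matrix.feature_names + list(RESULT_FIXED_COLUMNS)
    # cohort-level severity values identical on every row
    for col in ("silhouette", "calinski_harabasz", "davies_bouldin"):
        assert df[col].nunique() == 1


def test_results_csv_roundtrip_bit_equal(toy_run, tmp_path):
    table, matrix, emb, grouping, plan = toy_run
    path = write_results_csv(plan, grouping, emb, matrix, tmp_path / "r.csv")
    df = read_results_csv(path)
    order = {p: i for i, p in enumerate(matrix.patient_ids)}
    idx = [order[p] for p in df["patient_id"]]
    np.testing.assert_array_equal(df[matrix.feature_names].to_numpy(), matrix.values[idx])
    np.testing.assert_array_equal(df[["umap_x", "umap_y"]].to_numpy(), emb.coords[idx])


def test_results_csv_reconstructs_plan_and_grouping(toy_run, tmp_path):
    table, matrix, emb, grouping, plan = toy_run
    df = read_results_csv(write_results_csv(plan, grouping, emb, matrix, tmp_path / "r.csv"))
    rebuilt_groups = dict(zip(df["patient_id"], df["be_group"]))
    assert rebuilt_groups == dict(zip(grouping.patient_ids, (int(g) for g in grouping.group_index)))
    rebuilt_assign = dict(zip(df["patient_id"], df["assignment"]))
    assert rebuilt_assign == {p: plan.render(p) for p in plan.patient_ids}


def test_results_csv_patient_mismatch_fatal(toy_run, tmp_path):
    table, matrix, emb, grouping, plan = toy_run
    other = BEGrouping(["X1", "X2"], np.array([0, 1]), k=2)
    with pytest.raises(ReportError, match="different patient sets"):
        write_results_csv(plan, other, emb, matrix, tmp_path / "r.csv")


def test_assignment_plot_written(toy_run, tmp_path):
    table, matrix, emb, grouping, plan = toy_run
    path = render_assignment_plot(emb, grouping, plan, tmp_path / "plot.png")
    img = Image.open(path)
    assert img.size[0] > 100 and img.size[1] > 100


def test_plot_deterministic_bytes(toy_run, tmp_path):
    table, matrix, emb, grouping, plan = toy_run
    p1 = render_assignment_plot(emb, grouping, plan, tmp_path / "a.png")
    p2 = render_assignment_plot(emb, grouping, plan, tmp_path / "b.png")
    assert p1.read_bytes() == p2.read_bytes()


def test_fold_plan_renders(toy_run, tmp_path):
    table, matrix, emb, grouping, plan = toy_run
    folds = make_folds_best_case(grouping, n_folds=3, seed=0)
    path = render_assignment_plot(emb, grouping, folds, tmp_path / "folds.png")
    assert path.exists()


def test_contact_sheet_grid(tmp_path, small_cohort):
    table, _ = small_cohort
    imgdir = tmp_path / "imgs"
    imgdir.mkdir()
    paths = []
    for i, iid in enumerate(table.image_ids):
        p = imgdir / f"{iid}"
        Image.new("RGB", (32, 32), (i % 255, 100, 50)).save(p)
        paths.append(str(p))
    table_with_paths = QCMetricTable(
        image_ids=list(table.image_ids),
        patient_ids=list(table.patient_ids),
        metric_names=list(table.metric_names),
        metrics=table.metrics.copy(),
        image_path=paths,
    )
    matrix = standardize(aggregate_per_patient(table_with_paths))
    emb = make_embedding(matrix.values[:, :2], matrix.patient_ids)
    grouping = cluster_replicated(emb, k=3, seed=0)
    sheet = build_contact_sheet(table_with_paths, grouping, emb, per_group=2,
                                path=tmp_path / "sheet.png", tile=32)
    img = Image.open(sheet)
    assert img.size == (2 * 32, 3 * 32)  # 3 groups x 2 representatives


def test_contact_sheet_skipped_without_paths(toy_run, tmp_path):
    table, matrix, emb, grouping, plan = toy_run
    out = build_contact_sheet(table, grouping, emb, per_group=2, path=tmp_path / "s.png")
    assert out is None
    assert not (tmp_path / "s.png").exists()


def test_contact_sheet_placeholder_for_unreadable(tmp_path, small_cohort):
    table, _ = small_cohort
    table_bad = QCMetricTable(
        image_ids=list(table.image_ids),
        patient_ids=list(table.patient_ids),
        metric_names=list(table.metric_names),
        metrics=table.metrics.copy(),
        image_path=["/nonexistent/img.png"] * table.n_images,
    )
    matrix = standardize(aggregate_per_patient(table_bad))
    emb = make_embedding(matrix.values[:, :2], matrix.patient_ids)
    grouping = cluster_replicated(emb, k=2, seed=0)
    sheet = build_contact_sheet(table_bad, grouping, emb, per_group=1,
                                path=tmp_path / "s.png", tile=16)
    assert sheet is not None and sheet.exists()
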