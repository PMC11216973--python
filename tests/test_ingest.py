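import numpy as np
import pytest

from cohortsplit import PatientRule, QCMetricTable, read_qc_table, validate_table
from cohortsplit.ingest import IngestError


def write_tsv(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


FIXTURE = [
    "#preamble line one",
    "#preamble line two",
    "filename\tbrightness\tcontrast",
    "P01_roi1.png\t0.2\t1.5",
    "P01_roi2.png\t0.4\t1.7",
    "P02_roi1.png\t0.6\t1.1",
    "P02_roi2.png\t0.8\t1.3",
]


def test_reads_fixture_with_preamble(tmp_path):
    path = write_tsv(tmp_path / "qc.tsv", FIXTURE)
    table = read_qc_table(path, dialect="histoqc")
    assert table.n_images == 4
    assert table.metric_names == ["brightness", "contrast"]
    assert table.metrics[1, 0] == pytest.approx(0.4)
    # order-preserving ingestion
    assert table.image_ids == [l.split("\t")[0] for l in FIXTURE[3:]]


def test_undeclared_text_column_excluded_and_recorded(tmp_path):
    lines = [FIXTURE[2] + "\tcomments"] + [l + "\tok" for l in FIXTURE[3:]]
    path = write_tsv(tmp_path / "qc.tsv", lines)
    table = read_qc_table(path, dialect="generic")
    assert table.metric_names == ["brightness", "contrast"]
    assert "comments" in table.dropped_columns


@pytest.mark.parametrize(
    "rule,expected",
    [
        (PatientRule(delimiter="_"), ["P01", "P01", "P02"]),
        (PatientRule(regex=r"^(P\d+)_"), ["P01", "P01", "P02"]),
        (PatientRule(), ["P01_roi1.png", "P01_roi2.png", "P02_roi1.png"]),
    ],
)
def test_patient_rules(tmp_path, rule, expected):
    path = write_tsv(tmp_path / "qc.tsv", FIXTURE[:6])
    table = read_qc_table(path, patient_rule=rule)
    assert table.patient_ids == expected


def test_patient_rule_unmatched_is_fatal(tmp_path):
    path = write_tsv(tmp_path / "qc.tsv", FIXTURE)
    with pytest.raises(IngestError, match="matched nothing"):
        read_qc_table(path, patient_rule=PatientRule(regex=r"(Q\d+)"))


def test_missing_file_and_duplicate_ids_and_no_metrics(tmp_path):
    with pytest.raises(IngestError, match="not found"):
        read_qc_table(tmp_path / "absent.tsv")
    dup = FIXTURE[:4] + [FIXTURE[3]]
    with pytest.raises(IngestError, match="duplicate image ids"):
        read_qc_table(write_tsv(tmp_path / "dup.tsv", dup))
    text_only = ["filename\tnotes", "a.png\thello", "b.png\tworld"]
    with pytest.raises(IngestError, match="no usable metrics"):
        read_qc_table(write_tsv(tmp_path / "text.tsv", text_only))


def test_label_columns_routed(tmp_path):
    lines = [FIXTURE[2] + "\tsite"] + [l + f"\tsite{i % 2}" for i, l in enumerate(FIXTURE[3:])]
    path = write_tsv(tmp_path / "qc.tsv", lines)
    table = read_qc_table(path, label_column="site")
    assert table.site_label == ["site0", "site1", "site0", "site1"]
    assert table.metric_names == ["brightness", "contrast"]


def test_missing_values_imputed_with_column_median(tmp_path):
    lines = [
        "filename\tm1\tm2",
        "a.png\t1.0\t5.0",
        "b.png\t\t7.0",
        "c.png\t3.0\t9.0",
    ]
    table = read_qc_table(write_tsv(tmp_path / "qc.tsv", lines))
    assert table.metrics[1, 0] == pytest.approx(2.0)  # median of {1, 3}
    assert np.isfinite(table.metrics).all()


def test_mostly_missing_column_dropped(tmp_path):
    lines = [
        "filename\tm1\tm2",
        "a.png\t1.0\t5.0",
        "b.png\t\t7.0",
        "c.png\t\t9.0",
    ]
    table = read_qc_table(write_tsv(tmp_path / "qc.tsv", lines))
    assert table.metric_names == ["m2"]
    assert "m1" in table.dropped_columns


def test_roundtrip_write_read(tmp_path, small_cohort):
    table, _ = small_cohort
    path = tmp_path / "roundtrip.tsv"
    table.write_tsv(path)
    back = read_qc_table(path, dialect="generic",
                         patient_rule=PatientRule(delimiter="_"),
                         label_column="site")
    assert back.image_ids == table.image_ids
    assert back.patient_ids == table.patient_ids
    assert back.metric_names == table.metric_names
    np.testing.assert_allclose(back.metrics, table.metrics, rtol=0, atol=0)


def test_validate_table_findings(tiny_table):
    # clean table with site labels -> single-image-patient info only
    findings = validate_table(tiny_table)
    assert all("zero variance" not in f.message for f in findings)
    assert any("no site label" in f.message for f in findings)

    const = QCMetricTable(
        image_ids=["a", "b"],
        patient_ids=["a", "b"],
        metric_names=["flat"],
        metrics=np.array([[1.0], [1.0]]),
        site_label=["s1", "s2"],
    )
    messages = [f.message for f in validate_table(const)]
    assert any("zero variance: flat" in m for m in messages)
    assert not any("no site label" in m for m in messages)
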