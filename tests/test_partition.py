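import numpy as np
import pytest

from cohortsplit import (
    BEGrouping,
    QCMetricTable,
    make_folds_best_case,
    partition_average_case,
    partition_best_case,
    partition_worst_case,
    verify_patient_integrity,
)
from cohortsplit.partition import PartitionError, largest_remainder_counts

from conftest import blob_coords, make_embedding


def grouping_from_sizes(sizes):
    ids, labels = [], []
    for g, n in enumerate(sizes):
        for i in range(n):
            ids.append(f"G{g}P{i}")
            labels.append(g)
    return BEGrouping(ids, np.array(labels), k=len(sizes))


def enumerate_largest_remainder(sizes, ratio):
    """Independent oracle: enumerate apportionments, apply the stated rule."""
    import math

    total = int(math.floor(ratio * sum(sizes) + 0.5))
    quotas = [ratio * s for s in sizes]
    floors = [math.floor(q) for q in quotas]
    seats = list(floors)
    leftovers = total - sum(floors)
    by_frac = sorted(range(len(sizes)), key=lambda g: (-(quotas[g] - floors[g]), g))
    for g in by_frac[:leftovers]:
        seats[g] += 1
    return seats


@pytest.mark.parametrize(
    "sizes,ratio",
    [((10,), 0.2), ((3, 3, 3), 1 / 3), ((5, 4, 3), 0.5), ((7, 2, 6, 5), 0.25)],
)
def test_apportionment_matches_oracle(sizes, ratio):
    assert largest_remainder_counts(sizes, ratio) == enumerate_largest_remainder(sizes, ratio)


def test_apportionment_tie_break_documented_case():
    # floors (2,2,1) leave one seat; fractional parts (.5, 0, .5) tie 0 vs 2 -> group 0
    assert largest_remainder_counts((5, 4, 3), 0.5) == [3, 2, 1]


def test_best_case_ratio_counts():
    plan = partition_best_case(grouping_from_sizes([10]), test_ratio=0.2, seed=0)
    assert len(plan.test_patients()) == 2
    assert len(plan.train_patients()) == 8

    plan = partition_best_case(grouping_from_sizes([3, 3, 3]), test_ratio=1 / 3, seed=0)
    for g in range(3):
        members = {f"G{g}P{i}" for i in range(3)}
        assert sum(plan.assignment[p] == "test" for p in members) == 1


def test_best_case_singleton_goes_to_training():
    plan = partition_best_case(grouping_from_sizes([1, 4, 4]), test_ratio=0.5, seed=1)
    assert plan.assignment["G0P0"] == "train"


def test_best_case_folds_exact_dealing():
    plan = make_folds_best_case(grouping_from_sizes([3, 3, 3]), n_folds=3, seed=0)
    assert plan.fold_sizes() == [3, 3, 3]
    for g in range(3):
        folds = {plan.assignment[f"G{g}P{i}"] for i in range(3)}
        assert folds == {0, 1, 2}  # one member per fold


def test_best_case_folds_short_group_balances_overall():
    # 31 groups of <=3 patients summing to 91 -> overall fold sizes within 1
    rng = np.random.default_rng(0)
    sizes = [3] * 29 + [2, 2]
    assert sum(sizes) == 91
    plan = make_folds_best_case(grouping_from_sizes(sizes), n_folds=3, seed=4)
    fs = sorted(plan.fold_sizes(), reverse=True)
    assert fs == [31, 30, 30]


def test_average_case_counts_and_determinism():
    ids = [f"P{i}" for i in range(90)]
    plan = partition_average_case(ids, n_folds=3, seed=2)
    assert plan.fold_sizes() == [30, 30, 30]

    ids10 = [f"P{i}" for i in range(10)]
    plan_r = partition_average_case(ids10, test_ratio=0.3, seed=2)
    assert len(plan_r.test_patients()) == 3
    again = partition_average_case(ids10, test_ratio=0.3, seed=2)
    assert plan_r.assignment == again.assignment


def test_worst_case_blobs_become_folds():
    rng = np.random.default_rng(1)
    coords, truth = blob_coords(rng, [3, 3], [(0, 0), (100, 0)], sd=0.5)
    plan, grouping = partition_worst_case(make_embedding(coords), n_folds=2, seed=0)
    assert sorted(plan.fold_sizes()) == [3, 3]
    # each fold is exactly one blob (brute force over balanced splits agrees:
    # the blob split minimizes within-group scatter by construction)
    fold_of_blob0 = {plan.assignment[p] for p, t in zip(plan.patient_ids, truth) if t == 0}
    fold_of_blob1 = {plan.assignment[p] for p, t in zip(plan.patient_ids, truth) if t == 1}
    assert len(fold_of_blob0) == 1 and len(fold_of_blob1) == 1
    assert fold_of_blob0 != fold_of_blob1


@pytest.mark.parametrize("n,k,expected", [(91, 3, [31, 30, 30]), (9, 3, [3, 3, 3])])
def test_worst_case_balance(n, k, expected):
    rng = np.random.default_rng(7)
    emb = make_embedding(rng.normal(size=(n, 2)) * 5)
    plan, grouping = partition_worst_case(emb, n_folds=k, seed=3)
    assert sorted(plan.fold_sizes(), reverse=True) == expected
    assert sorted(grouping.group_sizes(), reverse=True) == expected


def test_worst_case_degenerate_embedding():
    emb = make_embedding(np.zeros((7, 2)))
    plan, _ = partition_worst_case(emb, n_folds=3, seed=0)
    assert sorted(plan.fold_sizes(), reverse=True) == [3, 2, 2]


def test_worst_case_separation_property():
    """Within-fold embedding distances do not exceed between-fold distances
    on blob cohorts (averaged over seeds)."""
    ok = 0
    for s in range(20):
        rng = np.random.default_rng(100 + s)
        sizes = [7, 7, 7]
        centers = rng.normal(size=(3, 2)) * 20
        coords, _ = blob_coords(rng, sizes, centers, sd=1.0)
        plan, _ = partition_worst_case(make_embedding(coords), n_folds=3, seed=s)
        labels = np.array([plan.assignment[p] for p in plan.patient_ids])
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        within = d[same].mean()
        between = d[~same & ~np.eye(len(labels), dtype=bool)].mean()
        ok += within <= between
    assert ok == 20


def test_patient_integrity_checks(tiny_table):
    grouping = BEGrouping(["P01", "P02", "P03"], np.array([0, 0, 1]), k=2)
    plan = partition_best_case(grouping, test_ratio=0.34, seed=0)
    ok, findings = verify_patient_integrity(plan, tiny_table)
    assert ok and findings == []

    # corrupt the table: one image re-pointed at a patient absent from the plan
    corrupted = QCMetricTable(
        image_ids=list(tiny_table.image_ids),
        patient_ids=["P01", "P99", "P02", "P03"],
        metric_names=list(tiny_table.metric_names),
        metrics=tiny_table.metrics.copy(),
    )
    ok, findings = verify_patient_integrity(plan, corrupted)
    assert not ok and len(findings) == 1

    empty = QCMetricTable([], [], ["m"], np.empty((0, 1)))
    ok, findings = verify_patient_integrity(plan, empty)
    assert ok and findings == []


def test_fold_rendering_is_one_based():
    plan = make_folds_best_case(grouping_from_sizes([3, 3]), n_folds=3, seed=0)
    rendered = {plan.render(p) for p in plan.patient_ids}
    assert rendered <= {"BC_1", "BC_2", "BC_3"}


def test_ratio_and_folds_mutually_exclusive():
    with pytest.raises(PartitionError):
        partition_average_case(["a", "b"], test_ratio=0.5, n_folds=2, seed=0)
    with pytest.raises(PartitionError):
        partition_average_case(["a", "b"], seed=0)
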