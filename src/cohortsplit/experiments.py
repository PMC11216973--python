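"""Desk-scale evaluation experiments.

The package's claims are checked by four Monte-Carlo experiments on synthetic
cohorts, each runnable on one CPU in minutes:

* **cluster recovery** — replicated k-means on UMAP embeddings recovers
  planted batch blobs (adjusted Rand index against generator ground truth);
* **type-I calibration** — on null cohorts (no batch signal, labels
  independent of metrics) the permutation test rejects at about its nominal
  level;
* **power** — on cohorts with a 3-sd planted batch shift the test rejects
  nearly always;
* **partition spectrum** — a nearest-centroid proxy classifier scores best
  under batch-balanced folds, intermediate under random folds, and worst
  under batch-maximizing folds, reproducing the qualitative ordering that
  motivates balanced partitioning, without any GPU training.

All functions are deterministic given their ``seed``.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.metrics import adjusted_rand_score

from ._rng import derive_seed
from .betest import run_be_test
from .clustering import cluster_replicated, default_cluster_count
from .embedding import fit_embedding
from .features import PatientFeatureMatrix, aggregate_per_patient, standardize
from .partition import (
    PartitionPlan,
    make_folds_best_case,
    partition_average_case,
    partition_worst_case,
)
from .simulate import SyntheticCohortSpec, generate_cohort

logger = logging.getLogger("cohortsplit")

#: forest settings for the Monte-Carlo permutation-test experiments; a small
#: forest keeps ~50k statistic evaluations tractable and leaves the test's
#: validity untouched (observed and null replicates share the settings)
MC_TREES = 5
MC_CV_FOLDS = 3


def _cohort_features(spec: SyntheticCohortSpec):
    """Generate a cohort and return (standardized matrix, per-patient site, truth)."""
    table, truth = generate_cohort(spec)
    matrix = standardize(aggregate_per_patient(table))
    site_of: dict[str, str] = {}
    for pid, site in zip(table.patient_ids, table.site_label):
        site_of.setdefault(pid, site)
    labels = [site_of[p] for p in matrix.patient_ids]
    return matrix, labels, truth


def cluster_recovery(
    n_seeds: int = 20,
    n_patients: int = 60,
    separation: float = 6.0,
    seed: int = 0,
) -> list[float]:
    """ARI of recovered vs planted batches over ``n_seeds`` cohorts.

    Cohorts have 3 planted blobs; 60 patients keeps each blob (20) larger
    than the default UMAP neighborhood (15), which the k-NN graph needs to
    respect the planted structure.
    """
    aris = []
    for i in range(n_seeds):
        spec = SyntheticCohortSpec(
            n_patients=n_patients, n_batches=3, separation=separation,
            seed=derive_seed(seed, "recovery", i),
        )
        matrix, _, truth = _cohort_features(spec)
        emb = fit_embedding(matrix, seed=derive_seed(seed, "recovery-emb", i))
        grouping = cluster_replicated(emb, k=3, seed=derive_seed(seed, "recovery-km", i))
        aris.append(float(adjusted_rand_score(truth, grouping.group_index)))
    return aris


def _null_cohort_labels(seed: int, n_patients: int, n_batches: int, cv_folds: int):
    """A null cohort whose random site classes are all large enough for CV.

    Redrawing on a too-small class is independent of the metric-label
    relationship under the null, so it does not bias the type-I rate.
    """
    for attempt in range(20):
        spec = SyntheticCohortSpec(
            n_patients=n_patients, n_batches=n_batches, separation=0.0,
            label_confounding=1.0 / n_batches,
            seed=derive_seed(seed, "null", attempt),
        )
        matrix, labels, _ = _cohort_features(spec)
        _, counts = np.unique(labels, return_counts=True)
        if counts.size >= 2 and counts.min() >= cv_folds:
            return matrix, labels
    raise RuntimeError("could not draw a null cohort with usable class sizes")


def type1_calibration(
    n_cohorts: int = 200,
    B: int = 199,
    alpha: float = 0.05,
    n_patients: int = 30,
    n_batches: int = 3,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of the BE test on null cohorts."""
    rejections = 0
    for i in range(n_cohorts):
        matrix, labels = _null_cohort_labels(
            derive_seed(seed, "type1", i), n_patients, n_batches, MC_CV_FOLDS
        )
        result = run_be_test(
            matrix, labels, B=B, seed=derive_seed(seed, "type1-test", i),
            cv_folds=MC_CV_FOLDS, n_trees=MC_TREES,
        )
        rejections += result.p_value <= alpha
    return rejections / n_cohorts


def power_experiment(
    n_cohorts: int = 50,
    separation: float = 3.0,
    B: int = 199,
    alpha: float = 0.05,
    n_patients: int = 30,
    seed: int = 0,
) -> float:
    """Rejection rate on cohorts with a planted batch->metric shift.

    Sites coincide with batches (full confounding), the situation the test
    exists to flag.
    """
    rejections = 0
    for i in range(n_cohorts):
        spec = SyntheticCohortSpec(
            n_patients=n_patients, n_batches=3, separation=separation,
            label_confounding=1.0, seed=derive_seed(seed, "power", i),
        )
        matrix, labels, _ = _cohort_features(spec)
        result = run_be_test(
            matrix, labels, B=B, seed=derive_seed(seed, "power-test", i),
            cv_folds=MC_CV_FOLDS, n_trees=MC_TREES,
        )
        rejections += result.p_value <= alpha
    return rejections / n_cohorts


def nearest_centroid_cv_score(
    matrix: PatientFeatureMatrix, labels: dict[str, str], plan: PartitionPlan
) -> float:
    """Mean cross-fold accuracy of a nearest-class-centroid classifier.

    For each fold, class centroids are computed from the other folds in
    standardized feature space; test patients are assigned the label of the
    nearest centroid. A test class absent from training counts as wrong —
    exactly the failure mode batch-maximizing folds create.
    """
    assert plan.n_folds is not None
    X = {p: v for p, v in zip(matrix.patient_ids, matrix.values)}
    accs = []
    for f in range(plan.n_folds):
        test = plan.fold_members(f)
        train = [p for p in plan.patient_ids if plan.assignment[p] != f]
        if not test or not train:
            continue
        centroids: dict[str, np.ndarray] = {}
        for lab in set(labels[p] for p in train):
            members = [X[p] for p in train if labels[p] == lab]
            centroids[lab] = np.mean(members, axis=0)
        correct = 0
        names = list(centroids)
        for p in test:
            d = [np.linalg.norm(X[p] - centroids[nm]) for nm in names]
            correct += names[int(np.argmin(d))] == labels[p]
        accs.append(correct / len(test))
    return float(np.mean(accs))


def partition_spectrum(
    n_cohorts: int = 20,
    n_patients: int = 30,
    separation: float = 4.0,
    label_confounding: float = 0.9,
    n_folds: int = 3,
    seed: int = 0,
) -> dict[str, float]:
    """Mean proxy-classifier score per strategy over batch-confounded cohorts.

    Returns mean accuracies for ``best_case``, ``average_case`` and
    ``worst_case`` fold plans; balanced partitioning should score highest and
    batch-maximizing folds lowest.
    """
    scores: dict[str, list[float]] = {"best_case": [], "average_case": [], "worst_case": []}
    for i in range(n_cohorts):
        spec = SyntheticCohortSpec(
            n_patients=n_patients, n_batches=n_folds, separation=separation,
            label_confounding=label_confounding,
            seed=derive_seed(seed, "spectrum", i),
        )
        matrix, labels, _ = _cohort_features(spec)
        label_of = dict(zip(matrix.patient_ids, labels))
        emb = fit_embedding(matrix, seed=derive_seed(seed, "spectrum-emb", i))
        k = default_cluster_count(matrix.n_patients, n_folds)
        grouping = cluster_replicated(emb, k, seed=derive_seed(seed, "spectrum-km", i))

        pseed = derive_seed(seed, "spectrum-part", i)
        bc = make_folds_best_case(grouping, n_folds, seed=pseed)
        ac = partition_average_case(matrix.patient_ids, n_folds=n_folds, seed=pseed)
        wc, _ = partition_worst_case(emb, n_folds, seed=pseed)

        scores["best_case"].append(nearest_centroid_cv_score(matrix, label_of, bc))
        scores["average_case"].append(nearest_centroid_cv_score(matrix, label_of, ac))
        scores["worst_case"].append(nearest_centroid_cv_score(matrix, label_of, wc))
    return {k: float(np.mean(v)) for k, v in scores.items()}
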