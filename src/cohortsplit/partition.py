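"""Patient-level train/test partitions and cross-validation folds.

Three strategies span the spectrum of batch-effect exposure:

* **best_case** — every BE group contributes train and test members in the
  user-given ratio (or one member per fold), so both sides of the split see
  the full spread of technical presentations;
* **average_case** — plain random assignment, the field's default practice;
* **worst_case** — folds coincide with (size-balanced) BE groups, so a model
  is always evaluated on a technical presentation it never trained on.

All assignment happens at patient level: every image of a patient inherits
the patient's assignment, which prevents within-patient leakage across folds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._rng import derive_seed
from .clustering import BEGrouping, ClusteringError, _canonicalize, cluster_replicated
from .embedding import EmbeddingResult
from .ingest import Finding, QCMetricTable

logger = logging.getLogger("cohortsplit")

TRAIN, TEST = "train", "test"

STRATEGY_PREFIX = {"best_case": "BC", "average_case": "AC", "worst_case": "WC"}


class PartitionError(ValueError):
    pass


@dataclass
class PartitionPlan:
    """A patient-level partition (train/test, or folds).

    ``assignment`` maps each patient id either to ``"train"``/``"test"`` or to
    a 0-based fold index. Reports render folds 1-based with the strategy
    prefix (``BC_1`` ...).
    """

    patient_ids: list[str]
    assignment: dict[str, object]
    strategy: str
    seed: int
    test_ratio: Optional[float] = None
    n_folds: Optional[int] = None
    source_grouping: Optional[BEGrouping] = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGY_PREFIX:
            raise PartitionError(f"unknown strategy {self.strategy!r}")
        if set(self.assignment) != set(self.patient_ids):
            raise PartitionError("assignment keys must equal patient_ids exactly")
        if (self.test_ratio is None) == (self.n_folds is None):
            raise PartitionError("exactly one of test_ratio / n_folds must be set")

    @property
    def is_fold_mode(self) -> bool:
        return self.n_folds is not None

    def test_patients(self) -> list[str]:
        return [p for p in self.patient_ids if self.assignment[p] == TEST]

    def train_patients(self) -> list[str]:
        return [p for p in self.patient_ids if self.assignment[p] == TRAIN]

    def fold_members(self, f: int) -> list[str]:
        return [p for p in self.patient_ids if self.assignment[p] == f]

    def fold_sizes(self) -> list[int]:
        assert self.n_folds is not None
        return [len(self.fold_members(f)) for f in range(self.n_folds)]

    def render(self, patient_id: str) -> str:
        """Human-readable assignment label (``train``/``test`` or ``BC_1``)."""
        a = self.assignment[patient_id]
        if isinstance(a, str):
            return a
        return f"{STRATEGY_PREFIX[self.strategy]}_{int(a) + 1}"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def largest_remainder_counts(
    sizes: Sequence[int],
    ratio: float,
    caps: Optional[Sequence[int]] = None,
) -> list[int]:
    """Hamilton apportionment of test slots to groups.

    Quota of group g is ``ratio * |g|``; each group gets its floor, and the
    remaining seats (up to the half-up round of ``ratio * sum(sizes)``) go by
    descending fractional part, ties broken by ascending group index. A group
    never receives more than ``ceil(quota)`` or its cap (default: its size);
    if the caps make the total unreachable the allocation falls short, which
    the caller logs.
    """
    sizes = list(sizes)
    if caps is None:
        caps = sizes
    total_seats = _round_half_up(ratio * sum(sizes))
    quotas = [ratio * s for s in sizes]
    seats = [min(int(math.floor(q)), c) for q, c in zip(quotas, caps)]
    leftover = total_seats - sum(seats)
    order = sorted(
        range(len(sizes)),
        key=lambda g: (-(quotas[g] - math.floor(quotas[g])), g),
    )
    for g in order:
        if leftover <= 0:
            break
        if seats[g] < min(caps[g], int(math.ceil(quotas[g]))):
            seats[g] += 1
            leftover -= 1
    return seats


def partition_best_case(grouping: BEGrouping, test_ratio: float, seed: int) -> PartitionPlan:
    """Train/test split sampling test patients from every BE group.

    Per-group test counts follow largest-remainder apportionment of
    ``test_ratio * |group|``; test members are drawn uniformly within each
    group under the seed. Singleton groups go to training with a warning —
    a test-only technical presentation unseen in training is exactly the
    pathology the tool exists to avoid.
    """
    if not 0.0 < test_ratio < 1.0:
        raise PartitionError("test_ratio must be in (0, 1)")
    groups = [m for m in (grouping.members(g) for g in range(grouping.k)) if m]
    for m in groups:
        if len(m) == 1:
            logger.warning("BE group with single patient %r assigned to training", m[0])

    sizes = [len(m) for m in groups]
    # cap at |g| - 1 so every group keeps a training member (singletons -> 0)
    seats = largest_remainder_counts(sizes, test_ratio, caps=[s - 1 for s in sizes])
    target = _round_half_up(test_ratio * sum(sizes))
    if sum(seats) < target:
        logger.warning(
            "test set has %d patients instead of %d: group-size caps bind",
            sum(seats), target,
        )

    assignment: dict[str, object] = {p: TRAIN for m in groups for p in m}
    for i, (members, n_test) in enumerate(zip(groups, seats)):
        rng = np.random.default_rng(derive_seed(seed, "best_case", i))
        chosen = rng.choice(len(members), size=n_test, replace=False)
        for c in chosen:
            assignment[members[c]] = TEST

    return PartitionPlan(
        patient_ids=list(grouping.patient_ids),
        assignment=assignment,
        strategy="best_case",
        seed=seed,
        test_ratio=test_ratio,
        source_grouping=grouping,
    )


def make_folds_best_case(grouping: BEGrouping, n_folds: int, seed: int) -> PartitionPlan:
    """Deal each BE group's members across folds, keeping fold sizes within 1.

    Members of a group are shuffled under the seed and dealt round-robin over
    the folds ordered by ascending (current size, fold index), so each group
    is spread as evenly as possible and overall fold sizes never differ by
    more than one.
    """
    if n_folds < 2:
        raise PartitionError("n_folds must be at least 2")
    assignment: dict[str, object] = {}
    fold_sizes = [0] * n_folds
    for g in range(grouping.k):
        members = grouping.members(g)
        if not members:
            continue
        rng = np.random.default_rng(derive_seed(seed, "bc_folds", g))
        members = [members[i] for i in rng.permutation(len(members))]
        order = sorted(range(n_folds), key=lambda f: (fold_sizes[f], f))
        for j, patient in enumerate(members):
            f = order[j % n_folds]
            assignment[patient] = f
            fold_sizes[f] += 1

    return PartitionPlan(
        patient_ids=list(grouping.patient_ids),
        assignment=assignment,
        strategy="best_case",
        seed=seed,
        n_folds=n_folds,
        source_grouping=grouping,
    )


def partition_average_case(
    patient_ids: Sequence[str],
    test_ratio: Optional[float] = None,
    n_folds: Optional[int] = None,
    seed: int = 0,
) -> PartitionPlan:
    """Uniform random assignment ignoring BE groups (the field's default)."""
    if (test_ratio is None) == (n_folds is None):
        raise PartitionError("set exactly one of test_ratio / n_folds")
    patient_ids = list(patient_ids)
    rng = np.random.default_rng(derive_seed(seed, "average_case"))
    perm = [patient_ids[i] for i in rng.permutation(len(patient_ids))]
    assignment: dict[str, object] = {}
    if test_ratio is not None:
        if not 0.0 < test_ratio < 1.0:
            raise PartitionError("test_ratio must be in (0, 1)")
        n_test = _round_half_up(test_ratio * len(patient_ids))
        for i, p in enumerate(perm):
            assignment[p] = TEST if i < n_test else TRAIN
    else:
        if n_folds < 2:
            raise PartitionError("n_folds must be at least 2")
        for i, p in enumerate(perm):
            assignment[p] = i % n_folds
    return PartitionPlan(
        patient_ids=patient_ids,
        assignment=assignment,
        strategy="average_case",
        seed=seed,
        test_ratio=test_ratio,
        n_folds=n_folds,
    )


def partition_worst_case(
    embedding: EmbeddingResult,
    n_folds: int,
    seed: int,
    n_replicates: int = 10,
) -> tuple[PartitionPlan, BEGrouping]:
    """Folds that coincide with size-balanced BE groups.

    Patients are clustered into ``n_folds`` groups in embedding space, then
    balanced greedily: while the sizes are uneven, the largest group's member
    closest (Euclidean, in embedding space) to the smallest group's centroid
    moves there, with centroids recomputed after every move. Each balanced
    group becomes one fold verbatim; fold sizes differ by at most one
    (91 patients, 3 folds -> 31/30/30).
    """
    n = embedding.n_patients
    if n_folds < 2:
        raise PartitionError("n_folds must be at least 2")
    if n < n_folds:
        raise PartitionError(f"cannot form {n_folds} folds from {n} patients")

    coords = embedding.coords
    if np.allclose(coords, coords[0]):
        logger.warning("degenerate embedding (all points identical): arbitrary balanced split")
        labels = np.array([i % n_folds for i in range(n)])
    else:
        grouping0 = cluster_replicated(embedding, k=n_folds, n_replicates=n_replicates, seed=seed)
        labels = grouping0.group_index.copy()

    cap = math.ceil(n / n_folds)
    sizes = np.bincount(labels, minlength=n_folds)
    guard = 0
    while sizes.max() > cap or sizes.max() - sizes.min() > 1:
        guard += 1
        if guard > 10 * n:  # pragma: no cover - safety valve
            raise PartitionError("worst-case balancing did not converge")
        big = int(np.argmax(sizes))
        small = int(np.argmin(sizes))
        small_centroid = coords[labels == small].mean(axis=0) if sizes[small] else coords.mean(axis=0)
        members = np.flatnonzero(labels == big)
        dists = np.linalg.norm(coords[members] - small_centroid, axis=1)
        mover = members[int(np.argmin(dists))]
        labels[mover] = small
        sizes = np.bincount(labels, minlength=n_folds)

    labels = _canonicalize(labels)
    grouping = BEGrouping(
        patient_ids=list(embedding.patient_ids),
        group_index=labels,
        k=n_folds,
        n_replicates=n_replicates,
    )
    assignment: dict[str, object] = {
        p: int(g) for p, g in zip(embedding.patient_ids, labels)
    }
    plan = PartitionPlan(
        patient_ids=list(embedding.patient_ids),
        assignment=assignment,
        strategy="worst_case",
        seed=seed,
        n_folds=n_folds,
        source_grouping=grouping,
    )
    return plan, grouping


def holdout_one_per_site(table: QCMetricTable, seed: int) -> list[str]:
    """Pick one patient per site label for an external benchmark test set."""
    if table.site_label is None:
        raise PartitionError("table has no site labels")
    by_site: dict[str, list[str]] = {}
    for pid, site in zip(table.patient_ids, table.site_label):
        by_site.setdefault(site, [])
        if pid not in by_site[site]:
            by_site[site].append(pid)
    chosen = []
    for site in sorted(by_site):
        rng = np.random.default_rng(derive_seed(seed, "holdout", site))
        chosen.append(by_site[site][int(rng.integers(len(by_site[site])))])
    return chosen


def verify_patient_integrity(
    plan: PartitionPlan, table: QCMetricTable
) -> tuple[bool, list[Finding]]:
    """Check that no patient's images straddle two assignments.

    Maps every image through its patient's assignment and reports any patient
    missing from the plan. True means the partition is leakage-safe at
    patient level.
    """
    findings: list[Finding] = []
    seen: dict[str, object] = {}
    ok = True
    for img, pid in zip(table.image_ids, table.patient_ids):
        if pid not in plan.assignment:
            findings.append(Finding("warning", f"patient {pid!r} (image {img!r}) absent from plan"))
            ok = False
            continue
        a = plan.assignment[pid]
        if pid in seen and seen[pid] != a:
            findings.append(Finding("warning", f"patient {pid!r} has images in multiple assignments"))
            ok = False
        seen[pid] = a
    return ok, findings
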