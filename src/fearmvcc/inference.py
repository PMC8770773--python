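"""Group-level inference for cross-classification accuracies.

Decoding significance is assessed non-parametrically in two stages:

1. **Within-participant permutation null.**  For each of ``n_perm``
   iterations the training labels are permuted (class-balanced: a
   permutation of the label vector preserves class counts), feature
   selection and SVM training are re-run from scratch on the permuted
   labels, and the re-trained model is evaluated on the fixed, unpermuted
   test subsets.  Every condition of a participant is evaluated under the
   same permuted model per iteration, so nulls for different conditions
   are seed-paired by construction.
2. **Group bootstrap null.**  ``n_boot`` group-mean accuracies are formed
   by drawing, with replacement, one permutation-null value per
   participant and averaging.

The observed group-mean accuracy is compared to the group null with the
add-one empirical rule p = (1 + #{null >= obs}) / (1 + n_boot) (one-tailed
greater; two-tailed doubles the smaller tail, capped at 1), which keeps
every p-value strictly positive.  Between-condition tests reuse the
seed-paired nulls: the per-iteration difference A_j - B_j per participant
is bootstrap-aggregated into a null of group accuracy differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._seeds import derive_rng
from .decoder import ROIDataset, cross_classify, select_features, train_classifier

__all__ = [
    "ParticipantNull",
    "GroupNull",
    "PermutationTestResult",
    "DifferenceTestResult",
    "participant_null",
    "group_null",
    "empirical_p",
    "condition_difference_test",
    "group_observed_accuracy",
]

DEFAULT_N_PERM = 10_000
DEFAULT_N_BOOT = 10_000


class InferenceError(ValueError):
    pass


@dataclass
class ParticipantNull:
    """Permutation-null accuracies for one participant, all conditions paired."""

    participant_id: str
    nulls: dict            # condition -> (n_perm,) accuracy vector, percent
    observed: dict         # condition -> observed accuracy, percent
    n_perm: int
    seed: int

    def conditions(self) -> list[str]:
        return list(self.nulls)


@dataclass
class GroupNull:
    """Bootstrap distribution of group-mean null accuracies (percent)."""

    values: np.ndarray
    condition: str
    n_boot: int
    seed: int


@dataclass
class PermutationTestResult:
    condition: str
    observed: float        # group-mean accuracy, percent
    p_value: float
    tail: str
    n_perm: int
    n_boot: int


@dataclass
class DifferenceTestResult:
    condition_a: str
    condition_b: str
    observed_difference: float   # percentage points
    p_value: float
    tail: str
    n_perm: int
    n_boot: int


def participant_null(
    train: ROIDataset,
    test: ROIDataset,
    subsets: dict,
    K: int,
    n_perm: int,
    seed: int,
    *,
    target: str = "auto",
    targets: dict | None = None,
) -> ParticipantNull:
    """Permutation null for one participant across all condition subsets.

    Iteration j permutes the training label vector with the j-th draw of a
    generator seeded from ``seed`` (independently of the data), re-runs
    feature selection and SVM training under the permuted labels, and
    scores every test subset with that one model.
    """
    if n_perm < 1:
        raise InferenceError("n_perm must be >= 1")
    from .decoder import _binary_labels  # shared label convention

    y = _binary_labels(train)
    sel = select_features(train, K)
    clf = train_classifier(train, sel)
    observed = {
        r.condition: r.accuracy
        for r in cross_classify(clf, test, subsets, target=target, targets=targets)
    }

    rng = derive_rng(seed, "perm", train.participant_id, train.roi_name)
    nulls = {c: np.empty(n_perm) for c in subsets}

    # materialize each test subset once; the loop then only permutes labels,
    # re-selects features, refits and predicts (numerically identical to the
    # public select_features/train_classifier/cross_classify route, which a
    # test pins down, but without per-iteration container overhead)
    from .decoder import _fit_linear_svm

    Xtr = train.X
    n_train = len(y)
    voxel_order_tiebreak = np.arange(Xtr.shape[1])
    test_sets = {}
    for name, mask in subsets.items():
        sub = test.subset(np.asarray(mask, bool))
        y_sub = _binary_labels(sub, (targets or {}).get(name, target))
        test_sets[name] = (sub.X, y_sub)

    for j in range(n_perm):
        y_perm = y[rng.permutation(n_train)]
        scores = Xtr[y_perm == 1].mean(axis=0) - Xtr[y_perm == -1].mean(axis=0)
        idx = np.lexsort((voxel_order_tiebreak, -scores))[:K]
        Xs = Xtr[:, idx]
        mean_norm = float(np.linalg.norm(Xs, axis=1).mean())
        C = 1.0 / mean_norm if mean_norm > 0 else 1.0
        w, b = _fit_linear_svm(Xs, y_perm, C)
        for name, (Xte, yte) in test_sets.items():
            pred = np.where(Xte[:, idx] @ w + b >= 0, 1, -1)
            nulls[name][j] = 100.0 * np.mean(pred == yte)
    return ParticipantNull(
        participant_id=train.participant_id,
        nulls=nulls,
        observed=observed,
        n_perm=n_perm,
        seed=seed,
    )


def _check_comparable(nulls: list[ParticipantNull], condition: str) -> None:
    if not nulls:
        raise InferenceError("empty participant list")
    n_perm = nulls[0].n_perm
    for pn in nulls:
        if pn.n_perm != n_perm:
            raise InferenceError("participants must share n_perm")
        if condition not in pn.nulls:
            raise InferenceError(
                f"participant {pn.participant_id} lacks condition {condition!r}"
            )


def group_null(
    nulls: list[ParticipantNull],
    condition: str,
    n_boot: int,
    seed: int,
) -> GroupNull:
    """Bootstrap group-mean null: one resampled null value per participant."""
    _check_comparable(nulls, condition)
    if n_boot < 1:
        raise InferenceError("n_boot must be >= 1")
    rng = derive_rng(seed, "boot", condition)
    mat = np.stack([pn.nulls[condition] for pn in nulls])   # (n_part, n_perm)
    idx = rng.integers(mat.shape[1], size=(len(nulls), n_boot))
    values = mat[np.arange(len(nulls))[:, None], idx].mean(axis=0)
    return GroupNull(values=values, condition=condition, n_boot=n_boot, seed=seed)


def group_observed_accuracy(nulls: list[ParticipantNull], condition: str) -> float:
    """Group-mean observed accuracy (percent) across participants."""
    _check_comparable(nulls, condition)
    return float(np.mean([pn.observed[condition] for pn in nulls]))


def _empirical_p_value(observed: float, null: np.ndarray, tail: str) -> float:
    n = len(null)
    p_greater = (1 + int((null >= observed).sum())) / (1 + n)
    if tail == "greater":
        return p_greater
    p_less = (1 + int((null <= observed).sum())) / (1 + n)
    if tail == "less":
        return p_less
    if tail == "two":
        return min(1.0, 2.0 * min(p_greater, p_less))
    raise InferenceError(f"unknown tail {tail!r}")


def empirical_p(
    observed: float,
    null: GroupNull,
    tail: str = "greater",
    *,
    n_perm: int = 0,
) -> PermutationTestResult:
    """Add-one empirical p-value of an observed group accuracy vs its null."""
    if len(null.values) == 0:
        raise InferenceError("empty null distribution")
    return PermutationTestResult(
        condition=null.condition,
        observed=observed,
        p_value=_empirical_p_value(observed, null.values, tail),
        tail=tail,
        n_perm=n_perm,
        n_boot=null.n_boot,
    )


def condition_difference_test(
    nulls: list[ParticipantNull],
    condition_a: str,
    condition_b: str,
    n_boot: int,
    seed: int,
    tail: str = "two",
) -> DifferenceTestResult:
    """Seed-paired test of the accuracy difference between two conditions.

    Requires that each participant's nulls for both conditions came from
    the same permutation sequence (one :func:`participant_null` call);
    the per-iteration differences then form a valid difference null.
    """
    _check_comparable(nulls, condition_a)
    _check_comparable(nulls, condition_b)
    for pn in nulls:
        if condition_a not in pn.nulls or condition_b not in pn.nulls:
            raise InferenceError("both conditions required per participant")
    diff_nulls = [
        ParticipantNull(
            participant_id=pn.participant_id,
            nulls={"diff": pn.nulls[condition_a] - pn.nulls[condition_b]},
            observed={"diff": pn.observed[condition_a] - pn.observed[condition_b]},
            n_perm=pn.n_perm,
            seed=pn.seed,
        )
        for pn in nulls
    ]
    gn = group_null(diff_nulls, "diff", n_boot, seed)
    observed = group_observed_accuracy(diff_nulls, "diff")
    return DifferenceTestResult(
        condition_a=condition_a,
        condition_b=condition_b,
        observed_difference=observed,
        p_value=_empirical_p_value(observed, gn.values, tail),
        tail=tail,
        n_perm=nulls[0].n_perm,
        n_boot=n_boot,
    )
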