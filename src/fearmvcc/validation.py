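"""Calibration checks for the decoding inference machinery.

These routines quantify the statistical health of the permutation +
bootstrap pipeline on signal-free synthetic data: the empirical chance
level of the group null (which must sit at 50% for balanced two-class
decoding) and the type-I error rate of the group-level test at a given
alpha.  They run the exact production code path
(:func:`fearmvcc.inference.participant_null` etc.) on datasets drawn with
zero condition signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._seeds import derive_rng
from .decoder import ROIDataset
from .inference import empirical_p, group_null, group_observed_accuracy, participant_null

__all__ = ["balanced_noise_dataset", "chance_calibration", "type_i_error_rate"]


def balanced_noise_dataset(
    n_trials: int,
    n_voxels: int,
    rng: np.random.Generator,
    *,
    participant_id: str = "sub-01",
    roi_name: str = "noise_roi",
    phase: str = "classifier_training",
) -> ROIDataset:
    """Class-balanced view-trial dataset with i.i.d. Gaussian voxel noise.

    The first half of the trials is labeled CS+, the second half CS-; no
    voxel carries condition information, so true decodability is exactly
    chance (50%).
    """
    half = n_trials // 2
    n_trials = 2 * half
    meta = pd.DataFrame(
        {
            "viewed_stimulus": ["CSplus"] * half + ["CSminus"] * half,
            "imagined_stimulus": ["none"] * n_trials,
            "instruction": ["view"] * n_trials,
            "run": [1] * n_trials,
            "included": [True] * n_trials,
            "reinforced": [False] * n_trials,
        }
    )
    return ROIDataset(X=rng.standard_normal((n_trials, n_voxels)), meta=meta,
                      roi_name=roi_name, participant_id=participant_id, phase=phase)


def _signal_free_group(
    seed: int,
    replicate: int,
    n_participants: int,
    n_perm: int,
    n_train: int,
    n_test: int,
    n_voxels: int,
    K: int,
):
    nulls = []
    for p in range(n_participants):
        pid = f"sub-{p + 1:02d}"
        rng = derive_rng(seed, "signal_free", replicate, pid)
        train = balanced_noise_dataset(n_train, n_voxels, rng, participant_id=pid)
        test = balanced_noise_dataset(n_test, n_voxels, rng, participant_id=pid,
                                      phase="conditioning")
        subsets = {"view": np.ones(test.n_trials, bool)}
        nulls.append(
            participant_null(train, test, subsets, K=K, n_perm=n_perm,
                             seed=seed + replicate)
        )
    return nulls


def chance_calibration(
    seed: int,
    *,
    n_participants: int = 13,
    n_perm: int = 500,
    n_boot: int = 1000,
    n_train: int = 60,
    n_test: int = 1000,
    n_voxels: int = 300,
    K: int = 120,
) -> float:
    """Mean of the group-level null accuracy distribution, in percent.

    Defaults mirror the study's per-participant training dimensions
    (60 training trials, 300-voxel ROI, K = 120) with a large balanced
    signal-free test set so the chance level is measured precisely rather
    than confounded with small-test-set sampling noise.
    """
    nulls = _signal_free_group(seed, 0, n_participants, n_perm,
                               n_train, n_test, n_voxels, K)
    gn = group_null(nulls, "view", n_boot=n_boot, seed=seed)
    return float(gn.values.mean())


def type_i_error_rate(
    seed: int,
    *,
    n_replicates: int = 200,
    alpha: float = 0.05,
    n_participants: int = 13,
    n_perm: int = 500,
    n_boot: int = 1000,
    n_train: int = 20,
    n_test: int = 12,
    n_voxels: int = 30,
    K: int = 10,
) -> float:
    """Rejection rate of the group permutation test on signal-free data.

    Each replicate simulates a fresh group, runs the full within-participant
    permutation null and group bootstrap, and tests the observed group
    accuracy one-tailed at ``alpha``.  Problem sizes are deliberately small
    (calibration of a balanced two-class test does not depend on them) so
    many replicates are affordable.
    """
    rejections = 0
    for replicate in range(n_replicates):
        nulls = _signal_free_group(seed, replicate, n_participants, n_perm,
                                   n_train, n_test, n_voxels, K)
        gn = group_null(nulls, "view", n_boot=n_boot, seed=seed + replicate)
        observed = group_observed_accuracy(nulls, "view")
        res = empirical_p(observed, gn, tail="greater", n_perm=n_perm)
        rejections += res.p_value < alpha
    return rejections / n_replicates
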