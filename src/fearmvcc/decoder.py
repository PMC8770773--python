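"""ROI decoding: feature selection, linear SVM, cross-classification.

The decoding scheme is multivariate cross-classification (MVCC): a linear
support vector machine is trained to discriminate CS+ from CS- on view
trials of a training phase (the classifier-training phase, before any
conditioning), then tested — without retraining — on trials from a later
phase (conditioning or regulation).  Above-chance transfer to imagine
trials implies that imagery re-instates the perceptual stimulus
representation; reduced transfer on regulate trials implies that imagery
of the competing stimulus disrupts it.

Feature selection keeps the K voxels with the largest positive univariate
mean difference (CS+ minus CS-) computed on the training data only
(K = 120 for retinotopic visual ROIs, 300 for the bilateral amygdala).
The SVM regularization constant is set by norm auto-scaling:
C = 1 / mean ||x||2 over training vectors.  Chance is 50% throughout
(balanced two-class subsets).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.svm import SVC

try:  # fast path: sklearn's libsvm binding without estimator overhead
    from sklearn.svm import _libsvm as _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - depends on sklearn internals
    _libsvm = None

from .design import Instruction, PhaseSchedule, Stimulus, condition_of

__all__ = [
    "ROIDataset",
    "FeatureSelection",
    "LinearClassifier",
    "ConditionAccuracy",
    "select_features",
    "train_classifier",
    "cross_classify",
    "amygdala_gate",
    "DEFAULT_K_VISUAL",
    "DEFAULT_K_AMYGDALA",
]

DEFAULT_K_VISUAL = 120
DEFAULT_K_AMYGDALA = 300

#: Metadata columns every ROIDataset carries, one row per trial.
META_COLUMNS = (
    "viewed_stimulus",
    "imagined_stimulus",
    "instruction",
    "run",
    "included",
    "reinforced",
)


class DecodingError(ValueError):
    pass


@dataclass
class ROIDataset:
    """Trial x voxel response matrix with per-trial labels for one ROI/phase."""

    X: np.ndarray                # (n_trials, n_voxels)
    meta: pd.DataFrame           # META_COLUMNS, one row per trial
    roi_name: str
    participant_id: str
    phase: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DecodingError("X must be 2-D (trials x voxels)")
        if len(self.meta) != self.X.shape[0]:
            raise DecodingError("label cardinality must equal row count")
        missing = set(META_COLUMNS) - set(self.meta.columns)
        if missing:
            raise DecodingError(f"meta missing columns: {sorted(missing)}")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def subset(self, mask: np.ndarray) -> "ROIDataset":
        mask = np.asarray(mask, bool)
        return replace(
            self, X=self.X[mask], meta=self.meta.loc[mask].reset_index(drop=True)
        )

    def analysis_view(self) -> "ROIDataset":
        """Trials eligible for decoding: included and shock-free."""
        m = self.meta["included"].to_numpy(bool) & ~self.meta["reinforced"].to_numpy(bool)
        return self.subset(m)

    @classmethod
    def from_schedule(
        cls,
        X: np.ndarray,
        schedule: PhaseSchedule,
        roi_name: str,
        participant_id: str,
    ) -> "ROIDataset":
        if len(schedule.trials) != np.asarray(X).shape[0]:
            raise DecodingError("row count must match schedule length")
        meta = pd.DataFrame(
            {
                "viewed_stimulus": [t.viewed_stimulus.value for t in schedule.trials],
                "imagined_stimulus": [t.imagined_stimulus.value for t in schedule.trials],
                "instruction": [t.instruction.value for t in schedule.trials],
                "run": [t.run_index for t in schedule.trials],
                "included": [t.included for t in schedule.trials],
                "reinforced": [t.reinforced for t in schedule.trials],
            }
        )
        return cls(X=np.asarray(X, float), meta=meta, roi_name=roi_name,
                   participant_id=participant_id, phase=schedule.phase.value)


def _binary_labels(ds: ROIDataset, target: str = "auto") -> np.ndarray:
    """+1 for CS+, -1 for CS- according to the scoring target.

    ``target`` is "viewed", "imagined", or "auto" (score against the viewed
    stimulus unless the trials present none, as on imagine trials, in which
    case score against the imagined stimulus).
    """
    if target == "auto":
        viewed = ds.meta["viewed_stimulus"].to_numpy()
        target = "imagined" if (viewed == Stimulus.NONE.value).all() else "viewed"
    col = "viewed_stimulus" if target == "viewed" else "imagined_stimulus"
    stim = ds.meta[col].to_numpy()
    if (stim == Stimulus.NONE.value).any():
        raise DecodingError(f"trials without a {target} stimulus in labeling")
    return np.where(stim == Stimulus.CS_PLUS.value, 1, -1)


@dataclass(frozen=True)
class FeatureSelection:
    """Top-K voxel subset ranked by training-set CS+ minus CS- difference."""

    indices: np.ndarray       # ordered by descending score, ties by ascending index
    scores: np.ndarray        # score per original voxel
    K: int


@dataclass(frozen=True)
class LinearClassifier:
    weights: np.ndarray
    bias: float
    C: float
    selection: FeatureSelection
    training_fingerprint: int

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return X[:, self.selection.indices] @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)


@dataclass(frozen=True)
class ConditionAccuracy:
    condition: str
    n_correct: int
    n_trials: int

    @property
    def accuracy(self) -> float:
        """Percent correct."""
        return 100.0 * self.n_correct / self.n_trials


def select_features(
    train: ROIDataset,
    K: int,
    labels: np.ndarray | None = None,
) -> FeatureSelection:
    """Rank voxels by mean(CS+) - mean(CS-) on training data; keep the top K.

    Ties are broken by ascending voxel index.  If fewer than K voxels have a
    positive score, selection still takes the top K by signed score and a
    warning is emitted.  ``labels`` (+1/-1) overrides the dataset's viewed
    stimulus labels; permutation nulls use this to re-select under permuted
    labels, since selection is part of the pipeline under test.
    """
    if K < 1:
        raise DecodingError("K must be >= 1")
    if K > train.n_voxels:
        raise DecodingError(f"K={K} exceeds n_voxels={train.n_voxels}")
    y = _binary_labels(train) if labels is None else np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DecodingError("training data must contain both classes")
    scores = train.X[y == 1].mean(axis=0) - train.X[y == -1].mean(axis=0)
    # stable sort on (-score, index): lexsort's last key is primary
    order = np.lexsort((np.arange(scores.size), -scores))
    indices = order[:K]
    if (scores[indices] <= 0).any():
        warnings.warn(
            f"fewer than K={K} voxels with positive selection score; "
            "keeping top-K by signed score",
            stacklevel=2,
        )
    return FeatureSelection(indices=indices, scores=scores, K=K)


def _fit_linear_svm(X: np.ndarray, y: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    """Linear-kernel libsvm fit returning (weights, bias).

    Uses sklearn's libsvm binding directly when available (the estimator
    wrapper adds an order of magnitude of per-call overhead, which matters
    inside permutation loops); falls back to :class:`sklearn.svm.SVC`.
    Both routes solve the identical optimization, and the weight vector is
    oriented so that decision > 0 predicts the +1 class.
    """
    if _libsvm is None:  # pragma: no cover
        svc = SVC(kernel="linear", C=C).fit(X, y)
        return svc.coef_.ravel().copy(), float(svc.intercept_[0])
    Xc = np.ascontiguousarray(X, dtype=np.float64)
    yc = np.ascontiguousarray(y, dtype=np.float64)
    out = _libsvm.fit(Xc, yc, svm_type=0, kernel="linear", C=C,
                      tol=1e-3, max_iter=-1, random_seed=0)
    SV, sv_coef, intercept = out[1], out[3], out[4]
    # libsvm's raw binary decision has the opposite orientation to the
    # decision > 0 <=> +1 convention (same negation SVC applies); a test
    # pins the equivalence with SVC across random problems
    w = -np.asarray(sv_coef @ SV).ravel()
    b = -float(intercept[0])
    return w, b


def train_classifier(
    train: ROIDataset,
    sel: FeatureSelection,
    labels: np.ndarray | None = None,
) -> LinearClassifier:
    """Fit a linear-kernel SVM on the selected voxels.

    C is auto-scaled to the data norm: C = 1 / mean ||x||2 over training
    vectors (computed on the selected features).  Deterministic given data.
    """
    y = _binary_labels(train) if labels is None else np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or (counts < 2).any():
        raise DecodingError("need >= 2 training trials per class")
    Xs = train.X[:, sel.indices]
    mean_norm = float(np.linalg.norm(Xs, axis=1).mean())
    C = 1.0 / mean_norm if mean_norm > 0 else 1.0
    w, b = _fit_linear_svm(Xs, y, C)
    fingerprint = zlib.crc32(Xs.tobytes() + y.astype(np.int8).tobytes())
    return LinearClassifier(weights=w, bias=b, C=C, selection=sel,
                            training_fingerprint=fingerprint)


def cross_classify(
    clf: LinearClassifier,
    test: ROIDataset,
    subsets: dict[str, np.ndarray] | None = None,
    target: str = "auto",
    targets: dict[str, str] | None = None,
) -> list[ConditionAccuracy]:
    """Apply a trained classifier to held-out trials, per condition subset.

    ``subsets`` maps a condition label to a boolean trial mask over ``test``
    (default: one subset per instruction present).  Each subset must exclude
    reinforced and non-included trials and be class-balanced; accuracy is
    scored against the stimulus named by ``target`` ("viewed" or
    "imagined"), overridable per subset via ``targets``.
    """
    if subsets is None:
        instr = test.meta["instruction"].to_numpy()
        subsets = {name: instr == name for name in pd.unique(instr)}
    included = test.meta["included"].to_numpy(bool)
    reinforced = test.meta["reinforced"].to_numpy(bool)
    results = []
    for name, mask in subsets.items():
        mask = np.asarray(mask, bool)
        if (mask & (~included | reinforced)).any():
            raise DecodingError(
                f"subset {name!r} contains reinforced or excluded trials"
            )
        sub = test.subset(mask)
        y = _binary_labels(sub, (targets or {}).get(name, target))
        n_plus = int((y == 1).sum())
        if n_plus * 2 != len(y):
            raise DecodingError(f"subset {name!r} is not class-balanced")
        pred = clf.predict(sub.X)
        results.append(
            ConditionAccuracy(
                condition=name,
                n_correct=int((pred == y).sum()),
                n_trials=len(y),
            )
        )
    return results


def amygdala_gate(view_result_p: float, alpha: float = 0.05) -> bool:
    """Positive-control gate for fragile decoding analyses.

    The regulate-trial amygdala decoding is interpreted only if the view-trial
    cross-classification is significantly above chance (strictly p < alpha);
    otherwise the dependent analysis is reported as not run.
    """
    return view_result_p < alpha
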