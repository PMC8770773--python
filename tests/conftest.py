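import numpy as np
import pandas as pd
import pytest

from fearmvcc.decoder import ROIDataset
from fearmvcc.design import apply_exclusions, build_phase_schedule


def make_roi_dataset(
    X: np.ndarray,
    viewed: list[str],
    instruction: str | list[str] = "view",
    imagined: list[str] | None = None,
    *,
    participant_id: str = "sub-01",
    roi_name: str = "test_roi",
    phase: str = "classifier_training",
) -> ROIDataset:
    """Hand-build a small ROIDataset without going through a schedule."""
    n = len(viewed)
    if isinstance(instruction, str):
        instruction = [instruction] * n
    meta = pd.DataFrame(
        {
            "viewed_stimulus": viewed,
            "imagined_stimulus": imagined if imagined is not None else ["none"] * n,
            "instruction": instruction,
            "run": [1] * n,
            "included": [True] * n,
            "reinforced": [False] * n,
        }
    )
    return ROIDataset(X=np.asarray(X, float), meta=meta, roi_name=roi_name,
                      participant_id=participant_id, phase=phase)


def noise_roi_dataset(
    n_trials: int,
    n_voxels: int,
    rng: np.random.Generator,
    instruction: str = "view",
    **kwargs,
) -> ROIDataset:
    """Class-balanced pure-noise dataset (first half CS+, second half CS-)."""
    half = n_trials // 2
    viewed = ["CSplus"] * half + ["CSminus"] * (n_trials - half)
    return make_roi_dataset(
        rng.standard_normal((n_trials, n_voxels)), viewed, instruction, **kwargs
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def conditioning_schedule():
    return apply_exclusions(build_phase_schedule("conditioning", 6, 42))


@pytest.fixture(scope="session")
def regulation_schedule():
    return apply_exclusions(build_phase_schedule("regulation", 8, 42))


@pytest.fixture(scope="session")
def training_schedule():
    return apply_exclusions(build_phase_schedule("classifier_training", 6, 42))
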