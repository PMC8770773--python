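"""Skin-conductance preprocessing and trial-wise trough-to-peak scoring.

The raw electrodermal signal (microsiemens, 1 kHz) is, per run, linearly
detrended, smoothed with a 50-sample median filter to suppress MRI-induced
noise, and down-sampled to 100 Hz.  Trial epochs spanning -1 s to +8 s
around CS onset are baseline-corrected by subtracting the mean of the one
second before onset.  The trial amplitude is the maximum response in the
1-8 s window minus the minimum in the 0-0.99 s window; amplitudes below
0.02 uS are zeroed.  Peaks are finally averaged per condition and
participant; reinforced (shock) trials and the first/last CS- trial of
each run never enter the averages.

Window conventions at 100 Hz (sample indices relative to onset):
baseline [-100, -1], trough search [0, 99], peak search [100, 800]
inclusive, i.e. epochs carry 100 pre-onset and 801 post-onset samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import rank_filter

from .design import PhaseSchedule, condition_of

__all__ = [
    "SCRTrace",
    "EpochMatrix",
    "preprocess",
    "epoch_and_baseline",
    "score_trial_peak",
    "score_peaks",
    "average_by_condition",
    "ZERO_THRESHOLD_US",
    "MEDIAN_FILTER_SAMPLES",
    "RAW_FS",
    "ANALYSIS_FS",
]

RAW_FS = 1000
ANALYSIS_FS = 100
MEDIAN_FILTER_SAMPLES = 50
DOWNSAMPLE_FACTOR = RAW_FS // ANALYSIS_FS
ZERO_THRESHOLD_US = 0.02

# epoch sample layout at 100 Hz
N_BASELINE = 100          # [-1.00 s, -0.01 s]
N_POST = 801              # [0 s, 8.00 s] inclusive
TROUGH_SLICE = slice(N_BASELINE, N_BASELINE + 100)        # 0 .. 0.99 s
PEAK_SLICE = slice(N_BASELINE + 100, N_BASELINE + 801)    # 1.00 .. 8.00 s


class SCRInputError(ValueError):
    pass


@dataclass
class SCRTrace:
    """Conductance signal split by run, with per-trial CS-onset markers.

    ``onsets[r]`` holds sample indices into ``runs[r]``, one per trial, in
    schedule order; concatenating across runs aligns one-to-one with the
    trials of the driving :class:`~fearmvcc.design.PhaseSchedule`.
    """

    runs: list[np.ndarray]
    onsets: list[np.ndarray]
    fs: int = RAW_FS

    def __post_init__(self) -> None:
        if len(self.runs) != len(self.onsets):
            raise SCRInputError("runs and onsets must pair up")
        self.runs = [np.asarray(r, float) for r in self.runs]
        self.onsets = [np.asarray(o, int) for o in self.onsets]
        for o in self.onsets:
            if len(o) > 1 and not (np.diff(o) > 0).all():
                raise SCRInputError("onsets must be strictly increasing within a run")

    @property
    def n_trials(self) -> int:
        return sum(len(o) for o in self.onsets)


@dataclass
class EpochMatrix:
    """Trials x samples at 100 Hz, -1.0 s to +8.0 s around CS onset."""

    epochs: np.ndarray            # (n_trials, N_BASELINE + N_POST); NaN rows = missing
    baseline_corrected: bool

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.epochs).any(axis=1)


def _detrend_keep_mean(x: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend but retain the run mean (uS scale)."""
    n = len(x)
    t = np.arange(n, dtype=float)
    t0 = t - t.mean()
    slope = (t0 @ x) / (t0 @ t0)
    return x - slope * t0


def _median_filter_even(x: np.ndarray, size: int) -> np.ndarray:
    """Median filter with an even window covering samples [i-size/2, i+size/2-1].

    Edges are handled by reflection; the median of the even-length window is
    the mean of its two central order statistics (computed as two moving
    rank filters, identical to a naive per-window ``np.median``).
    """
    lo = rank_filter(x, size // 2 - 1, size=size, mode="reflect")
    hi = rank_filter(x, size // 2, size=size, mode="reflect")
    return (lo + hi) / 2.0


def preprocess(trace: SCRTrace) -> SCRTrace:
    """Detrend, median-filter and decimate each run from 1 kHz to 100 Hz.

    Per run: linear detrend (slope removed, mean retained), 50-sample median
    filter with reflected edges covering samples [i-25, i+24], then 10:1
    decimation.  Onsets are rescaled to the 100 Hz grid.
    """
    if trace.fs != RAW_FS:
        raise SCRInputError(f"expected {RAW_FS} Hz input, got {trace.fs}")
    runs_out, onsets_out = [], []
    for x, o in zip(trace.runs, trace.onsets):
        if len(x) < MEDIAN_FILTER_SAMPLES:
            raise SCRInputError("run shorter than the median-filter window")
        y = _detrend_keep_mean(x)
        y = _median_filter_even(y, MEDIAN_FILTER_SAMPLES)
        runs_out.append(y[::DOWNSAMPLE_FACTOR])
        onsets_out.append(o // DOWNSAMPLE_FACTOR)
    return SCRTrace(runs=runs_out, onsets=onsets_out, fs=ANALYSIS_FS)


def epoch_and_baseline(trace: SCRTrace) -> EpochMatrix:
    """Cut -1..+8 s epochs at 100 Hz and subtract each epoch's pre-onset mean.

    A trial whose window falls outside its run is flagged missing (all-NaN
    row) rather than scored, mirroring how absent physiological data are
    handled downstream (the condition mean is taken over the trials that
    remain).
    """
    if trace.fs != ANALYSIS_FS:
        raise SCRInputError(f"expected {ANALYSIS_FS} Hz input, got {trace.fs}")
    width = N_BASELINE + N_POST
    rows = []
    for x, onsets in zip(trace.runs, trace.onsets):
        for on in onsets:
            lo, hi = on - N_BASELINE, on + N_POST
            if lo < 0 or hi > len(x):
                rows.append(np.full(width, np.nan))
                continue
            ep = x[lo:hi].astype(float).copy()
            ep -= ep[:N_BASELINE].mean()
            rows.append(ep)
    return EpochMatrix(epochs=np.asarray(rows), baseline_corrected=True)


def score_trial_peak(epoch: np.ndarray) -> float:
    """Trough-to-peak amplitude of one baseline-corrected epoch, in uS.

    max over 1-8 s minus min over 0-0.99 s; responses below 0.02 uS are
    zeroed.  NaN epochs (missing trials) score NaN.
    """
    epoch = np.asarray(epoch, float)
    if np.isnan(epoch).any():
        return float("nan")
    peak = epoch[PEAK_SLICE].max() - epoch[TROUGH_SLICE].min()
    return float(peak) if peak >= ZERO_THRESHOLD_US else 0.0


def score_peaks(epochs: EpochMatrix, schedule: PhaseSchedule) -> pd.DataFrame:
    """Score every trial; rows align with the schedule's trial order.

    Returns a table with columns run, position_in_run, stimulus,
    instruction, included, reinforced, peak_uS, zeroed, missing.
    """
    if not epochs.baseline_corrected:
        raise SCRInputError("epochs must be baseline-corrected before scoring")
    if len(schedule.trials) != epochs.epochs.shape[0]:
        raise SCRInputError("epoch count must match schedule length")
    peaks = np.array([score_trial_peak(e) for e in epochs.epochs])
    stim_instr = [condition_of(t) for t in schedule.trials]
    return pd.DataFrame(
        {
            "run": [t.run_index for t in schedule.trials],
            "position_in_run": [t.position_in_run for t in schedule.trials],
            "stimulus": [s for s, _ in stim_instr],
            "instruction": [i for _, i in stim_instr],
            "included": [t.included for t in schedule.trials],
            "reinforced": [t.reinforced for t in schedule.trials],
            "peak_uS": peaks,
            "zeroed": (peaks == 0.0),
            "missing": np.isnan(peaks),
        }
    )


def average_by_condition(peaks: pd.DataFrame) -> pd.Series:
    """Mean peak per (stimulus, instruction) over included, shock-free trials.

    Missing trials shrink the denominator of their condition.  A condition
    with no scoreable trial yields NaN, flagging the participant for
    exclusion from contrasts involving that condition.
    """
    usable = peaks[peaks["included"] & ~peaks["reinforced"]]
    means = usable.groupby(["stimulus", "instruction"])["peak_uS"].mean()
    means.name = "mean_peak_uS"
    return means
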