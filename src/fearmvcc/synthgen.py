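"""Synthetic participants with known ground truth.

The generator emulates the data the analysis consumes, one level above the
scanner: trial x voxel response patterns (standing in for trial-wise GLM
beta estimates), 1 kHz skin-conductance traces, and 7-point Likert
ratings.  Ground truth is explicit so recovery can be tested.

Pattern model
-------------
Each ROI has two prototype patterns (CS+ / CS-) of equal norm and
configurable correlation.  A trial's expected pattern is a gain-weighted
combination:

* view trial:      ``view_gain * prototype(viewed)``
* imagine trial:   ``imagery_gain * prototype(imagined)`` — imagery acts
  as a weaker copy of perception, so ``imagery_gain <= view_gain`` by
  default
* regulate trial:  ``regulate_view_gain * prototype(viewed) +
  regulate_imagery_gain * prototype(imagined)`` — the imagined competitor
  mixes into, and thereby disrupts, the viewed-stimulus pattern

with i.i.d. Gaussian voxel noise on top.  Participants get individual
prototypes (group prototypes plus Gaussian perturbation); classifiers are
always trained within participant.

SCR model
---------
Event-locked responses with a difference-of-exponentials kernel
(latency, rise and decay time constants), per-condition amplitude, linear
drift per run and Gaussian noise, sampled at 1 kHz.

All randomness derives from one master seed via keyed substreams
(:mod:`fearmvcc._seeds`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seeds import derive_rng
from .decoder import ROIDataset
from .design import (
    CUE_S,
    ITI_S,
    STIM_S,
    Instruction,
    Phase,
    PhaseSchedule,
    Stimulus,
    condition_of,
)
from .scr import RAW_FS, SCRTrace

__all__ = [
    "PatternGroundTruth",
    "SCRGroundTruth",
    "RatingsGroundTruth",
    "SyntheticParticipant",
    "make_pattern_truth",
    "participant_pattern_truth",
    "simulate_roi_dataset",
    "simulate_scr",
    "simulate_ratings",
    "scr_kernel_peak_time",
]


class GroundTruthError(ValueError):
    pass


@dataclass(frozen=True)
class PatternGroundTruth:
    """Generative parameters for one ROI's trial patterns."""

    n_voxels: int
    prototype_plus: np.ndarray
    prototype_minus: np.ndarray
    view_gain: float = 1.0
    imagery_gain: float = 0.5
    regulate_view_gain: float = 1.0
    regulate_imagery_gain: float = 1.0
    noise_sd: float = 1.0
    participant_variability_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("view_gain", "imagery_gain", "regulate_view_gain",
                     "regulate_imagery_gain", "participant_variability_sd"):
            if getattr(self, name) < 0:
                raise GroundTruthError(f"{name} must be non-negative")
        if self.noise_sd <= 0:
            raise GroundTruthError("noise_sd must be positive")

    def prototype(self, stimulus: Stimulus | str) -> np.ndarray:
        stimulus = Stimulus(stimulus)
        if stimulus is Stimulus.CS_PLUS:
            return self.prototype_plus
        if stimulus is Stimulus.CS_MINUS:
            return self.prototype_minus
        return np.zeros(self.n_voxels)


def make_pattern_truth(
    n_voxels: int,
    seed: int,
    *,
    prototype_correlation: float = 0.0,
    view_gain: float = 1.0,
    imagery_gain: float = 0.5,
    regulate_view_gain: float = 1.0,
    regulate_imagery_gain: float = 1.0,
    noise_sd: float = 1.0,
    participant_variability_sd: float = 0.0,
) -> PatternGroundTruth:
    """Draw group-level prototypes and package the generative parameters.

    Prototypes have equal norm ``sqrt(n_voxels)`` (unit per-voxel RMS) and
    exact correlation ``prototype_correlation`` in [-1, 1), built from a
    seeded random orthonormal pair.
    """
    if n_voxels < 2:
        raise GroundTruthError("need n_voxels >= 2")
    if not (-1.0 <= prototype_correlation < 1.0):
        raise GroundTruthError("prototype correlation must lie in [-1, 1)")
    rng = derive_rng(seed, "prototypes")
    basis, _ = np.linalg.qr(rng.standard_normal((n_voxels, 2)))
    u, v = basis[:, 0], basis[:, 1]
    r = prototype_correlation
    scale = np.sqrt(n_voxels)
    return PatternGroundTruth(
        n_voxels=n_voxels,
        prototype_plus=scale * u,
        prototype_minus=scale * (r * u + np.sqrt(1.0 - r * r) * v),
        view_gain=view_gain,
        imagery_gain=imagery_gain,
        regulate_view_gain=regulate_view_gain,
        regulate_imagery_gain=regulate_imagery_gain,
        noise_sd=noise_sd,
        participant_variability_sd=participant_variability_sd,
    )


def participant_pattern_truth(
    truth: PatternGroundTruth, participant_id: str, master_seed: int
) -> PatternGroundTruth:
    """Individualize the group prototypes by Gaussian perturbation."""
    if truth.participant_variability_sd == 0:
        return truth
    rng = derive_rng(master_seed, "participant_prototypes", participant_id)
    sd = truth.participant_variability_sd
    return replace(
        truth,
        prototype_plus=truth.prototype_plus + rng.normal(0, sd, truth.n_voxels),
        prototype_minus=truth.prototype_minus + rng.normal(0, sd, truth.n_voxels),
    )


def _expected_pattern(truth: PatternGroundTruth, trial) -> np.ndarray:
    if trial.instruction is Instruction.VIEW:
        return truth.view_gain * truth.prototype(trial.viewed_stimulus)
    if trial.instruction is Instruction.IMAGINE:
        return truth.imagery_gain * truth.prototype(trial.imagined_stimulus)
    return (
        truth.regulate_view_gain * truth.prototype(trial.viewed_stimulus)
        + truth.regulate_imagery_gain * truth.prototype(trial.imagined_stimulus)
    )


def simulate_roi_dataset(
    schedule: PhaseSchedule,
    truth: PatternGroundTruth,
    seed: int,
    *,
    roi_name: str = "synthetic_roi",
    participant_id: str = "sub-01",
) -> ROIDataset:
    """Trial x voxel matrix whose rows follow the schedule's trial order."""
    rng = derive_rng(seed, "roi", participant_id, roi_name, schedule.phase.value)
    X = np.empty((len(schedule.trials), truth.n_voxels))
    for i, trial in enumerate(schedule.trials):
        X[i] = _expected_pattern(truth, trial) + rng.normal(
            0.0, truth.noise_sd, truth.n_voxels
        )
    return ROIDataset.from_schedule(X, schedule, roi_name, participant_id)


# ---------------------------------------------------------------------------
# SCR


@dataclass(frozen=True)
class SCRGroundTruth:
    """Generative parameters for the electrodermal channel (uS / seconds)."""

    amplitudes: dict          # (stimulus, instruction) -> response amplitude, uS
    shock_extra_uS: float = 0.0   # added on reinforced trials (US response)
    participant_amplitude_sd: float = 0.0   # relative spread of responder strength
    trial_amplitude_sd_uS: float = 0.0      # trial-to-trial amplitude jitter
    latency_s: float = 1.0
    rise_s: float = 0.75
    decay_s: float = 2.0
    drift_slope_uS_per_s: float = 0.0
    noise_sd_uS: float = 0.0
    baseline_uS: float = 5.0
    fs: int = RAW_FS

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes.values()):
            raise GroundTruthError("SCR amplitudes must be non-negative")
        if self.fs != RAW_FS:
            raise GroundTruthError(f"sampling rate fixed at {RAW_FS} Hz")
        if not (0 < self.rise_s < self.decay_s):
            raise GroundTruthError("need 0 < rise < decay time constants")


def scr_kernel_peak_time(truth: SCRGroundTruth) -> float:
    """Closed-form post-onset time (s) at which the response kernel peaks."""
    tr, td = truth.rise_s, truth.decay_s
    return truth.latency_s + np.log(td / tr) * tr * td / (td - tr)


def _scr_kernel(truth: SCRGroundTruth, n_samples: int) -> np.ndarray:
    """Difference-of-exponentials kernel, normalized to unit peak."""
    t = np.arange(n_samples) / truth.fs
    s = np.clip(t - truth.latency_s, 0.0, None)
    k = np.exp(-s / truth.decay_s) - np.exp(-s / truth.rise_s)
    k[t < truth.latency_s] = 0.0
    peak = k.max()
    return k / peak if peak > 0 else k


def simulate_scr(
    schedule: PhaseSchedule,
    truth: SCRGroundTruth,
    seed: int,
    *,
    participant_id: str = "sub-01",
    padding_s: float = 10.0,
) -> SCRTrace:
    """Per-run 1 kHz conductance traces with event-locked responses.

    Each run is baseline + linear drift + one kernel per trial (amplitude
    set by the trial's condition, plus ``shock_extra_uS`` on reinforced
    trials) + Gaussian noise.  Participants differ in overall electrodermal
    responsiveness: all of a participant's amplitudes share one
    multiplicative factor max(0, 1 + N(0, participant_amplitude_sd)).
    CS-onset markers follow the schedule's trial timing (1.5 s audio cue
    except in classifier training, 6.5 s stimulus, 12 s inter-trial
    interval).
    """
    for trial in schedule.trials:
        if condition_of(trial) not in truth.amplitudes:
            raise GroundTruthError(f"no amplitude for condition {condition_of(trial)}")
    cue = 0.0 if schedule.phase is Phase.CLASSIFIER_TRAINING else CUE_S
    trial_len_s = cue + STIM_S + ITI_S
    fs = truth.fs
    responder = 1.0
    if truth.participant_amplitude_sd > 0:
        p_rng = derive_rng(seed, "scr_responder", participant_id)
        responder = max(0.0, 1.0 + p_rng.normal(0.0, truth.participant_amplitude_sd))
    runs, onset_lists = [], []
    for run in range(1, schedule.n_runs + 1):
        trials = schedule.run(run)
        n = int(round((len(trials) * trial_len_s + padding_s) * fs))
        rng = derive_rng(seed, "scr", participant_id, schedule.phase.value, run)
        t = np.arange(n) / fs
        x = truth.baseline_uS + truth.drift_slope_uS_per_s * t
        onsets = np.array(
            [int(round(((i * trial_len_s) + cue) * fs)) for i in range(len(trials))]
        )
        kernel = _scr_kernel(truth, n)
        for on, trial in zip(onsets, trials):
            amp = responder * truth.amplitudes[condition_of(trial)]
            if trial.reinforced:
                amp += responder * truth.shock_extra_uS
            if truth.trial_amplitude_sd_uS > 0:
                # phasic responses vary strongly from trial to trial
                # (habituation, spontaneous fluctuations); never negative
                amp = max(0.0, amp + rng.normal(0.0, truth.trial_amplitude_sd_uS))
            if amp > 0:
                x[on:] += amp * kernel[: n - on]
        if truth.noise_sd_uS > 0:
            x = x + rng.normal(0.0, truth.noise_sd_uS, n)
        runs.append(x)
        onset_lists.append(onsets)
    return SCRTrace(runs=runs, onsets=onset_lists, fs=fs)


# ---------------------------------------------------------------------------
# Ratings


@dataclass(frozen=True)
class RatingsGroundTruth:
    """Per-condition latent means for a 7-point Likert item.

    Ratings are latent-Gaussian: condition mean + participant offset +
    trial noise, rounded and clipped to the 1..7 scale.
    """

    means: dict               # (stimulus, instruction) -> latent mean in [1, 7]
    participant_sd: float = 0.5
    noise_sd: float = 0.8

    def __post_init__(self) -> None:
        if any(not (1.0 <= m <= 7.0) for m in self.means.values()):
            raise GroundTruthError("condition means must lie within the 1..7 scale")
        if self.participant_sd < 0 or self.noise_sd < 0:
            raise GroundTruthError("dispersions must be non-negative")


def simulate_ratings(
    truth: RatingsGroundTruth,
    n_participants: int,
    seed: int,
    *,
    question: str = "fear_of_shock",
) -> pd.DataFrame:
    """Tidy ratings table: participant, stimulus, instruction, question, rating."""
    rows = []
    for p in range(1, n_participants + 1):
        pid = f"sub-{p:02d}"
        rng = derive_rng(seed, "ratings", pid, question)
        offset = rng.normal(0.0, truth.participant_sd)
        for (stim, instr), mu in truth.means.items():
            latent = mu + offset + rng.normal(0.0, truth.noise_sd)
            rating = int(np.clip(np.rint(latent), 1, 7))
            rows.append(
                {
                    "participant": pid,
                    "stimulus": stim,
                    "instruction": instr,
                    "question": question,
                    "rating": rating,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SyntheticParticipant:
    """Everything the pipeline consumes for one simulated participant."""

    participant_id: str
    schedules: dict                 # phase name -> PhaseSchedule (exclusions applied)
    roi_data: dict                  # (roi_name, phase name) -> ROIDataset
    scr_traces: dict                # phase name -> SCRTrace
    pattern_truths: dict            # roi_name -> PatternGroundTruth (individualized)
    scr_truth: SCRGroundTruth | None = None
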