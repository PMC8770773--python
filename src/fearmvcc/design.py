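"""Trial schedules for the two-visit differential fear-conditioning task.

The task pairs one of two oriented Gabor patches (the CS+) with a mild
shock on 50% of viewed presentations, while the other (the CS-) is never
reinforced.  Four phases exist:

* ``classifier_training`` — view-only presentations used to train decoders
  (5 trials per stimulus per run, no audio cue, no reinforcement).
* ``preconditioning`` — practice phase mixing view and imagine trials
  (4 view + 4 imagine per CS per run); carries no analysis role.
* ``conditioning`` — 4 view + 2 imagine trials per CS per run; 50% of view
  CS+ trials co-terminate with shock.
* ``regulation`` — 4 view + 2 regulate trials per CS per run; on regulate
  trials the participant views one CS while imagining the other.

Conditioning and regulation runs have a constrained order: the first and
last trials are view CS-, the second is a reinforced view CS+, and the
remaining trials (positions 3..11) are shuffled by seed.  Analyses exclude
reinforced trials and the first/last CS- of each run so that every
condition contributes an equal number of trials.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "Stimulus",
    "Instruction",
    "Trial",
    "PhaseSchedule",
    "build_phase_schedule",
    "apply_exclusions",
    "count_analyzable",
    "schedule_to_events",
    "condition_of",
]


class Phase(str, enum.Enum):
    CLASSIFIER_TRAINING = "classifier_training"
    PRECONDITIONING = "preconditioning"
    CONDITIONING = "conditioning"
    REGULATION = "regulation"


class Stimulus(str, enum.Enum):
    CS_PLUS = "CSplus"
    CS_MINUS = "CSminus"
    NONE = "none"


class Instruction(str, enum.Enum):
    VIEW = "view"
    IMAGINE = "imagine"
    REGULATE = "regulate"


_OPPOSITE = {Stimulus.CS_PLUS: Stimulus.CS_MINUS, Stimulus.CS_MINUS: Stimulus.CS_PLUS}

#: Trial timing in seconds: audio cue, stimulus presentation, inter-trial interval.
CUE_S = 1.5
STIM_S = 6.5
ITI_S = 12.0


class ScheduleError(ValueError):
    """Raised for invalid schedule configuration or a malformed schedule."""


@dataclass(frozen=True)
class Trial:
    """One trial: what is shown, what is imagined, and its analysis status."""

    phase: Phase
    run_index: int          # 1-based
    position_in_run: int    # 1-based
    viewed_stimulus: Stimulus
    imagined_stimulus: Stimulus
    instruction: Instruction
    reinforced: bool = False
    included: bool = True

    def __post_init__(self) -> None:
        if self.reinforced and not (
            self.instruction is Instruction.VIEW
            and self.viewed_stimulus is Stimulus.CS_PLUS
        ):
            raise ScheduleError("only view CS+ trials may be reinforced")
        if self.instruction is Instruction.REGULATE:
            if (
                self.viewed_stimulus is Stimulus.NONE
                or self.imagined_stimulus is Stimulus.NONE
                or self.viewed_stimulus is self.imagined_stimulus
            ):
                raise ScheduleError(
                    "regulate trials view one CS while imagining the other"
                )
        if self.instruction is Instruction.IMAGINE and self.viewed_stimulus is not Stimulus.NONE:
            raise ScheduleError("imagine trials present no stimulus")
        if self.instruction is Instruction.VIEW and self.imagined_stimulus is not Stimulus.NONE:
            raise ScheduleError("view trials involve no imagery")


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered trial list for one phase, reproducible from (phase, n_runs, seed)."""

    phase: Phase
    n_runs: int
    trials: tuple[Trial, ...]
    seed: int
    exclusions_applied: bool = False

    def run(self, run_index: int) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if t.run_index == run_index)

    def __len__(self) -> int:
        return len(self.trials)


def condition_of(trial: Trial) -> tuple[str, str]:
    """Condition key (stimulus, instruction) used for trial accounting.

    View and regulate trials are keyed by the viewed stimulus (the
    down-regulate condition views the CS+, up-regulate views the CS-);
    imagine trials by the imagined stimulus.
    """
    if trial.instruction is Instruction.IMAGINE:
        stim = trial.imagined_stimulus
    else:
        stim = trial.viewed_stimulus
    return (stim.value, trial.instruction.value)


def _view(phase: Phase, run: int, stim: Stimulus, reinforced: bool = False) -> Trial:
    return Trial(phase, run, 0, stim, Stimulus.NONE, Instruction.VIEW, reinforced)


def _imagine(phase: Phase, run: int, stim: Stimulus) -> Trial:
    return Trial(phase, run, 0, Stimulus.NONE, stim, Instruction.IMAGINE)


def _regulate(phase: Phase, run: int, viewed: Stimulus) -> Trial:
    return Trial(phase, run, 0, viewed, _OPPOSITE[viewed], Instruction.REGULATE)


def _conditioning_like_run(
    phase: Phase, run: int, rng: np.random.Generator
) -> list[Trial]:
    """One 12-trial conditioning or regulation run.

    Fixed positions: 1 = view CS-, 2 = reinforced view CS+, 12 = view CS-.
    The 9 middle trials (2 view CS+, one of them reinforced so that exactly
    2 of the 4 view CS+ are; plus one extra unreinforced view CS+, 2 view
    CS-, and 2 special trials per CS) are shuffled into positions 3..11.
    """
    special = Instruction.IMAGINE if phase is Phase.CONDITIONING else Instruction.REGULATE

    # Remaining view CS+ after the mandatory reinforced trial 2: three trials,
    # exactly one of which is reinforced (2 of 4 overall = 50%).
    reinforced_slot = int(rng.integers(3))
    middle: list[Trial] = [
        _view(phase, run, Stimulus.CS_PLUS, reinforced=(i == reinforced_slot))
        for i in range(3)
    ]
    middle += [_view(phase, run, Stimulus.CS_MINUS) for _ in range(2)]
    if special is Instruction.IMAGINE:
        middle += [_imagine(phase, run, Stimulus.CS_PLUS) for _ in range(2)]
        middle += [_imagine(phase, run, Stimulus.CS_MINUS) for _ in range(2)]
    else:
        middle += [_regulate(phase, run, Stimulus.CS_PLUS) for _ in range(2)]
        middle += [_regulate(phase, run, Stimulus.CS_MINUS) for _ in range(2)]

    order = rng.permutation(len(middle))
    trials = (
        [_view(phase, run, Stimulus.CS_MINUS)]
        + [_view(phase, run, Stimulus.CS_PLUS, reinforced=True)]
        + [middle[i] for i in order]
        + [_view(phase, run, Stimulus.CS_MINUS)]
    )
    return [replace(t, position_in_run=pos) for pos, t in enumerate(trials, start=1)]


def _classifier_training_run(run: int, rng: np.random.Generator) -> list[Trial]:
    trials = [
        _view(Phase.CLASSIFIER_TRAINING, run, stim)
        for stim in (Stimulus.CS_PLUS, Stimulus.CS_MINUS)
        for _ in range(5)
    ]
    order = rng.permutation(len(trials))
    return [
        replace(trials[i], position_in_run=pos)
        for pos, i in enumerate(order, start=1)
    ]


def _preconditioning_run(run: int, rng: np.random.Generator) -> list[Trial]:
    trials: list[Trial] = []
    for stim in (Stimulus.CS_PLUS, Stimulus.CS_MINUS):
        trials += [_view(Phase.PRECONDITIONING, run, stim) for _ in range(4)]
        trials += [_imagine(Phase.PRECONDITIONING, run, stim) for _ in range(4)]
    order = rng.permutation(len(trials))
    return [
        replace(trials[i], position_in_run=pos)
        for pos, i in enumerate(order, start=1)
    ]


def build_phase_schedule(phase: Phase | str, n_runs: int, seed: int) -> PhaseSchedule:
    """Construct the full trial order for one phase.

    Identical ``(phase, n_runs, seed)`` always yields an identical schedule.
    """
    phase = Phase(phase)
    if n_runs < 1:
        raise ScheduleError(f"n_runs must be >= 1, got {n_runs}")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for run in range(1, n_runs + 1):
        if phase is Phase.CLASSIFIER_TRAINING:
            trials += _classifier_training_run(run, rng)
        elif phase is Phase.PRECONDITIONING:
            trials += _preconditioning_run(run, rng)
        elif phase in (Phase.CONDITIONING, Phase.REGULATION):
            trials += _conditioning_like_run(phase, run, rng)
        else:  # pragma: no cover - Phase() above rejects unknowns
            raise ScheduleError(f"unknown phase {phase!r}")
    return PhaseSchedule(phase=phase, n_runs=n_runs, trials=tuple(trials), seed=seed)


def apply_exclusions(schedule: PhaseSchedule) -> PhaseSchedule:
    """Mark analysis exclusions: reinforced trials and per-run edge CS- trials.

    In conditioning/regulation phases the excluded trials are (a) the two
    reinforced view CS+ trials of each run and (b) the first and last view
    CS- trial of each run, leaving equal included counts per condition.
    Classifier-training and preconditioning trials are all retained.
    Idempotent.
    """
    if schedule.phase not in (Phase.CONDITIONING, Phase.REGULATION):
        return replace(schedule, exclusions_applied=True)

    out: list[Trial] = []
    for run in range(1, schedule.n_runs + 1):
        run_trials = list(schedule.run(run))
        cs_minus_view = [
            t for t in run_trials
            if t.instruction is Instruction.VIEW
            and t.viewed_stimulus is Stimulus.CS_MINUS
        ]
        edge = {id(cs_minus_view[0]), id(cs_minus_view[-1])} if cs_minus_view else set()
        for t in run_trials:
            keep = not t.reinforced and id(t) not in edge
            out.append(replace(t, included=keep))
    out.sort(key=lambda t: (t.run_index, t.position_in_run))
    return replace(schedule, trials=tuple(out), exclusions_applied=True)


def count_analyzable(schedule: PhaseSchedule) -> pd.Series:
    """Included-trial counts per (stimulus, instruction) condition.

    Raises
    ------
    ScheduleError
        If the conditions present do not all have the same included count,
        which signals a malformed schedule.
    """
    keys = [condition_of(t) for t in schedule.trials if t.included]
    counts = pd.Series(keys, dtype=object).value_counts().sort_index()
    counts.index = pd.MultiIndex.from_tuples(
        list(counts.index) if len(counts) else [],
        names=["stimulus", "instruction"],
    )
    counts.name = "n_included"
    if len(counts) and counts.nunique() != 1:
        raise ScheduleError(f"unequal included counts per condition:\n{counts}")
    return counts


def schedule_to_events(schedule: PhaseSchedule) -> pd.DataFrame:
    """Serialize a schedule to a BIDS-style events table.

    Onsets are stimulus (CS) onsets in seconds from run start; each trial
    occupies cue (except classifier training, which has no audio cue) +
    6.5 s stimulus + 12 s ITI.  Columns: onset, duration, trial_type, run,
    reinforced, included.
    """
    cue = 0.0 if schedule.phase is Phase.CLASSIFIER_TRAINING else CUE_S
    rows = []
    for run in range(1, schedule.n_runs + 1):
        t = 0.0
        for trial in schedule.run(run):
            stim, instr = condition_of(trial)
            rows.append(
                {
                    "onset": t + cue,
                    "duration": STIM_S,
                    "trial_type": f"{instr}_{stim}",
                    "run": run,
                    "reinforced": trial.reinforced,
                    "included": trial.included,
                }
            )
            t += cue + STIM_S + ITI_S
    return pd.DataFrame(rows)
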