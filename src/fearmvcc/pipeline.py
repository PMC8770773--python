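"""End-to-end synthetic replications of the two experiments.

Experiment 1 (visit 1): classifier-training phase (view only) and fear
conditioning phase (view + imagine, 50% reinforcement of viewed CS+).
Decoders are trained on classifier-training view trials and tested on
conditioning-phase view and imagine trials per visual ROI; SCR and fear
ratings get repeated-measures statistics.

Experiment 2 (visit 2): regulation phase (view + regulate, where the
participant imagines the competing CS while viewing the other).  Visual
ROIs reuse the visit-1 classifier-training data for training; the
bilateral amygdala analysis instead trains on day-one conditioning-phase
view trials, is gated on a view-trial positive control, and scores
regulate trials as a CS+/CS- discrimination against the viewed stimulus.

Everything is deterministic given (config, master seed).
"""

from __future__ import annotations

import json
import platform
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavioral, inference, scr
from ._seeds import derive_rng, derive_seed_sequence
from .decoder import (
    DEFAULT_K_AMYGDALA,
    DEFAULT_K_VISUAL,
    ROIDataset,
    amygdala_gate,
)
from .design import (
    Phase,
    PhaseSchedule,
    apply_exclusions,
    build_phase_schedule,
)
from .synthgen import (
    PatternGroundTruth,
    RatingsGroundTruth,
    SCRGroundTruth,
    SyntheticParticipant,
    make_pattern_truth,
    participant_pattern_truth,
    simulate_ratings,
    simulate_roi_dataset,
    simulate_scr,
)

__all__ = ["ExperimentConfig", "ResultsBundle", "run_experiment1",
           "run_experiment2", "write_report", "simulate_participant"]


def _default_rois() -> dict:
    rois = {name: {"n_voxels": 300, "K": DEFAULT_K_VISUAL}
            for name in ("V1", "V2", "V3", "V4-V3AB")}
    rois["amygdala"] = {"n_voxels": 600, "K": DEFAULT_K_AMYGDALA}
    return rois


def _default_pattern_params() -> dict:
    # Calibrated once by pilot simulation to reproduce the qualitative group
    # orderings of the study design: view decoding in the mid-60s percent,
    # imagine decoding in the mid-50s, regulate decoding below view.
    return {
        "prototype_correlation": 0.0,
        "view_gain": 1.0,
        "imagery_gain": 0.5,
        "regulate_view_gain": 1.0,
        "regulate_imagery_gain": 1.0,
        "noise_sd": 10.0,
        "participant_variability_sd": 0.3,
    }


def _default_scr_amplitudes(experiment: int) -> dict:
    base = {("CSplus", "view"): 0.50, ("CSminus", "view"): 0.25}
    if experiment == 1:
        base.update({("CSplus", "imagine"): 0.45, ("CSminus", "imagine"): 0.25})
    else:
        # regulation equalizes the two regulate conditions
        base.update({("CSplus", "regulate"): 0.30, ("CSminus", "regulate"): 0.30})
    return base


def _default_rating_means(experiment: int) -> dict:
    if experiment == 1:
        return {("CSplus", "view"): 5.5, ("CSminus", "view"): 1.8,
                ("CSplus", "imagine"): 4.5, ("CSminus", "imagine"): 1.8}
    return {("CSplus", "view"): 5.8, ("CSminus", "view"): 1.8,
            ("CSplus", "regulate"): 2.6, ("CSminus", "regulate"): 3.4}


@dataclass
class ExperimentConfig:
    """Full configuration of a synthetic replication.

    Defaults reproduce the study's procedural constants: 13 participants
    in experiment 1 and 12 in experiment 2; 6 classifier-training and 6
    conditioning runs, 8 regulation runs; K = 120 voxels for visual ROIs
    and 300 for the amygdala; 10,000 permutation and 10,000 bootstrap
    iterations.  Tests and desk-scale runs shrink n_perm/n_boot and the
    ROI list, never the code path.
    """

    n_participants: int = 13
    n_participants_exp2: int = 12
    rois: dict = field(default_factory=_default_rois)
    pattern_params: dict = field(default_factory=_default_pattern_params)
    scr_amplitudes_exp1: dict = field(default_factory=lambda: _default_scr_amplitudes(1))
    scr_amplitudes_exp2: dict = field(default_factory=lambda: _default_scr_amplitudes(2))
    scr_shock_extra_uS: float = 0.8
    scr_participant_amplitude_sd: float = 0.4
    scr_trial_amplitude_sd_uS: float = 0.35
    scr_drift_slope_uS_per_s: float = 0.002
    scr_noise_sd_uS: float = 0.02
    rating_means_exp1: dict = field(default_factory=lambda: _default_rating_means(1))
    rating_means_exp2: dict = field(default_factory=lambda: _default_rating_means(2))
    n_runs_classifier_training: int = 6
    n_runs_conditioning: int = 6
    n_runs_regulation: int = 8
    n_perm: int = inference.DEFAULT_N_PERM
    n_boot: int = inference.DEFAULT_N_BOOT
    master_seed: int = 0
    alpha: float = 0.05
    accuracy_tail: str = "greater"   # accuracy vs chance
    difference_tail: str = "two"     # between-condition differences
    scr_ttest_tail_exp1: str = "one"
    scr_ttest_tail_exp2: str = "two"
    simulate_scr_data: bool = True

    def to_jsonable(self) -> dict:
        d = asdict(self)
        for key in ("scr_amplitudes_exp1", "scr_amplitudes_exp2",
                    "rating_means_exp1", "rating_means_exp2"):
            d[key] = {f"{s}/{i}": v for (s, i), v in d[key].items()}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return f"{zlib.crc32(blob):08x}"


@dataclass
class ResultsBundle:
    """Every table a replication produces, regenerable from config + seed."""

    experiment: str
    decoding: pd.DataFrame
    differences: pd.DataFrame
    scr_means: pd.DataFrame
    scr_stats: pd.DataFrame
    ratings: pd.DataFrame
    ratings_stats: pd.DataFrame
    provenance: dict

    def tables(self) -> dict:
        return {
            "decoding": self.decoding,
            "differences": self.differences,
            "scr_means": self.scr_means,
            "scr_stats": self.scr_stats,
            "ratings": self.ratings,
            "ratings_stats": self.ratings_stats,
        }

    def to_json(self) -> str:
        payload = {"experiment": self.experiment, "provenance": self.provenance}
        for name, df in self.tables().items():
            payload[name] = df.to_dict(orient="records")
        return json.dumps(payload, sort_keys=True, indent=1, default=str)


# ---------------------------------------------------------------------------
# simulation


def _scr_truth(config: ExperimentConfig, experiment: int) -> SCRGroundTruth:
    amplitudes = (config.scr_amplitudes_exp1 if experiment == 1
                  else config.scr_amplitudes_exp2)
    return SCRGroundTruth(
        amplitudes=amplitudes,
        shock_extra_uS=config.scr_shock_extra_uS,
        participant_amplitude_sd=config.scr_participant_amplitude_sd,
        trial_amplitude_sd_uS=config.scr_trial_amplitude_sd_uS,
        drift_slope_uS_per_s=config.scr_drift_slope_uS_per_s,
        noise_sd_uS=config.scr_noise_sd_uS,
    )


def _participant_ids(n: int) -> list[str]:
    return [f"sub-{i:02d}" for i in range(1, n + 1)]


def simulate_participant(
    config: ExperimentConfig, experiment: int, participant_id: str
) -> SyntheticParticipant:
    """Schedules, ROI patterns and SCR traces for one participant.

    Experiment 1 yields classifier-training + conditioning phases;
    experiment 2 additionally yields the regulation phase (the visit-1
    training phases are regenerated identically from the same seeds, as
    the decoders reuse them).
    """
    seed = config.master_seed
    sched_seed = int(derive_seed_sequence(seed, "schedule", participant_id)
                     .generate_state(1)[0] >> 1)
    schedules = {
        "classifier_training": apply_exclusions(build_phase_schedule(
            Phase.CLASSIFIER_TRAINING, config.n_runs_classifier_training, sched_seed)),
        "conditioning": apply_exclusions(build_phase_schedule(
            Phase.CONDITIONING, config.n_runs_conditioning, sched_seed + 1)),
    }
    if experiment == 2:
        schedules["regulation"] = apply_exclusions(build_phase_schedule(
            Phase.REGULATION, config.n_runs_regulation, sched_seed + 2))

    group_truths = {
        roi: make_pattern_truth(p["n_voxels"], seed=seed, **config.pattern_params)
        for roi, p in config.rois.items()
    }
    truths = {roi: participant_pattern_truth(t, participant_id, seed)
              for roi, t in group_truths.items()}

    roi_data = {}
    for roi, truth in truths.items():
        for phase_name, schedule in schedules.items():
            roi_data[(roi, phase_name)] = simulate_roi_dataset(
                schedule, truth, seed, roi_name=roi, participant_id=participant_id
            )

    scr_traces = {}
    scr_truth = None
    if config.simulate_scr_data:
        scr_truth = _scr_truth(config, experiment)
        phase_name = "conditioning" if experiment == 1 else "regulation"
        scr_traces[phase_name] = simulate_scr(
            schedules[phase_name], scr_truth, seed, participant_id=participant_id
        )
    return SyntheticParticipant(
        participant_id=participant_id,
        schedules=schedules,
        roi_data=roi_data,
        scr_traces=scr_traces,
        pattern_truths=truths,
        scr_truth=scr_truth,
    )


# ---------------------------------------------------------------------------
# stage helpers


def _condition_subsets(ds: ROIDataset, instructions: list[str]) -> dict:
    instr = ds.meta["instruction"].to_numpy()
    return {name: instr == name for name in instructions}


def _decode_phase(
    participants: list[SyntheticParticipant],
    roi: str,
    K: int,
    train_phase: str,
    test_phase: str,
    instructions: list[str],
    config: ExperimentConfig,
) -> list[inference.ParticipantNull]:
    nulls = []
    for part in participants:
        train = part.roi_data[(roi, train_phase)].analysis_view()
        view_mask = train.meta["instruction"].to_numpy() == "view"
        train = train.subset(view_mask)
        test = part.roi_data[(roi, test_phase)].analysis_view()
        subsets = _condition_subsets(test, instructions)
        nulls.append(
            inference.participant_null(
                train, test, subsets, K,
                n_perm=config.n_perm,
                seed=config.master_seed,
            )
        )
    return nulls


def _accuracy_rows(
    nulls: list[inference.ParticipantNull],
    roi: str,
    conditions: list[str],
    config: ExperimentConfig,
) -> tuple[list[dict], dict]:
    rows, pvals = [], {}
    for cond in conditions:
        gn = inference.group_null(nulls, cond, config.n_boot, config.master_seed)
        obs = inference.group_observed_accuracy(nulls, cond)
        res = inference.empirical_p(obs, gn, tail=config.accuracy_tail,
                                    n_perm=config.n_perm)
        pvals[cond] = res.p_value
        rows.append({
            "roi": roi, "condition": cond,
            "observed_accuracy": res.observed, "p_value": res.p_value,
            "tail": res.tail, "n_perm": config.n_perm, "n_boot": config.n_boot,
            "seed": config.master_seed, "status": "run",
        })
    return rows, pvals


def _difference_row(
    nulls: list[inference.ParticipantNull],
    roi: str,
    cond_a: str,
    cond_b: str,
    config: ExperimentConfig,
) -> dict:
    res = inference.condition_difference_test(
        nulls, cond_a, cond_b, config.n_boot, config.master_seed,
        tail=config.difference_tail,
    )
    return {
        "roi": roi, "condition_a": cond_a, "condition_b": cond_b,
        "observed_difference": res.observed_difference,
        "p_value": res.p_value, "tail": res.tail,
        "n_perm": config.n_perm, "n_boot": config.n_boot,
        "seed": config.master_seed,
    }


def _score_scr(participants, phase_name: str) -> pd.DataFrame:
    rows = []
    for part in participants:
        trace = part.scr_traces.get(phase_name)
        if trace is None:
            continue
        schedule = part.schedules[phase_name]
        pre = scr.preprocess(trace)
        epochs = scr.epoch_and_baseline(pre)
        peaks = scr.score_peaks(epochs, schedule)
        means = scr.average_by_condition(peaks)
        for (stim, instr), value in means.items():
            rows.append({"participant": part.participant_id, "stimulus": stim,
                         "instruction": instr, "mean_peak_uS": value})
    return pd.DataFrame(rows)


def _within_stats(
    tidy: pd.DataFrame, value: str, ttest_tail: str, label: str
) -> pd.DataFrame:
    """2x2 rm-ANOVA plus per-instruction CS+ vs CS- paired contrasts."""
    rows = []
    table = behavioral.WithinSubjectTable.from_tidy(
        tidy, "stimulus", "instruction", value=value
    )
    for res in behavioral.rm_anova_2x2(table):
        rows.append({"measure": label, "test": "rm_anova", "effect": res.effect,
                     "F": res.F, "df_num": res.df_num, "df_den": res.df_den,
                     "p": res.p, "eta_G_sq": res.eta_G_sq,
                     "t": np.nan, "cohen_d": np.nan, "tail": "two",
                     "n": table.n_participants})
    wide = table.data
    for instr in sorted({b for _, b in wide.columns}):
        t_res = behavioral.paired_t(
            wide[("CSplus", instr)], wide[("CSminus", instr)], tail=ttest_tail
        )
        rows.append({"measure": label, "test": "paired_t",
                     "effect": f"CSplus vs CSminus ({instr})",
                     "F": np.nan, "df_num": np.nan, "df_den": t_res.df,
                     "p": t_res.p, "eta_G_sq": np.nan, "t": t_res.t,
                     "cohen_d": t_res.cohen_d, "tail": t_res.tail,
                     "n": table.n_participants})
    return pd.DataFrame(rows)


def _provenance(config: ExperimentConfig, experiment: str) -> dict:
    return {
        "experiment": experiment,
        "config": config.to_jsonable(),
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "python": platform.python_version(),
    }


# ---------------------------------------------------------------------------
# experiments


def run_experiment1(config: ExperimentConfig) -> ResultsBundle:
    """Fear transfer to imagined stimuli: decode view and imagine trials."""
    ids = _participant_ids(config.n_participants)
    participants = [simulate_participant(config, 1, pid) for pid in ids]

    decoding_rows, difference_rows = [], []
    for roi, roi_cfg in config.rois.items():
        if roi == "amygdala":
            continue  # amygdala decoding belongs to the visit-2 analysis
        nulls = _decode_phase(participants, roi, roi_cfg["K"],
                              "classifier_training", "conditioning",
                              ["view", "imagine"], config)
        rows, _ = _accuracy_rows(nulls, roi, ["view", "imagine"], config)
        decoding_rows += rows
        difference_rows.append(_difference_row(nulls, roi, "view", "imagine", config))

    scr_means = _score_scr(participants, "conditioning")
    scr_stats = (_within_stats(scr_means, "mean_peak_uS",
                               config.scr_ttest_tail_exp1, "scr")
                 if len(scr_means) else pd.DataFrame())

    ratings = simulate_ratings(
        RatingsGroundTruth(means=config.rating_means_exp1),
        config.n_participants, config.master_seed,
    )
    ratings_stats = _within_stats(ratings, "rating", "two", "fear_of_shock")

    return ResultsBundle(
        experiment="experiment1",
        decoding=pd.DataFrame(decoding_rows),
        differences=pd.DataFrame(difference_rows),
        scr_means=scr_means,
        scr_stats=scr_stats,
        ratings=ratings,
        ratings_stats=ratings_stats,
        provenance=_provenance(config, "experiment1"),
    )


def run_experiment2(config: ExperimentConfig) -> ResultsBundle:
    """Imagery-based regulation: decode view and regulate trials; gated amygdala."""
    ids = _participant_ids(config.n_participants_exp2)
    participants = [simulate_participant(config, 2, pid) for pid in ids]

    decoding_rows, difference_rows = [], []
    for roi, roi_cfg in config.rois.items():
        train_phase = "conditioning" if roi == "amygdala" else "classifier_training"
        nulls = _decode_phase(participants, roi, roi_cfg["K"],
                              train_phase, "regulation",
                              ["view", "regulate"], config)
        rows, pvals = _accuracy_rows(nulls, roi, ["view"], config)
        decoding_rows += rows
        if roi == "amygdala" and not amygdala_gate(pvals["view"], config.alpha):
            # positive control failed: dependent regulate decoding not run
            decoding_rows.append({
                "roi": roi, "condition": "regulate",
                "observed_accuracy": np.nan, "p_value": np.nan,
                "tail": config.accuracy_tail, "n_perm": config.n_perm,
                "n_boot": config.n_boot, "seed": config.master_seed,
                "status": "not_run_gate_failed",
            })
            continue
        rows, _ = _accuracy_rows(nulls, roi, ["regulate"], config)
        decoding_rows += rows
        difference_rows.append(_difference_row(nulls, roi, "view", "regulate", config))

    scr_means = _score_scr(participants, "regulation")
    scr_stats = (_within_stats(scr_means, "mean_peak_uS",
                               config.scr_ttest_tail_exp2, "scr")
                 if len(scr_means) else pd.DataFrame())

    ratings = simulate_ratings(
        RatingsGroundTruth(means=config.rating_means_exp2),
        config.n_participants_exp2, config.master_seed,
    )
    ratings_stats = _within_stats(ratings, "rating", "two", "fear_of_shock")

    return ResultsBundle(
        experiment="experiment2",
        decoding=pd.DataFrame(decoding_rows),
        differences=pd.DataFrame(difference_rows),
        scr_means=scr_means,
        scr_stats=scr_stats,
        ratings=ratings,
        ratings_stats=ratings_stats,
        provenance=_provenance(config, "experiment2"),
    )


def write_report(bundle: ResultsBundle, path: str | Path) -> list[Path]:
    """Write tidy TSV tables, a JSON summary, and a run log under ``path``."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in bundle.tables().items():
        p = out / f"{bundle.experiment}_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    summary = out / f"{bundle.experiment}_summary.json"
    summary.write_text(bundle.to_json())
    written.append(summary)
    log = out / f"{bundle.experiment}_run.log"
    log.write_text(
        f"experiment={bundle.experiment}\n"
        f"config_hash={bundle.provenance['config_hash']}\n"
        f"master_seed={bundle.provenance['master_seed']}\n"
    )
    written.append(log)
    return written
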