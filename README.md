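# fearmvcc

A tested Python pipeline for differential fear-conditioning experiments
that manipulate mental imagery: trial-schedule construction with analysis
exclusions, skin-conductance response (SCR) scoring, ROI-level
multivariate cross-classification (MVCC) of fMRI trial patterns,
permutation + bootstrap group inference, and repeated-measures behavioral
statistics — exercised end to end on synthetic participants with known
ground truth.

## The problem

In differential fear conditioning one stimulus (the CS+, here an oriented
Gabor patch) is paired with a mild shock on 50% of viewed presentations
while a second (the CS-) never is.  The scientific questions this pipeline
serves: does the conditioned response transfer to merely *imagining* the
CS+, and can imagining the competing stimulus while viewing a CS
*regulate* the response?  The computational answers come from three
channels:

- **Decoding (MVCC).**  A linear SVM is trained to discriminate CS+ from
  CS- on view trials of a pre-conditioning classifier-training phase
  (top-K voxel selection by univariate CS+ − CS- difference, K = 120 for
  visual ROIs, 300 for the amygdala; C = 1/mean‖x‖₂), then tested without
  retraining on later-phase trials: view trials, imagine trials, and
  regulate trials (viewing one CS while imagining the other).  Chance is
  50%.  Significance comes from within-participant permutation nulls
  (training labels permuted, selection + training re-run, 10,000
  iterations at full study scale) aggregated by a group bootstrap (one null
  draw per participant per iteration, 10,000 iterations), with add-one
  empirical p-values, p = (1 + #{null ≥ obs})/(1 + n).  Between-condition
  tests reuse seed-paired nulls.  A fragile analysis (amygdala regulate
  decoding) is gated behind a view-trial positive control (p < 0.05).
- **SCR.**  1 kHz traces are detrended, median-filtered (50 samples),
  down-sampled to 100 Hz, epoched −1…+8 s around CS onset,
  baseline-corrected, and scored trough-to-peak (max over 1–8 s minus min
  over 0–0.99 s; responses < 0.02 µS zeroed), then averaged per condition
  over included shock-free trials.
- **Behavior.**  2×2 within-participant ANOVA (CS-Type × Instruction)
  with generalized eta-squared, η²G = SS_eff/(SS_eff + ΣSS_subject-related),
  plus paired/one-sample t-tests with Cohen's d = mean(diff)/sd(diff).

Trial bookkeeping underlies everything: conditioning-like runs fix the
first/last trial (view CS-) and the second (reinforced view CS+), shuffle
positions 3–11 by seed, and exclusions drop reinforced and edge CS-
trials so every condition contributes equally (12 trials/condition over 6
conditioning runs; 16 over 8 regulation runs).

See `docs/methods.md` for the full model, parameter defaults, and design
decisions.

## Worked example

A single-ROI synthetic replication of the first experiment (13
participants, 6 classifier-training + 6 conditioning runs, 500
permutations / 1000 bootstrap draws):

```python
from fearmvcc import ExperimentConfig, run_experiment1

config = ExperimentConfig(
    rois={"V2": {"n_voxels": 300, "K": 120}},
    n_perm=500, n_boot=1000, master_seed=7,
)
bundle = run_experiment1(config)
print(bundle.decoding[["roi", "condition", "observed_accuracy", "p_value"]])
```

```
roi condition  observed_accuracy  p_value
 V2      view            61.8590    0.001
 V2   imagine            57.3718    0.003
```

Both group accuracies beat the permutation null: viewing is decodable,
and the attenuated imagery signal (generated at half the perceptual gain)
still transfers — the synthetic analogue of fear-relevant imagery
re-instating a perceptual representation.  The same bundle carries the
SCR and ratings statistics, e.g. the SCR ANOVA recovers the generated
main effect of CS-Type with no Instruction interaction:

```
    test                   effect      F     p     t  cohen_d tail
rm_anova                 stimulus 90.636 0.000   NaN      NaN  two
rm_anova              instruction  0.000 0.999   NaN      NaN  two
rm_anova   stimulus x instruction  0.045 0.835   NaN      NaN  two
paired_t CSplus vs CSminus (view)    NaN 0.000 5.368    1.489  one
```

`run_experiment2` adds the regulation phase: regulate-trial decoding of
the viewed stimulus drops below view-trial decoding when the generator
mixes in the imagined competitor, and the amygdala analysis runs only if
its positive control passes.  `write_report(bundle, path)` emits tidy TSV
tables plus a JSON summary, byte-identical under a fixed (config, seed).

A CLI mirrors the library: `fearmvcc schedule|simulate|scr-score|decode|
infer|stats|run-exp1|run-exp2|report` (see `--help`).

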