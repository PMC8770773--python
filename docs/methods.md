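# Methods

`fearmvcc` re-implements, as a tested library, the computational core of a
two-visit differential fear-conditioning / mental-imagery decoding study:
trial-schedule construction with analysis exclusions, skin-conductance
response (SCR) scoring, ROI-level multivariate cross-classification
(MVCC), group permutation + bootstrap inference, and repeated-measures
behavioral statistics.  It runs end to end on synthetic data with known
ground truth; an optional reader for real trial-wise pattern matrices can
feed the same decoding surface.

## Experimental design model

Two conditioned stimuli (CS+ and CS-, two oriented Gabor patches) drive
four phases:

- **Classifier training** (6 runs, 5 view trials per stimulus per run,
  no reinforcement): supplies decoder training data untouched by
  conditioning.
- **Pre-conditioning** (3 runs, 4 view + 4 imagine per CS per run):
  practice only; constructible but without an analysis role.
- **Conditioning** (6 runs, 4 view + 2 imagine per CS per run, 12
  trials/run): 50% of view CS+ trials co-terminate with shock.
- **Regulation** (8 runs, 4 view + 2 regulate per CS per run): regulate
  trials view one CS while the participant imagines the other
  (down-regulate = view CS+/imagine CS-; up-regulate = the converse).

Conditioning-like runs fix trial 1 and trial 12 as view CS- and trial 2 as
a reinforced view CS+; positions 3–11 hold the remaining multiset (three
view CS+, exactly one of them reinforced so that 2 of 4 per run are; two
view CS-; two special trials per CS) in a seeded uniform shuffle.
Exclusions mark reinforced trials and the first/last view CS- of each run
as non-analyzable, leaving equal included counts per condition: 12 per
condition over 6 conditioning runs, 16 over 8 regulation runs (10 over 5
runs for a truncated session).  `count_analyzable` enforces the equality
and treats a violation as an integrity error.

One textual ambiguity is resolved in favor of arithmetic consistency: the
regulation phase is eight runs (4 + 2 trials per CS per run with four
exclusions per run gives 16 per condition only under eight runs).

## SCR pipeline

Raw traces are modeled at 1 kHz in microsiemens.  Per run: least-squares
linear detrend that removes the slope but retains the run mean (keeping
the µS scale interpretable; the subsequent baseline step removes offsets
anyway), then a 50-sample median filter, then 10:1 decimation to 100 Hz.
The even-length median window covers samples [i-25, i+24] with reflected
edges, and the median of 50 values is the mean of the two central order
statistics — implemented as two moving rank filters, which equals a naive
per-window `np.median` exactly and is what the brute-force oracle tests
assert.

Epochs span −1.0 s to +8.0 s around CS onset at 100 Hz (100 baseline
samples plus 801 post-onset samples, so the 8.0 s sample itself is
available to the peak search); each epoch has its 1 s pre-onset mean
subtracted.  The trial amplitude is trough-to-peak: max over post-onset
samples [100, 800] (1.00–8.00 s) minus min over samples [0, 99]
(0–0.99 s); amplitudes below 0.02 µS are zeroed.  A trial whose window
falls outside its run is flagged missing and simply shrinks the
denominator of its condition mean.  Condition means use included,
shock-free trials only.

Tail policy: visit-1 CS+ vs CS- SCR contrasts are one-tailed (a
directional conditioning hypothesis); visit-2 contrasts are two-tailed
(regulation could move responses either way).  Both are configuration, not
hard-coded.

## Decoding (MVCC)

The decoding unit is an `ROIDataset`: a trial × voxel matrix (standing in
for trial-wise GLM betas) with per-trial labels.  Feature selection keeps
the K voxels with the largest positive univariate mean difference (CS+
minus CS-) on training data — K = 120 for visual ROIs, 300 for the
bilateral amygdala; ties break by ascending voxel index, and if fewer than
K voxels score positive the top-K by signed score are kept with a warning.
The classifier is a linear-kernel SVM with norm auto-scaled
regularization, C = 1 / mean‖x‖₂ over training vectors.  Training uses
view trials of the designated training phase only; a dedicated test
asserts that corrupting test data cannot change selection or weights.

For speed inside resampling loops the SVM is fit through scikit-learn's
libsvm binding directly rather than the `SVC` estimator wrapper; a test
pins exact agreement of weights and bias with `SVC` across random
problems.

Cross-classification applies the trained model, without retraining, to
balanced condition subsets of a later phase: view and imagine trials of
the conditioning phase, or view and regulate trials of the regulation
phase.  Accuracy is scored against the viewed stimulus except on imagine
trials (no stimulus is shown), which are scored against the imagined one;
regulate trials are scored against the viewed stimulus, which for the
amygdala analysis coincides with the down-regulate-CS+ vs up-regulate-CS-
discrimination.  Chance is exactly 50% for every balanced subset.

The amygdala analysis is gated: regulate-trial decoding is interpreted
only if the view-trial positive control is significant (strictly
p < 0.05); otherwise it is reported as not run.

## Inference

Within-participant permutation nulls retrain the whole pipeline — feature
selection included, since leaving it fixed would leak label information
into the null — under permuted training labels (a permutation of the
label vector, hence class-balanced), and evaluate on the fixed test
subsets.  All condition subsets of a participant are scored under the same
permuted model per iteration, so nulls for different conditions are
seed-paired by construction; between-condition tests difference the
paired null entries before bootstrap aggregation.  The group null draws,
with replacement, one permutation value per participant per iteration and
averages (10,000 + 10,000 iterations at full study scale; tests use 500 +
1,000, same code path).

Empirical p-values use the add-one rule, p = (1 + #{null ≥ obs}) /
(1 + n), one-tailed above chance for accuracy tests and two-tailed
(doubled smaller tail, capped at 1) for differences; p-values can never
be zero.  No multiple-ROI correction is applied by default (a Holm option
exists on the tidy results table downstream).

A subtlety the validation suite accounts for: conditioned on one fixed
small test set, the permutation null's mean can sit a percentage point or
two away from 50% — the permuted models' per-trial vote probabilities do
not average out over 24 trials.  Only the expectation over datasets is
exactly 50%.  The chance-calibration routine therefore uses study-scale
training data (60 trials, 300 voxels, K = 120) but a large (1000-trial)
balanced signal-free test set per participant, measuring the chance level
to ±0.2 pp rather than confounding it with test-set sampling noise.  The
type-I-error routine, by contrast, keeps realistic small test sets and
checks the rejection rate over 200 replicate groups; calibration of a
balanced two-class test does not depend on problem size, so replicates run
at a small size (20 training trials, 30 voxels, K = 10) to stay affordable.

## Behavioral statistics

The 2×2 fully within-participant ANOVA (CS-Type × Instruction) uses the
classical effect-by-subject error terms, df = (1, n−1), and reports
generalized eta-squared: η²G = SS_effect / (SS_effect + SS_subject +
ΣSS_factor×subject).  This is deliberately not partial η²; the generalized
form is comparable across designs.  The implementation is a from-scratch
sums-of-squares decomposition, cross-checked in tests against both a
hand-computed oracle and `pingouin.rm_anova(effsize="ng2")`.  Sphericity
is moot with two-level factors.  Cohen's d for paired contrasts defaults
to mean(diff)/sd(diff) (with a pooled-SD variant behind
`d_convention="av"`); one-tailed p is half the two-tailed p when the
effect lies in the hypothesized direction.  Zero-variance differences with
a nonzero mean are reported at the machine bound with a `degenerate` flag.

## Synthetic data generator

The generator produces what the analysis consumes, one level above the
scanner; it does not model hemodynamics, spatial autocorrelation, or
physiological noise spectra, so passing tests certify the analysis code,
not real-data effect sizes.

**Patterns.**  Each ROI has two equal-norm prototype patterns with
configurable correlation (default 0, built from a seeded orthonormal
pair, norm √n_voxels so per-voxel RMS is 1).  Expected trial patterns
are gain mixtures — view: `view_gain·proto(viewed)`; imagine:
`imagery_gain·proto(imagined)` with `imagery_gain ≤ view_gain` (imagery
as a weaker copy of perception); regulate:
`regulate_view_gain·proto(viewed) + regulate_imagery_gain·proto(imagined)`
— plus i.i.d. Gaussian voxel noise.  Participants receive individually
perturbed prototypes (`participant_variability_sd`); classifiers are
always within-participant.  Defaults (view_gain 1, imagery_gain 0.5,
regulate gains 1/1, noise_sd 10, variability 0.3 at 300 voxels) were
calibrated once by pilot simulation to land the qualitative group
orderings the design predicts — view decoding in the mid-60s percent,
imagine in the high-50s, regulate below view — not any printed accuracy;
no voxel-level effect-size anchors exist to calibrate against.

**SCR.**  Difference-of-exponentials response kernel (latency 1 s, rise
0.75 s, decay 2 s, unit peak; the peak time has the closed form
L + ln(τd/τr)·τrτd/(τd−τr) used by the tests), per-condition amplitudes,
an extra shock response on reinforced trials, linear drift, Gaussian
noise, 1 kHz.  Participants share one multiplicative responsiveness
factor across conditions, and trial amplitudes jitter (sd 0.35 µS,
clipped at zero) — without both, group-level effect sizes would be
absurdly large.  Default amplitudes encode the design's expectations:
conditioning CS+ > CS- under both view (0.50/0.25) and imagine
(0.45/0.25); regulation equalizes the two regulate conditions (0.30/0.30)
while view keeps its differential.

**Ratings.**  Latent-Gaussian 7-point Likert items: condition mean +
participant offset + noise, rounded and clipped to [1, 7].  Default means
produce a strong CS-Type effect and a CS-Type × Instruction interaction
for visit 1, and the reversed regulate-condition pattern for visit 2.

**Seeding.**  Every random draw flows from one master seed through keyed
`SeedSequence` substreams (participant, phase, purpose), so any single
participant or iteration is replayable in isolation and full runs are
byte-identical under a fixed (config, seed) pair.

## Problem sizes and runtime

Tests and the acceptance script run the full code paths at reduced
resampling scale — n_perm ≤ 500, n_boot ≤ 1000, ROI sizes of a few
hundred voxels — chosen so the whole suite completes in minutes on one
CPU; study-scale 10,000/10,000 resampling is the library default and
available throughout by configuration.

## Known limitations

- No hemodynamic model, GLM inversion, or fMRI preprocessing; the
  contract starts at trial × voxel matrices.
- No SCR deconvolution; trough-to-peak scoring only.
- Within-phase cross-validation, searchlights, nonlinear kernels and
  whole-brain univariate analyses are out of scope.
- The real-data path expects trial-wise pattern matrices already
  extracted from beta-series images; no NIfTI I/O is bundled.
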