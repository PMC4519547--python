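# Methods

This note documents the models, defaults and numerical choices behind
`fmvpa`, and what the synthetic-data experiments do and do not establish.

## Experimental design model

A subject receives 124 events over 3 runs (40, 40, 44). Events are built
from fixed sub-stages — question 3 s, picture 2 s, response 1.5 s,
feedback 0.5 s — plus a fixation of 2 s or 6 s, so each event lasts 9 or
13 s (mean 11 s). Events come in pseudorandomized sequences of 8
(4 novel targets / 2 familiar targets / 2 baseline) with a final 4-event
sequence (2/1/1) in run 3, giving 62 novel, 31 familiar and 31 baseline
trials per subject. Runs open with a 12 s lead-in whose volumes are
excluded from analysis.

Two choices in the schedule are interpretive:

- **Inter-sequence blanks.** The 6 s blank is placed *after every*
  sequence, including the last of each run. Only this placement reproduces
  the stated run durations exactly (40×11 + 12 + 5×6 = 482 s;
  44×11 + 12 + 6×6 = 532 s, i.e. 241 and 266 volumes at TR = 2 s), so the
  printed durations were treated as authoritative over the word "between".
- **Fixation balance.** The 2 s / 6 s split is enforced exactly half/half
  at the *run* level (the only constraint the duration arithmetic
  requires); within-sequence balance is not imposed. Ordering within a
  sequence is a uniform seeded shuffle — no further pseudorandomization
  constraints are modeled.

## BOLD simulator

The simulator reproduces the statistical structure the decoding analysis
assumes, not scanner physics. Default geometry matches the emulated
acquisition (TR = 2 s; 64×64×32 grid of 3×3×5 mm voxels; runs of
241/241/266 volumes); experiments here run on 16×16×8 grids, which changes
voxel count but not the per-voxel signal model.

- **Signal.** Each informative region holds one fixed standard-normal
  spatial pattern per outcome class (remembered / forgotten). Every novel
  trial contributes a boxcar from picture onset lasting 3.5 s (picture +
  response window) convolved with a canonical double-gamma HRF
  (peak-normalized; gamma(6,1) − gamma(16,1)/6, peaking ≈ 5 s, consistent
  with sampling the response 6–8 s after trial onset). Pattern amplitude is
  `effect_size × noise_sd` at the single-event response peak. Baseline and
  familiar trials add no class signal. There is no effect-size estimate to
  borrow from real data, so defaults are illustrative, not fitted.
- **Patterns across subjects.** `simulate_subject` draws patterns per
  subject; `pipeline.simulate_cohort` draws them once per cohort and shares
  them across subjects. The shared-pattern mode emulates spatially
  normalized data in which a common multivoxel code distinguishes
  later-remembered trials — without it, leave-one-subject-out decoding has
  no transferable signal and sits at chance by construction. Within a
  subject, patterns are stable across trials and runs.
- **Noise.** Per-voxel AR(1) series (default coefficient 0.3, innovation
  SD 1.0, stationary initialization), plus linear and half-cosine drift
  with per-voxel random amplitudes (default 0.5) and a constant baseline
  (default 100). Motion, spikes, physiological noise and anatomy are out
  of scope, so passing tests show internal statistical validity of the
  pipeline, not robustness to real-scanner artifacts.
- **Memory outcomes.** Each novel trial is remembered i.i.d. with
  probability `p_remember`; when unset, the condition's empirical
  recognition rate is used (FM 0.3528, EE 0.4367).
- **Seeding.** All randomness descends from one master seed through named
  BLAKE2-hashed substreams (design, labels, patterns, per-run noise,
  counterbalancing, permutations), so components can be varied
  independently without perturbing each other.

## Preprocessing

Per voxel and run: remove the linear trend, then z-score using the mean
and SD of the *baseline-trial* volumes only (those acquired 6–8 s after a
baseline-trial onset, excluding the lead-in). Voxels with zero baseline SD
are zeroed and flagged. Trial features average the volumes acquired in the
inclusive 6–8 s post-onset window (volume i at time i×TR); because onsets
alternate parity, a trial spans one or two such volumes. Averaging keeps
one sample per trial, matching per-trial labels and the counterbalancing
rule; a concatenate mode (each peak volume its own sample) is provided
since either reading of "selecting volumes" is defensible. Counterbalancing
randomly down-samples the majority class to the minority count within each
run; single-class runs are dropped with a warning.

## Decoding

Linear soft-margin SVM, fixed C = 1 (no tuning is modeled; configurable).
The solver tolerance is tightened to 1e−9 so the fitted boundary does not
depend on the incidental ordering of training samples — a reproducibility
contract the searchlight relies on. Feature selection scores each voxel
with the two-group one-way ANOVA F (df 1, n−2; identically the squared
pooled t) and keeps the k = 100 largest, ties broken toward lower voxel
index; selection is recomputed inside every training fold. A deliberately
leaky "global" selection mode is retained solely for regression tests,
which require it to inflate null accuracy while the nested mode does not.
Within-subject results are averaged over the 3 leave-one-run-out folds and
then over subjects; cross-subject results pool subjects in the common
voxel grid under leave-one-subject-out. For small ROIs, k clamps to the
region size rather than erroring.

## Permutation inference

Each permutation shuffles the label vector dataset-wise, relabels only the
training portion of every fold (feature selection included) and scores
predictions against the original test labels; p = (1 + #{perm ≥ obs}) /
(1 + B), never exactly zero. Defaults are 10000 permutations within
subject and 1000 across subjects; experiments here use 200 for tractable
runtimes. A run-stratified shuffle is available but non-default: measured
on label-free data (300 datasets, 200 permutations, 48 samples), the
stratified orbit combined with original-label scoring is slightly
anti-conservative (type-I ≈ 0.07 at α = 0.05) whereas the dataset-wise
shuffle is calibrated (≈ 0.057; the fully exchangeable score-against-
permuted-labels variant measures 0.047, confirming the implementation).

## Searchlight

Neighborhoods are integer-lattice balls in voxel-index units (radius 4 →
257 voxels, matching the lattice count exactly); a millimetre-radius mode
for the anisotropic voxels is available but non-default. Within each
neighborhood the same SVM cross-validation runs with *no* top-k selection —
the projection is the selection. Neighborhoods are clipped at grid edges
and scored whenever ≥ 2 voxels remain. Centers are thresholded by a
one-sided exact binomial test of the pooled correct count against 0.5,
uncorrected by default with optional Benjamini–Hochberg FDR; group maps
average per-subject maps and threshold at the pooled trial count, using
FDR in the localization experiments since several thousand centers are
tested at once. Peak tables report 6-connected clusters with world-space
peak coordinates via the affine, sorted by peak accuracy.

## Behavioral scoring

4AFC chance is 1/4, always derived from the alternative count. Items
reported as pre-experimentally familiar are excluded before scoring (lure
familiarity is not grounds for exclusion). Inclusion requires one-sided
binomial evidence above chance on the first test *and* on a two-test
consistency criterion; the consistency null is operationalized as the
both-tests-correct count against (1/4)² = 0.0625, with the test-2 marginal
offered as an alternative because the published criterion does not pin
down its null distribution. Decoding labels come from the first test.

## Validation experiments and problem sizes

The validation battery runs at desk scale: 16×16×8 grids, 12 subjects for
null calibration, 6 for signal recovery, 100 label-free datasets × 200
permutations for type-I error, 30 datasets for the leakage contrast, with
searchlight radius 2 in the localization runs. At these sizes the full
suite completes in a few minutes on one CPU. What they establish: the
pipeline is unbiased at chance on signal-free data, the permutation test
is calibrated, nested selection does not leak, regional restriction
recovers a confined signal (region ≈ whole brain; control region at
chance) and the searchlight localizes it (Dice ≈ 0.5 against the true
region after FDR thresholding). What they do not establish: performance
under realistic anatomy, motion, or inter-subject variability in pattern
geometry, none of which the generator emulates.

## Known limitations

- Without the original analysis code, the exact SVM scaling and
  regularization cannot be matched; only qualitative accuracy patterns are
  reproducible.
- Group statistics on accuracy tables (repeated-measures ANOVA, t-tests)
  are intentionally left to external stats packages; the pipeline emits
  tidy TSVs for them.
- Searchlight centers are evaluated serially; the map contract (identical
  output regardless of scheduling) keeps the door open for
  parallelization.
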