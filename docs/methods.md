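# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `decabt` package: what is computed, under which
assumptions, and why the open design choices were resolved the way they
were.

## Trial-level attentional-bias labelling

The unit of analysis is the single approach–avoidance trial.  Within each
block, the mean RT of valid neutral trials — approach and avoidance
separately — forms the empirical baseline; a gaming trial is *positive*
(attention drawn towards gaming) when pulled faster than the approach
baseline or pushed slower than the avoidance baseline, *negative* in the
strict opposite case.  Decisions taken where the definition is silent:

- **Ties** (RT exactly equal to the baseline) are *excluded* rather than
  assigned.  For continuous RTs this is a measure-zero event, but fixtures
  and rounded data need a deterministic rule, and excluding avoids biasing
  either class.
- **Fake index self-inclusion.**  The fake index labels each neutral trial
  against a baseline whose mean includes that trial's own RT.  This is the
  literal reading of the definition and is the default; because
  self-inclusion shrinks deviations towards zero by a factor (n−1)/n, a
  leave-one-out variant is available (`label_trials(..., leave_one_out=True)`).
- **Split halves** are chronological within participant (runs, then blocks,
  then trials), pooled across blocks; the reliability correlation is
  Pearson on the per-participant half-means, then Spearman–Brown corrected
  (ρ = 2r/(1+r)).  A rank-based variant is available via `method="spearman"`.
- **Trial filtering.**  The published exclusion rules live in a supplement
  that is not reproduced here; the package implements configurable defaults:
  task-recorded wrong/no responses, RT < 150 ms (anticipations), and RT
  above the participant mean + 3 s.d. (lapses).  Outlier statistics are
  computed over response-valid, above-floor trials independent of previous
  outlier flags, which makes filtering idempotent.  Whether baselines should
  use filtered or unfiltered neutral trials is unstated in the source
  protocol; filtered is assumed throughout.

## Preprocessing

Voxel QC uses raw whole-run statistics (mean ≥ 80, s.d. ≤ 8, population
s.d.); thresholds of this kind are only meaningful on raw scanner units, so
QC always precedes detrending.  When several runs are fit jointly the
per-run retained sets are intersected.  Retained voxels are linearly
detrended and z-scored *per block* (mean 0, s.d. 1, population s.d.); a
per-run detrending scope would differ only when a run holds several blocks,
and the block scope matches the scope of the z-scoring.  Residuals whose
variance falls at numerical-noise level (≤ 1e−10 of the raw block s.d.)
are treated as degenerate and the voxel is dropped with a warning.

The feature of trial *t* is the single volume `iti_onset(t) + shift_tr`
(default 3 TRs = 5.25 s at TR 1.75 s): the first TR of the trial's
pre-stimulus fixation period, read after the hemodynamic shift.  The shift
is applied at extraction time, not by rolling the whole time course; the
two conventions differ only at block edges.  Volume indexing is 0-based
half-open everywhere.  Trials whose shifted index leaves the run are
excluded with a warning rather than erroring.

## Sparse Bayesian logistic regression (ARD)

Each weight carries an independent zero-mean Gaussian prior with its own
precision α<sub>i</sub>.  Inference alternates:

1. *Inner loop* — damped Newton iterations on the penalised logistic
   negative log posterior for fixed α (step halving on the objective,
   Cholesky solves on the Hessian H = XᵀRX + diag(α));
2. *Outer loop* — MacKay evidence fixed-point updates
   γ<sub>i</sub> = 1 − α<sub>i</sub>Σ<sub>ii</sub>,
   α<sub>i</sub> ← γ<sub>i</sub>/w<sub>i</sub>², with Σ = H⁻¹ at the MAP.

Features whose precision exceeds `prune_alpha` (default 1e8) are pruned to
exactly zero and leave the active set, so later iterations shrink.  The
intercept keeps a fixed weak prior (α₀ = 1e−6) and is never pruned.  The
outer loop stops when max |Δw| < 1e−6 or after 200 iterations; all of these
are configurable (`SLRHyper`) and the defaults were chosen for
reproducibility, not tuned to data.  The update scheme is validated against
an independent oracle: on tiny two-feature instances the fitted precisions
reach the maximum of a brute-force grid search over the
Laplace-approximated log evidence (`log_evidence`).

The iterative wrapper refits the base classifier on the feature subspace
excluding everything selected by earlier stages, for up to 10 stages,
stopping early when no features remain or a stage selects none (the first
stage is always kept so a fitted model can predict).  Test probabilities
combine multiplicatively and are renormalised,
P = Πp / (Πp + Π(1−p)), before thresholding at 0.5.  This is one reading of
"multiplied probabilities entering a logit"; a raw-product scheme is
available (`scheme="product"`), and the two agree on binary decisions when
thresholds are matched.

## Cross-validation and statistics

Folds are scanner runs (leave-one-run-out).  Class imbalance is handled by
downsampling the training majority class *without replacement* to the
minority size, independently `n_resamples` times (default 10); fold
accuracy is the mean over resamples, and the headline accuracy the mean
over folds.  Condition crossings reuse the same fold structure — train on
condition A in runs ≠ r, test on condition B in run r — so the four
crossing accuracies are comparable.  Per-direction accuracies pool all
held-out predictions, which makes the overall pooled accuracy exactly the
trial-count-weighted mean of the two directions.

Group inference is a two-sided one-sample t against the 50% chance level
(or a paired t for contrasts) with Cohen's d, and Benjamini–Hochberg FDR
over the declared family — all (ROI × condition) cells for the ROI
analysis, all regions for a search-ROI sweep.  The subsample bootstrap for
unequal group sizes draws n_sub participants from the larger group without
replacement, uses the difference of means as the default statistic
(configurable), and reports the two-sided p as the fraction of draws on the
far side of zero from the full-sample statistic with a +1 continuity
correction, p = (count+1)/(B+1).  When C(n, n_sub) ≤ B the test enumerates
all subsets exactly instead of sampling.

## ROI geometry

Sphere masks include a voxel iff the Euclidean distance from its centre
(mapped through the NIfTI affine, RAS+ mm) to the sphere centre is ≤ the
radius; the inclusive boundary is a package convention, the source
coordinates are taken verbatim (including the apparently mirrored
right-VTA x = 4.1).  Composite ROIs (mesolimbic = SN ∪ VTA ∪ VS) are
voxelwise unions on identical grids.  Atlas-derived regions are consumed as
externally supplied label volumes; synthetic parcellations stand in for
tests.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes —
and only that structure:

- **Design**: one block per run; a 21 s baseline (12 volumes at TR 1.75 s)
  followed by 56 gaming + 24 neutral trials in pseudo-random order;
  348-volume decoding runs; the pre/post training assessment variant is
  80 trials (40/40) over two 210-volume blocks.  Each trial is ≥ 2 TRs of
  fixation then a 2-TR stimulus epoch; the true inter-trial timing of the
  source protocol is only published schematically, so this timing is a
  stand-in chosen so a first pre-stimulus TR always exists.
- **Behaviour**: a latent biased/unbiased state follows a first-order
  Markov chain per trial (switch probability 0.2).  RTs are lognormal
  (median 600 ms, log-s.d. 0.15 ≈ 15% variability); in the biased state
  gaming approach RTs shift −150 ms and gaming avoidance +150 ms, and the
  opposite in the unbiased state; neutral RTs are state-independent.  The
  symmetric shift is required for the labelling rule to be able to recover
  the state (a one-sided shift caps label–state agreement near 75%); with
  these defaults agreement is ≈ 95%.  Lognormal RTs give realistic right
  skew and closed-form control of medians.
- **BOLD**: 200 voxels per run at baseline 100 with AR(1) noise (ϕ = 0.3,
  marginal s.d. 2), per-run linear drift (slope ± 0.02/volume), 5 dead
  voxels (level 50, raw mean < 80) and 5 noisy voxels (s.d. 12 > 8) to
  exercise QC.  Ten informative voxels carry the latent state as a ±1 s.d.
  (standardised effect 1.0) offset injected *directly into the volume the
  pipeline extracts as the feature*.  No hemodynamic forward model,
  physiological noise or head motion is simulated: the pipeline only reads
  the pre-stimulus volume, so injecting signal there isolates exactly what
  the decoder is asked to do.  Consequently, passing tests demonstrate that
  the pipeline recovers the structure it assumes — not that real BOLD data
  contain that structure.
- **Parcellations** are grown breadth-first from random seed voxels
  (166 blob-like regions by default), giving contiguous-ish parcels that
  partition the in-brain mask.

All generation is deterministic given the config seed (per-run generators
are seeded with (seed, participant, run, stream)).

## Closed-loop simulator

Trials run back to back on a per-TR probability stream (either precomputed
or decoded online from a feature stream).  "Above 95%" is implemented
strictly (P > 0.95).  The post-trigger stimulus/response epoch consumes 3
TRs by default (not printed in the source protocol; configurable).  The
stimulus draw at trigger time is gaming with probability 0.7 — the design
probability behind the empirically reported ~69% gaming rate is not
printed, so the empirical rate rounds to the default.  The threshold is
applied to the single-TR probability, not a running average.  The
`decabt-sim` CLI drives the simulator with a logit-AR(1) synthetic
probability stream whose defaults (ϕ = 0.5, s.d. 3.0, mean 0.5) produce
about one NG trial per ten-trial block, matching the training sessions the
simulator emulates.

## Problem sizes used in the shipped studies

The package's own studies (tests and the acceptance script) choose sizes
that make the statistics stable while keeping the suite quick to run:

- the chance-level control runs the full default-size pipeline (4 runs ×
  80 trials, 200 voxels) over 20 seeds with 3 balancing resamples — under
  permuted labels, resampling only averages noise, so extra resamples
  change the variance but not the mean;
- multi-seed property studies (accuracy monotone in signal effect,
  permutation-to-chance) use a scaled-down session (3 runs × 30 trials,
  50 voxels, 6 informative) with 20 seeds per grid point;
- the group t-test calibration study feeds 200 simulated signal-free
  datasets (21 participants × 112 held-out trials, binomial at 0.5) to the
  group-test machinery.

## Known limitations

- The generator's timing, noise and signal placement are stand-ins; no
  claim is made that decoding accuracies on synthetic data predict
  accuracies on scanner data.
- The linear mixed-effects condition × experiment analysis, whole-brain
  univariate GLMs, image realignment/normalisation and real-time scanner
  integration are out of scope.
- A single extreme RT in a small sample cannot exceed mean + 3 s.d. of
  statistics that include it (the deviation is bounded near (n−1)/√n
  s.d.); the default lapse filter therefore only bites in realistically
  sized sessions, and fixtures for it use a lower k.
- `search_roi_sweep` refits the entire pipeline per region; for atlases at
  realistic voxel counts this is the dominant cost and is embarrassingly
  parallel across regions, but no parallelism is built in.
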