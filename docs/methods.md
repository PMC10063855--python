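# Methods

`ahrfsig` implements a cross-cohort discovery pipeline for a whole-blood
gene-expression signature of severe acute hypoxemic respiratory failure
(AHRF) in children, where severity is a binary contrast (severe:
PaO2/FiO2 < 200 vs. mild: PaO2/FiO2 ≥ 200).  The pipeline is designed for
the p >> n regime of expression arrays: a few dozen to a few hundred
samples against thousands of genes, where univariate FDR screens are
underpowered and single train/test splits of sparse models are unstable.

## Synthetic twin cohorts

Because the motivating cohorts are microarray series with restricted-access
clinical annotation, the package carries a generator that emulates their
structure and provides planted ground truth for every downstream stage.

Expression model, per cohort, on the log2 scale:

- gene baseline `b_g ~ N(7, 1.5)` — typical log2 array intensity;
- gene signal of sample `s`: `b_g + s_g·δ·1[informative ∧ case] +
  β(batch(s)) + N(0, σ)`, with effect sign `s_g = ±1` drawn per informative
  gene (signatures contain both up- and down-regulated genes), effect size
  `δ` (log2 shift in cases), within-class SD `σ` (`noise_sd`, default 0.5),
  and one additive offset `β ~ N(0, batch_shift_sd)` per batch, constant
  across genes;
- probe value = gene signal + `N(0, 0.25·σ)`; per-gene probe counts default
  to 70% / 25% / 5% for 1 / 2 / 3 probes, giving the multi-probe redundancy
  the collapsing stage must handle.

Paired generation draws a single gene universe, plants `shared_informative`
genes in both cohorts and keeps the cohort-specific remainders disjoint, so
the truth-set intersection is exact.  Default sample counts mirror the
emulated studies: 26 mild / 70 severe (cohort A) and 65 mild / 96 severe
(cohort B).  Default scale is 5,000 genes with 50 informative and 30 shared;
tests and the acceptance script run at 250–1,500 genes, which preserves the
p >> n geometry while keeping a full run in seconds to minutes on one core.

What the generator does **not** emulate: probe-sequence (GC) effects,
gene–gene correlation beyond sibling probes, heavy-tailed noise, latent
(unrecorded) confounders, or platform differences between cohorts.  Passing
tests therefore demonstrate the pipeline's correctness and its behavior
under idealized planted signal — not expected performance on real arrays.

## Preprocessing

- **Quantile normalization** forces every sample onto the common quantile
  vector (row means of the per-sample sorted values); ties within a sample
  receive the mean of the quantile values their positions span.  This is the
  distribution-matching stand-in for platform-level background correction,
  which requires raw array files and probe sequences.
- **Probe collapsing** averages a gene's probes arithmetically on the log2
  scale; probes without a gene annotation are dropped (logged), a probe
  mapped to two genes is an error.
- **Batch correction** is gene-wise z-scoring within known batches —
  sufficient to remove the additive batch offsets the generator plants, and
  deliberately free of latent-factor estimation (batch labels are explicit
  inputs).  Genes constant within a batch are centered only and flagged in
  `meta["constant_genes"]`.
- **DE screen**: per-gene Welch t-test (unequal variances — the cohorts are
  imbalanced) with Benjamini–Hochberg step-up q-values; genes with zero
  variance in both classes get p = 1.  The screen is diagnostic context, not
  part of signature construction.

## Stability selection

For bootstrap iteration `t = 0..n_boot-1`, a stratified with-replacement
resample of the samples (class counts preserved) is drawn as a deterministic
function of `(seed, t)`.  Features are standardized **on the resample only**
(no leakage from out-of-draw samples), and an L1-penalized logistic
regression (case = 1, control = 0, fixed) is fit.  A gene is *selected* when
|coefficient| > 1e-8; its **stability score** is its selection frequency
over all `n_boot` iterations (skipped non-convergent iterations keep the
denominator at `n_boot`; a run fails if > 10% skip).  Genes are ranked by
descending score, ties by descending mean |coefficient| over selected
iterations, remaining ties lexicographically.  Sample columns are put in
sorted-ID order before any draw, so results are invariant to input column
order.

Parameters that matter:

- `n_boot = 100` and `score_threshold = 0.6`: the classic recipe for this
  analysis; scores are then multiples of 0.01.
- `penalty_strength` (sklearn's `C`, inverse regularization, dimensionless).
  The default **0.08** is calibrated for *thresholded* selection: on null
  cohorts (no signal, ~10^3 genes, ~50/class) no gene reaches the 0.6
  threshold, while strongly informative genes (effect ≥ 2σ) stay near 1.
  This calibration is the single-penalty analogue of controlling the
  expected number of null selections per draw.  For *ranking* runs that
  feed the cross-cohort intersection, a larger budget (`C ≈ 0.3`) is
  preferable: with several dozen informative genes, a tight budget makes
  them compete and weaker ones score near 0; the budget should be at least
  the expected signature size.  The pipeline config exposes this knob.
- liblinear penalizes the intercept; `intercept_scaling = 100` makes that
  penalty negligible (features are standardized, so the intercept is ~0
  anyway).  `random_state` is pinned: liblinear shuffles internally, and all
  run-level randomness must come from the bootstrap draws.

A known behavior worth stating: when a few genes are individually strong
enough to separate the classes, the L1 model needs only a subset per draw,
and sibling informative genes can legitimately score low.  The contract is
that noise genes never score high — not that every planted gene does.

## Cross-cohort signature

Genes common to both cohorts' top-k stability rankings (k = 1,500 by
default) form the candidate list, ordered by ascending rank sum, ties by
ascending min-rank, then lexicographically.  This ordering is a package
convention — any deterministic combined-rank order would do — and is
recorded in the output manifest.  Nested prefixes grow by 10 genes per step
(or at explicit user sizes, e.g. 12, 21, 48, 69, 92, 185), and each size is
scored on each cohort by leave-one-out cross-validation: an L2-logistic
model per fold, standardized on the training fold, scoring the held-out
sample; AUROC and AUPRC are computed once on the n pooled out-of-fold
scores.  L2 (not L1) in evaluation avoids re-running selection inside folds
and keeps all signature genes in play.

- AUROC: rank-sum (concordance) formulation, ties counting 1/2.
- AUPRC: step-wise average precision over distinct thresholds — no PR
  interpolation, which would bias the area upward, and prevalence-sensitive
  as intended for the imbalanced severe/mild contrast.
- 95% CIs: percentile bootstrap over (score, label) pairs resampled
  **within class** (2,000 resamples by default), preserving the prevalence
  that AUPRC depends on.
- Optimum: smallest size attaining the maximum of the chosen metric;
  per-cohort optima use each cohort's curve, the pipeline's bundle optimum
  maximizes the mean AUROC across the two cohorts.

Degenerate inputs: an empty top-k intersection yields an explicit empty
result with a warning (the pipeline then aborts with a clear message); a
class with a single sample makes LOOCV impossible and raises with advice to
use stratified k-fold instead.

## Enrichment and network stages

Over-representation analysis tests each gene set with the one-sided
hypergeometric upper tail, population = the analysis universe (default: all
genes on the collapsed matrix — the array content; overridable), successes
= |set ∩ universe|, draws = |signature|, followed by BH FDR across the sets
tested.  Sets are intersected with the universe first; emptied sets drop
out.  A Jaccard > 0.25 set-overlap edge list is exported for external
pathway-network viewers.

Interaction networks load from SIF (`A <tab> relation <tab> B [C ...]`,
multi-target lines expanding pairwise); duplicate/reversed edges collapse,
self-loops drop with a warning, shorter lines are errors.  Hub genes are
nodes with degree ≥ 10, the common PPI-network convention.

## Pipeline determinism

The single global seed derives one seed per stage via
`numpy.random.SeedSequence([seed, stage_index])`, so stages have
independent streams but the whole bundle is reproducible byte-for-byte from
the config (the manifest's wall-times are the only non-deterministic
output, and the `bundle_checksums` helper excludes it).  Logs are
line-delimited JSON without timestamps for the same reason.

## Design choices on genuinely open points

- Welch rather than pooled-variance t for the DE screen (imbalanced groups).
- Stratified bootstrap draws (preserve class mix in each resample).
- Percentile bootstrap CIs rather than analytic (exact under no
  distributional assumption; stratification keeps them valid under
  imbalance).
- Both signature batching modes (fixed step of 10 and explicit sizes) are
  provided; they answer different questions and neither is privileged.
- Missing expression values are a hard error, not silently imputed.

## Limitations

- The per-batch standardization assumes batch labels are known and batch
  effects are additive and gene-constant; latent confounding is out of scope.
- A single fixed L1 penalty is used per run (no penalty path); conclusions
  about threshold-crossing gene counts depend on it, which is why it is
  config-exposed and its two calibration regimes are documented above.
- LOOCV metrics at n ≈ 100 have substantial variance; the bootstrap CIs
  quantify score-resampling uncertainty only, not fold-assignment or
  cohort-sampling uncertainty.
- Synthetic fixtures prove correctness, determinism and planted-signal
  recovery — not clinical performance.
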