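# Methods

## The problem

Only a minority of advanced NSCLC patients benefit from immune checkpoint
inhibitors (ICIs), and the approved companion biomarkers (PD-L1 TPS, tumor
mutational burden) separate benefiters poorly.  This package implements a
transcriptome-based assessment: from a two-arm randomized cohort
(ICI vs chemotherapy) with bulk RNA-seq and progression-free survival
(PFS), it selects genes whose association with outcome is *predictive*
(treatment-modifying) rather than merely prognostic, trains a random
survival forest on the ICI-treated arm, and scores new tumors with a
single number — the model score in months — that stratifies patients into
expected-benefit groups.

## Model construction

Gene selection applies three criteria in sequence, on log(TPM + 1)
expression (natural log):

1. **Univariate screen.** Per gene, a univariate Cox proportional-hazards
   fit on the standardized log-expression against PFS; genes with
   p < 0.01 pass.  The OS p-value is reported alongside but not filtered
   on, and an optional HR < 1 filter is off by default — the model may
   legitimately contain "advanced" genes whose high expression marks poor
   prognosis.
2. **Treatment-interaction screen.** Each passing gene is dichotomized at
   the cohort median; the interaction between expression subgroup and
   treatment arm is tested by a likelihood-ratio test between
   Cox(arm + group + arm:group) and Cox(arm + group) (1 df).  Genes with
   interaction p < 0.05 pass.  A 2-df variant that compares against
   Cox(arm) alone, and a continuous-interaction variant, are exposed as
   options (`df_mode`, `continuous_interaction`).  Treatment HRs within
   the low/high-expression subgroups are reported per gene.
3. **Importance ranking.** A random survival forest is grown on the
   ICI-treated arm over all double-passers; genes are ranked by
   out-of-bag permutation importance (VIMP) and the top 50 are retained
   (all of them, with a warning, when fewer than 50 double-pass).  The
   final forest is retrained on the retained genes.

### The survival forest

Trees are grown on bootstrap samples; each node draws `mtry = ceil(sqrt(p))`
candidate genes and takes the split maximizing the absolute standardized
two-sample log-rank statistic, requiring at least `min_leaf_events = 3`
events per child.  Leaves store the Nelson-Aalen cumulative hazard of
their in-bag members on the grid of training event times.  Defaults:
1000 trees (the benchmark harness uses 200 so the full recovery benchmark
runs in minutes on one core).

**Score.**  The per-sample score is the ensemble restricted mean
event-free time,

    score = ∫₀^τ  S̄(t) dt,   S̄(t) = mean over trees of exp(−CHF_leaf(t)),

with τ the maximum training follow-up, integrated by the trapezoid rule
on the event-time grid.  It is measured in months and higher is better.
Plausible alternatives (ensemble mortality, survival probability at a
fixed horizon) are monotone transforms of closely related quantities;
RMST was chosen because it is on an interpretable months scale, needs no
horizon choice, and orients naturally ("above the threshold = low
risk").  `predict_mortality` exposes the mortality variant.

**Missing model genes.**  Genes absent from an input matrix are omitted:
a sample reaching a split on a missing gene descends into both children
with halved weight, and the leaf distribution is the weighted average.
This is deterministic, needs no retraining, and degrades smoothly; more
than 50% missing model genes is refused as unreliable.

**VIMP.**  Per gene and tree: the increase in out-of-bag error (1 −
Harrell's C of the tree's mortality prediction) after permuting that
gene's OOB values, averaged over trees.  Permuting a gene no tree splits
on gives exactly zero.

## Stratification

The headline grouping rule is the cohort-mean threshold: score >
mean(score) ⇒ "high" (ties at the mean go low).  For the frozen
reference cutoff, a maximally selected log-rank cutpoint on PFS is used:
the candidate grid is the unique score values, each side must hold at
least `minprop = 0.1` of the cohort (the conventional default of
maximally-selected-statistic tools), and ties break toward the smaller
cutoff.  The log-rank p at the selected cutpoint is reported with an
explicit selection-biased annotation and no multiplicity correction,
because its downstream use is threshold transfer, not inference.

## Single-sample prediction (reference database)

A frozen bundle holds the ICI-treated reference cohort, the trained
forest, the reference score table, the PFS-optimal cutoff, and per-gene
reference moments.  Incoming samples are mapped onto the reference —
never the other way round, since the frozen cutoff is only meaningful if
reference scores cannot drift — then scored and classified (score >
cutoff ⇒ predicted benefit).

Batch adjustment is an empirical-Bayes location/scale correction on the
log scale with two levels:

* **Global shift.**  The batch-mean deviation from the reference has a
  known null scale: sqrt(v0/m), with v0 the between-sample variance of
  the mean deviation inside the reference itself and m the batch size.
  A shift within 3 null-SDs is indistinguishable from sampling/biology
  and is left alone; beyond 6 null-SDs it is an unambiguous technical
  shift and is removed in full; between 3 and 6 the correction ramps
  linearly.  This keeps the single-sample round trip essentially the
  identity for in-distribution samples (re-scoring a reference sample
  alone reproduces its stored score to well under half a month) while a
  genuine platform shift — which sits tens of null-SDs out — is removed
  exactly.
* **Per-gene effects.**  Gene-level location effects get a normal prior
  moment-matched across genes with the sampling-noise contribution
  subtracted; a batch whose shift is constant across genes therefore
  yields a degenerate prior (τ² = 0) and is corrected exactly, and a
  single sample never receives per-gene corrections, because with m = 1
  batch and biology are confounded.  Scale effects are shrunk on the
  log-variance-ratio scale and skipped for batches of fewer than three
  samples.

## Evaluation suite

* **Time-dependent AUC**: cumulative-case / dynamic-control AUC with
  inverse-probability-of-censoring weights from the Kaplan-Meier
  estimate of the censoring distribution.  Chosen over nearest-neighbor
  smoothing because it is unbiased under independent censoring and
  reduces *exactly* to the Mann-Whitney AUC without censoring, which
  makes it testable against a closed form.  Scores are on the benefit
  scale (risk = −score); tied risks get half credit.
* **AUC comparison**: paired bootstrap (default B = 1000) over samples,
  two-sided normal p on ΔAUC/SE.  A bootstrap was preferred to an
  analytic iid-representation test because it is simple to validate on
  small data and seed-controlled.
* **Marker combinations**: Cox fits on subsets of {model score, TPS,
  TMB} (complete-case); the combined score is the fitted linear
  predictor.
* **Decision curves**: net benefit TP/n − (FP/n)·pt/(1−pt) with IPCW
  handling of censoring before the horizon; uncensored data reduce to
  the plain 2×2 formula.
* **Response tables**: per-group BOR counts with percentages recomputed
  from counts (3 significant figures); ORR = CR + PR over group n,
  intention-to-treat style with NE in the denominator (configurable).
* **Durable clinical benefit**: CR/PR, or SD lasting strictly more than
  6 months; PD or SD ≤ 6 months is NDB; NE propagates.

## Core statistics

Cox regression maximizes the Efron-tie partial likelihood by
Newton-Raphson with step-halving (gradient ∞-norm < 1e−8, ≤ 50 steps);
Efron handling matches the default of the R survival ecosystem and is
more accurate than Breslow under ties.  Monotone likelihood (perfect
separation) caps |β| at 15 and clears the convergence flag.  Wald 95%
CIs use exp(β ± 1.96·SE).  The score test at β = 0 for a binary
covariate reproduces the two-group log-rank chi-square, which the tests
assert to 1e−6.  Kaplan-Meier uses Greenwood standard errors; the
log-rank test is the multi-group Mantel-Cox statistic;
Benjamini-Hochberg is the standard step-up with monotonicity capping.

## The synthetic-trial generator

`simulate_cohort` emulates a second-line randomized NSCLC trial:
~600 patients randomized 1:1, exponential PFS with baseline hazard
0.2/month (median ≈ 3.5 months on chemotherapy), ~30% uniform
independent censoring (calibrated by bisection against the realized
event times), OS = PFS plus an independent exponential post-progression
tail (hazard 0.08/month) — which makes the PFS signal stronger than the
OS signal, as observed for ICI benefit.  BOR is drawn with response
probability increasing in predicted benefit; TPS and TMB are weakly
correlated noisy markers.

Expression is Gaussian on the log-TPM scale with per-gene location
Uniform(1, 5) and scale Uniform(0.4, 1.2).  Effect genes are
*co-expressed modules*: the 30 predictive genes load on a latent
"ICI-benefit program" and the 50 prognostic-only genes on a "prognosis
program" (within-block correlation ρ = 0.8), and the stated effect sizes
(interaction log-HR −0.8/SD, prognostic log-HR −0.8/SD) act on the
standardized program scores.  This matters: 80 *independent* genes each
at |β| = 0.8/SD would give the latent log-hazard an SD above 7 — event
times spanning twelve orders of magnitude — while attenuating every
marginal per-gene association below detectability; real predictive
signatures are co-expressed programs, not 80 independent hazards.  The
implied marginal per-gene log-HR, β·sqrt(ρ + (1−ρ)/k) for a k-gene
block, is recorded in the ground truth, and a single-gene block reduces
exactly to "β per SD of that gene", so single-gene calibration checks
hold as written.

What the generator does **not** emulate: RNA-seq count overdispersion
and library-size artifacts (expression is Gaussian in log space),
non-proportional hazards, informative censoring, competing risks, and
covariate-dependent arm assignment.  Passing benchmarks therefore show
that the pipeline recovers treatment-interaction structure under clean
randomized-trial assumptions — not that it is robust to real-data
violations of them.

## Benchmark sizes and determinism

The standard recovery benchmark is 10 simulated cohorts (600 × 2000,
30 predictive / 50 prognostic genes) through the full pipeline with
200-tree forests; interaction operating characteristics use 500 null
replicates at n = 400 and 20 powered replicates at n = 600.  All
randomness flows from explicit seeds (`numpy` PCG64, per-tree seeds
spawned from a root `SeedSequence`), so identically-seeded runs produce
byte-identical model archives and score tables.

## Known limitations

* Gene lists, score values and reference cutoffs fitted on the original
  controlled-access clinical cohorts are not reproducible here.  The
  package reproduces the *procedure* and verifies it on synthetic trials
  with known ground truth.
* The interaction screen inherits the mild anti-conservatism of testing
  a dichotomized covariate under a continuous true effect with
  arm-dependent frailty; the benchmark quantifies the resulting
  prognostic-gene contamination of the final gene set rather than
  pretending it is zero.
* Forest scores are step functions of expression; monotone response to a
  favorable gene holds for shallow trees but is not guaranteed pointwise
  for deep bootstrap ensembles.
* The batch-adjustment detection ramp (3-6 null-SDs) is a design choice
  trading single-sample fidelity against sensitivity to small real batch
  shifts; shifts inside the null band are deliberately left uncorrected.
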