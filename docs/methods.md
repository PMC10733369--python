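# Methods

`das28ml` re-implements, as a tested pipeline, a machine-learning
re-evaluation of the DAS28-CRP composite score for psoriatic arthritis
(PsA): unsupervised structure detection in the four score components,
density-guided augmentation of small patient subgroups, and supervised
distillation of the most informative of the 58 individual score items.
Because the kind of clinic data this analysis targets is confidential, the
package ships a synthetic cohort generator that reproduces the statistical
structure the analysis assumes; every procedure is exercised and tested on
generated cohorts.

## The score and its decomposition

DAS28-CRP = 0.56·√TJC28 + 0.28·√SJC28 + 0.36·ln(CRP+1) + 0.014·GH + 0.96,
with tender/swollen joint counts over 28 predefined joints (shoulders,
elbows, wrists, MCP 1–5, PIP 1–5, knees, bilaterally), CRP in mg/L and the
patient global-health VAS (GH) in mm on a 0–100 scale.  Activity stages:
remission < 2.6, low < 3.2, moderate ≤ 5.1, high > 5.1; boundaries are
inclusive upward except 5.1, which is moderate.  The weights and cut-offs
are the standard published constants; both are overridable
(`ScoreWeights`, `StageThresholds`).  The GH scale is taken as 0–100 mm,
the convention consistent with the 0.014 coefficient.

Two feature representations are used: the d = 4 composite components
(tjc28, sjc28, crp, gh) and the d = 58 item-level expansion (28 tender
flags, 28 swollen flags, CRP, GH) in a fixed documented order.

## Synthetic cohort generator

Each patient draws a latent activity class from a configurable mixture
(default 59/16/5 remission/low/moderate over n = 80, the composition of the
cohort being emulated), then the observables conditional on the class:

* per-joint tenderness/swelling as independent Bernoulli flags
  (`base_tender_prob`, `base_swollen_prob` per class);
* CRP ~ lognormal(μ, σ) and GH ~ 100·Beta(α, β) per class;
* one *signal joint* (default: tenderness of the right index-finger MCP
  joint) with its own remission baseline prevalence (`signal_base_prob`,
  default 0.10 — a commonly affected joint) whose odds are multiplied by
  `signal_odds_ratio` (default 8) in the non-remission classes.  Applying
  the multiplier to the remission baseline makes the configured value
  exactly the active-vs-remission odds ratio identifiable from the data.

The recorded stage is never stored: it is always re-derived from the
generated components through the scoring module, which guarantees internal
consistency with the score formula.  The default component distributions
were calibrated once so that the re-derived stages reproduce the configured
mixture within ±5 percentage points at n = 1000; the calibration places the
staging signal in the joint flags while the CRP and GH marginals overlap
strongly across classes, mirroring a cohort in which activity subgroups
differ significantly only in joint counts.  A seeded regression test pins
this calibration.

Three outlier patients (two swollen-dominant, one tender-dominant; ≥ 6
affected joints of the dominant symptom, ≤ 1 of the other) can be appended,
emulating atypical presentations the structure analysis should flag.  They
model real patients, so they are not marked synthetic.

What the generator does *not* model: joint–joint correlation beyond the
planted signal (real arthritis patterns are symmetric and oligoarticular),
demographics, longitudinal visits, and measurement error in CRP/GH.
Passing tests therefore show that the pipeline recovers structure it is
designed to recover under idealized independence assumptions — not that it
would behave identically on clinic data.

## Unsupervised structure

**PCA.** Classical correlation-matrix PCA of the z-standardized d = 4
components; the contribution of variable j to component k is
100·loading²ⱼₖ.  Constant columns are rejected.

**ESOM.** The [0,100]-scaled components are projected onto an emergent
self-organizing map: 50 × 80 = 4,000 neurons on a toroidal grid, trained
online for 20 epochs with the learning rate decaying linearly 0.3 → 0.05
and a Gaussian neighborhood whose radius decays linearly from
max(rows, cols)/2 to 1.  Online (per-sample) updates were chosen over batch
updates to match the emergent-map training practice; all distances are
Euclidean.  Training is deterministic given the seed.

**Structure matrices.** U-matrix: per-neuron mean distance to the
(wrap-deduplicated) Moore 8-neighborhood prototypes.  P-matrix: number of
data points within radius r of each prototype, boundary inclusive; r
defaults to the Pareto radius, the 20th percentile of the nonzero pairwise
data distances.  U*-matrix: u*(i) = u(i)·f(i) with
f(i) = (p(i) − max P)/(mean P − max P), so f = 1 at mean density, 0 at
maximum density, > 1 in sparse regions.  The published toolchain states the
idea of the U*-combination but not this normalization; the linear factor is
this package's documented choice, and uniform density degenerates to
u* = u with a warning.

**Clusters and outliers.** The published analyses delineate clusters
visually on a topographic rendering; the automated surrogate here is:
threshold the U* heights at the median (configurable percentile) of the
occupied neurons, flood-fill 8-connected below-threshold basins on the
torus, and let patients inherit their BMU's basin.  Above-threshold BMUs
join the nearest below-threshold basin by toroidal grid distance — unless
they are farther than an isolation radius (default max(rows, cols)/6) from
*every* below-threshold neuron, in which case they form their own basins.
The isolation rule captures the "volcanic crater" reading of the map: a
patient pair far from all valleys is an outlier group, not a member of the
nearest valley.  Basins with fewer than `min_cluster_size` (default 3)
patients are reported as outlier groups, mirroring the one- and two-member
outlier "clusters" such maps produce.  Cluster-vs-stage consistency is
tested by Pearson χ² on the contingency table restricted to clusters with
at least 5 members.

## Density-guided augmentation

Small clusters cannot be analyzed supervised, and resampling with
replacement would duplicate cases across training and validation splits.
Instead, candidates are generated around uniformly drawn seed members of a
cluster (Gaussian perturbation, σ defaulting to half the Pareto radius of
the scaled data, clipped to the observed ranges) and accepted with
probability p(BMU)/max(P) — the P-matrix read as an existence probability,
normalized by its maximum to make it a proper probability — and only if the
candidate's BMU lies in the seed cluster's basin.  Every cluster and
outlier group is raised to the size of the largest cluster; generated rows
are flagged `is_synthetic` with their seed patient recorded.  Generation
operates in the scaled d = 4 component space: a Gaussian perturbation of a
binary joint flag would be meaningless.  An acceptance-sampling failure
(bounded by `max_attempts_per_case`) raises an error reporting the
acceptance rate rather than looping forever.

## Supervised distillation

The binary target is remission vs active (low + moderate merged — the
moderate group is too small to model separately).  The discipline:

1. **Holdout.** A class-proportional third of the cases is reserved for
   validation and never touched by selection or tuning.
2. **Tuning.** Random forests (chosen for tabular data mixing binary flags
   and interval variables without rescaling) are tuned by seeded uniform
   random search — 50 draws by default (configurable; reduced budgets are
   used in the shipped experiments, see below) over tree count {50, 100,
   200}, depth {∞, 2, 4, 8}, features per split {√d, 25%, 50%} and minimum
   leaf size {1, 2, 5} — scored by stratified 5-fold balanced accuracy.
   Random search replaces heavier Bayesian optimization; at equal budgets
   the difference on a 4-parameter grid is marginal.
3. **Importance.** Permutation importance = mean drop in balanced accuracy
   over 50 column shuffles, computed on the training/test pool (not the
   holdout).
4. **cABC.** The computed ABC analysis sorts the (0-clipped) importances
   descending and builds the ABC curve (cumulative item fraction vs
   cumulative importance fraction).  The A|B boundary is the curve point
   closest to the ideal (0, 1); the B|C boundary is the first point where
   the per-item chord slope falls below parity (tolerance 1e-12; strict
   inequality so that a uniform profile yields the expected diagonal
   split).  Boundaries are ordered by min/max so A ≼ B ≼ C always holds.
   Set A is the "important few" retained as the reduced feature set.
5. **Nested Monte-Carlo CV.** 4 outer × 25 inner = 100 runs; each run
   resamples a stratified 80% of the pool, re-tunes, retrains, and scores
   balanced accuracy and ROC-AUC on a fresh stratified 80% subsample of the
   validation third.  Medians and 2.5th/97.5th percentiles are reported.
   The "4 × 25" factorization is recorded as 4 outer resampling blocks of
   25 repeats.
6. **Overfitting control.** The same evaluation with each training feature
   column independently permuted; an honest protocol scores at the 50%
   guessing level with the 95% interval containing 0.5.

Cluster attribution repeats the same machinery one-vs-rest per (equalized)
cluster on the d = 4 components, reporting each cluster's most important
component and its single-feature classification performance.  One-vs-rest
tasks with fewer than 6 members on either side are skipped with a warning —
below that, a stratified holdout plus inner folds is not constructible.

## Association statistics

Quartile rescaling uses type-7 (linear interpolation) quantiles with ties
sharing the lower label; χ² is plain Pearson without continuity correction
(matching the convention of the analyses being reproduced); Kruskal–Wallis
uses the tie-corrected rank statistic, returning H = 0 with a warning on
degenerate all-equal input.

## Problem sizes and numerical choices

The shipped experiments and tests use: synthetic cohorts of n = 200 for
supervised analyses (more stable class counts than the emulated n = 80 at
the same mixture); ESOM grids of 20 × 30 for structure tests (the 50 × 80
default is exercised for shape contracts); tuning budgets of 2–5 random
draws in tests and in `scripts/acceptance.py` (the full 50-draw default
remains the library default).  These sizes were chosen to keep the full
suite reproducible on a single CPU while leaving every protocol element —
holdout discipline, re-tuning per run, 50-shuffle importance, 100-run
nested CV — intact.

Ties in BMU assignment break toward the lowest row-major index; constant
columns scale to 0 in the [0,100] rescaling; negative permutation
importances are clipped to zero before cABC (which requires positive data);
seeds propagate explicitly to every stochastic step, and derived seeds stay
below 2³¹.

## Known limitations

* The basin extraction is a surrogate for visual delineation; its
  percentile threshold and isolation radius are heuristics that may split
  or merge basins on data without clear valley structure (a unimodal
  continuum yields a single cluster, correctly but uninformatively).
* The generator's independence assumptions make the planted signal easier
  to recover than a correlated real-world symptom would be.
* Reported performance distributions on synthetic cohorts are not
  comparable to any real cohort's values; only the protocol arithmetic and
  control behavior (guessing-level permuted performance) transfer.
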