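# Methods

This note documents the statistical model behind each stage of the screen,
the defaults and why they were chosen, what the synthetic cohorts do and do
not emulate, and the numerical conventions.

## Statistical primitives

All per-gene machinery lives in `bonescreen.stats_core` and is implemented
from first principles (scipy supplies only distribution CDFs, midranks and
the Shapiro–Wilk statistic), so every statistic can be cross-checked against
independent references — the test suite compares them to explicit
enumeration oracles and to scipy/lifelines.

**Two-group test selection.** The screen follows the convention of gating on
normality per gene: Shapiro–Wilk is run on each arm and the *t* test is used
only when both arms have n ≥ 3, non-constant values and Shapiro–Wilk
p ≥ `alpha_norm` (default 0.05); otherwise Mann–Whitney. The *t* test
defaults to the Welch form (robust to unequal arm variances; the pooled
Student form is available via `equal_var=True` for strict fidelity to a
classic two-sample *t*). Which normality test and threshold to use was a
genuinely open choice; Shapiro–Wilk at 0.05 per group is the common default
in clinical statistics software.

**Mann–Whitney U.** Midrank tie handling; two-sided p by normal
approximation with tie-corrected variance and no continuity correction. For
n₁+n₂ ≤ 10 the p-value is exact: all C(n₁+n₂, n₁) group labelings of the
pooled midranks are enumerated and p = 2·min(P(U ≤ u), P(U ≥ u)), capped
at 1.

**Spearman.** ρ is the Pearson correlation of midrank-transformed inputs;
two-sided p from t = ρ√((n−2)/(1−ρ²)) on n−2 df, with p = 0 at |ρ| = 1 and
an exact permutation mode for n ≤ 8. Constant ranks raise an
undefined-correlation error rather than returning NaN.

**Survival.** Kaplan–Meier product-limit with the standard convention that
events precede censorings at tied times (both count as at risk there);
censored-only times reduce the risk set without a survival step. The
two-group log-rank test uses the 1-df chi-square form
(O₁−E₁)²/ΣV with hypergeometric variance per event time; no events or zero
variance yields statistic 0, p = 1. Arm-level risk direction in the survival
screen compares restricted mean survival times integrated to the shorter
arm's last observed time (avoiding step-function extrapolation); the exact
tie goes to "high expression worse", which is immaterial in continuous data.

## Differential-expression cascade

Significance is raw p < α = 0.05 with **no multiple-testing correction by
default**: the screen's published-style stage counts only make sense under
raw thresholds (an FDR step would empty the cascade at these effect sizes
and sample sizes). A Benjamini–Hochberg switch (`bh=True`, via statsmodels)
exists for users who want it.

Direction is the sign of the difference of arm means of log2 expression,
also for Mann–Whitney-tested genes — a single consistent effect sign across
test branches. Genes constant in both arms are skipped and logged. The
cross-cohort step requires significance in both cohorts *and* identical
direction; genes present in only one cohort are dropped with a logged count.

Bone specificity is a set difference: validated bone-contrast candidates
minus the union of other-site-metastasis DEGs from both cohorts. Using the
union (rather than one cohort's list) is the conservative reading; any gene
that is genuinely pan-metastatic is an other-site DEG in both cohorts at
these power levels, so the choice does not affect planted-signal recovery.

The adaptive contrast requires a gene to separate bone lesions from primary
tumours *and* from other-site metastases, significant in both contrasts with
concordant direction. Each adaptive record carries the bone-vs-primary
effect and the larger (worst-case) of the two contrast p-values.

## Survival screen

Expression is dichotomised at the per-gene median with ties assigned to the
low arm — with distinct values the low arm gets ⌈n/2⌉ samples. The
dichotomisation rule was an open choice; the median split is the most common
convention for expression biomarkers and a top-vs-bottom-quartile mode is
available (`cut="quartile"`). The endpoint is bone-metastasis-free survival:
event = occurrence of bone metastasis; samples whose distant metastasis is
at another site are **censored** at their follow-up time (no competing-risk
modelling — out of scope, as is Cox regression). No multiple-testing
correction across the screened candidates, matching the raw-threshold
design.

## Axis scoring

The five marker panels (homing 8 genes, immune escape 7, angiogenesis 8,
osteoclastic 10, osteoblastic 9) are built in and exchangeable via GMT
files. Matching is by uppercased symbol with a small synonym table
(RANKL/TNFSF11, OPG/TNFRSF11B, CXCR7/ACKR3, CTGF/CCN2). The axis score sums
**all** available marker ρ values, significant or not (a significant-only
mode exists but is off by default: the summed-coefficient construction is
defined on the full panel). Markers absent from a cohort reduce the marker
count rather than contributing zero — zero-filling would shrink sums toward
0 asymmetrically across panels. A gene is never correlated with itself when
it overlaps its own panel.

Cross-axis comparison normalises |score| by the number of markers actually
used, because panels differ in size; within-panel rankings use the raw sum.
Ties resolve to the fixed axis order (homing, immune escape, angiogenesis,
osteoclastic, osteoblastic). Correlations are computed over all samples of
the supplied matrix; a sample mask can be applied upstream via
`ExpressionMatrix.subset_samples`.

## Synthetic cohorts

`bonescreen.synthetic_data` generates log2 expression as Gaussian noise
(default sd 1.0 around baseline 8.0 — typical magnitudes for normalised
log2 array/RNA-seq data) with planted structure:

* **Class shifts.** Fixed NONE/OTHER/BONE counts (defaults 100/30/20, a
  150-tumour cohort with a realistic bone-metastasis fraction);
  BONE_SPECIFIC genes shift only BONE samples, PAN_METASTATIC genes shift
  BONE and OTHER.
* **Latent axis factors.** One standard-normal factor per axis per sample;
  markers load on their own axis with `marker_loading` (default 1.0) and
  AXIS_LINKED genes with their own loading λ. The induced Pearson
  correlation is λg·λm/√((λg²+σ²)(λm²+σ²)) and the Spearman target follows
  from the bivariate-normal identity ρs = (6/π)·arcsin(ρ/2); the generator
  exposes this as `closed_form_spearman` and tests verify the realised
  correlations against it.
* **Survival.** A latent bone-metastasis time per sample, exponential with
  hazard h₀·exp(Σ βg·zg) over SURVIVAL_LINKED genes (z = standardised
  expression, h₀ = 0.02/month giving a ~35-month median under the null),
  under Uniform(0, τ) administrative censoring with τ solved by bisection so
  the expected censored fraction equals `censor_rate` (default 0.4, i.e.
  ~60% events).

Two class-assignment modes exist because the bone-specific endpoint masks
events of non-BONE samples. The default fixes class counts and lets only
BONE samples experience the event — right for DEG-stage studies. With
`met_from_hazard=True` the realised event defines the class (event → BONE;
non-events split NONE/OTHER in the configured proportion), which is the only
coherent way to make an expression-linked hazard visible to the median-split
screen; survival-calibration and power studies use this mode. A per-sd
hazard coefficient of ln(3)/(2√(2/π)) ≈ 0.688 yields a median-split hazard
ratio of 3 (the mean |z| within each half of a standard normal is √(2/π)).

What the generator does **not** emulate: count-level noise
(negative-binomial overdispersion), platform/batch effects, RNA-seq vs
array scale differences, correlated background genes, informative
censoring, and competing-risk structure. Passing the recovery tests
demonstrates that the screening logic is correct and calibrated under its
own assumptions, not that real cohorts satisfy those assumptions.

## Numerical conventions and problem sizes

* Expression TSVs are written with 17 significant digits; read/write round
  trips preserve values to < 1e-12.
* All simulations flow from a single integer seed through
  `numpy.random.SeedSequence` spawning (separate streams for factors,
  noise, survival and class assignment), so reruns are bit-identical.
* The verification script and acceptance tests use 2000-gene null
  calibrations (two arms of 40; survival n = 200), 20-seed cascade
  recoveries (1020 genes × 150 samples per cohort), 50-replicate survival
  power runs and 20-seed axis recoveries (25 genes × 300 samples) — sizes
  at which binomial bands of ±3 SD around nominal rates are tight enough to
  be informative while the whole suite completes in a few minutes on one
  CPU.

## Known limitations

* Gene identity is the uppercased symbol string; beyond the four built-in
  synonym pairs, no alias/ID mapping is attempted, so cross-platform symbol
  drift silently reduces the usable marker count (it is logged and recorded
  per record in `missing_markers`).
* Expression is assumed pre-normalised and log2-scale; the pipeline
  performs no normalisation and analyses cohorts separately.
* The survival filter is univariate log-rank only — no covariate
  adjustment, no proportional-hazards model, no competing-risk estimator.
* Raw p < 0.05 thresholds imply a known false-positive load at every stage;
  the cascade relies on cross-cohort concordance, not per-stage error
  control, to suppress it.
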