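# Methods

## Measurement model

A sample's relative telomere length is the ratio T/S of two qPCR-derived
quantities: telomere repeat signal (T) and a single-copy gene signal
(S, human beta-globin), each measured in its own reaction against a
shared reference-DNA dilution series. The model chain is:

1. **Standard curve.** Per run and per target, ordinary least squares of
   Cq on log10(input ng) over the dilution series
   (26, 8.75, 2.9, 0.97, 0.324, 0.108 ng, each in triplicate).
   Efficiency `E = 10^(−1/slope) − 1`; a warning is emitted outside
   80–110%, and a non-negative slope is a hard error (no amplification).
2. **Interpolation.** `q = 10^((Cq − intercept)/slope)`; values outside
   the fitted standard range warn as extrapolations.
3. **Triplicate QC.** Dixon's Q test with the two-tailed n = 3 critical
   values (0.941 / 0.970 / 0.994 at α = 0.10 / 0.05 / 0.01; default
   α = 0.05, configurable because the source protocol names the test but
   not the level). The *decision* is made on the Cq scale: Cq is
   log-concentration, so a gross displacement is the same size anywhere
   on the plate, whereas on the concentration scale a failed (late-Cq)
   well collapses toward zero and the Q gap ratio saturates at the ratio
   of the two good wells — under ordinary triplicate noise roughly 40%
   of such dropouts would pass a concentration-scale test. Averaging of
   the retained wells is arithmetic on the concentration scale ("average
   concentrations after the Q test"), not mean-Cq-then-interpolate; the
   two differ under noise.
4. **Batch adjustment.** Eight control DNAs ride on every run. A
   reference panel is the per-control mean over the first
   `reference_run_count` runs (default 10; fewer allowed with a
   warning). Per run, each control contributes `reference/observed`; the
   run factor is the mean of the eight, and every raw T/S on the run is
   multiplied by it. The orientation means a run reading high is scaled
   down. The correction is *relative to the reference batch*: with a
   drift-free reference it cancels any planted run multiplier exactly
   (verified to 1e-9 in the noiseless limit); with a drifting reference
   batch all runs are normalized onto that batch's mean level, which is
   what removes between-run variance from the study.
5. **Replicates.** Each sample is measured in two runs. Because the two
   measurements carry different run factors, adjustment precedes the
   concordance check. Duplicates agreeing within 7% of their mean report
   their mean; otherwise a third run is consulted and the closest pair
   (ties toward the pair containing the earliest run) reports its mean.
   The 7% denominator is the mean of the two values (symmetric);
   alternatives (first value, min) are a config choice away.
6. **Assay precision.** Mean across controls of per-control SD/mean of
   the adjusted history, in percent.

## Cohort statistics

Timepoint windows: T1 up to 20^0/7 weeks, T2 20^1/7–36^6/7, T3 from
37^0/7 through 9 weeks postpartum. A draw at exactly 20^0/7 — a day the
window prose leaves unassigned — goes to T1 with a warning. Postpartum
draws are placed at delivery GA plus postpartum days on a common
pseudo-GA axis capped at 50 weeks; GA is always serialized as separate
integer week and day columns to avoid decimal ambiguity.

Paired within-person changes (pairs 1–2, 2–3, 1–3; later minus earlier)
use the Wilcoxon signed-rank test: zeros dropped, mid-ranks for ties,
exact null (dynamic programming over all sign assignments, two-sided
p = P(|W − μ| ≥ |w − μ|), valid because the null is symmetric even under
ties) for up to 25 informative pairs, tie-corrected normal approximation
beyond. No multiplicity correction across the three pairs by default
(matching how such pilot analyses are reported); Holm adjustment is
available downstream of the returned p-values. The delivery-mode
contrast uses the rank-sum test, exact (subset-sum DP over the label
shuffle) for tie-free pooled samples up to n = 20, otherwise the
tie-corrected normal approximation without continuity correction — the
latter so that Kruskal–Wallis with k = 2 gives the identical p
(H = z²), keeping the screen's type dispatch decision-consistent. The
age-adjusted model is OLS of log T/S on a cesarean indicator plus age,
reporting the indicator coefficient with its 95% CI.

Descriptive tables report n (%) with per-variable denominators excluding
missing values, and percentages round half-up to one decimal, matching
printed-table conventions; continuous variables report mean ± SD.

## Stress screen

Feature types are declared or inferred (≤2 observed levels → binary;
non-numeric or integer-coded with ≤6 levels → categorical; else
numeric — a 7-level scale is numeric by this rule, so scales meant as
categories should be declared). Dispatch: Kendall tau-b / Kruskal–Wallis
/ two-sided rank-sum; constant features degenerate to p = 1 rather than
erroring so a screen over 79 features never aborts. Imputation is
per-feature median (binary medians snap to an observed level) or mode
(ties to the lowest code). The network uses Spearman correlations
throughout; coordinates come from t-SNE on the rows of the absolute
correlation matrix with perplexity `min(15, (n_features − 1)/3)`, a
fixed seed, random initialization, and 500 iterations — all recorded in
the graph metadata so identical inputs give identical layouts. Edges:
|r| ≥ 0.3 thin, |r| ≥ 0.7 thick; nodes: size −log10(p), colored
orange/blue by direction when p < 0.1, bold at p < 0.05.

The multivariate check is an RBF-kernel support vector regression with
library-default regularization on standardized, imputed features, scored
by out-of-fold R² (and MSE) under shuffled 10-fold cross-validation.
Significance is defined against a permutation null (outcome permuted
≥100 times, same folds): the observed R² must exceed the null's 95th
percentile. Hyperparameters are deliberately not searched; the question
is whether the default-profile model carries signal at all.

## Synthetic generator

`SimConfig` defines the study conditions; defaults emulate a 46-subject
nulliparous cohort: per-target efficiencies 0.932/0.940, baseline T/S
1.15 with cross-sectional SD 0.26, within-pregnancy drift −0.07 (applied
over a progress scale running 0 at ~12 weeks to 1 at delivery), cesarean
rate 0.391 with a −0.18 log effect on postpartum draws, 79 survey
features, and draw-presence rates giving ≈41/39/35 draws per timepoint.

Choices the generator makes where the emulated study is silent:

- **Variance split.** The cross-sectional SD (0.26) is split into a
  between-person component and a visit-level component
  (`visit_noise_sd`, default 0.18): within-person differences then
  scatter with SD √2·0.18 ≈ 0.25, matching the reported paired-change
  SDs (0.26/0.29/0.21), while a single timepoint still shows SD ≈ 0.26.
  Without the visit term, trajectories are deterministic and paired
  tests are degenerately overpowered.
- **Cq noise.** `cq_noise_sd` default 0.04 cycles, set analytically: a
  well's relative concentration error is ln10·σ/|slope| ≈ 2.6%, a
  triplicate mean ≈ 1.5%, a T/S ratio √2 of that ≈ 2.2%, which is the
  control-CV scale the assay is meant to show. Measured end to end the
  pipeline CV lands at ≈ 1.7–2.3% across seeds.
- **Batch drift.** Per-run, per-*target* log-normal quantity multipliers
  (SD `batch_drift_sds`, default 0.04, a free parameter). A single
  multiplier shared by T and S would cancel in the ratio and make batch
  adjustment vacuous; independent per-target factors give the net T/S
  drift (d_T/d_S) that the control panel must remove. The magnitude is
  unstated in the emulated protocol.
- **Outliers.** With probability `outlier_rate` (default 0.01) one well
  of a triplicate is displaced by 5–10 cycles, sign random, and flagged
  in the ground truth.
- **Sleep effect.** One designated numeric feature is the latent
  sleep-quality score; it shifts log baseline T/S by `sleep_effect` per
  unit (default 0.08 — a modest planted association that does not
  materially inflate the emulated cross-sectional SD). The remaining
  features load on 8 latent factors (primary loading 0.75, assignments
  fixed per seed), giving the correlated block structure the network
  view needs; types cycle numeric/categorical(4 levels)/binary, and
  cells go missing completely at random at `missing_rate` (default
  0.05).
- **Measurement plan.** Every sample is simulated in three waves of runs
  (default 20 samples per run, shuffled per wave); the pipeline uses the
  third wave only where the first two replicates are discordant,
  mirroring measure-twice-resolve-third practice while keeping the
  simulation single-pass.

All randomness derives from `SimConfig.seed` through named
`SeedSequence` streams; identical configs give byte-identical outputs.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: plate-position (edge) effects, melt-curve
failures, amplification-curve shapes (Cq values are emitted directly),
DNA-extraction batch effects, informative missingness in the survey,
correlation between stress features and demographics, and any
non-linear LTL trajectory. Parameter-recovery results say the estimators
are consistent under the stated noise model, not that the model captures
every failure mode of a real assay.

## Problem sizes

The test suite enumerates exact-test nulls up to n = 10 against
brute-force oracles, checks Dixon and closest-pair decisions on 10,000
random triplicates, calibrates the signed-rank type-I error over 500
null cohorts of 32 subjects, measures sleep-screen power over 200
cohorts of 27 at standardized effect 1.0, recovers the cesarean effect
as the mean over five 500-subject cohorts run through the full
measurement chain (the ±0.04 window is ~1.5 SE for a single cohort, so
averaging keeps Monte-Carlo error well inside it), and evaluates the
SVR permutation screen over 100 null cohorts of 27 with 100 permutations
each. The acceptance script repeats the headline computations at the
default 46-subject scale plus three 500-subject recovery replicates.

## Known limitations

- Dixon's test is defined here only for triplicates; controls and
  unknowns with fewer finite wells fall back to a plain mean.
- The exact rank-sum branch requires tie-free data; tied small samples
  use the asymptotic approximation, which is anticonservative at very
  small n.
- The network's t-SNE layout is deterministic per seed but not stable
  across library versions; only the edge set and node annotations are
  contract, coordinates are presentation.
- The SVR permutation test controls the false-positive rate for "any
  multivariate signal" but has limited power at n ≈ 27; a negative
  result there is weak evidence of absence.
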