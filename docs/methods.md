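# Methods

`svhotspot` analyses the association between cancer genome rearrangement
breakpoints and two families of non-B DNA structure — stem-loops
(cruciform-forming inverted repeats) and G-quadruplexes — at the level of
genomic windows. This note records the models, the parameter choices that
matter, the numerical conventions, and what the synthetic-data tests do and
do not demonstrate.

## Breakpoint ingest

Structural-variant call tables list, per record, two breakpoint ends
(donor and acceptor chromosome positions, 1-based) and a *range*: the
radius in bp around the stated position that may contain the true
breakpoint. A missing range cell means the call is exact and is imputed as
0; records with a range above 10 bp on either end are discarded as too
imprecise (in ICGC-scale data ~95% of calls have range ≤ 10, which
motivates the default threshold; it is a parameter). Each surviving record
contributes **both** ends to downstream density: the intervals
`[pos − range − 1, pos + range)` in 0-based half-open coordinates, length
`2·range + 1`. Chromosome names are normalized to the un-prefixed
convention; chromosome Y and the mitochondrial contig are excluded by
default (Y because coverage of male-only, poorly assembled sequence makes
its densities incomparable; both are configurable).

## Density profiles and hotspots

The genome is tiled with disjoint windows of a chosen *aggregation level*
(defaults 10 kb–1 Mb; the last window per chromosome is truncated). The
density of a window is the number of breakpoint ends overlapping it
divided by the **total number of ends** for that cancer type, so a profile
is the conditional probability P(A|Bᵢ) of a breakpoint falling in the
window given cancer type Bᵢ. An end straddling a window boundary is
counted in both windows, so a profile's sum can exceed 1 by at most
(boundary-spanning ends)/(total ends); with ranges ≤ 10 bp and windows
≥ 10 kb this excess is ≤ ~0.2%.

The *general cancer profile* is the total-probability mixture
P(A) = Σᵢ P(A|Bᵢ)·P(Bᵢ), where P(Bᵢ) are incidence weights from a
new-cases count table. Cancers missing from the table receive the minimum
available count before normalization; weights are renormalized to sum to 1
over the cancers actually modeled (the source is silent on normalization;
renormalizing keeps the mixture a probability profile).

Hotspots at labeling percent p ∈ {1, 0.5, 0.1, 0.05, 0.01} are implemented
as deterministic top-k selection with k = floor(p/100 · N windows), ordered
by density descending with ties broken in genome order. For distinct
densities this equals "density above the (100−p)th percentile"; under ties
a strict-quantile rule is ill-defined, whereas top-k is exact and
reproducible. The quantile population is all windows genome-wide,
including zero-density windows. Labelings with fewer than 10 hotspots are
pruned (too few positives to fit), and labelings identical in (cancer,
aggregation level, label vector) are de-duplicated keeping the coarsest
labeling percent — neighboring thresholds often select identical windows.

Profile comparison uses Spearman rank correlation (average ranks under
ties; undefined below 3 paired windows, reported as NaN), hotspot-set
comparison uses the Jaccard index (defined as 0 when both sets are empty),
and region overlap reports the percentage of hotspot windows (or end
intervals) intersecting ≥ 1 bp of each region category. Promoters default
to 1 kb upstream of the gene start and downstream regions to 1 kb past the
gene end, strand-aware; these lengths are conventional, not canonical, and
are parameters.

## Structure annotation

**G-quadruplexes** use the canonical quadparser-style motif
`G{3,}([ACGT]{1,7}G{3,}){3}` — four runs of at least three guanines
separated by 1–7 bp loops — matched greedily left-to-right without
overlap; the C-run mirror is reported on the minus strand. Run length,
loop bounds and tetrad count are parameters. N never matches; soft-masked
lower-case bases are uppercased first.

**Stem-loops** are inverted repeats: two arms of stem length s flanking a
loop of length l ≤ 10 such that one arm and the reverse complement of the
other disagree at ≤ m positions. Three classes are annotated —
S6–15/1 mismatch (short), S15–30/5 (medium), S16–50/3 (long) — with
mismatches counted in the stem only (the loop is the unpaired region) and
N counting as a mismatch. Only locally maximal hits are reported: a hit is
suppressed when the stem extends outward by one base at the same center
within the class bounds and mismatch budget. The scanner exploits the fact
that outward extension preserves the inner end of the left arm: per
(inner end, loop length) the per-pair mismatch indicators accumulate
monotonically, so the maximal stem is the largest prefix under the budget,
giving an O(n · stem_max · loops) scan verified exactly against an
exhaustive (i, s, l) enumeration in the test suite. Positions that cannot
pair (past the sequence end) poison any stem containing them.

**Coverage** of a window is the length of the union of a class's
annotation intervals clipped to the window, divided by the window width.
Union coverage is invariant to splitting, duplicating or nesting
annotations, which also makes the maximal-hit suppression above a pure
efficiency choice — it cannot change coverage.

## Model pipeline

A model dataset aligns a hotspot labeling (binary target) with coverage
tracks (predictors) on the same window grid. Default predictor sets are
stem-loop = {SL_short, SL_long}, quadruplex = {G4}, and joint =
{SL_short, SL_long, G4}; medium stem-loops are computed but excluded from
the defaults because they are ~94% correlated with short stem-loops
(inclusion is a switch). Constant predictors are rejected.

Evaluation is 15× repeated stratified 3-fold cross-validation, 45 folds in
total. Per fold:

1. **Split** with per-class stratification (class counts differ by ≤ 1
   across folds), seeded.
2. **Oversample** the training folds: every minority (hotspot) index is
   duplicated the same whole number of times and the non-divisible
   remainder is drawn without replacement, giving *exactly* balanced
   classes. Test folds are never oversampled.
3. **Standardize**: z-score statistics (mean, sample sd with n−1) are
   fitted on the oversampled training data only and applied to train and
   test; fitting on the full dataset would leak test information.
   Oversample-then-standardize order is fixed (the alternative order is a
   config option for sensitivity checks).
4. **Fit** an unpenalized maximum-likelihood logistic regression (lbfgs,
   tol 1e−10). Small hotspot folds can be quasi-separable; on
   non-convergence or exploding coefficients the fit falls back to a tiny
   L2 ridge (α = 1e−6), indistinguishable at reporting precision.
5. **Record** train/test ROC AUC, coefficients, scaler, and test-set
   predicted probabilities.

All randomness expands from a single root seed through a counter-based
`SeedSequence` scheme keyed by (repeat, fold), so runs are exactly
reproducible and folds are independent of execution order.

## Evaluation metrics

ROC AUC is the Mann–Whitney probability that a random positive outscores a
random negative, ties counting ½ (exact over all pairs; verified against a
brute-force enumeration). The mean of the 45 test AUCs receives two
confidence intervals:

* **t-interval**: mean ± t₁₋α/₂,ₙ₋₁ · s/√n over the n = 45 fold values;
* **SE(W) interval**: mean ± z₁₋α/₂ · SE(W), with the Hanley–McNeil
  standard error SE(W) = √[(Q(1−Q) + (n₁−1)(Q₁−Q²) + (n₀−1)(Q₂−Q²)) /
  (n₀n₁)], Q₁ = Q/(2−Q), Q₂ = 2Q²/(1+Q), evaluated at Q = mean test AUC
  with n₀/n₁ the average test-fold class sizes. The z (rather than t)
  quantile is used for this interval; the choice is config-exposed.

A model **has power** when both intervals exclude 0.5.

Recall is evaluated at top-fraction thresholds f ∈ {0.05, …, 0.50}: the
m = round(f·n) highest-probability test observations are called positive
(score ties broken by stable input order) and recall is the fraction of
true hotspots among them. These fractions are the complements of the
predicted-probability quantiles 0.95…0.50. The **lift of recall** is the
median (over the 45 folds, not over pooled predictions) recall divided by
f: random ranking recovers ~f of the positives in the top f, so lift 1 is
random-equivalent and lift > 1 beats random. Best models per cancer are
chosen by maximum lift, ties broken by higher median test AUC then smaller
aggregation level. Cross-cancer transfer freezes a source model (median
coefficients and scaler over folds) and applies it unchanged to a target
dataset, reporting the recall/lift curve there.

### A caveat on the t-interval

The 45 fold AUCs are highly correlated: they share one dataset, so any
chance association between the fixed positives and the predictor draw
shifts *all* folds together. The t-interval's s/√45 width treats them as
independent and is therefore anticonservative for across-dataset
uncertainty: in null simulations (5,000 windows, 50 random positives) the
dataset-level AUC offset has SD ≈ 0.03–0.05 while the t half-width is
≈ 0.016, so the t-interval alone frequently excludes 0.5 even with no
signal. The SE(W) interval, whose width reflects the small positive count,
contains 0.5 essentially always under the null — which is why the power
criterion requires **both** intervals to exclude 0.5, and why the null
calibration tests assert the has-power flag (and SE-interval containment)
rather than t-interval containment.

## Synthetic data

The generator produces the full input set at desk scale so every stage
runs without downloads:

* **Genomes**: i.i.d. uniform A/C/G/T chromosomes (default 3 × 200 kb)
  with planted pattern-conforming G4 motifs and perfect inverted repeats
  (one per stem-loop class range), ≥ 50 bp apart with non-G flanks.
  Background segments that happen to contain a quadruplex motif on either
  strand are re-randomized (A/T, which can form neither G- nor C-runs)
  until none remain, so the scanner recovers planted G4 intervals
  *exactly*. Stem-loop hits are **not** suppressed in the background:
  mismatch-tolerant short inverted repeats occur at a few percent of the
  positions of any random sequence, so a stem-loop-free background does
  not exist at realistic composition; planted stem-loops are instead
  guaranteed to be contained in scan hits (a planted perfect stem is
  usually outward-extendable within the mismatch budget, so the maximal
  hit properly contains it).
* **Breakpoints**: per cancer, a window propensity vector
  ∝ exp(b₀ + Σβⱼzⱼ + ε), ε ~ N(0, noise_sd), with z the z-scored coverage
  tracks — exactly the structure the models assume, which makes parameter
  recovery a fair oracle. Each donor (default 20 per cancer) contributes
  100 records; the from-end window follows the propensity (position
  uniform within the window), the to-end is uniform genome-wide, so
  from-ends carry all the signal and both-end counting dilutes but does
  not destroy it. Range cells follow shares (zero 0.35, 1–10 0.45,
  > 10 0.05, missing-as-empty-string 0.15), emulating mostly precise calls
  with occasional outliers the range filter must remove.
* **Incidence weights**: positive counts with the last cancer omitted from
  the table, exercising the minimum-count imputation rule.

Default planted effects are β(SL_short) = +1.5, β(SL_long) = −1.0,
β(G4) = +1.0 with noise SD 0.3 — strong enough that sign recovery is
expected in nearly all seeds at 3,000 windows and 1% labeling, weak enough
that the pipeline, not the generator, does the work. What passing these
tests shows: the pipeline recovers window-level log-linear structure
effects, is calibrated at AUC 0.5 under the null, and its lift scale sits
at 1 for random ranking. What they do not show: anything about real
genomes — real coverage tracks are not smooth random fields, real
breakpoint placement is shaped by replication timing, chromatin and
mutational processes the generator does not emulate, and real cancer-type
proportions and hg19 motif densities are out of scope.

## Problem sizes and numerics

The test-suite and calibration experiments use 3,000–5,000 windows, 30–250
positives, 20 seeds, and ≤ 2 kb sequences for exact brute-force
cross-checks — sizes chosen so the whole suite completes in about a
minute while keeping every statistical assertion comfortably powered.
Numerical conventions: sample (n−1) standard deviations throughout;
hotspot ties broken in genome order; score ties at the top-fraction cut
broken by stable input order; m = round-half-up(f·n); Spearman undefined
below 3 points; degenerate inputs (empty end sets, constant predictors,
single-class folds, zero train variance) raise immediately rather than
propagating NaNs.

## Known limitations

* The t-interval anticonservativeness described above is a property of the
  evaluation scheme itself, reproduced faithfully.
* Hotspot labeling is genome-wide; per-chromosome quantiles are not
  offered.
* The stem-loop scanner reports one maximal hit per (inner end, loop);
  nested/overlapping sub-hits are deliberately suppressed, which union
  coverage makes immaterial downstream.
* Random Forest variants, SMOTE, LOOCV and train/test-split schemes are
  out of scope; repeated 3-fold CV with oversampling is the canonical
  pipeline.
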