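# Methods

## Cohort data model

Clinical items are ternary (`present` / `absent` / `missing`). In PMS
cohorts the evaluable denominator differs per item, so blank cells are
read as *missing*, never as *absent*, and every frequency is computed
over evaluated patients only (pairwise deletion throughout the package;
listwise deletion is never used). Each item carries an explicit polarity:
most are adverse, while *ability to make sentences*, *sphincter control*
and *walking by 15 months* are protective — they mark a milder course and
are reverse-scored in the severity index (switchable off via
`reverse_protective=False`).

Coordinates enter and leave the package 1-based inclusive (the clinical
reporting convention) and are held 0-based half-open internally. The
GRCh37 chr22 q terminus is fixed at 51,304,566 bp; a deletion whose
distal end is within 100 kb of it is treated as terminal even when the
input does not flag it (the literature distinguishes terminal from
interstitial but states no numeric rule; 100 kb comfortably exceeds
array-breakpoint uncertainty while staying below any interstitial
deletion's distal gap the generator emits). Patients with a deletion plus
additional rearrangements are one finding with overlay booleans, because
the analysis groups treat additional rearrangements as overlays on
deletion cases, not as separate cases.

## GFAP severity score

The score weights each item by its frequency bin: [0, 20] → 1,
(20, 35] → 2, (35, 70] → 5, (70, 100] → 10 points. The published rule is
ambiguous at the 20/35/70 boundaries; this package adopts
left-open/right-closed bins because the top weight is stated strictly as
"above 70%". The bin edges are an argument of `weight_for_frequency` for
anyone preferring the other convention. Weights default to the analyzed
cohort's own frequencies (an external frequency table can be passed
instead), and scores are raw sums — no normalization by items evaluated —
with a `normalize` option dividing by the attainable maximum over the
patient's evaluated items.

Construct validation computes, on the pairwise-complete Pearson
correlation matrix R of the 0/1 item codes (an SPSS-style default for
binary symptom panels): Bartlett's sphericity statistic
χ² = −(n − 1 − (2p + 5)/6)·ln det R with df = p(p−1)/2, taking n as the
mean pairwise-complete sample size; the KMO measure
Σr² / (Σr² + Σq²) over off-diagonal entries, with q the anti-image
partial correlations from the inverse of R; and an unrotated PCA of R
(eigenvalue loadings, explained-variance proportions). A singular R
raises with a suggestion to prune collinear items rather than silently
pseudo-inverting.

## Synthetic cohort generator

The generator's defaults are the published cohort's structure:

* **Mechanisms** drawn from the deletion-case partition
  144 simple terminal : 20 ring 22 : 8+5 unbalanced translocations
  (de novo/inherited) : 12 interstitial (denominator 189). Post-zygotic
  mosaicism is an independent overlay at rate 17/189 with fraction
  uniform on [0.10, 0.82] — in the source cohort mosaicism overlaps the
  mechanism classes (8 of the 20 rings are mosaic), so it cannot be a
  partition member. `whole_cohort_calibration()` adds a 10% *SHANK3*
  sequence-variant share for full-cohort work; the default deletion
  calibration (n = 189) is the unit of all size-based analyses.
* **Deletion sizes** from the 4-component Gaussian mixture with weights
  64:66:29:28 and (mean ± sd) 0.52 ± 0.51 / 3.39 ± 0.77 / 6.10 ± 0.69 /
  8.27 ± 0.74 Mb, truncated by *resampling* (not clipping, which would
  pile mass on the bound) into [12 kb, 10.30 Mb] — the extremes observed
  in the source cohort. Truncation shifts the first component's mean
  upward by ~0.1–0.2 Mb (about 16% of N(0.52, 0.51²) lies below 12 kb);
  recovery tests therefore compare against truncated-normal theory, and
  the smallest Ward cluster's mean is expected near 0.7 Mb, not 0.52.
* **Clinical items** are Bernoulli with a logistic size coupling,
  P(present) = expit(logit(base) + slope·(size − 3.5 Mb)), centred near
  the mixture mean so marginal prevalences stay at their published
  baselines. Fourteen size-linked items (the features reported to
  correlate with deletion size: sentences, sphincter control and
  microcephaly with negative sign; lymphedema, macrocephaly,
  renal/urogenital anomalies, seizures, abnormal MRI, deep-set eyes,
  growth >95th centile, herniae, abnormal emotional response, toe
  syndactyly, epicanthal folds with positive sign) carry slope
  ±`SIZE_SLOPE` = 0.32 logit/Mb; all other items have slope 0. The
  magnitude is a documented calibration constant chosen once so the mean
  Pearson correlation between size and GFAP across seeds is ≈ 0.33, the
  cohort-level association the score is meant to exhibit. Missingness is
  masked independently of the true state at each item's published
  missing rate.
* **Demographics**: female:male ≈ 1.1:1; age at diagnosis
  N(72 − 8·(size − 3.5), 55²) months, floored at 1 — smaller deletions
  are recognized later, reproducing the direction of the reported inverse
  size–age-at-diagnosis association; age at evaluation N(12.44, 8.7²)
  years.

One global seed spawns a named substream per stage (mechanisms, sizes,
items, masking, mosaic, demographics, overlays), so each stage is
individually reproducible and insensitive to changes in the others.

What the generator does **not** emulate: family structure (the published
germinal-mosaicism sib pair), item–item dependence beyond the shared size
coupling, informative missingness, genotyping/array noise on breakpoints,
and any non-22q13 genomic content. Tests passing on synthetic cohorts
therefore demonstrate the pipeline's correctness and calibration under
this model, not clinical validity on real cohorts.

## CNV analytics

Sizes are inclusive (+1) lengths; terminal deletions are measured from
their proximal breakpoint to the q terminus regardless of the recorded
distal coordinate. The primary analysis groups 1–7 partition findings
with mechanism precedence ring 22 > unbalanced translocation > mosaic >
interstitial > size-split terminal (threshold 0.25 Mb, the minimal
telomeric segment containing *SHANK3*; configurable). Overlay groups 8/9
come from the additional-rearrangement flags and 10 = 8 ∪ 9; overlays
attach to any primary group except the variant group 4.

Hotspot detection clusters 5′ breakpoints of all deletions and 3′
breakpoints of interstitial deletions separately with a greedy
fixed-width window (default 30 kb — the span of the reported 3′
recurrent region; minimum 3 members), anchored at breakpoints, largest
window first, ties to the smaller coordinate. Sequence-level mechanism
analysis (Alu/LINE content) is out of scope.

## MLPA model

ratio = (area/Σcontrols)_sample ÷ (area/Σcontrols)_reference. Calls use
community-standard bands (deleted < 0.70, duplicated > 1.30) with a
±0.02 indeterminate guard band, all configurable — the source protocol
relies on Coffalyser-style analysis without printing cut-offs. The
mosaic estimator assumes a homogeneous blood mixture of diploid and
deleted cells, giving expected ratio 1 − m/2 and inverse
m = clamp(2(1 − ratio), 0, 1); fractions below 0.15 are flagged as below
the practical detection limit of array-based dosage. Regional estimates
average ratios over the deleted block before inversion, suppressing
per-probe noise. Constitutional heterozygous deletions appear as m = 1.

## Trio parental origin

Strict consensus: any single contradicting marker yields `conflict`
(no genotyping-error model is assumed); `min_markers` can require more
than one concordant marker. Markers where the proband shows two alleles
are outside the deletion and are excluded automatically. Verdicts are
symmetric under swapping the parents.

## Statistical battery

* Contingency tables: Pearson chi-square without continuity correction;
  when any expected count is below 5 the p-value is replaced by an
  exact test — full enumeration of the margin lattice under the
  multivariate hypergeometric (the r×c generalization of Fisher's
  test), flagged "FET". Post hoc: pairwise column-proportion z tests,
  Bonferroni-adjusted.
* ANOVA post hocs: Bonferroni uses pairwise t on the pooled ANOVA error
  variance (df = N − k); Dunnett T3 uses Welch t with the studentized
  maximum-modulus approximation 1 − (2F_t(|t|; df_Welch) − 1)^m,
  matching the behaviour of mainstream packages; exact SMM quantiles are
  not exposed by scipy.
* Kendall tau-b uses the tie-corrected denominator (scipy's variant
  "b"), verified in tests against an O(n²) pair-counting oracle.
* Significance threshold 0.05 throughout.

### Ward clustering and cluster-count selection

Deletion sizes are clustered with Ward minimum-variance agglomeration
(scipy linkage; the merge tree is verified against a brute-force greedy
ESS-minimizing oracle at small n). The tree is cut at k = 1..k_max and
each cut is scored with the variance-offset dispersion likelihood
−Σ_c (n_c/2)·log(s²_tot + var_c) — the log-likelihood distance used by
the auto-clustering procedures of mainstream statistical software. The
offset is what makes the criterion usable on hard cuts: an unregularized
hard-assignment Gaussian likelihood is monotone increasing in k (halving
any Gaussian cluster shrinks its variance to ~0.36×, a gain of ~1 nat
per point that always beats an information-criterion penalty), so its
argmin is degenerate at k_max.

`select_k` first asks whether the data cluster at all — a 1- versus
2-component Gaussian-mixture BIC comparison (EM, deterministic seed);
unimodal data return k = 1 — then minimizes AIC (default) or BIC of the
dispersion likelihood with 2k parameters. AIC is the default because
with tens of observations per candidate cluster the heavier BIC penalty
is known to merge adjacent real components; on the default calibration
it selects k = 4 in ~96% of seeds while BIC typically stops at 3.

A singleton or zero-variance cluster is handled by the offset itself
(the total-variance term keeps the log argument positive); fully
degenerate (all-equal) data are floored and return deterministic
assignments.

### Regression screens

Each 0/1 item is regressed (simple OLS) on the chosen dependent variable
(deletion size in Mb, age at diagnosis, age at evaluation), reporting
|r|, R² and the regression F-test p-value; |r| is reported as the
"coefficient of correlation" with R² alongside, since either reading of
that phrase is possible. Constant items are skipped with a note. The
summary reports significant/tested and the α·tested count expected by
chance.

## Decision engine

The rule cascade is reconstructed from the narrative management
recommendations; each emitted action carries its source rule as the
rationale string. When several rules fire, confirmatory cytogenetics
(karyotype, FISH) precede sequencing, mirroring the narrative order. Any
state no rule covers resolves to an explicit terminal
(`diagnosis_complete` when a positive finding exists, otherwise
`workup_exhausted`), and the full bounded state space is enumerated in
tests to prove there are no dead ends and that no conclusive test is
ever re-recommended.

## Problem sizes and determinism

Default analyses run at the source-cohort scale (189 deletion cases);
parameter-recovery properties use n = 20,000, the trio-correctness
oracle 10,000 simulated trios, the MLPA round trip 500 runs of 34 region
probes (the probe count of the combined PMS-specific kits), and
criterion stability checks 20–50 seeds — sizes at which every check
completes in seconds. All randomness flows from explicit integer seeds;
reruns are byte-identical.

## Known limitations

The severity score's absolute level depends on the item catalog; no
per-patient reference values exist to anchor it, so only relative and
correlational statements are meaningful. The MLPA mosaic model ignores
tissue heterogeneity and probe-specific efficiency. The trio module does
not model genotyping error or mutation at STR markers. The decision
engine covers laboratory testing only, not clinical management.
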