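# pmscohort

Genotype–phenotype analysis toolkit for Phelan-McDermid syndrome (PMS,
22q13.3 deletion syndrome) cohorts. PMS arises from terminal or
interstitial deletions of distal 22q13 (nearly always removing *SHANK3*)
or from *SHANK3* sequence variants, and presents with developmental delay,
absent or severely delayed speech, neonatal hypotonia and autistic
behavior. Cohort studies of the syndrome revolve around a small set of
recurring computations, which this package implements as a tested,
reusable pipeline:

* **GFAP severity score** — a frequency-weighted severity index over the
  cohort's clinical items. Each item's cohort frequency *f* (percent,
  among evaluated patients) maps to a weight
  *w(f)* = 1 for *f* ∈ [0, 20], 2 for (20, 35], 5 for (35, 70] and 10 for
  *f* > 70; a patient's score is Σ *w* over adverse items present plus
  Σ *w* over protective items absent. Construct validation via Bartlett's
  sphericity test, the Kaiser–Meyer–Olkin measure and unrotated PCA on the
  item correlation matrix.
* **CNV analytics** — deletion sizes (1-based inclusive; terminal
  deletions run to the GRCh37 chr22 q terminus at 51,304,566), the
  10-group analysis classification (terminal >0.25 Mb / ≤0.25 Mb,
  interstitial, *SHANK3* variant, ring 22, unbalanced translocation,
  mosaic, plus additional-rearrangement overlays) and sliding-window
  breakpoint-hotspot detection.
* **MLPA dosage and mosaicism** — probe ratios normalized against control
  probes and a reference run; a mosaic deleted-cell fraction estimated as
  *m* = 2(1 − ratio) with a 15% detection-limit flag.
* **STR trio parental origin** — at markers inside the deletion the
  hemizygous proband's retained allele identifies the transmitting
  parent; the other parent contributed the deleted chromosome.
* **Statistical battery** — chi-square with automatic Fisher-exact
  fallback and column-proportion z post hoc tests, one-way ANOVA with
  Bonferroni or Dunnett-T3, Pearson/Spearman/Kendall tau-b, Ward
  minimum-variance clustering of deletion sizes with model-based
  cluster-count selection, and per-feature linear-regression screens.
* **Diagnostic decision engine** — the laboratory-management pathway
  (CMA first tier; karyotype after terminal deletions to rule out r(22);
  parental FISH on translocation suspicion; proband FISH for low-grade
  mosaicism; NF2 tumor surveillance for confirmed r(22); *SHANK3*
  exome/panel after a negative workup) as a deterministic rule cascade.
* **Synthetic cohort generator** — calibrated to the published cohort
  structure (mechanism proportions, a 64:66:29:28 deletion-size mixture
  at 0.52/3.39/6.10/8.27 Mb, per-item prevalences and missingness,
  mosaic overlay) with logistic size→phenotype coupling, so every stage
  is testable without patient-level data.

## Worked example

```python
from pmscohort.simulate import default_calibration, generate_cohort
from pmscohort.gfap import build_weight_table, score_cohort
from pmscohort.stats import cluster_deletion_sizes

cohort, truth = generate_cohort(default_calibration(seed=42))
weights = build_weight_table(cohort)          # cohort-frequency bin weights
scores = score_cohort(cohort, weights)
print(scores.head(3))

solutions, k = cluster_deletion_sizes(cohort)
best = next(s for s in solutions if s.k == k)
print(k, best.means.round(2), best.counts)
```

prints

```
patient_id  gfap  n_scored
   SIM0001 120.0        59
   SIM0002  90.0        60
   SIM0003  92.0        61
4 [0.74 3.46 6.46 8.86] [72 47 50 20]
```

`gfap` is the summed severity weight over each patient's evaluated items
(`n_scored` of them; higher = more severe). The Ward tree over the 189
deletion sizes, cut at the count selected by the information criterion,
recovers the four size strata the generator plants (small ~0.5 Mb,
medium ~3.4 Mb, large ~6 Mb and very large ~8.5 Mb deletions). On this
seed the Pearson correlation between deletion size and GFAP is 0.49
(p ≈ 1e-12); across seeds it averages ~0.33.

The same stages are available from the command line:

```bash
pmscohort run --n 189 --seed 42 --out-dir out/
pmscohort recommend --state case.json
```

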