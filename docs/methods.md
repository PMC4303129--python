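# Methods

This note documents the statistical models behind `methclust`, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic cohort does and does not emulate.

## β values and quality control

A CpG's methylation fraction is β = max(Cy5, 0)/(|Cy5| + |Cy3| + 100),
where Cy5 is the methylated-allele and Cy3 the unmethylated-allele
fluorescence.  Signals may be negative after background subtraction; the
max() clips a negative methylated signal to β = 0, and the +100 offset
keeps the ratio defined at low intensity and strictly below 1.

QC runs in a fixed order, each stage appending a reconciling record
(input − removed = retained) to a provenance log:

1. **Sample filter.** A sample is removed iff strictly more than 25% of
   its probes have detection p strictly greater than 1e-5.  Both
   comparisons are strict, so a sample at exactly 25% is retained.
2. **Probe filters**, in order: (a) probes flagged in the manifest as
   overlapping a SNP or repeat; (b) probes whose *median* detection p
   across retained samples exceeds 1e-5 — the per-probe aggregation of
   cellwise p-values is a package choice, since only a per-probe threshold
   is conventionally stated, and the median is insensitive to a few bad
   samples; (c) probes whose sample standard deviation (ddof = 1) across
   retained samples is strictly below 0.06.  Counts are order-dependent
   and logged per stage.
3. **Ineligible tumors** are dropped as whole columns.
4. **Replicate averaging.** Replicate hybridisations of a tumor that
   survived the sample filter are averaged probe-wise; singletons pass
   through; tumors with no surviving samples are dropped with a log entry.
   Replicate concordance is reported as pairwise Pearson r over shared
   non-missing probes (pairs with < 3 shared probes are reported missing).

Variant-probe selection keeps probes with across-tumor SD ≥ 0.2 (strictly
smaller SD excluded).  The logit transform used by the regression models
clamps β into [eps, 1 − eps] with eps = 1e-3 (configurable) before
log(β/(1−β)); the clamp handles exact 0/1 without creating infinities.

## Consensus clustering

For each k in 2…10, 100 iterations each subsample 80% of tumors without
replacement and run k-means on their untransformed variant-probe β
profiles (squared-Euclidean objective, k-means++ initialisation, one
restart, ≤ 300 Lloyd iterations, per-iteration seed drawn from the master
seed).  The consensus entry for a tumor pair is co-clustered runs divided
by co-sampled runs; pairs never co-sampled (probability ≈ 0 at these
settings) are imputed as 0 with a warning.  Final labels derive from
average-linkage hierarchical clustering of 1 − consensus cut at k — the
standard consensus-clustering convention, since the subsampled base
clusterings themselves do not define a single partition — and clusters are
renumbered 1…k by decreasing size for reproducible reporting.  Cluster
consensus is the mean consensus over unordered within-cluster pairs
(singletons defined as 1), and the chosen k is the largest whose *minimum*
per-cluster consensus is ≥ 0.9; we read "90% cluster consensus across all
clusters" as this minimum-over-clusters rule.  If no k ≥ 2 qualifies the
procedure returns k = 1 with a warning.

## Differential methylation

Rank tests operate on raw β (they are invariant to monotone transforms):
Wilcoxon rank-sum for two groups — exact enumeration null when the
combined n ≤ 12 without ties, otherwise the normal approximation with tie
and continuity corrections — and tie-corrected Kruskal-Wallis with a
χ²(g−1) reference for more groups (all-identical data returns H = 0,
p = 1).

Regression models are OLS on logit β.  The factor enters as a 0/1
indicator against a declared reference level (or as an ordinal score for
the stage and grade trend analyses); adjustment covariates are age
(continuous years) plus race, menopausal status and stage as indicator
contrasts.  Exceptions mirror the analysis design: stage models adjust for
age/race/menopause only; tumor-size models swap stage for nodal status and
vice versa; the subtype-controlled p53 model adds subtype as a 5-level
categorical.  Complete cases only, with dropped counts logged; a
rank-deficient design raises and the probe is skipped.  For speed all
probes sharing one design matrix are solved in a single vectorised
least-squares pass, verified in the tests to agree with probe-wise
statsmodels fits to ~1e-9.

BH FDR is applied within each comparison (m = probes tested in that
comparison, never pooled).  Direction is the sign of the factor
coefficient (hyper = higher methylation in the index group).  Volcano
tables pair the coefficient with −log10 of the *raw* p.  Signature
overlaps use the one-sided (enrichment) Fisher exact test against the full
probe background.  Methylation-expression correlation is plain Pearson r
with a two-sided t-based p, computed over all samples and within strata,
skipping strata with < 3 pairs.

## Survival

Kaplan-Meier product-limit curves and the standard log-rank test
(observed − expected with hypergeometric variance per distinct event time)
come from lifelines.  Cox models use Efron tie handling by default
(lifelines); Breslow is available through an in-package Newton-Raphson
maximiser of the Breslow partial likelihood (≤ 50 iterations, convergence
at step < 1e-9, diverging estimates flagged as monotone likelihood), which
also supplies the score statistic used to verify the identity between the
two-group log-rank test and the Cox score test on tie-free data.
Confidence intervals are exp(coef ± 1.96·SE); stage enters Cox models as
an ordinal 1–4 trend, grade as a 1 vs 2+3 indicator, and the reference
cluster is the largest.  Disease-specific and overall survival are
separate event indicators on the same records; competing risks are not
modelled.  The proportional-hazards screen is the scaled-Schoenfeld
residual slope test against event-time rank; the reported "global" row
sums the per-term χ² on as many degrees of freedom, a screening
approximation rather than the exact quadratic-form global test.  The check
is skipped with a diagnostic when the fit did not converge or fewer than
two distinct event times exist.

## Gene-set enrichment

Plain one-sided hypergeometric over-representation per term, after
intersecting each term with the background universe (genes surviving probe
filtering by default); genes with several CpG probes count once.  BH FDR
across terms, significance at q < 0.05.  An EASE-style conservative
variant (overlap reduced by one in the tail) is available behind a flag.
Functional-annotation clustering of terms is deliberately out of scope.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, at
the emulated study's own scale and composition; its defaults are fixed
study conditions, not tuning knobs.

* **Cluster structure.** Four latent clusters with proportions
  123/108/99/187 (≈ 0.24/0.21/0.19/0.36).  167 variant probes in four
  blocks carry per-block per-cluster mean β
  (rows = blocks): (0.15, 0.70, 0.80, 0.30), (0.30, 0.15, 0.80, 0.65),
  (0.15, 0.40, 0.80, 0.20), (0.60, 0.15, 0.85, 0.70) — cluster 3 is
  globally hypermethylated, and every block's across-cluster SD sits
  comfortably above the 0.2 variant cut.
* **β noise.** Two beta-distributed layers parameterised by (mean,
  concentration): a tumor-level biological layer (concentration 150 for
  variant probes; 30 for background probes, whose baseline means are
  uniform on [0.25, 0.75] so their SD lands between the 0.06 floor and the
  0.2 variant cut) and a measurement layer (concentration 100) shared by
  replicate samples of a tumor.  The measurement concentration is
  calibrated so replicate Pearson r exceeds 0.9, matching reported
  replicate concordance; designated low-SD probes use concentration 2000
  and no biological layer.  A beta noise model is the natural
  bounded-support choice; no specific noise law is asserted by the
  emulated study.
* **QC targets.** Probe classes are disjoint by construction: 273
  SNP/repeat-flagged, 13 detection-failed and 93 low-SD probes at the
  1000-probe default (411/19/140 at the 1505-probe study scale), 13
  QC-failing samples (30% of probes given failing detection p) and 3
  ineligible tumors (14 and 3 at study scale), 90 replicated tumors — 89
  duplicates and one triplicate.
* **Covariates** are drawn per tumor conditional on its latent cluster
  from the cluster-wise composition counts of the emulated cohort
  (e.g. 61% basal-like and 80% HR-negative in the basal-enriched cluster),
  so cluster↔phenotype associations are realistic; a 2% missingness rate
  exercises complete-case handling.  Continuous age is uniform within the
  drawn age band.
* **Survival.** Disease-specific event times are exponential with
  cluster-specific rates: baseline hazard 0.01/month for the reference
  cluster and log hazard ratios log(1.11, 1.91, 1.71, 1.00).  Censoring is
  independent exponential with rate h0·c/(1−c) for censoring fraction
  c = 0.30 (so a reference-cluster subject is censored with probability
  ≈ c).  An independent other-cause hazard of 0.002/month produces the
  overall-survival endpoint.
* **Expression.** For 50 designated variant-probe genes, expression is
  ρ·z + √(1−ρ²)·ε on a log2-like scale with ρ = −0.6 against the
  standardised tumor-level β of a representative probe; 50 control genes
  are independent noise.
* **Intensities** invert the β formula exactly (Cy3 = (1−β)·5000,
  Cy5 = β(Cy3+100)/(1−β)); β = 1 is rejected since the offset makes it
  unattainable.  Reliable detection p-values are log-uniform on
  [1e-9, 1e-6], failing cells log-uniform on [1e-4, 1e-2].

What the generator does **not** emulate: probe sequence and bisulfite
chemistry, dye bias, batch and scanner artifacts, spatially correlated
probe noise, realistic missingness mechanisms, treatment effects, or
competing-risk structure.  Passing tests therefore demonstrate that the
pipeline recovers planted statistical structure under the stated model —
not that it is robust to artifacts a real cohort would add.

## Problem sizes and numerical choices

The default cohort is 500 tumors × 1000 probes; the test suite mostly uses
reduced cohorts (90–160 tumors, 200–300 probes) with the same structure,
and the acceptance script runs the full 1505-probe / 625-sample scale,
which completes in well under a minute per stage on one CPU.  Monte-Carlo
checks use 40–200 replicates as noted in each test.  All randomness flows
from one seeded `numpy.random.Generator` per run; consensus iterations and
k-means restarts draw child seeds from it, so identical configs are
byte-reproducible.  Ties in cluster renumbering break by first occurrence;
degenerate consensus matrices (all off-diagonal entries equal) still
return a deterministic split with a warning.

## Known limitations

* The per-probe detection-failure rule (median across samples) is a
  declared convention, not a reproduction of any vendor algorithm.
* The global proportional-hazards p is a sum-of-χ² screening
  approximation, not the exact quadratic-form test.
* Enrichment ignores annotation-term topology (no GO-DAG propagation) and
  term clustering.
* Data-dependent quantities of any real cohort (specific probe lists,
  hazard ratios, log-rank p-values) are not reproduced here; the
  acceptance machinery validates arithmetic, oracle equivalence and
  planted-parameter recovery instead.
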