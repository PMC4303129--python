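# methclust

Consensus clustering and differential analysis of promoter CpG-methylation
arrays, aimed at tumor subclassification studies of the kind run on the
Illumina GoldenGate Cancer Panel I platform: several hundred tumors assayed
at ~1500 promoter CpG sites, with clinical covariates and survival
follow-up.  The package is written for epidemiologists and computational
biologists who want the whole chain — β-value QC, unsupervised subtype
discovery, covariate-adjusted differential methylation, survival
comparison and gene-set enrichment — as tested, seeded, reusable code
rather than a one-off script, together with a synthetic-cohort generator
that makes every stage verifiable without access to any restricted data.

## What it computes

**β values and QC.** Methylation at a CpG is quantified as
β = max(Cy5, 0) / (|Cy5| + |Cy3| + 100), the methylated-channel share of
total signal with an offset that stabilises low intensities.  QC removes
samples with more than 25% unreliable detection p-values (p > 1e-5), then
probes in the order: SNP/repeat-overlapping → detection-failed → standard
deviation below 0.06; replicate hybridisations of one tumor are averaged
after their Pearson concordance is checked.  Every stage's removal count is
logged in a provenance record that must reconcile exactly.

**Consensus clustering.** The most variant probes (SD ≥ 0.2 across tumors)
feed a subsampled consensus procedure: in each of 100 iterations, 80% of
tumors are sampled and k-means (squared-Euclidean) is run for k = 2…10;
entry (i, j) of the consensus matrix is the fraction of co-sampled runs in
which tumors i and j co-clustered.  Final labels come from average-linkage
hierarchical clustering of 1 − consensus, and the chosen k is the largest
whose every cluster keeps mean within-cluster consensus ≥ 0.9.

**Differential methylation.** Wilcoxon / Kruskal-Wallis rank tests on raw
β for cluster-defined groups, and OLS on logit-transformed β with
adjustment for age, race, menopausal status and stage (with the documented
exceptions for the stage, tumor-size and nodal analyses), with
Benjamini-Hochberg FDR within each comparison and hyper/hypo direction
splits, Venn overlaps, Fisher signature tests and methylation-expression
correlations.

**Survival.** Kaplan-Meier curves and log-rank tests per methylation
cluster, univariate and multivariate Cox proportional-hazards models
(Efron ties via lifelines, Breslow via an in-package Newton-Raphson
solver), and a scaled-Schoenfeld-residual proportional-hazards screen.

**Enrichment.** Hypergeometric over-representation of a gene list against
the array's post-filtering gene background, genes with several CpGs
counted once, FDR across terms, GMT input.

## Worked example

```python
from methclust.simulate import SimConfig, generate_dataset
from methclust.pipeline import PipelineConfig, run_qc
from methclust.preprocess import select_variant_probes
from methclust.cluster import ConsensusKMeans
from sklearn.metrics import adjusted_rand_score

ds = generate_dataset(SimConfig(seed=1))        # 500 tumors x 1000 probes
beta = run_qc(ds.intensities, ds.manifest, PipelineConfig(seed=1),
              ineligible_tumors=ds.ineligible_tumors)
print(beta.provenance_frame().to_string(index=False))

variant = select_variant_probes(beta)           # SD >= 0.2
model = ConsensusKMeans(random_state=1).fit(beta.beta.loc[variant].T)
truth = ds.truth_clusters.reindex(beta.samples)
print("chosen k:", model.best_k_,
      "ARI vs truth:", round(adjusted_rand_score(truth, model.labels_), 3))
```

prints

```
                stage  n_input  n_removed  n_retained
            sample_qc      591         13         578
probe_snp_repeat_flag     1000        273         727
 probe_detection_fail      727         13         714
         probe_low_sd      714         93         621
           ineligible      578          3         575
  replicate_averaging      575         91         484
chosen k: 4 ARI vs truth: 1.0
```

Reading the provenance: of 591 hybridised samples, 13 fail the 25%
detection rule; the probe filters remove 273 SNP/repeat-flagged, 13
detection-failed and 93 low-SD probes, leaving 621; 3 ineligible tumors
are dropped and the 91 extra replicate samples collapse onto their tumors,
leaving 484 tumors.  Exactly the 167 planted variant probes pass the
SD ≥ 0.2 cut, and the consensus procedure recovers the four planted
clusters perfectly.

The same stages are available from the shell:

```bash
methclust simulate --out data/ --seed 1
methclust qc --data data/ --out qc/
methclust run-all --out run/ --seed 1
```

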