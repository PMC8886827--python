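# methylator

Methylator-phenotype analysis of *SDC2*/*TFPI2* promoter methylation in
colorectal cancer.

Hypermethylated *SDC2* and *TFPI2* promoters are standard markers for
colorectal-cancer detection, yet some tumors stay low-methylated at one or
both and escape the test. This package classifies tumors into the three
methylator groups — **HH** (both genes high-methylated), **HL** (exactly
one), **LL** (neither) — and runs the group-association and expression
analyses that characterize the missed tumors. It is a library for
epigenomics analysts working with 450K-style β-value matrices,
methylation-specific PCR (MSP) Ct exports, clinical tables and RNA
read-count matrices, with a thin `mp` command-line interface.

## The method in brief

* **Scales.** β ∈ [0,1] is the methylated fraction; M = log2(β/(1−β)) its
  log-odds.
* **Target regions.** Probes with Δβ = β̄_tumor − β̄_normal ≥ 0.3 are
  chained into contiguous "methylation blocks" (gap ≤ 1 kb, non-passing
  interior probes filled in); a gene's score is the mean β over its primary
  block.
* **Threshold.** A two-component Gaussian mixture is fitted to pooled
  M-values by EM; the high/low boundary is the equal-weighted-density point
  between the peaks, mapped back to the β scale and rounded to the working
  cutoff (0.2 under the published fit).
* **Classification.** Array: high iff region β > 0.2 (strict). MSP: high
  iff mean Ct < 38 (strict), triplicates averaged with no-amplification
  replicates set to 45.00, sample invalid when mean ACTB Ct > 36.00.
* **Associations.** Fisher's exact test (full r × c enumeration with a
  seeded Monte Carlo fallback), Kruskal–Wallis, Pearson correlation, and
  MANTIS > 0.4 MSI-H grouping.
* **Expression.** Zero-inflated gene filtering, median-of-ratios size
  factors, pairwise rank-based differential expression with BH adjustment,
  group-specific DEG assignment by highest group mean, and hypergeometric
  gene-set enrichment.
* **Synthetic cohorts.** A seeded generator emits β matrices, manifests,
  clinical tables, counts and Ct exports with the statistical structure the
  analysis assumes, plus per-sample ground truth.

See `docs/methods.md` for the full model description, defaults and
limitations.

## Worked example

Generate a synthetic cohort, classify it, and test the planted
HL/left-colon association:

```python
import methylator as mp

bundle = mp.generate_cohort(mp.CohortSpec(n_tumor=300, seed=5))
calls = mp.classify_cohort(bundle.beta, bundle.manifest)
summary = mp.summarize_groups(calls, phenotype=bundle.beta.phenotype)
print(summary["group_percentages"])

fit = mp.fit_threshold(bundle.beta, seed=5)
print(round(fit.boundary_m, 3), round(fit.boundary_beta, 3))

report = mp.group_association_report(calls, bundle.clinical,
                                     variables=("location", "age"), seed=5)
print(f"{report['location']['test'].p_value:.4f} "
      f"{report['age']['test'].p_value:.2e}")
```

This prints:

```
{'HH': 91.33, 'HL': 6.67, 'LL': 2.0}
-1.097 0.319
0.0069 8.17e-15
```

Read: ~91% of the 300 synthetic tumors are HH (the generator plants
0.88/0.09/0.03 group proportions), the mixture boundary lands at β ≈ 0.32
(the generating background mixture crosses at 1/3), and both the planted
left-sided enrichment of HL tumors and the planted age differences between
groups are detected.

The same steps from a shell:

```bash
mp simulate --seed 5 --out cohort/
mp classify --beta cohort/beta.tsv --manifest cohort/manifest.tsv --out calls.tsv
mp threshold --beta cohort/beta.tsv --seed 5
mp associate --calls calls.tsv --clinical cohort/clinical.tsv --vars location,age
```

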