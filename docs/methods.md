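# Methods

## The problem

Hypermethylation of the *SDC2* and *TFPI2* promoters is widely used to
detect colorectal cancer (CRC), but a minority of tumors escapes one or
both markers. Classifying tumors by the joint promoter status — HH (both
high-methylated), HL (exactly one high), LL (both low) — and asking how the
groups differ in tumor location, age, microsatellite instability (MSI),
mutation load and expression turns the "missed sample" problem into a
reproducible analysis. This package implements that analysis as a library:
target-region selection from 450K-style probe data, a mixture-model-derived
high/low threshold, classification from array β-values or MSP Ct values,
exact association tests, and a simple built-in differential-expression
stage, all exercisable against a bundled synthetic-cohort generator.

## Models and procedures

### Scales

A probe's β-value is the methylated fraction in [0, 1]; the M-value is its
log2 odds, M = log2(β/(1−β)). β of exactly 0 or 1 is clipped to
[1e−6, 1−1e−6] before the logit, because array betas compress against the
bounds while the logit is unbounded. The two transforms are exact inverses
to 1e−12 over β ∈ [1e−6, 1−1e−6] (property-tested).

### Target regions

For each gene, per-probe Δβ = mean tumor β − mean normal β (missing values
ignored per group). Probes with Δβ ≥ 0.3 (inclusive) pass. Passing probes
are chained into "methylation blocks" when consecutive genomic distance is
at most `max_gap` (default 1000 bp — the threshold the field's promoter
probe clusters motivate; the notion of "contiguous" has no canonical
quantitative definition). Non-passing probes strictly between two passing
members of a block join it (`fill_interior`, on by default), so a block's
endpoints always pass. The primary region of a gene is the block with the
most passing probes; ties break to the larger block, then the leftmost.
The assembly is property-tested against a brute-force run enumerator.

### High/low threshold

All probe × sample M-values are pooled (tumor-only restriction available)
and fitted with a two-component univariate Gaussian mixture by EM.
Initialization is a deterministic median split — robust for well-separated
bimodality and independent of random starts; the seed only controls
optional subsampling. Convergence is a relative log-likelihood change below
1e−8 (max 500 iterations); the log-likelihood trace is asserted
non-decreasing at every iteration. Degenerate fits (component sd < 1e−6 or
weight < 1e−4) raise instead of returning garbage.

The decision boundary is the point between the two component means where
the weighted component densities are equal (the Bayes decision boundary):
the root of a quadratic, linear for equal variances, the plain midpoint for
equal variances and weights. If no root lies strictly between the means
(extreme imbalance), the weight-averaged mean is used with a logged
warning. The working β threshold is the boundary mapped through the
logistic and rounded to two decimals (a fitted 0.205 becomes the practical
cutoff 0.2); an explicit override bypasses the fit.

### Classification rules

All inequalities are strict, and boundary cases are pinned by unit tests:

* array: status high iff region-mean β > 0.2 (so β = 0.20 is low);
* MSP: status high iff mean Ct < 38 (so Ct = 38.0 is low);
* ACTB control: the sample is invalid iff mean ACTB Ct > 36.00 (36.00
  itself is valid);
* replicates with no amplification within 45 cycles are assigned Ct 45.00
  before averaging; a Ct of exactly 45.00 counts as not detected.

Control validity uses the mean of the ACTB replicates, mirroring how the
targets are averaged. Group = HH/LL when both statuses agree, HL when
exactly one is high, invalid when any status is missing or the control
failed. The four-state breakdown (which of the two genes is the single
high one) is preserved so published-style summary tables are recoverable.

### Association tests

Fisher's exact test is implemented for general r × c tables with the
probability-ordering two-sided rule: p is the total conditional
(multivariate hypergeometric) probability of margin-preserving tables whose
probability is at most that of the observed table, compared with 1e−7
relative tolerance (exact-test definitions vary across software; this is
the dominant convention and the one documented here). Enumeration is
recursive cell assignment with margin pruning; it is used when the table
total is ≤ 5000 *and* a compositions-based bound on the enumeration tree is
below `enum_cap` (default 5e5). Otherwise a margin-preserving Monte Carlo
permutation estimate with a mandatory seed is returned and flagged
(`fisher_mc`, with the (hits+1)/(reps+1) estimator). The enumeration path
is verified against the closed-form hypergeometric two-sided p on every
2 × 2 table with total ≤ 40 and against its own Monte Carlo estimate on
r × c tables.

Continuous variables use Kruskal–Wallis (midrank ties correction, χ²
reference with k−1 df; all-identical values return H = 0, p = 1 by
convention), including for two groups. Pearson correlation uses the
t-transform p with n−2 df. MANTIS scores map to MSI-H when > 0.4, MSS when
≤ 0.4. The per-gene mutation tables get Benjamini–Hochberg adjusted
p-values alongside the raw ones; raw remains primary. qPCR relative
methylation is 2^(−ΔCt) with ΔCt = target − ACTB, the direction that makes
the quantity increase with methylation (suitable for age correlations).

### Expression stage

Genes zero in strictly more than 90% of samples are removed (exactly 90%
is kept). Size factors are median-of-ratios over genes nonzero in every
sample. Pairwise comparisons between the three groups use a rank-based
two-sample test per gene on normalized counts, BH-adjusted across genes
within each pair; a gene is a DEG when any pair's adjusted p ≤ 0.05 (the
level is configurable; no fold-change criterion is imposed). This built-in
test is deliberately simple and does **not** aim to reproduce the gene
lists of negative-binomial DE engines; it exists so the group-specific
logic downstream is fully testable. A DEG is group-specific when its mean
normalized expression is strictly highest in one group; exact ties are
left unassigned (reproducible and conservative). Enrichment of a gene set
against GMT collections is the upper-tail hypergeometric p with BH across
sets, the standard replacement for web enrichment services.

## The synthetic cohort generator

Defaults mirror the study conditions: 257 tumors and 54 normals, group
proportions 0.88/0.09/0.03, HL split 3:1 toward low-SDC2/high-TFPI2,
location margins 0.32/0.19/0.35/0.14 (left/right/rectum/other), HL left
odds multiplied by 4, age baseline 60 with offsets +8 (HH) and −6 (LL)
plus a positive β–age coupling, negative-binomial nonsynonymous mutation
counts with means 10.55/3.91/7.02, MSI-H rates highest in HH with MANTIS
drawn on the matching side of 0.4, BRAF mutations concentrated in HH, 500
expression genes with 20 signature genes per group upregulated 4-fold, and
triplicate Ct = 43 − 25·β + N(0, 0.8) truncated at the 45-cycle ceiling
with ACTB near 25 (2% of samples get a deliberately failed control).

Gene-region probe betas are Beta-distributed per gene and status; the
low-status component of *TFPI2* is centred higher than *SDC2*'s,
reproducing its higher background methylation in normal tissue. The 300
background probes carry no disease signal: each is latently methylated or
unmethylated and draws M ~ N(−4, 1) or N(2, 1) (a logit-normal β), so the
pooled M histogram has a genuine two-peak structure whose analytic
equal-density crossing (M = −1, β = 1/3 under the defaults) is the ground
truth for threshold recovery. A single global seed fans out through named
`SeedSequence` substreams, so generating a subset of components never
perturbs the others, and equal seeds give byte-identical bundles.

What the generator does *not* emulate: batch effects between datasets,
missing-value structure of real arrays, probe cross-reactivity, copy-number
artefacts, realistic linkage between mutation load and expression, and the
real genomic coordinates of the 450K manifest (the 4+7 target probe ids
are real; their coordinates and the background probes are invented). Tests
passing on synthetic data therefore demonstrate the pipeline's internal
correctness and statistical calibration, not performance on real cohorts.

## Numerical choices and degenerate inputs

* β clip ε = 1e−6; boundary-β rounding to 2 decimals in the threshold
  chooser only.
* EM: median-split init, tol 1e−8 (relative), max 500 iterations,
  monotonicity asserted with a 1e−8 relative rounding allowance.
* Fisher probability comparisons: 1e−7 relative tolerance; Monte Carlo
  estimator adds one pseudo-count.
* Duplicate ids, zero margins, empty groups, all-invalid calls and
  out-of-domain scalars raise typed exceptions rather than propagating NaN.
* Missing β handling on read is a policy (`drop_probe` default, logged);
  region scoring averages the available probes and reports how many.

## Problem sizes used in the checks

The bundled end-to-end checks run at n_tumor = 300 for single-cohort
recovery, 50 cohorts for the planted-location detection rate, 200 cohorts
for the null calibration of the location test (Monte Carlo Fisher at 4000
reps), and 20 replicates of 20,000 M-values for mixture recovery — sizes at
which the binomial/EM sampling error is far below the asserted margins.

## Known limitations

* The rank-based DE stand-in has less power than shrinkage-based
  negative-binomial engines at small n and does not model dispersion.
* The exact-test Monte Carlo fallback has p-value resolution 1/(reps+1).
* The generator's detection rate for the planted HL-left association under
  the default conditions is about 0.76 (the HL group is only ~9% of
  tumors), so single-cohort location tests will miss the effect in roughly
  a quarter of runs; the calibration of the test itself is verified
  separately (empirical type-I ≈ 0.05).
* Batch correction, imputation beyond the read policies, MANTIS score
  computation and genome-wide DMR calling are out of scope; the package
  consumes those quantities as inputs.
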