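# Methods

## The statistical problem

Public tumor-expression cohorts are numerous but individually small, and
each carries its own platform and processing signature. Concatenating
samples across cohorts and testing tumor vs normal treats those
study-level signatures as biology: whenever the tumor/normal composition
differs across studies, study-level location offsets leak into the group
contrast and the pooled test's null distribution is wrong. The package
therefore works in two stages — an effect size with a variance inside
each study, then inverse-variance random-effects pooling across studies —
and ships an explicit diagnostic (the label-permutation experiment) that
demonstrates the failure mode of the pooled shortcut.

## Per-study estimators

**Standardized mean difference.** Hedges' g: Cohen's d with pooled SD on
n₁+n₂−2 degrees of freedom, multiplied by J = 1 − 3/(4(n₁+n₂−2)−1);
variance (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)). This is the common large-sample
variance (the default of the standard meta-analysis packages). Genes with
zero pooled SD are masked per study and simply contribute no estimate,
which interacts with the inclusion rules below rather than aborting a
run.

**Survival association.** Expression is standardized to mean 0, SD 1
over the study's cancer samples (the samples entering the model), so the
Cox coefficient reads "log hazard ratio per 1 SD". The univariate partial
likelihood is maximized by Newton–Raphson started at β = 0 with
step-halving whenever a step lowers the likelihood, convergence on
|Δℓ| < 1e−9, at most 50 iterations, steps clipped to |Δβ| ≤ 5. Tied event
times use the Efron correction, which matters on the coarse time grids of
real clinical tables. Constant genes (zero information) and
monotone-likelihood separation (|β| diverging) are masked/flagged. The
implementation is vectorized across genes — one set of risk-set cumsums
serves every gene per iteration — because a genome × studies analysis
needs tens of thousands of univariate fits; it agrees with lifelines to
~1e−8 including tied times.

**Correlation.** Pearson r mapped to the Fisher z scale (variance
1/(n−3)); |r| is clamped to 1 − 1e−12 before atanh so degenerate queries
(a gene against itself) stay finite. Pooling happens on the z scale and
is back-transformed for reporting.

## Inclusion rules and pooling

A study enters the tumor-vs-normal analysis only with ≥ 10 samples in
each group, and the survival/correlation analyses only with ≥ 10
informative samples; a gene is pooled only when ≥ 3 qualifying studies
contribute. Pooling uses DerSimonian–Laird τ² (closed form, the classical
default) with REML available behind a flag; CIs and p-values are Wald
(normal), with the Knapp–Hartung t-based adjustment behind a flag.
Two-sided p-values receive Bonferroni and Benjamini–Hochberg columns.
Results tables carry k, summary, se, CI, z, p, Q, τ², I² per gene.

Two small-k properties of this classical recipe are worth knowing, and
the test suite measures both. Under a true null with k ≈ 8–10 studies,
τ̂² = max(0, ·) is positive for roughly 43% of genes, which inflates SEs
and makes the p-value distribution mildly conservative (KS vs uniform
≈ 0.04; the same value is obtained from R's metafor, so it is a property
of the estimator, not of this implementation). Conversely, with genuine
heterogeneity the Wald CI undercovers slightly at small k (~0.91–0.93
instead of 0.95 at k = 8; nominal again by k ≈ 20–40 or with the
Knapp–Hartung flag). Both effects vanish in the many-study regime the
method is designed for.

## The inflation experiment

Tissue labels are permuted **within** each study (preserving each study's
group sizes; a global permutation option exists but makes the pooled
samples exchangeable and hence hides the effect). Both routes then run on
the same permuted data: a Welch t-test per gene on the concatenated
samples, and per-study Hedges' g followed by the full inclusion-rule +
meta pipeline. The report carries both p-vectors, QQ data, the fraction
significant after the chosen correction, and KS statistics against
Uniform(0,1). Welch was chosen for the pooled test as the conservative
default for variance-heterogeneous pools — the demonstrated inflation is
therefore not an artifact of an anti-conservative pooled test. The
per-study PCA check (silhouette of the tumor/normal partition in PC1–PC2)
turns the usual visual separation judgment into a score.

## Preranked enrichment

Genes are ranked by a meta summary statistic (pooled SMD for
tumor-vs-normal, z for survival), ties broken by gene id for determinism.
Hits advance the running sum by |stat|/Σ_hits|stat| (weight 1; weight 0
gives the rank-only statistic), misses retreat by 1/(N−N_hits); ES is the
signed extreme deviation and the leading edge collects the hits at or
before (after, for negative ES) the extremum. Significance uses a
gene-sampling null — n_perm random same-size subsets of the ranked
universe, shared across sets of equal size — with the plus-one estimator
over same-sign nulls, so p ≥ 1/(n_perm+1); when C(N, m) ≤ n_perm the null
is enumerated exhaustively instead of sampled. NES divides ES by the mean
|null ES| of the same sign. This sampling null trades the multilevel
refinement of fgsea's small-p machinery for simplicity; rankings and
leading edges, which downstream interpretation rests on, are unaffected.
Defaults: min size 5, max size 500, n_perm 10,000.

## Synthetic cohorts

The generator emulates the statistical structure of a harmonized
multi-study compendium, per study s and gene g:

- normal tissue: Normal(μ_g + b_{s,g}, (σ_g c_s)²) with μ_g ~ N(7, 1),
  σ_g ~ U(0.6, 1.4) (log-intensity scale), batch offsets
  b_{s,g} ~ N(0, batch_shift_sd²) and one scale c_s per study from
  batch_scale_range;
- tumors shifted by δ_{s,g} σ_g c_s with δ_{s,g} ~ N(true_smd_g, τ²) —
  δ is the study-level *realized* SMD, so estimator recovery can be
  checked against exact truth;
- survival (tumor samples): exponential proportional hazards, baseline
  0.02/month, linear predictor Σ_g true_loghr_g z_{g,i} (+ optional
  age effect), independent exponential censoring with rate matched to
  the requested censoring proportion at linear predictor 0;
- correlated gene pairs via a Gaussian copula on the residual noise
  (marginal SMD structure untouched); mutation subgroups as tumor-only
  labels with an expression shift in within-study SD units; optional
  per-study random gene dropout emulating platform panels.

Defaults encode the compendium being emulated: study sizes U(50, 200)
(≈120 samples/study, the scale of a 56-study / 6700-patient database);
per-study tumor fraction U(0.4, 0.98), because real collections span
balanced surgical cohorts to nearly tumor-only series — this composition
spread is precisely what lets shared batch offsets reach a pooled
two-group contrast (with equal fractions everywhere they cancel exactly,
and no pooled inflation would exist to demonstrate); τ²_smd = 0.05,
back-derived from the reproducibility such compendia report (median
pairwise correlation ≈ 0.75 between per-study SMD vectors given a
true-SMD spread of SD 0.5 and v̄ ≈ 0.035). One global seed feeds a
SeedSequence; each study draws from its own child stream.

What the generator does **not** model: count-level RNA-seq noise or
probe-level artifacts (values are continuous log-scale intensities, as in
a harmonized database), realistic platform gene panels (dropout is
uniform at random), correlated gene modules beyond the requested pairs,
and informative censoring. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated model, not robustness to
every failure mode of real expression data.

## Numerical and design choices

- Exponential baseline hazard in the generator: Cox estimation is
  baseline-free, so the simplest PH-consistent choice is fully general
  for testing.
- Stage covariates are encoded ordinal-numeric; age in decades; gender as
  a male-vs-female indicator.
- Reproducibility cells require ≥ 30 shared genes per study pair;
  sparser pairs are reported missing and excluded from the median.
- Gene ranks use minimum-tie ranking (a single integer answer).
- The pipeline splits by histology, writes TSV only, and records in its
  manifest an exact conservation identity per analysis:
  genes_total = genes_masked + genes_filtered + genes_in_results.
- Test and acceptance problem sizes (≤ 5000 genes, ≤ 10 studies, ≤ 200
  replicates) keep the whole suite in the minutes range on one CPU while
  leaving Monte-Carlo error well below the asserted margins.

## Known limitations

Univariate survival models only (no adjusted or time-varying effects, no
competing risks); no meta-regression or publication-bias diagnostics; no
batch-*correction* methods — the package demonstrates the pooled-analysis
failure and provides the meta-analytic alternative rather than repairing
pooled data; DL small-k conservatism/undercoverage as quantified above.
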