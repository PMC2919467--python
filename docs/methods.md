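# Methods

## Enrichment meta-analysis

A study contributes counts (candidates under the QTL or donor region,
platform probes, genome-wide selections, selected candidates). The 2×2
table against a reference of size N is

    a = selected candidates        b = selected non-candidates
    c = unselected candidates      d = N − a − b − c

with both margins treated as fixed. The odds ratio is the conditional
maximum-likelihood estimate: the ψ solving E[X | margins, ψ] = a under
Fisher's noncentral hypergeometric distribution. Two solvers are exposed:

* `method="precise"` (default of `odds_ratio_cmle`): Brent root-finding on
  log ψ ∈ [−50, 50], xtol 1e-10. This is the mathematically defined
  statistic and is what the likelihood-maximizer cross-check in the test
  suite verifies to 1e-6.
* `method="reference"` (default of `run_meta_analysis`): replicates the
  two-branch reciprocal-scale Brent iteration, with convergence tolerance
  eps^0.25, used by the R `fisher.test` implementation that historical
  tables in this literature were produced with. Its iteration error is
  ≈ ψ²·1.2e-4, invisible except in the last printed decimals of very large
  odds ratios (e.g. 26.76 vs the exact 26.77). The meta-analysis workflow
  defaults to this mode because its job is digit-level regression against
  published tables.

Boundary tables return 0 (a at the bottom of the support) or an infinity
sentinel (b or c empty with a > 0); a degenerate single-point support
returns 1. The two-sided p sums all hypergeometric point probabilities no
larger than the observed one, with a 1e-7 relative tolerance on
floating-point ties (the R convention). Genome references default to 26,404
mouse and 22,503 rat protein-coding genes.

The candidate selection rate is the unweighted per-study mean of
100·a/(a+c); studies with zero candidates are rejected rather than skipped.

## Differential-expression pipeline

Per strain, 24 arrays in six tissue×genotype groups:

* **Bead summarization** removes beads beyond 3 MADs of the median; the MAD
  is scaled by 1.4826 (normal-consistent) by default, with an unscaled mode.
  A zero MAD keeps only beads at the median. The mean and sample variance
  of the survivors are returned.
* **Quantile normalization** maps every array onto the mean empirical
  distribution; ties within an array receive the mean of the reference
  values at their tied ranks.
* **Detection filtering** keeps a probe for a tissue when ≥4 samples of
  that tissue detect it at p < 0.01; a probe enters analysis if kept in any
  tissue. Detection p-values are consumed as data (the generator produces
  them); no scanner background model is re-implemented.
* **Cell-means fit**: per-probe group means; pooled residual variance with
  ν = n − k degrees of freedom (18 in the canonical design).
* **James–Stein variance shrinkage** on the log scale: with X_g = ln σ̂²_g
  and V = trigamma(ν/2) (the sampling variance of the log of a scaled-χ²
  variance estimate), B = max(0, 1 − (G−3)V/Σ(X_g − X̄)²) and
  σ̃²_g = exp(X̄ + B(X_g − X̄)). The additive sampling bias of the log,
  digamma(ν/2) + ln(2/ν), is identical for every probe and cancels in the
  deviations; the mean is left on the observed scale, so a homogeneous
  input is a fixed point (equal inputs come back unchanged). Variances are
  floored at 1e-12 before the log.
* **Contrast F**: F_s = (c·μ̂)²/(σ̃² Σ c_k²/n_k) for the three per-tissue
  genotype contrasts (congenic − background). Substituting the raw
  variances gives exactly the classical 1-df F.
* **Permutation p**: genotype labels are permuted within tissue by default
  (preserving the tissue structure; an unrestricted mode is exposed — the
  choice is a documented design decision, since either reading of "sample
  labels" is defensible). The full fit/shrink/F pipeline is recomputed per
  permutation; the null pools all probes × permutations per contrast
  (pooling across contrasts is an option), and
  p = (1 + #{null ≥ F_s})/(1 + n_perm·G), so p > 0 always and a fixed seed
  is bit-reproducible. When fewer distinct permutations exist than
  requested, sampling is with replacement and a warning is logged.
* **FDR** is Benjamini–Hochberg (a q-value variant would also fit the
  historical description; BH is the reproducible default). Probes with
  q < 0.10 in any tissue are selected; a gene is selected if any of its
  probes is.

## Post-DE congenic analyses

* Probes with multiple genomic hits or alignment gaps > 10 kb are excluded
  from annotation; surviving probes take the maximally overlapping gene
  from the highest-priority annotation source that overlaps them.
* The SNP filter removes probes contained in the donor region that overlap
  ≥1 cataloged SNP; probes outside donor regions are never removed, because
  there both genotypes carry the reference allele and no mismatch can
  arise.
* DE genes fully contained in the donor interval are cis candidates;
  all others are trans (tallied per chromosome). Containment (both
  endpoints inside) is used for donor regions, mirroring the explicit
  IBD rule; strand is ignored throughout.
* Donor-region enrichment reuses the Fisher machinery with the array's
  gene content as reference.
* The homogeneity test conditions on expressed-gene counts in 2-Mb bins
  (genes assigned by start coordinate; bins tile the region from its
  start) and samples tables with both margins fixed — multivariate
  hypergeometric draws, equivalent to permuting gene→bin labels — scoring
  each by its conditional probability;
  p = (1 + #{tables at most as probable})/(1 + n_mc), default n_mc = 2×10⁶
  (reducible; the Monte-Carlo standard error scales as 1/√n_mc and the
  tests verify 3-SE agreement with the exact Fisher p on 2-bin
  reductions).
* IBD blocks: fixed 10-kb tiles anchored at coordinate 0 qualify with ≥10
  uninformative SNPs and zero informative ones (an informative SNP
  contradicts IBD; the strictest reading of an ambiguous rule — sliding
  windows and informative-tolerant variants were considered and rejected
  as a design decision); runs of adjacent qualifying tiles merge. A gene
  is in IBD iff one block contains both its endpoints. The IBD
  enrichment test reports how many DE genes an IBD filter would discard
  but never applies the filter.
* Allelic bias is log2(mean C57 intensity / mean CAST intensity), averaged
  on the linear scale ("average intensity"; mean-of-logs mode available),
  per detected probe, stratified donor/background × has-SNP/no-SNP, with
  two-sided rank-sum stratum comparisons (Welch t optional).
* Candidate accounting: genes with no usable probe, or only SNP-filtered
  probes, are "untested" and added back:
  raw reduction = 1 − DE/candidates; effective = 1 − (DE+untested)/candidates.

## Synthetic-data generator

The generator emulates the canonical screen's structure, not any real
mouse data: 5 chromosomes × 50 Mb × 400 genes (≈2,000 genes — the scale at
which the statistical checks below are run on one CPU), three strains with
donor regions covering 26/20/21% of one chromosome each (≈5.2/4.0/4.2% of
genes, matching the array shares of the motivating design), informative-SNP
density 3/kb outside IBD (the C57/CAST divergence scale), uninformative
density 2/kb genome-wide, IBD covering 10% of each donor region in
grid-aligned segments (observed range ~6–15%), 30% of SNPs hidden from the
catalog, cis effects ±1.0 log2 on 10% of donor genes, 20 trans targets,
binding artifact δ = 0.5 log2 against the congenic genotype at probes
overlapping any true SNP, residual noise 0.25 log2, 4 replicates.
log2 intensity = baseline + tissue effect + genotype effect − artifact +
noise; detection p is ~0 for expressed probes and uniform for the 10%
unexpressed. An optional bead level adds 10% CV bead noise with outliers.
All randomness derives from one seed via per-stage substreams.

What it does **not** model: real linkage-disequilibrium structure,
sequence-dependent hybridization thermodynamics, correlated expression
modules, array spatial artifacts, or batch effects. Passing tests therefore
show the pipeline's statistics are calibrated and its filters behave as
specified under the stated noise model — not that the biological
conclusions transfer to any particular real dataset.

## Numerical and degenerate-input choices

Tolerances: CMLE xtol 1e-10 (precise) / eps^0.25 (reference); pmf tie
tolerance 1e-7 relative; homogeneity log-probability ties 1e-7 relative.
Zero-variance probes are floored at 1e-12; a zero F-denominator yields NaN,
never an overflow; infinite odds ratios are a sentinel, never a float
overflow. Empty SNP lists give empty block lists; single-bin homogeneity
returns p = 1; degenerate IBD tables return a flagged result instead of a
test. Validation errors name the offending study or gene.

## Known limitations

* The reference-mode odds ratio intentionally reproduces a historical
  solver's tolerance; use the precise mode for new analyses.
* Permutation p-values are pooled across probes, which assumes exchangeable
  null F statistics; strong variance heterogeneity that survives shrinkage
  would miscalibrate the tails.
* The generator's detection p-values are stylized (near-zero vs uniform)
  rather than derived from a background-bead model.
* With four replicates per group, trans effects at realistic sizes are
  underpowered by design; sensitivity claims in the tests concern the
  planted 2-fold cis effects.
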